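"""Gold-standard construction from per-individual call sets.

Two independent germline callers are run on individual sequencing data; per
individual, the intersection of their normalized call sets is labelled HIGH
confidence and the symmetric difference LOW confidence. From the per-individual
sets we derive (a) theoretical pool call sets — the union of the member
individuals' variants per row/column pool — and (b) the private
("pinpointable") variants: those carried by exactly one individual in the
matrix, the only class the 2-D pooling design can uniquely assign.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .layout import MatrixLayout
from .variants import VariantKey

__all__ = [
    "HIGH",
    "LOW",
    "GoldStandard",
    "confidence_partition",
    "build_theoretical_pools",
    "private_variants",
]

HIGH = "HIGH"
LOW = "LOW"


@dataclass
class GoldStandard:
    """Per-individual truth sets with two-caller confidence labels.

    ``confidence[sample][key]`` is HIGH iff the key is in both callers' sets
    for that individual, LOW iff in exactly one. ``caller_origin`` records
    which caller(s) reported each key. Derived objects (theoretical pools,
    private sets) are always recomputed from this, never cached.
    """

    per_individual: dict[str, set[VariantKey]]
    confidence: dict[str, dict[VariantKey, str]]
    caller_origin: dict[str, dict[VariantKey, frozenset]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return sorted(self.per_individual)

    def variant_set(self, sample: str, confidence: str = "union") -> set[VariantKey]:
        """Filtered call set for one individual.

        ``confidence`` is ``"HIGH"`` (intersection only), ``"LOW"``
        (discordant only) or ``"union"`` (everything).
        """
        conf = self.confidence[sample]
        if confidence == "union":
            return set(self.per_individual[sample])
        if confidence in (HIGH, LOW):
            return {k for k, c in conf.items() if c == confidence}
        raise ValueError(f"unknown confidence filter {confidence!r}")


def confidence_partition(
    calls_a: Mapping[str, set],
    calls_b: Mapping[str, set],
) -> GoldStandard:
    """Partition two callers' per-individual sets into HIGH/LOW confidence.

    HIGH = A ∩ B, LOW = A △ B per individual; the union is preserved. Both
    inputs must already be normalized and cover the same sample ids.
    """
    if set(calls_a) != set(calls_b):
        only_a = sorted(set(calls_a) - set(calls_b))
        only_b = sorted(set(calls_b) - set(calls_a))
        raise ValueError(
            f"sample-id mismatch between callers: only in A {only_a}, only in B {only_b}"
        )
    per_individual: dict[str, set[VariantKey]] = {}
    confidence: dict[str, dict[VariantKey, str]] = {}
    origin: dict[str, dict[VariantKey, frozenset]] = {}
    for sample in calls_a:
        a, b = set(calls_a[sample]), set(calls_b[sample])
        per_individual[sample] = a | b
        conf = {}
        orig = {}
        for k in a & b:
            conf[k] = HIGH
            orig[k] = frozenset({"callerA", "callerB"})
        for k in a - b:
            conf[k] = LOW
            orig[k] = frozenset({"callerA"})
        for k in b - a:
            conf[k] = LOW
            orig[k] = frozenset({"callerB"})
        confidence[sample] = conf
        origin[sample] = orig
    return GoldStandard(per_individual, confidence, origin)


def build_theoretical_pools(
    layout: MatrixLayout,
    gold: GoldStandard,
    confidence: str = HIGH,
) -> tuple[dict[str, set], dict[str, set]]:
    """Union the member individuals' filtered call sets per pool.

    Returns ``(row_pools, col_pools)``, each mapping pool id to a deduplicated
    set of :class:`VariantKey`. A 10x10 layout yields 20 pools.
    """
    missing = [s for s in layout.samples if s not in gold.per_individual]
    if missing:
        raise ValueError(f"layout samples missing from gold standard: {missing}")
    row_pools: dict[str, set] = {}
    for r in range(1, layout.n_rows + 1):
        pool: set = set()
        for sid in layout.row_members(r):
            pool |= gold.variant_set(sid, confidence)
        row_pools[layout.row_pool_id(r)] = pool
    col_pools: dict[str, set] = {}
    for c in range(1, layout.n_cols + 1):
        pool = set()
        for sid in layout.col_members(c):
            pool |= gold.variant_set(sid, confidence)
        col_pools[layout.col_pool_id(c)] = pool
    return row_pools, col_pools


def private_variants(
    gold: GoldStandard,
    confidence: str = HIGH,
    samples: Optional[Iterable[str]] = None,
) -> dict[str, set]:
    """Variants carried by exactly one individual in the cohort.

    ``result[s]`` contains ``v`` iff ``s`` is the only individual (among
    ``samples``, default: all in the gold standard) whose filtered set
    contains ``v``.
    """
    sample_list = list(samples) if samples is not None else gold.samples
    carrier_count: Counter = Counter()
    filtered = {s: gold.variant_set(s, confidence) for s in sample_list}
    for s in sample_list:
        carrier_count.update(filtered[s])
    return {
        s: {v for v in filtered[s] if carrier_count[v] == 1} for s in sample_list
    }
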