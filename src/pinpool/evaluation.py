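"""Genotype-agnostic call-set comparison and performance metrics.

A called variant is a true positive when its normalized key is present in the
truth set for the same pool (or individual), a false positive otherwise; a
truth variant absent from the calls is a false negative. From these counts:

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    FDR         = FP / (TP + FP) = 1 - precision
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero-denominator metrics are explicitly undefined (``None``), never silently
zero; F1 is computed as ``2TP / (2TP + FP + FN)``, which is 0 when there are
no true positives but calls/truth exist. Confidence intervals use the
percentile bootstrap over call-level outcome events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pinpoint import PinpointResult, PoolCallSet
from .variants import INDEL, SNV, VariantKey

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "bootstrap_ci",
    "evaluate_pools",
    "evaluate_pinpointing",
    "round3",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalReport:
    """Confusion counts plus the four derived metrics for one stratum/scope."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    precision: Optional[float]
    fdr: Optional[float]
    f1: Optional[float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    stratum: str = "ALL"  # ALL | SNV | INDEL
    scope: str = "POOL"   # POOL | PINPOINT
    unit: str = ""        # pool id / sample id / "aggregate"


def confusion(calls: set, truth: set) -> ConfusionCounts:
    """Set-based confusion counts on normalized variant keys."""
    calls, truth = set(calls), set(truth)
    return ConfusionCounts(
        tp=len(calls & truth), fp=len(calls - truth), fn=len(truth - calls)
    )


def _metric_values(c: ConfusionCounts) -> dict[str, Optional[float]]:
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    fdr = (1.0 - prec) if prec is not None else None
    denom = 2 * c.tp + c.fp + c.fn
    f1 = (2 * c.tp / denom) if denom else None
    return {"sensitivity": sens, "precision": prec, "fdr": fdr, "f1": f1}


def metrics(
    c: ConfusionCounts, stratum: str = "ALL", scope: str = "POOL", unit: str = ""
) -> EvalReport:
    """Compute the four performance metrics from confusion counts."""
    m = _metric_values(c)
    return EvalReport(
        counts=c,
        sensitivity=m["sensitivity"],
        precision=m["precision"],
        fdr=m["fdr"],
        f1=m["f1"],
        stratum=stratum,
        scope=scope,
        unit=unit,
    )


def round3(x: Optional[float]) -> Optional[float]:
    """Round to 3 decimals, half away from zero (serialization only)."""
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


_METRIC_NAMES = ("sensitivity", "precision", "fdr", "f1")


def bootstrap_ci(
    outcomes: Sequence[str],
    metric: Union[str, Callable[[ConfusionCounts], Optional[float]]],
    n_boot: int = 1000,
    seed: int = 0,
    return_excluded: bool = False,
):
    """Percentile bootstrap CI over per-variant outcome events.

    ``outcomes`` is a sequence of tags in {"TP", "FP", "FN"}; events are
    resampled with replacement ``n_boot`` times (the metric depends only on
    category counts, so replicate counts are drawn multinomially — exactly
    equivalent and much faster), the metric recomputed per replicate, and the
    empirical 2.5/97.5 percentiles returned. Replicates where the metric is
    undefined are excluded; their count is available via ``return_excluded``.
    """
    tags = list(outcomes)
    if not tags:
        raise ValueError("bootstrap requires at least one outcome event")
    bad = set(tags) - {"TP", "FP", "FN"}
    if bad:
        raise ValueError(f"unknown outcome tags: {sorted(bad)}")
    if isinstance(metric, str):
        if metric not in _METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}")
        name = metric
        metric_fn = lambda c: _metric_values(c)[name]  # noqa: E731
    else:
        metric_fn = metric
    n = len(tags)
    counts = np.array([tags.count("TP"), tags.count("FP"), tags.count("FN")])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, counts / n, size=n_boot)
    values = []
    excluded = 0
    for tp, fp, fn in draws:
        v = metric_fn(ConfusionCounts(int(tp), int(fp), int(fn)))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            excluded += 1
        else:
            values.append(v)
    if not values:
        raise ValueError("metric undefined in every bootstrap replicate")
    lo, hi = np.percentile(values, [2.5, 97.5])
    if return_excluded:
        return (float(lo), float(hi)), excluded
    return float(lo), float(hi)


def outcome_events(calls: set, truth: set) -> list[str]:
    """Per-variant outcome tags, the resampling unit for the bootstrap."""
    calls, truth = set(calls), set(truth)
    return (
        ["TP"] * len(calls & truth)
        + ["FP"] * len(calls - truth)
        + ["FN"] * len(truth - calls)
    )


def _strata(keys: set, stratum: str) -> set:
    if stratum == "ALL":
        return keys
    return {k for k in keys if k.vtype == stratum}


def _evaluate_units(
    unit_calls: Mapping[str, set],
    unit_truth: Mapping[str, set],
    scope: str,
    strata: Sequence[str],
) -> list[EvalReport]:
    reports: list[EvalReport] = []
    for stratum in strata:
        agg = ConfusionCounts()
        for unit in sorted(unit_truth):
            c = confusion(
                _strata(unit_calls.get(unit, set()), stratum),
                _strata(unit_truth[unit], stratum),
            )
            reports.append(metrics(c, stratum=stratum, scope=scope, unit=unit))
            agg = agg + c
        reports.append(metrics(agg, stratum=stratum, scope=scope, unit="aggregate"))
    return reports


def evaluate_pools(
    pool_calls: Mapping[str, Union[PoolCallSet, set]],
    theoretical_pools: Mapping[str, set],
    strata: Sequence[str] = ("ALL", SNV, INDEL),
) -> list[EvalReport]:
    """Compare each pool's calls with its theoretical truth pool.

    Per-pool confusion counts are summed before aggregate metrics are
    computed. Each pool is an independent comparison: a variant present in
    both a row and a column pool contributes one event per pool.
    """
    missing = sorted(set(theoretical_pools) - set(pool_calls))
    if missing:
        raise ValueError(f"pools missing from calls: {missing}")
    calls = {
        pid: (c.keys() if isinstance(c, PoolCallSet) else set(c))
        for pid, c in pool_calls.items()
    }
    return _evaluate_units(calls, dict(theoretical_pools), "POOL", strata)


def evaluate_pinpointing(
    result: Union[PinpointResult, Mapping[str, set]],
    private_gold: Mapping[str, set],
    strata: Sequence[str] = ("ALL", SNV, INDEL),
) -> list[EvalReport]:
    """Compare assigned variants with the private gold standard per individual.

    A variant assigned to the wrong individual counts as a false positive
    there and a false negative at the true carrier.
    """
    assigned = result.assigned if isinstance(result, PinpointResult) else dict(result)
    return _evaluate_units(assigned, dict(private_gold), "PINPOINT", strata)


def report_table(reports: Iterable[EvalReport]) -> pd.DataFrame:
    """Tabular serialization with 3-decimal rounding (half away from zero)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "scope": r.scope,
                "unit": r.unit,
                "stratum": r.stratum,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "sensitivity": round3(r.sensitivity),
                "precision": round3(r.precision),
                "fdr": round3(r.fdr),
                "f1": round3(r.f1),
            }
        )
    return pd.DataFrame(rows)
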