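"""Variant-level simulation of 2-D overlapped pool sequencing.

The simulator emulates a pooled experiment at the level of called variants
rather than reads: a cohort of diploid individuals is drawn under
Hardy-Weinberg equilibrium from a rare-skewed allele-frequency spectrum,
arranged in an R x C matrix, and each pool's per-site sequencing is modelled
as Poisson depth with binomial alt-read sampling at the pooled allele
fraction. A call is emitted when alt reads clear both an absolute and a
fractional detection threshold; artifact calls are injected at a configurable
per-pool rate. Every emitted call carries synthetic technical annotations
drawn from class-conditional distributions (true calls versus artifacts) and a
hidden truth label, so the downstream decoder, filter and evaluation modules
can be exercised end to end without any sequencing data.

Pool depth follows from the design: a pool of m diploid individuals has
ploidy 2m, so expected site depth is ``2m * allelic_coverage`` (pools of 10 at
100x allelic coverage ~ 2000x pool coverage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .layout import COL, ROW, MatrixLayout
from .pinpoint import PoolCallSet, assign
from .variants import INDEL, SNV, AnnotatedCall, ReferenceWindow, VariantKey

__all__ = [
    "SimConfig",
    "SimTruth",
    "ANNOTATION_MODEL",
    "sample_cohort",
    "simulate_pool_calls",
    "simulate_matrix",
    "run_grid",
]

_BASES = "ACGT"

# Class-conditional annotation distributions (a modeling device, clearly
# synthetic): true calls mimic clean germline calls (high quality-by-depth and
# mapping quality, low strand bias, centred rank sums); artifacts are shifted
# toward low QD, high strand bias and extreme rank sums. Families are
# gamma(shape, scale) and normal(loc, scale).
ANNOTATION_MODEL: dict[str, dict[str, tuple]] = {
    "QD": {"true": ("gamma", 12.0, 1.5), "fp": ("gamma", 2.5, 1.6)},
    "FS": {"true": ("gamma", 1.2, 1.5), "fp": ("gamma", 3.0, 8.0)},
    "MQ": {"true": ("normal", 60.0, 0.7), "fp": ("normal", 52.0, 6.0)},
    "SOR": {"true": ("gamma", 3.0, 0.35), "fp": ("gamma", 4.0, 0.9)},
    "MQRankSum": {"true": ("normal", 0.0, 0.6), "fp": ("normal", -1.5, 1.2)},
    "ReadPosRankSum": {"true": ("normal", 0.0, 0.7), "fp": ("normal", -1.2, 1.3)},
    "BaseQRankSum": {"true": ("normal", 0.0, 0.8), "fp": ("normal", -0.8, 1.3)},
}
# Annotations that real callers frequently leave missing (rank sums need both
# ref and alt reads); drawn missing at `annotation_missing_rate`.
_OPTIONAL_ANNOTATIONS = ("MQRankSum", "ReadPosRankSum", "BaseQRankSum")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated pooling experiment.

    Defaults describe the reference design: a 10x10 matrix (pool ploidy 20)
    at 100x allelic coverage (~2000x pool coverage) over a gene-panel-sized
    set of polymorphic sites with a rare-skewed allele-frequency spectrum.
    """

    n_rows: int = 10
    n_cols: int = 10
    allelic_coverage: float = 100.0  # expected reads per haplotype copy
    n_sites: int = 500
    af_alpha: float = 0.3  # beta-distribution allele-frequency spectrum,
    af_beta: float = 8.0   # rare-skewed by default
    indel_fraction: float = 0.15
    seq_error_rate: float = 0.001  # per-base substitution error
    fp_site_rate: float = 30.0  # expected artifact call sites per pool
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.01
    # Indel detection suffers upstream of any depth model (alignment in
    # low-complexity regions); modelled as an extra per-pool miss probability
    # that grows with pool size.
    indel_miss_base: float = 0.03
    indel_miss_per_member: float = 0.008
    annotation_missing_rate: float = 0.1
    contig: str = "sim1"
    site_spacing: int = 20  # mean spacing between polymorphic sites (bp)
    contig_length: int = 100_000  # artifact sites draw from the whole contig,
    # so its length sets how often the same artifact recurs in two pools
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "af_alpha",
            "af_beta",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "indel_fraction",
            "seq_error_rate",
            "min_alt_fraction",
            "indel_miss_base",
            "indel_miss_per_member",
            "annotation_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.allelic_coverage < 0:
            raise ValueError("allelic_coverage must be >= 0")
        if self.fp_site_rate < 0:
            raise ValueError("fp_site_rate must be >= 0")
        if self.n_rows < 1 or self.n_cols < 1 or self.n_sites < 1:
            raise ValueError("matrix dimensions and n_sites must be >= 1")

    def indel_miss_probability(self, pool_size: int) -> float:
        return min(0.95, self.indel_miss_base + self.indel_miss_per_member * (pool_size - 1))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``site_table`` lists every polymorphic site as ``(key, allele_frequency,
    vtype)``; the genotype matrix stores alt-allele copies (0/1/2) per sample
    and site. ``genotypes`` exposes the sparse per-sample map form.
    """

    samples: list[str]
    keys: list[VariantKey]
    allele_frequencies: np.ndarray
    genotype_matrix: np.ndarray  # shape (n_samples, n_sites), values 0/1/2
    reference: ReferenceWindow

    @property
    def site_table(self) -> list[tuple[VariantKey, float, str]]:
        return [
            (k, float(self.allele_frequencies[i]), k.vtype)
            for i, k in enumerate(self.keys)
        ]

    @property
    def genotypes(self) -> dict[str, dict[VariantKey, int]]:
        out: dict[str, dict[VariantKey, int]] = {}
        for si, sample in enumerate(self.samples):
            row = self.genotype_matrix[si]
            nz = np.nonzero(row)[0]
            out[sample] = {self.keys[i]: int(row[i]) for i in nz}
        return out

    def carrier_counts(self) -> np.ndarray:
        return (self.genotype_matrix > 0).sum(axis=0)

    def variant_set(self, sample: str) -> set[VariantKey]:
        si = self.samples.index(sample)
        nz = np.nonzero(self.genotype_matrix[si])[0]
        return {self.keys[i] for i in nz}

    def private_variants(self) -> dict[str, set[VariantKey]]:
        """Variants with exactly one carrier, keyed by that carrier."""
        carriers = self.carrier_counts()
        private_idx = np.nonzero(carriers == 1)[0]
        out: dict[str, set[VariantKey]] = {s: set() for s in self.samples}
        for i in private_idx:
            si = int(np.nonzero(self.genotype_matrix[:, i])[0][0])
            out[self.samples[si]].add(self.keys[i])
        return out

    def pool_variant_sets(
        self, layout: MatrixLayout
    ) -> tuple[dict[str, set], dict[str, set]]:
        """Theoretical (noiseless) pool call sets under a layout."""
        idx = {s: i for i, s in enumerate(self.samples)}
        row_pools: dict[str, set] = {}
        for r in range(1, layout.n_rows + 1):
            members = [idx[s] for s in layout.row_members(r)]
            ac = self.genotype_matrix[members].sum(axis=0)
            row_pools[layout.row_pool_id(r)] = {
                self.keys[i] for i in np.nonzero(ac)[0]
            }
        col_pools: dict[str, set] = {}
        for c in range(1, layout.n_cols + 1):
            members = [idx[s] for s in layout.col_members(c)]
            ac = self.genotype_matrix[members].sum(axis=0)
            col_pools[layout.col_pool_id(c)] = {
                self.keys[i] for i in np.nonzero(ac)[0]
            }
        return row_pools, col_pools


def _generate_sites(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[VariantKey], ReferenceWindow]:
    """Draw site positions and alleles on a synthetic contig.

    Alleles are constructed already left-aligned: single-base indels never
    duplicate their anchor base, so normalization is a fixed point.
    """
    length = max(config.n_sites * config.site_spacing + 10, config.contig_length)
    seq = "".join(rng.choice(list(_BASES), size=length))
    window = ReferenceWindow(config.contig, 1, seq)
    # distinct positions, >= 2 bp apart so indel REF spans never overlap
    positions = (
        2 + np.arange(config.n_sites) * config.site_spacing
        + rng.integers(0, max(1, config.site_spacing - 2), size=config.n_sites)
    )
    is_indel = rng.random(config.n_sites) < config.indel_fraction
    keys: list[VariantKey] = []
    for pos, indel in zip(positions.tolist(), is_indel.tolist()):
        anchor = window.base(pos)
        if not indel:
            alt = _BASES[(_BASES.index(anchor) + int(rng.integers(1, 4))) % 4]
            keys.append(VariantKey(config.contig, pos, anchor, alt))
        elif rng.random() < 0.5:  # deletion of the next base
            nxt = window.base(pos + 1)
            if nxt == anchor:  # would be left-shiftable; mutate mentally to a SNV-safe del
                # pick an anchor position where the deleted base differs
                keys.append(VariantKey(config.contig, pos, anchor, _other_base(anchor, rng)))
                continue
            keys.append(VariantKey(config.contig, pos, anchor + nxt, anchor))
        else:  # insertion after the anchor
            ins = _other_base(anchor, rng)
            keys.append(VariantKey(config.contig, pos, anchor, anchor + ins))
    return keys, window


def _other_base(base: str, rng: np.random.Generator) -> str:
    return _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]


def _random_site_key(
    pos: int, window: "ReferenceWindow", rng: np.random.Generator, indel: bool
) -> Optional[VariantKey]:
    """A normalized random SNV/indel key anchored at ``pos``, or None if the
    local sequence would make the indel left-shiftable."""
    anchor = window.base(pos)
    if not indel:
        return VariantKey(window.chrom, pos, anchor, _other_base(anchor, rng))
    if rng.random() < 0.5 and pos + 1 <= window.end:
        nxt = window.base(pos + 1)
        if nxt == anchor:
            return None
        return VariantKey(window.chrom, pos, anchor + nxt, anchor)
    return VariantKey(window.chrom, pos, anchor, anchor + _other_base(anchor, rng))


def sample_cohort(
    config: SimConfig,
    sample_ids: Optional[Sequence[str]] = None,
    allele_frequencies: Optional[np.ndarray] = None,
) -> SimTruth:
    """Draw a cohort of diploid genotypes under Hardy-Weinberg equilibrium.

    Per site with allele frequency ``p``, each individual independently
    carries 0/1/2 alt copies with probabilities ``(1-p)^2, 2p(1-p), p^2``.
    Bit-reproducible under ``config.seed``. By default the cohort fills the
    configured matrix and uses the full-grid sample naming.
    """
    rng = np.random.default_rng(config.seed)
    if sample_ids is None:
        sample_ids = MatrixLayout.full_grid(config.n_rows, config.n_cols).samples
    samples = list(sample_ids)
    keys, window = _generate_sites(config, rng)
    if allele_frequencies is not None:
        afs = np.asarray(allele_frequencies, dtype=float)
        if afs.shape != (config.n_sites,):
            raise ValueError("allele_frequencies must have one entry per site")
        if np.any((afs < 0) | (afs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
    else:
        afs = rng.beta(config.af_alpha, config.af_beta, size=config.n_sites)
    genotypes = rng.binomial(2, afs[None, :], size=(len(samples), config.n_sites)).astype(np.int8)
    return SimTruth(samples, keys, afs, genotypes, window)


def _draw_annotations(
    n: int, label: str, rng: np.random.Generator, missing_rate: float
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, dists in ANNOTATION_MODEL.items():
        family, a, b = dists[label]
        if family == "gamma":
            vals = rng.gamma(a, b, size=n)
        else:
            vals = rng.normal(a, b, size=n)
        if name == "MQ":
            vals = np.clip(vals, 0.0, 60.0)
        out[name] = vals
    if missing_rate > 0:
        for name in _OPTIONAL_ANNOTATIONS:
            mask = rng.random(n) < missing_rate
            vals = out[name].astype(object)
            vals[mask] = None
            out[name] = vals
    return out


def _emit_pool(
    pool_id: str,
    axis: str,
    index: int,
    member_rows: np.ndarray,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[PoolCallSet, dict[VariantKey, int]]:
    m = len(member_rows)
    if m == 0:  # empty row/column of a partially filled matrix
        return PoolCallSet(pool_id, axis, index, {}), {}
    ploidy = 2 * m
    ac = truth.genotype_matrix[member_rows].sum(axis=0).astype(np.int64)
    n_sites = len(truth.keys)
    e = config.seq_error_rate
    depth = rng.poisson(ploidy * config.allelic_coverage, size=n_sites)
    p_alt = (ac / ploidy) * (1.0 - e) + (1.0 - ac / ploidy) * (e / 3.0)
    alt = rng.binomial(depth, p_alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    detected = (alt >= config.min_alt_reads) & (frac >= config.min_alt_fraction) & (depth > 0)

    # indel-specific detection failure (alignment artifacts upstream of depth)
    vtypes = np.array([k.vtype for k in truth.keys])
    q_indel = config.indel_miss_probability(m)
    indel_true = (vtypes == INDEL) & (ac > 0)
    dropout = indel_true & (rng.random(n_sites) < q_indel)
    detected &= ~dropout

    calls: list[AnnotatedCall] = []
    labels: dict[VariantKey, int] = {}
    det_idx = np.nonzero(detected)[0]
    is_true = ac[det_idx] > 0
    ann_true = _draw_annotations(int(is_true.sum()), "true", rng, config.annotation_missing_rate)
    ann_fp = _draw_annotations(int((~is_true).sum()), "fp", rng, config.annotation_missing_rate)
    ti = fi = 0
    for j, i in enumerate(det_idx.tolist()):
        if is_true[j]:
            ann = {name: ann_true[name][ti] for name in ann_true}
            ti += 1
            label = 1
        else:
            ann = {name: ann_fp[name][fi] for name in ann_fp}
            fi += 1
            label = 0
        d, a = int(depth[i]), int(alt[i])
        record = {
            name: (None if v is None else float(v)) for name, v in ann.items()
        }
        record["DP"] = float(d)
        record["AF"] = a / d if d else 0.0
        record["QUAL"] = float(record["QD"]) * a if record["QD"] is not None else None
        key = truth.keys[i]
        calls.append(AnnotatedCall(key, record, pool_id))
        labels[key] = label

    # artifact sites: caller false positives at positions off the truth table
    n_art = rng.poisson(config.fp_site_rate)
    if n_art > 0 and config.allelic_coverage > 0:
        ann_art = _draw_annotations(n_art, "fp", rng, config.annotation_missing_rate)
        truth_positions = {k.pos for k in truth.keys}
        made = 0
        attempts = 0
        while made < n_art and attempts < 50 * n_art:
            attempts += 1
            pos = int(rng.integers(2, len(truth.reference.seq)))
            if pos in truth_positions or pos - 1 in truth_positions:
                continue
            key = _random_site_key(pos, truth.reference, rng,
                                   indel=bool(rng.random() < config.indel_fraction))
            if key is None or key in labels:
                continue
            anchor = key.ref[0]
            d = int(rng.poisson(ploidy * config.allelic_coverage))
            if d == 0:
                continue
            a = max(config.min_alt_reads, int(rng.poisson(max(1.0, 0.02 * d))))
            ann = {name: (None if ann_art[name][made] is None else float(ann_art[name][made]))
                   for name in ann_art}
            ann["DP"] = float(d)
            ann["AF"] = min(1.0, a / d)
            ann["QUAL"] = float(ann["QD"]) * a if ann["QD"] is not None else None
            calls.append(AnnotatedCall(key, ann, pool_id))
            labels[key] = 0
            made += 1

    return PoolCallSet.from_calls(pool_id, axis, index, calls), labels


def simulate_pool_calls(
    truth: SimTruth,
    layout: MatrixLayout,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PoolCallSet], list[PoolCallSet], dict[str, dict[VariantKey, int]]]:
    """Simulate row and column pool call sets plus per-call truth labels.

    Returns ``(row_pools, col_pools, labels)`` where ``labels[pool_id][key]``
    is 1 for calls at sites genuinely carried by a pool member and 0 for
    error-driven or artifact calls.
    """
    missing = [s for s in layout.samples if s not in truth.samples]
    if missing:
        raise ValueError(f"layout samples absent from truth: {missing}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    idx = {s: i for i, s in enumerate(truth.samples)}
    row_pools: list[PoolCallSet] = []
    col_pools: list[PoolCallSet] = []
    labels: dict[str, dict[VariantKey, int]] = {}
    for r in range(1, layout.n_rows + 1):
        members = np.array([idx[s] for s in layout.row_members(r)])
        pool_id = layout.row_pool_id(r)
        pool, lab = _emit_pool(pool_id, ROW, r, members, truth, config, rng)
        row_pools.append(pool)
        labels[pool_id] = lab
    for c in range(1, layout.n_cols + 1):
        members = np.array([idx[s] for s in layout.col_members(c)])
        pool_id = layout.col_pool_id(c)
        pool, lab = _emit_pool(pool_id, COL, c, members, truth, config, rng)
        col_pools.append(pool)
        labels[pool_id] = lab
    return row_pools, col_pools, labels


def simulate_matrix(
    config: SimConfig,
) -> tuple[SimTruth, MatrixLayout, list[PoolCallSet], list[PoolCallSet], dict]:
    """Convenience: cohort + full-grid layout + pool call sets in one call."""
    truth = sample_cohort(config)
    layout = MatrixLayout.full_grid(config.n_rows, config.n_cols)
    rows, cols, labels = simulate_pool_calls(truth, layout, config)
    return truth, layout, rows, cols, labels


def _score_assignment(
    result_assigned: dict[str, set],
    private: dict[str, set],
    vtype: str,
) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for sample, truth_set in private.items():
        t = {k for k in truth_set if k.vtype == vtype}
        c = {k for k in result_assigned.get(sample, set()) if k.vtype == vtype}
        tp += len(c & t)
        fp += len(c - t)
        fn += len(t - c)
    return tp, fp, fn


def run_grid(
    matrix_sizes: Sequence[int],
    coverages: Sequence[float],
    reps: int,
    base_config: SimConfig,
) -> pd.DataFrame:
    """Sweep matrix size x allelic coverage; decode and score each replicate.

    Each configuration is simulated ``reps`` times with seeds derived from the
    base config seed; pools are decoded with :func:`pinpoint.assign` and the
    assignment is scored against the truth's private variants. Returns a
    long-format table with one row per (size, coverage, rep, vtype).
    """
    rows = []
    for si, size in enumerate(matrix_sizes):
        for ci, cov in enumerate(coverages):
            for rep in range(reps):
                ss = np.random.SeedSequence([base_config.seed, si, ci, rep])
                seed = int(ss.generate_state(1)[0] % (2**31))
                cfg = replace(
                    base_config,
                    n_rows=size,
                    n_cols=size,
                    allelic_coverage=cov,
                    seed=seed,
                )
                truth, layout, rpools, cpools, _ = simulate_matrix(cfg)
                result = assign(rpools, cpools, layout)
                private = truth.private_variants()
                for vtype in (SNV, INDEL):
                    tp, fp, fn = _score_assignment(result.assigned, private, vtype)
                    sens = tp / (tp + fn) if tp + fn else float("nan")
                    fdr = fp / (tp + fp) if tp + fp else float("nan")
                    rows.append(
                        {
                            "matrix_size": size,
                            "allelic_coverage": cov,
                            "rep": rep,
                            "seed": seed,
                            "vtype": vtype,
                            "tp": tp,
                            "fp": fp,
                            "fn": fn,
                            "sensitivity": sens,
                            "fdr": fdr,
                        }
                    )
    return pd.DataFrame(rows)
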