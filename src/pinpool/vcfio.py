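"""VCF, FASTA and sample-sheet plumbing.

VCF reading and writing go through pysam; the reference sequence is read from
an indexed FASTA via pyfaidx. Pool identity is always bound through the sample
sheet — never inferred from file names. Written VCFs carry minimal
spec-compliant headers plus a provenance line naming the producing command.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .layout import COL, ROW, LayoutError, MatrixLayout
from .pinpoint import PinpointResult, PoolCallSet
from .variants import (
    AnnotatedCall,
    NormalizationError,
    ReferenceWindow,
    VariantKey,
    normalize_record,
)

__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_pool_vcf",
    "read_individual_vcf",
    "write_calls_vcf",
    "write_keys_vcf",
    "write_reference_fasta",
    "pinpoint_report",
]

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ["sample_id", "row", "col", "row_pool", "col_pool"]

# left flank retained around a record when extracting a normalization window
_WINDOW_FLANK = 200


def read_sample_sheet(path) -> MatrixLayout:
    """Parse the TSV sample sheet into a validated :class:`MatrixLayout`.

    Required header: ``sample_id  row  col  row_pool  col_pool`` with 1-based
    integer row/col indices. Schema violations are reported with line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: sample sheet missing column(s) {missing}")
    cells: dict[tuple[int, int], str] = {}
    row_pool_by_index: dict[int, str] = {}
    col_pool_by_index: dict[int, str] = {}
    for i, rec in df.iterrows():
        line = i + 2  # header is line 1
        try:
            r, c = int(rec["row"]), int(rec["col"])
        except (TypeError, ValueError):
            raise LayoutError(f"{path}:{line}: row/col must be integers") from None
        if r < 1 or c < 1:
            raise LayoutError(f"{path}:{line}: row/col must be 1-based positive")
        sid = rec["sample_id"]
        if not isinstance(sid, str) or not sid:
            raise LayoutError(f"{path}:{line}: empty sample_id")
        if (r, c) in cells:
            raise LayoutError(f"{path}:{line}: duplicate cell ({r},{c})")
        if sid in cells.values():
            raise LayoutError(f"{path}:{line}: duplicate sample_id {sid!r}")
        for store, idx, pool in ((row_pool_by_index, r, rec["row_pool"]),
                                 (col_pool_by_index, c, rec["col_pool"])):
            if idx in store and store[idx] != pool:
                raise LayoutError(
                    f"{path}:{line}: pool name {pool!r} conflicts with "
                    f"{store[idx]!r} for index {idx}"
                )
            store[idx] = pool
        cells[(r, c)] = sid
    n_rows = max(r for r, _ in cells)
    n_cols = max(c for _, c in cells)
    row_ids = [row_pool_by_index.get(i, f"rowpool{i}") for i in range(1, n_rows + 1)]
    col_ids = [col_pool_by_index.get(j, f"colpool{j}") for j in range(1, n_cols + 1)]
    layout = MatrixLayout(n_rows, n_cols, cells, row_ids, col_ids)
    logger.info("read sample sheet %s: %dx%d, %d samples", path, n_rows, n_cols, len(cells))
    return layout


def write_sample_sheet(layout: MatrixLayout, path) -> None:
    rows = [
        {
            "sample_id": sid,
            "row": r,
            "col": c,
            "row_pool": layout.row_pool_id(r),
            "col_pool": layout.col_pool_id(c),
        }
        for (r, c), sid in sorted(layout.cells.items())
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


class _FastaWindows:
    """Reference-window provider backed by an indexed FASTA."""

    def __init__(self, fasta_path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    def window(self, chrom: str, pos: int, ref_len: int) -> ReferenceWindow:
        start = max(1, pos - _WINDOW_FLANK)
        end = min(len(self._fasta[chrom]), pos + ref_len + 5)
        seq = str(self._fasta[chrom][start - 1 : end])
        return ReferenceWindow(chrom, start, seq)


def _numeric(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _record_keys_and_annotations(
    rec, windows: Optional[_FastaWindows]
) -> list[tuple[VariantKey, dict]]:
    """Split + normalize one VCF record; per-allele annotations follow their alt."""
    alts = [a for a in (rec.alts or ()) if a is not None]
    if not alts:
        return []
    if windows is not None:
        window = windows.window(rec.chrom, rec.pos, len(rec.ref))
        keys = normalize_record(rec.chrom, rec.pos, rec.ref, alts, window)
    else:
        # no reference: split and trim only (no left shift)
        window = ReferenceWindow(rec.chrom, rec.pos, rec.ref)
        keys = []
        for alt in alts:
            from .variants import _left_align

            try:
                p, r, a = _left_align(rec.pos, rec.ref.upper(), alt.upper(), window)
            except NormalizationError:
                p, r, a = rec.pos, rec.ref.upper(), alt.upper()
            keys.append(VariantKey(rec.chrom, p, r, a))
    header_info = rec.header.info
    out = []
    for ai, (alt, key) in enumerate(zip(alts, keys)):
        ann: dict[str, Optional[float]] = {}
        for name, value in rec.info.items():
            meta = header_info.get(name)
            if meta is not None and meta.number == "A" and isinstance(value, (tuple, list)):
                ann[name] = _numeric(value[ai] if ai < len(value) else None)
            else:
                ann[name] = _numeric(value)
        if rec.qual is not None:
            ann.setdefault("QUAL", float(rec.qual))
        out.append((key, ann))
    return out


def read_pool_vcf(
    path,
    pool_id: str,
    axis: str,
    index: int,
    reference_fasta=None,
) -> PoolCallSet:
    """Read one pool's VCF into a normalized :class:`PoolCallSet`.

    Records are multi-allelic-split and (when a reference FASTA is given)
    left-aligned; technical annotations are captured from INFO and QUAL.
    """
    windows = _FastaWindows(reference_fasta) if reference_fasta else None
    calls: list[AnnotatedCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                for key, ann in _record_keys_and_annotations(rec, windows):
                    calls.append(AnnotatedCall(key, ann, pool_id))
            except NormalizationError as exc:
                raise NormalizationError(
                    f"{path}: record {rec.chrom}:{rec.pos} {rec.ref}>{rec.alts}: {exc}"
                ) from exc
    logger.info("read %d call(s) from %s for pool %s", len(calls), path, pool_id)
    return PoolCallSet.from_calls(pool_id, axis, index, calls)


def read_individual_vcf(path, reference_fasta=None) -> set[VariantKey]:
    """Read a per-individual VCF as a normalized set of variant keys.

    Records with at least one called alternate allele are kept; half calls and
    missing genotypes do not exclude a record (genotype is never identity).
    """
    windows = _FastaWindows(reference_fasta) if reference_fasta else None
    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for key, _ in _record_keys_and_annotations(rec, windows):
                keys.add(key)
    return keys


def _build_header(
    contigs: Mapping[str, int],
    info_fields: Sequence[str],
    provenance: str,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for name in info_fields:
        if name == "QUAL":
            continue
        vtype = "Integer" if name == "DP" else "Float"
        number = "A" if name.endswith("AF") else 1  # allele fraction is per-alt
        header.info.add(name, number=number, type=vtype, description=f"{name} annotation")
    header.add_line(f"##pinpool_provenance={provenance}")
    return header


def _contigs_from_keys(keys: Iterable[VariantKey]) -> dict[str, int]:
    contigs: dict[str, int] = {}
    for k in keys:
        end = k.pos + len(k.ref) + 1
        contigs[k.chrom] = max(contigs.get(k.chrom, 0), end)
    return contigs


def write_calls_vcf(
    calls: Iterable[AnnotatedCall],
    path,
    contigs: Optional[Mapping[str, int]] = None,
    provenance: str = "pinpool",
) -> None:
    """Write annotated calls as a sorted single-sample-free VCF."""
    calls = sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.key.ref, c.key.alt))
    info_fields = sorted({name for c in calls for name in c.annotations})
    if contigs is None:
        contigs = _contigs_from_keys(c.key for c in calls) or {"sim1": 1000}
    header = _build_header(contigs, info_fields, provenance)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.key.chrom,
                start=c.key.pos - 1,
                alleles=(c.key.ref, c.key.alt),
            )
            qual = c.annotations.get("QUAL")
            if qual is not None:
                rec.qual = float(qual)
            for name, value in c.annotations.items():
                if name == "QUAL" or value is None:
                    continue
                if name.endswith("AF"):
                    rec.info[name] = (float(value),)
                elif name == "DP":
                    rec.info[name] = int(value)
                else:
                    rec.info[name] = float(value)
            out.write(rec)


def write_keys_vcf(
    keys: Iterable[VariantKey],
    path,
    contigs: Optional[Mapping[str, int]] = None,
    provenance: str = "pinpool",
) -> None:
    """Write bare variant keys (deduplicated, sorted) as a VCF."""
    calls = [AnnotatedCall(k) for k in sorted(set(keys))]
    write_calls_vcf(calls, path, contigs=contigs, provenance=provenance)


def write_reference_fasta(window: ReferenceWindow, path) -> None:
    """Write a reference window (which must start at position 1) as FASTA + index."""
    if window.start != 1:
        raise ValueError("FASTA export requires a window anchored at position 1")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{window.chrom}\n")
        for i in range(0, len(window.seq), 60):
            fh.write(window.seq[i : i + 60] + "\n")
    pysam.faidx(str(path))


def pinpoint_report(
    result: PinpointResult,
    layout: MatrixLayout,
    row_pools: Sequence[PoolCallSet],
    col_pools: Sequence[PoolCallSet],
    out_dir,
    contigs: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Write one VCF of assigned variants per individual plus a summary table.

    Annotations are copied from the row pool's call; the column pool's
    observations are preserved under a ``COL_``-prefixed namespace rather than
    merged. Output naming is ``<sample_id>.pinpoint.vcf``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row_by_index = {p.index: p for p in row_pools}
    col_by_index = {p.index: p for p in col_pools}
    summary = []
    for (r, c), sample in sorted(layout.cells.items()):
        assigned = result.assigned.get(sample, set())
        calls = []
        for key in sorted(assigned):
            try:
                ann = dict(row_by_index[r].calls[key].annotations)
            except KeyError as exc:
                raise KeyError(
                    f"assigned variant {key} missing from row pool "
                    f"{row_by_index[r].pool_id} for sample {sample}"
                ) from exc
            col_call = col_by_index[c].calls.get(key)
            if col_call is not None:
                for name, value in col_call.annotations.items():
                    ann[f"COL_{name}"] = value
            calls.append(AnnotatedCall(key, ann, source_pool=row_by_index[r].pool_id))
        write_calls_vcf(
            calls,
            out_dir / f"{sample}.pinpoint.vcf",
            contigs=contigs,
            provenance=f"pinpool pinpoint sample={sample}",
        )
        summary.append({"sample_id": sample, "row": r, "col": c, "n_assigned": len(assigned)})
    df = pd.DataFrame(summary, columns=["sample_id", "row", "col", "n_assigned"])
    df.to_csv(out_dir / "pinpoint_summary.tsv", sep="\t", index=False)
    return df
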