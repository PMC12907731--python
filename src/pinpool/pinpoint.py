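"""The 2-D pool decoding ("pinpointing") algorithm.

A variant that appears in exactly one row pool and exactly one column pool is
assigned to the single individual at the intersecting cell. Variants unique
along only one axis, or unique along neither, cannot be assigned and are
reported separately — they correspond to variants shared by two or more
individuals, which the design cannot resolve without follow-up sequencing.
Genotypes are ignored throughout; all operations are on variant identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .layout import COL, ROW, LayoutError, MatrixLayout
from .variants import AnnotatedCall, VariantKey

__all__ = ["PoolCallSet", "PinpointResult", "unique_axis_variants", "assign"]

logger = logging.getLogger(__name__)


@dataclass
class PoolCallSet:
    """One pool's called variants, keyed by variant identity.

    ``axis`` is ``"row"`` or ``"col"``; ``index`` is the 1-based position of
    the pool on its axis. At most one call per variant key.
    """

    pool_id: str
    axis: str
    index: int
    calls: dict[VariantKey, AnnotatedCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in (ROW, COL):
            raise ValueError(f"axis must be 'row' or 'col', got {self.axis!r}")
        if self.index < 1:
            raise ValueError(f"pool index must be 1-based positive, got {self.index}")

    @classmethod
    def from_calls(
        cls, pool_id: str, axis: str, index: int, calls: Iterable[AnnotatedCall]
    ) -> "PoolCallSet":
        d: dict[VariantKey, AnnotatedCall] = {}
        for c in calls:
            d[c.key] = c  # last call wins; one call per key per pool
        return cls(pool_id, axis, index, d)

    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass
class PinpointResult:
    """Decoder output.

    ``assigned`` maps sample id to the variants pinpointed to it; a variant
    key appears in at most one individual's set. ``row_only``/``col_only``
    hold variants unique on one axis but not the other; ``unassigned_shared``
    holds variants unique on neither axis (plus intersections pointing at
    empty cells of a partially filled matrix).
    """

    assigned: dict[str, set[VariantKey]]
    row_only: dict[int, set[VariantKey]]
    col_only: dict[int, set[VariantKey]]
    unassigned_shared: set[VariantKey]

    @property
    def all_assigned(self) -> set[VariantKey]:
        out: set[VariantKey] = set()
        for s in self.assigned.values():
            out |= s
        return out


def unique_axis_variants(pools: Sequence[PoolCallSet], index: int) -> set[VariantKey]:
    """Variants in the pool at ``index`` that occur in no other pool on the axis."""
    axes = {p.axis for p in pools}
    if len(axes) > 1:
        raise ValueError(f"pools span multiple axes: {sorted(axes)}")
    by_index = {p.index: p for p in pools}
    if index not in by_index:
        raise KeyError(f"no pool with index {index} on axis {axes.pop() if axes else '?'}")
    others: set[VariantKey] = set()
    for i, p in by_index.items():
        if i != index:
            others |= p.keys()
    return by_index[index].keys() - others


def assign(
    row_pools: Sequence[PoolCallSet],
    col_pools: Sequence[PoolCallSet],
    layout: MatrixLayout,
) -> PinpointResult:
    """Decode pooled call sets: intersect row-unique and column-unique variants.

    For each occupied cell ``(i, j)``, the assigned set is
    ``unique_axis_variants(rows, i) ∩ unique_axis_variants(cols, j)``.
    Iteration order is irrelevant (pure set semantics).
    """
    if len(row_pools) != layout.n_rows or len(col_pools) != layout.n_cols:
        raise LayoutError(
            f"layout is {layout.n_rows}x{layout.n_cols} but got "
            f"{len(row_pools)} row pools and {len(col_pools)} column pools"
        )
    row_idx = sorted(p.index for p in row_pools)
    col_idx = sorted(p.index for p in col_pools)
    if row_idx != list(range(1, layout.n_rows + 1)) or col_idx != list(
        range(1, layout.n_cols + 1)
    ):
        raise LayoutError("pool indices do not cover the layout axes exactly once")

    unique_row = {i: unique_axis_variants(row_pools, i) for i in row_idx}
    unique_col = {j: unique_axis_variants(col_pools, j) for j in col_idx}

    assigned: dict[str, set[VariantKey]] = {}
    unassigned_shared: set[VariantKey] = set()
    claimed: set[VariantKey] = set()
    for i in row_idx:
        for j in col_idx:
            inter = unique_row[i] & unique_col[j]
            if not inter:
                continue
            sample = layout.cells.get((i, j))
            if sample is None:
                logger.warning(
                    "variants unique to row %d and column %d point at an empty cell; "
                    "recording %d variant(s) as unassigned",
                    i,
                    j,
                    len(inter),
                )
                unassigned_shared |= inter
                continue
            overlap = inter & claimed
            assert not overlap, f"variant(s) {overlap} would be assigned twice"
            assigned[sample] = inter
            claimed |= inter

    union_unique_rows: set[VariantKey] = set().union(*unique_row.values()) if unique_row else set()
    union_unique_cols: set[VariantKey] = set().union(*unique_col.values()) if unique_col else set()
    row_only = {i: unique_row[i] - union_unique_cols for i in row_idx}
    col_only = {j: unique_col[j] - union_unique_rows for j in col_idx}

    all_keys: set[VariantKey] = set()
    for p in list(row_pools) + list(col_pools):
        all_keys |= p.keys()
    unassigned_shared |= all_keys - union_unique_rows - union_unique_cols

    for sid in layout.samples:
        assigned.setdefault(sid, set())
    return PinpointResult(assigned, row_only, col_only, unassigned_shared)
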