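"""The R x C pooling matrix.

Each DNA sample occupies exactly one cell of the matrix and is therefore a
member of exactly one row pool and one column pool; any two pools overlap in
at most one individual, which is what makes private variants decodable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MatrixLayout", "LayoutError"]

ROW = "row"
COL = "col"


class LayoutError(ValueError):
    """Invalid pooling-matrix description."""


@dataclass
class MatrixLayout:
    """An R x C grid mapping (row, col) cells to sample ids.

    Indices are 1-based. Cells may be empty (partially filled matrices are
    allowed) but at least one cell must be occupied. Pool ids must be unique
    across both axes.
    """

    n_rows: int
    n_cols: int
    cells: dict[tuple[int, int], str]
    row_pool_ids: list[str] = field(default_factory=list)
    col_pool_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError("matrix must have at least one row and one column")
        if not self.row_pool_ids:
            self.row_pool_ids = [f"rowpool{i}" for i in range(1, self.n_rows + 1)]
        if not self.col_pool_ids:
            self.col_pool_ids = [f"colpool{j}" for j in range(1, self.n_cols + 1)]
        if len(self.row_pool_ids) != self.n_rows:
            raise LayoutError("need one row pool id per row")
        if len(self.col_pool_ids) != self.n_cols:
            raise LayoutError("need one column pool id per column")
        all_pool_ids = list(self.row_pool_ids) + list(self.col_pool_ids)
        if len(set(all_pool_ids)) != len(all_pool_ids):
            raise LayoutError("pool ids must be unique across both axes")
        if not self.cells:
            raise LayoutError("matrix must contain at least one sample")
        seen: dict[str, tuple[int, int]] = {}
        for (r, c), sid in self.cells.items():
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise LayoutError(f"cell ({r},{c}) outside {self.n_rows}x{self.n_cols} matrix")
            if sid in seen:
                raise LayoutError(f"sample {sid!r} occurs in cells {seen[sid]} and ({r},{c})")
            seen[sid] = (r, c)

    @classmethod
    def full_grid(cls, n_rows: int, n_cols: int, sample_prefix: str = "S") -> "MatrixLayout":
        """A fully occupied matrix with systematic sample and pool names."""
        cells = {
            (r, c): f"{sample_prefix}{r:02d}_{c:02d}"
            for r in range(1, n_rows + 1)
            for c in range(1, n_cols + 1)
        }
        return cls(n_rows, n_cols, cells)

    @property
    def samples(self) -> list[str]:
        """Sample ids in row-major cell order."""
        return [self.cells[rc] for rc in sorted(self.cells)]

    def cell_of(self, sample_id: str) -> tuple[int, int]:
        for rc, sid in self.cells.items():
            if sid == sample_id:
                return rc
        raise LayoutError(f"sample {sample_id!r} not in layout")

    def row_members(self, row: int) -> list[str]:
        return [self.cells[(row, c)] for c in range(1, self.n_cols + 1) if (row, c) in self.cells]

    def col_members(self, col: int) -> list[str]:
        return [self.cells[(r, col)] for r in range(1, self.n_rows + 1) if (r, col) in self.cells]

    def pool_members(self, axis: str, index: int) -> list[str]:
        if axis == ROW:
            return self.row_members(index)
        if axis == COL:
            return self.col_members(index)
        raise LayoutError(f"unknown axis {axis!r}")

    def row_pool_id(self, row: int) -> str:
        return self.row_pool_ids[row - 1]

    def col_pool_id(self, col: int) -> str:
        return self.col_pool_ids[col - 1]
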