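"""Nucleus-to-cell association in 3D label volumes.

Each segmented nucleus is assigned to the cell in which it resides, taken
as the cell with the largest voxel intersection (ties broken by lowest cell
ID). The assignment carries the cell's parent tissue label when a
cell→tissue table is supplied. Derived annotation sets mirror the standard
proofreading aids: cells holding more than one nucleus (duplicated nuclei —
a marker of undersegmented cells) and cells with no nucleus at all
(airspaces or missed nuclei).

A 2.5D variant links 3D nuclei to a single-layer surface cell map by
projecting each nucleus's voxel footprint along z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._overlap import as_voxels, contingency
from .volumes import LabelVolume

__all__ = [
    "OverlapTable",
    "LinkRow",
    "LinkTable",
    "overlap_table",
    "label_nuclei",
    "select_duplicated_nuclei",
    "label_cells_without_nucleus",
    "label_nuclei_surface",
]


@dataclass
class OverlapTable:
    """Voxel intersections between every co-occurring (nucleus, cell) pair."""

    entries: dict[tuple[int, int], int]  # (nucleus_id, cell_id) -> voxels
    nucleus_sizes: dict[int, int]
    cell_sizes: dict[int, int]

    def frac_of_nucleus(self, nucleus_id: int, cell_id: int) -> float:
        """|n∩c| / |n| — the share of the nucleus inside the cell."""
        return self.entries.get((nucleus_id, cell_id), 0) / self.nucleus_sizes[nucleus_id]

    def frac_of_cell(self, nucleus_id: int, cell_id: int) -> float:
        """|n∩c| / |c| — the share of the cell occupied by the nucleus."""
        return self.entries.get((nucleus_id, cell_id), 0) / self.cell_sizes[cell_id]

    def cells_of(self, nucleus_id: int) -> dict[int, int]:
        return {c: v for (n, c), v in self.entries.items() if n == nucleus_id}

    def nuclei_of(self, cell_id: int) -> dict[int, int]:
        return {n: v for (n, c), v in self.entries.items() if c == cell_id}


@dataclass
class LinkRow:
    nucleus_id: int
    cell_id: int | None  # None = unassigned (background-only overlap)
    frac_of_nucleus: float
    tissue: int | str | None = None


@dataclass
class LinkTable:
    """One row per nucleus: assigned cell (or none), fraction and tissue."""

    rows: dict[int, LinkRow]

    def assigned(self) -> dict[int, int]:
        """nucleus_id → cell_id over assigned nuclei only."""
        return {n: r.cell_id for n, r in self.rows.items() if r.cell_id is not None}

    def nuclei_by_cell(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for n, r in sorted(self.rows.items()):
            if r.cell_id is not None:
                out.setdefault(r.cell_id, []).append(n)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus_id": r.nucleus_id,
                    "cell_id": r.cell_id,
                    "tissue": r.tissue,
                    "frac_of_nucleus": r.frac_of_nucleus,
                }
                for _, r in sorted(self.rows.items())
            ],
            columns=["nucleus_id", "cell_id", "tissue", "frac_of_nucleus"],
        )


def overlap_table(
    cells: LabelVolume | np.ndarray, nuclei: LabelVolume | np.ndarray
) -> OverlapTable:
    """Exact intersection voxel counts for all co-occurring (nucleus, cell) pairs."""
    pairs_cn, cell_sizes, nucleus_sizes = contingency(cells, nuclei)
    entries = {(n, c): v for (c, n), v in pairs_cn.items()}
    return OverlapTable(entries=entries, nucleus_sizes=nucleus_sizes, cell_sizes=cell_sizes)


def _assign(
    overlaps_by_nucleus: dict[int, dict[int, int]],
    nucleus_sizes: dict[int, int],
    tissue_map: dict | None,
    min_frac: float,
) -> LinkTable:
    rows: dict[int, LinkRow] = {}
    for n, size in nucleus_sizes.items():
        cells_dict = overlaps_by_nucleus.get(n, {})
        if cells_dict:
            # max intersection, ties to the lowest cell ID
            best = min(cells_dict, key=lambda c: (-cells_dict[c], c))
            frac = cells_dict[best] / size
            if frac > min_frac:
                tissue = tissue_map.get(best) if tissue_map else None
                rows[n] = LinkRow(n, best, frac, tissue)
                continue
        rows[n] = LinkRow(n, None, 0.0, None)
    return LinkTable(rows)


def label_nuclei(
    overlap: OverlapTable,
    tissue_map: dict[int, int | str] | None = None,
    min_frac: float = 0.0,
) -> LinkTable:
    """Assign each nucleus to the cell with maximal intersection volume.

    A nucleus is left unassigned when its best overlap fraction does not
    exceed ``min_frac`` (default 0: any overlap assigns) or when it meets
    only background. Tissue labels of assigned cells are copied onto the
    nuclei when ``tissue_map`` is given; tissue entries for cell IDs absent
    from the volume are reported as a warning, never a failure.
    """
    if tissue_map:
        unknown = set(tissue_map) - set(overlap.cell_sizes)
        if unknown:
            warnings.warn(
                f"tissue map references {len(unknown)} unknown cell IDs "
                f"(e.g. {sorted(unknown)[:5]})",
                stacklevel=2,
            )
    by_nucleus: dict[int, dict[int, int]] = {}
    for (n, c), v in overlap.entries.items():
        by_nucleus.setdefault(n, {})[c] = v
    return _assign(by_nucleus, overlap.nucleus_sizes, tissue_map, min_frac)


def select_duplicated_nuclei(link: LinkTable) -> dict[int, list[int]]:
    """Cells with two or more assigned nuclei — a cell segmentation error marker."""
    return {c: ns for c, ns in link.nuclei_by_cell().items() if len(ns) >= 2}


def label_cells_without_nucleus(
    link: LinkTable, cells: LabelVolume | np.ndarray
) -> set[int]:
    """All cell IDs present in the volume with no assigned nucleus (e.g. airspaces)."""
    v = as_voxels(cells)
    present = {int(i) for i in np.unique(v) if i > 0}
    occupied = set(link.nuclei_by_cell())
    return present - occupied


def label_nuclei_surface(
    surface_cells: np.ndarray, nuclei: LabelVolume | np.ndarray
) -> LinkTable:
    """Link 3D nuclei to a 2.5D surface cell map by z-projected footprints.

    Each nucleus's voxels are flattened along z to a (y, x) footprint (each
    pixel counted once, however many voxels project onto it); the nucleus is
    assigned to the surface cell covering the largest part of that
    footprint. Nuclei whose footprint meets only background stay unassigned.
    """
    surface_cells = np.asarray(surface_cells)
    nv = as_voxels(nuclei)
    if surface_cells.ndim != 2 or surface_cells.shape != nv.shape[1:]:
        raise ValueError(
            f"surface map shape {surface_cells.shape} does not match the "
            f"(y, x) extent {nv.shape[1:]} of the nuclei volume"
        )
    zz, yy, xx = np.nonzero(nv)
    ids = nv[zz, yy, xx].astype(np.int64)
    ny, nx = surface_cells.shape
    # unique (nucleus, y, x) triples = the projected footprints
    keys = np.unique(ids * (ny * nx) + yy * nx + xx)
    f_ids = keys // (ny * nx)
    f_y = (keys % (ny * nx)) // nx
    f_x = keys % nx
    under = surface_cells[f_y, f_x].astype(np.int64)

    footprint_sizes: dict[int, int] = {
        int(i): int(c) for i, c in zip(*np.unique(f_ids, return_counts=True))
    }
    by_nucleus: dict[int, dict[int, int]] = {}
    hit = under > 0
    for n, c in zip(f_ids[hit], under[hit]):
        d = by_nucleus.setdefault(int(n), {})
        d[int(c)] = d.get(int(c), 0) + 1
    return _assign(by_nucleus, footprint_sizes, None, 0.0)
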