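"""Seeded synthetic 3D tissues with exact ground truth.

The generator builds the data regime the rest of the toolkit consumes,
without any microscopy:

* **cells** — a nearest-seed (Voronoi) tessellation of an ellipsoidal organ
  mask, with anisotropy-aware distances so cells are convex space-filling
  polyhedra in physical units; voxels outside the organ are background;
* **layers** — concentric tissue layers (outermost first, e.g. L1/L2/L3)
  assigned by the normalized ellipsoidal radius of each cell seed, each
  layer carrying its own target N/C ratio;
* **nuclei** — one per cell (minus a stated nucleus-free fraction standing
  in for airspaces), grown as the target number of interior cell voxels
  nearest a jittered center under a random per-axis ellipsoidal metric, so
  nuclei are clipped ellipsoids strictly inside their cell and the realized
  per-cell N/C ratio is exact up to voxel rounding;
* **boundary pmap** — near 1 on cell walls and the organ surface, near 0
  inside cells, optionally with selected walls scaled down to emulate faint
  cell-wall staining (the classic cause of undersegmentation);
* **corruption** — controlled false merges (adjacent mono-nucleate cell
  pairs relabeled to one ID) and false splits (a mono-nucleate cell cut by
  a plane through its nucleus centroid), each recorded for audit.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .volumes import LabelVolume, ProbabilityVolume, VoxelSpacing

__all__ = [
    "CellTruth",
    "CorruptionRecord",
    "SyntheticTissue",
    "make_tissue",
    "make_boundary_pmap",
    "corrupt_segmentation",
]


@dataclass
class CellTruth:
    """Generator-recorded ground truth for one cell."""

    cell_id: int
    layer: str
    nucleus_id: int | None  # None = generated nucleus-free (airspace stand-in)
    target_nc: float | None
    realized_nc: float | None
    offset_um: np.ndarray | None  # realized nucleus-centroid − cell-centroid, (z, y, x) µm


@dataclass
class CorruptionRecord:
    """Audit trail of injected segmentation errors."""

    merges: list[dict] = field(default_factory=list)  # {"cells": [a, b], "merged_id": m}
    splits: list[dict] = field(default_factory=list)  # {"cell": c, "new_ids": [c, k], "nucleus": n}

    @property
    def merged_ids(self) -> list[int]:
        return [m["merged_id"] for m in self.merges]


@dataclass
class SyntheticTissue:
    cells: LabelVolume
    nuclei: LabelVolume
    pmap: ProbabilityVolume
    truth: list[CellTruth]
    corruption: CorruptionRecord | None = None

    def nucleus_map(self) -> dict[int, int]:
        """Ground-truth nucleus_id → cell_id over nucleate cells."""
        return {t.nucleus_id: t.cell_id for t in self.truth if t.nucleus_id is not None}

    def nucleus_free_cells(self) -> set[int]:
        return {t.cell_id for t in self.truth if t.nucleus_id is None}

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            off = t.offset_um if t.offset_um is not None else (np.nan,) * 3
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "layer": t.layer,
                    "nucleus_id": t.nucleus_id,
                    "target_nc": t.target_nc,
                    "realized_nc": t.realized_nc,
                    "offset_z_um": off[0],
                    "offset_y_um": off[1],
                    "offset_x_um": off[2],
                }
            )
        return pd.DataFrame(rows)


def _layer_targets(nc_targets) -> dict[str, float]:
    if isinstance(nc_targets, Mapping):
        return {str(k): float(v) for k, v in nc_targets.items()}
    if isinstance(nc_targets, (int, float)):
        nc_targets = [nc_targets]
    return {f"L{i + 1}": float(v) for i, v in enumerate(nc_targets)}


def _sample_seeds(
    rng: np.random.Generator,
    inside_phys: np.ndarray,
    n_cells: int,
    voxel_volume: float,
) -> np.ndarray:
    """Pick n_cells seed points among organ voxels with a minimum-separation
    greedy pass; falls back to unconstrained sampling if the organ is tight."""
    # min separation scaled to the physical mean cell volume
    min_sep = 0.7 * (len(inside_phys) * voxel_volume / n_cells) ** (1 / 3)
    order = rng.permutation(len(inside_phys))
    chosen: list[int] = []
    pts = np.empty((0, 3))
    budget = 100 * n_cells
    for idx in order[:budget]:
        p = inside_phys[idx]
        if len(pts) == 0 or np.min(np.einsum("ij,ij->i", pts - p, pts - p)) >= min_sep**2:
            chosen.append(int(idx))
            pts = np.vstack([pts, p])
            if len(chosen) == n_cells:
                break
    if len(chosen) < n_cells:
        taken = set(chosen)
        for idx in order:
            if int(idx) not in taken:
                chosen.append(int(idx))
                if len(chosen) == n_cells:
                    break
    return inside_phys[np.asarray(chosen)]


def make_tissue(
    shape: tuple[int, int, int] = (64, 64, 64),
    n_cells: int = 100,
    nc_targets: float | Sequence[float] | Mapping[str, float] = 0.25,
    spacing: VoxelSpacing = VoxelSpacing(0.25, 0.25, 0.25),
    nucleus_free_fraction: float = 0.0,
    nc_cv: float = 0.25,
    jitter_frac: float = 0.15,
    pmap_sigma: float = 0.7,
    seed: int = 0,
) -> SyntheticTissue:
    """Generate a space-filling synthetic tissue with known ground truth.

    ``nc_targets`` maps concentric layers (outermost first) to target N/C
    ratios; per-cell targets are drawn around the layer target with
    coefficient of variation ``nc_cv`` to emulate biological spread.
    ``jitter_frac`` displaces each nucleus center from its cell centroid by
    up to that fraction of the cell's equivalent radius; the realized
    centroid offset is recorded per cell.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    targets = _layer_targets(nc_targets)
    if any(v > 0.9 for v in targets.values()):
        raise ValueError("N/C target > 0.9 is infeasible on a voxel grid")
    rng = np.random.default_rng(seed)
    sp = spacing.as_array()

    grid = np.indices(shape).reshape(3, -1).T  # (z, y, x) voxel indices
    phys = (grid + 0.5) * sp
    center = np.asarray(shape) * sp / 2
    semi = np.asarray(shape) * sp * 0.48
    r2 = (((phys - center) / semi) ** 2).sum(axis=1)
    inside = r2 <= 1.0
    if inside.sum() / n_cells < 64:
        raise ValueError("grid too small: mean cell volume would be < 64 voxels")

    seeds_phys = _sample_seeds(rng, phys[inside], n_cells, spacing.voxel_volume)
    labels_flat = np.zeros(len(phys), dtype=np.int32)
    _, nearest = cKDTree(seeds_phys).query(phys[inside], k=1, workers=1)
    labels_flat[inside] = nearest + 1
    cells_vox = labels_flat.reshape(shape)

    # layers by normalized ellipsoidal radius of the seed: outermost = first target
    seed_r = np.sqrt((((seeds_phys - center) / semi) ** 2).sum(axis=1))
    layer_names = list(targets)
    n_layers = len(layer_names)
    ranks = np.argsort(np.argsort(-seed_r))  # 0 = outermost
    layer_of = {
        cid: layer_names[min(ranks[cid - 1] * n_layers // n_cells, n_layers - 1)]
        for cid in range(1, n_cells + 1)
    }

    n_free = int(round(nucleus_free_fraction * n_cells))
    free_cells = set(rng.choice(np.arange(1, n_cells + 1), size=n_free, replace=False).tolist())

    nucleate = [c for c in range(1, n_cells + 1) if c not in free_cells]
    nucleus_ids = rng.permutation(len(nucleate)) + 1  # shuffled, contiguous IDs

    nuclei_vox = np.zeros(shape, dtype=np.int32)
    truth: list[CellTruth] = []
    struct = ndi.generate_binary_structure(3, 1)
    slices = ndi.find_objects(cells_vox)

    for cid in range(1, n_cells + 1):
        if cid in free_cells:
            truth.append(CellTruth(cid, layer_of[cid], None, None, None, None))
            continue
        nid = int(nucleus_ids[nucleate.index(cid)])
        box = slices[cid - 1]
        sub = cells_vox[box] == cid
        cell_count = int(sub.sum())
        interior = ndi.binary_erosion(sub, structure=struct, border_value=0)
        if not interior.any():
            interior = sub  # degenerate sliver cell; keep it nucleate anyway
        t_layer = targets[layer_of[cid]]
        t_cell = float(np.clip(rng.normal(t_layer, nc_cv * t_layer), 0.05, 0.6))
        n_target = max(1, min(int(round(t_cell * cell_count)), int(interior.sum())))

        coords = np.argwhere(interior)  # box-local voxel indices
        coords_phys = (coords + [s.start for s in box] + 0.5) * sp
        # full-cell centroid is the jitter reference
        cell_coords = np.argwhere(sub)
        cell_centroid = (cell_coords + [s.start for s in box] + 0.5).mean(axis=0) * sp
        eq_radius = (3 * cell_count * spacing.voxel_volume / (4 * np.pi)) ** (1 / 3)
        jitter = rng.normal(size=3)
        jitter *= (rng.uniform(0, jitter_frac) * eq_radius) / np.linalg.norm(jitter)
        nuc_center = cell_centroid + jitter

        axis_scale = rng.uniform(0.75, 1.3, size=3)
        axis_scale /= axis_scale.prod() ** (1 / 3)  # volume-neutral ellipsoidal metric
        d = (((coords_phys - nuc_center) / axis_scale) ** 2).sum(axis=1)
        pick = coords[np.argpartition(d, n_target - 1)[:n_target]]
        gz = pick[:, 0] + box[0].start
        gy = pick[:, 1] + box[1].start
        gx = pick[:, 2] + box[2].start
        nuclei_vox[gz, gy, gx] = nid

        realized_nc = n_target / cell_count
        nuc_centroid = (np.stack([gz, gy, gx], axis=1) + 0.5).mean(axis=0) * sp
        truth.append(
            CellTruth(
                cid, layer_of[cid], nid, t_cell, realized_nc,
                np.asarray(nuc_centroid - cell_centroid),
            )
        )

    cells = LabelVolume(cells_vox, spacing)
    pmap = make_boundary_pmap(cells, sigma=pmap_sigma)
    return SyntheticTissue(
        cells=cells,
        nuclei=LabelVolume(nuclei_vox, spacing),
        pmap=pmap,
        truth=truth,
    )


def make_boundary_pmap(
    cells: LabelVolume,
    sigma: float = 0.7,
    weak_walls: set[tuple[int, int]] | None = None,
    weak_factor: float = 0.0,
) -> ProbabilityVolume:
    """Boundary-probability map: ~1 on walls/organ surface, ~0 inside cells.

    ``weak_walls`` lists unordered cell-ID pairs whose shared wall is scaled
    by ``weak_factor`` before smoothing — with factor 0 the wall vanishes,
    emulating locally faint cell-wall staining.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    v = cells.voxels
    weak = {tuple(sorted(p)) for p in (weak_walls or set())}
    wall = np.zeros(v.shape, dtype=np.float32)
    for axis in range(3):
        a = v.take(range(v.shape[axis] - 1), axis=axis)
        b = v.take(range(1, v.shape[axis]), axis=axis)
        diff = (a != b) & ((a > 0) | (b > 0))
        strength = np.where(diff, 1.0, 0.0).astype(np.float32)
        if weak:
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            for (p, q) in weak:
                on_wall = diff & (lo == p) & (hi == q)
                strength[on_wall] = weak_factor
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, v.shape[axis] - 1)
        sl_b[axis] = slice(1, v.shape[axis])
        np.maximum(wall[tuple(sl_a)], strength, out=wall[tuple(sl_a)])
        np.maximum(wall[tuple(sl_b)], strength, out=wall[tuple(sl_b)])
    if sigma > 0:
        sm = ndi.gaussian_filter(wall, sigma=sigma)
        peak = sm.max()
        if peak > 0:
            sm = sm / max(peak, 1e-9)
        wall = np.clip(sm, 0.0, 1.0)
    return ProbabilityVolume(wall, cells.spacing)


def corrupt_segmentation(
    tissue: SyntheticTissue,
    n_merges: int = 0,
    n_splits: int = 0,
    seed: int = 0,
) -> tuple[LabelVolume, CorruptionRecord]:
    """Inject controlled segmentation errors into the tissue's cell volume.

    Merges relabel an adjacent mono-nucleate cell pair to one ID
    (undersegmentation: two nuclei in one label); splits cut a mono-nucleate
    cell by a random plane through its nucleus centroid into two IDs
    (oversegmentation: one nucleus straddling two labels, both sides holding
    well above a third of it). The record lists every injected edit.
    """
    rng = np.random.default_rng(seed)
    cells = tissue.cells.copy()
    v = cells.voxels
    record = CorruptionRecord()
    nucleate = {t.cell_id: t.nucleus_id for t in tissue.truth if t.nucleus_id is not None}

    # adjacency between cells (6-connectivity face contacts)
    edges: set[tuple[int, int]] = set()
    for axis in range(3):
        a = v.take(range(v.shape[axis] - 1), axis=axis)
        b = v.take(range(1, v.shape[axis]), axis=axis)
        m = (a != b) & (a > 0) & (b > 0)
        pairs = np.stack([a[m], b[m]])
        lo = pairs.min(axis=0)
        hi = pairs.max(axis=0)
        edges.update(zip(lo.tolist(), hi.tolist()))
    edges = sorted(e for e in edges if e[0] in nucleate and e[1] in nucleate)

    used: set[int] = set()
    rng.shuffle(edges)
    merged = 0
    for a, b in edges:
        if merged == n_merges:
            break
        if a in used or b in used:
            continue
        target = min(a, b)
        v[v == max(a, b)] = target
        record.merges.append({"cells": [a, b], "merged_id": target})
        used.update((a, b))
        merged += 1
    if merged < n_merges:
        raise ValueError(
            f"only {merged} disjoint adjacent mono-nucleate pairs available "
            f"for {n_merges} requested merges"
        )

    candidates = [c for c in sorted(nucleate) if c not in used]
    rng.shuffle(candidates)
    sp = cells.spacing.as_array()
    next_id = int(v.max()) + 1
    split_done = 0
    for cid in candidates:
        if split_done == n_splits:
            break
        nid = nucleate[cid]
        cell_idx = np.argwhere(v == cid)
        nuc_mask = tissue.nuclei.voxels[tuple(cell_idx.T)] == nid
        n_nuc = int(nuc_mask.sum())
        if n_nuc < 8:
            continue
        nuc_phys = (cell_idx[nuc_mask] + 0.5) * sp
        center = nuc_phys.mean(axis=0)
        cell_phys = (cell_idx + 0.5) * sp
        ok = False
        for _ in range(30):
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            side_nuc = (nuc_phys - center) @ normal > 0
            f = side_nuc.mean()
            side_cell = (cell_phys - center) @ normal > 0
            if 0.4 <= f <= 0.6 and 0 < side_cell.sum() < len(cell_idx):
                ok = True
                break
        if not ok:
            continue
        moved = cell_idx[side_cell]
        v[tuple(moved.T)] = next_id
        record.splits.append({"cell": cid, "new_ids": [cid, next_id], "nucleus": nid})
        used.add(cid)
        next_id += 1
        split_done += 1
    if split_done < n_splits:
        raise ValueError(
            f"only {split_done} cells eligible for {n_splits} requested splits"
        )
    return cells, record
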