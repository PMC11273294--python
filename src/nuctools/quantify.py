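"""Per-instance geometry and nucleus/cell ratio statistics.

Volumes are exact voxel counts scaled by the physical voxel volume
(dz·dy·dx µm³); centroids are unweighted means of voxel centers scaled by
the spacing, so nucleus–cell centroid distances are anisotropy-aware
Euclidean distances in µm. The N/C ratio of a linked pair is
V_nucleus / V_cell.

Group comparisons use the two statistics standard for this kind of
analysis: the Pearson product-moment correlation between nuclear and cell
volumes, and the unpaired two-tailed Student's t-test (pooled variance)
between N/C ratio groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import LinkTable
from .volumes import LabelVolume

__all__ = [
    "GeometryTable",
    "NCRecord",
    "NCResult",
    "instance_geometry",
    "distance_nuclei",
    "nc_table",
    "pearson_r",
    "ttest_two_tailed",
]


@dataclass
class GeometryTable:
    """Voxel count, physical volume (µm³) and centroid (µm, z/y/x) per instance."""

    counts: dict[int, int]
    volumes: dict[int, float]
    centroids: dict[int, np.ndarray]
    voxel_volume: float

    @property
    def ids(self) -> list[int]:
        return sorted(self.counts)

    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


@dataclass
class NCRecord:
    """One linked cell/nucleus pair with volumes, ratio and centroid distance."""

    cell_id: int
    nucleus_id: int
    tissue: int | str | None
    cell_volume_um3: float
    nucleus_volume_um3: float
    nc_ratio: float
    centroid_distance_um: float

    @property
    def ratio_exceeds_one(self) -> bool:
        """Flagged (not rejected) when the nucleus outweighs its cell."""
        return self.nc_ratio > 1.0


@dataclass
class NCResult:
    records: list[NCRecord]
    n_unlinked_nuclei: int
    n_cells_without_nucleus: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.__dict__ for r in sorted(self.records, key=lambda r: r.cell_id)],
            columns=[
                "cell_id",
                "nucleus_id",
                "tissue",
                "cell_volume_um3",
                "nucleus_volume_um3",
                "nc_ratio",
                "centroid_distance_um",
            ],
        )


def instance_geometry(volume: LabelVolume) -> GeometryTable:
    """Exact voxel counts, volumes and centroids for every instance."""
    v = volume.voxels
    sp = volume.spacing.as_array()
    flat = v.ravel().astype(np.int64)
    maxid = int(flat.max(initial=0))
    counts_all = np.bincount(flat, minlength=maxid + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(v.shape[0]), np.arange(v.shape[1]), np.arange(v.shape[2]),
        indexing="ij", sparse=True,
    )
    sums = np.stack(
        [
            np.bincount(flat, weights=np.broadcast_to(c, v.shape).ravel(), minlength=maxid + 1)
            for c in (zz, yy, xx)
        ],
        axis=1,
    )
    counts: dict[int, int] = {}
    volumes: dict[int, float] = {}
    centroids: dict[int, np.ndarray] = {}
    for i in range(1, maxid + 1):
        if counts_all[i] == 0:
            continue
        counts[i] = int(counts_all[i])
        volumes[i] = float(counts_all[i] * volume.spacing.voxel_volume)
        centroids[i] = sums[i] / counts_all[i] * sp
    return GeometryTable(counts, volumes, centroids, volume.spacing.voxel_volume)


def distance_nuclei(
    cell_geom: GeometryTable, nuc_geom: GeometryTable, link: LinkTable
) -> dict[int, float]:
    """Euclidean cell-centroid to nucleus-centroid distance (µm) per linked nucleus."""
    out: dict[int, float] = {}
    for n, c in link.assigned().items():
        if n not in nuc_geom.centroids:
            raise KeyError(f"nucleus {n} missing from the nucleus geometry table")
        if c not in cell_geom.centroids:
            raise KeyError(f"cell {c} missing from the cell geometry table")
        out[n] = float(np.linalg.norm(nuc_geom.centroids[n] - cell_geom.centroids[c]))
    return out


def nc_table(
    cell_geom: GeometryTable, nuc_geom: GeometryTable, link: LinkTable
) -> NCResult:
    """One N/C record per linked pair; unlinked counts go to the side report."""
    distances = distance_nuclei(cell_geom, nuc_geom, link)
    records = []
    for n, c in link.assigned().items():
        records.append(
            NCRecord(
                cell_id=c,
                nucleus_id=n,
                tissue=link.rows[n].tissue,
                cell_volume_um3=cell_geom.volumes[c],
                nucleus_volume_um3=nuc_geom.volumes[n],
                nc_ratio=nuc_geom.volumes[n] / cell_geom.volumes[c],
                centroid_distance_um=distances[n],
            )
        )
    linked_cells = set(link.assigned().values())
    return NCResult(
        records=sorted(records, key=lambda r: (r.cell_id, r.nucleus_id)),
        n_unlinked_nuclei=sum(1 for r in link.rows.values() if r.cell_id is None),
        n_cells_without_nucleus=len(set(cell_geom.counts) - linked_cells),
    )


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def ttest_two_tailed(a, b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test with pooled variance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=True, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
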