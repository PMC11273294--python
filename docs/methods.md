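# Methods

## Scoring model

Two instances match when their Jaccard index

IoU(g, p) = |g ∩ p| / (|g| + |p| − |g ∩ p|)

exceeds a threshold *t* (strict `>` by default; `strict=False` gives `≥`).
An IoU of 1 is a voxel-perfect match; 0.5 means the correctly matched
voxels equal the missed plus false-positive voxels combined. Matching is a
single one-to-one assignment over all pairs above threshold that maximizes
the number of matches, with ties broken toward maximal summed IoU. This is
solved as one linear assignment with weight `B + IoU` per admissible pair,
`B = min(n_gt, n_pred) + 1`, so one extra match always outweighs any IoU
total; a greedy best-overlap-first matcher can return strictly fewer
matches on competing overlaps, which is why the optimal variant is fixed
and oracle-tested against exhaustive search.

Counts follow the detection convention: TP = matched pairs, FP = unmatched
predictions, FN = unmatched ground-truth instances, so
p(t) = TP/(TP+FP+FN), which is non-increasing in *t*. AP averages p(t)
over *t* = 0.50 : 0.05 : 0.95 (M = 10); `mAP50` uses the single threshold
0.5. Means over image/model pairs carry the sample standard deviation
(ddof = 1). Background (ID 0) never scores; an optional foreground mask
drops predicted instances entirely outside it, for upstream methods that
oversegment the background. A ground truth with no instances makes
precision undefined and raises rather than returning 0.

## Linkage model

A nucleus belongs to the cell with which it shares the most voxels; ties
go to the lowest cell ID so results are deterministic under relabeling.
The centroid-in-cell alternative was rejected because the centroid of a
bent nucleus can fall outside its own mask. `min_frac` (default 0: any
overlap assigns) optionally requires the winning overlap to exceed a
fraction of the nucleus volume; nuclei meeting only background stay
explicitly unassigned rather than being dropped, so airspace/no-cell cases
remain visible. The 2.5D variant projects each nucleus's voxels along z to
a (y, x) footprint — each pixel counted once regardless of column depth —
and assigns by maximal footprint overlap with the surface cell map. For
any link table the duplicated-nuclei cells, single-nucleus cells and
cells-without-nucleus partition the cell-ID set; this is property-tested.

## Geometry and statistics

Volumes are voxel counts × dz·dy·dx, exact on the label grid (a
marching-cubes mesh volume of the same instance differs slightly near
boundaries; that discrepancy is a meshing artifact and is not modeled).
Centroids are unweighted means of voxel centers scaled per axis by the
spacing, so centroid distances are correct under anisotropy. N/C ratio is
V_nuc/V_cell per linked pair; pairs with ratio > 1 are flagged, not
rejected. Group statistics are the Pearson product-moment correlation
(undefined and rejected under zero variance) and the unpaired two-tailed
Student's t-test with pooled variance — pooled, not Welch, matching the
stated test; both delegate to scipy.stats.

## Proofreading

Both triggers are fractions of the nucleus volume: a cell is a split
candidate when ≥2 nuclei each lie more than `t_split = 0.66` inside it; a
nucleus is a merge trigger when ≥2 cells each hold more than
`t_merge = 0.33` of it. Reading the split trigger against the *cell*
volume is geometrically impossible for two disjoint nuclei (they cannot
both exceed 66% of one cell), so the nucleus denominator is the default
and the literal cell-volume reading sits behind `split_frac_of_cell=True`.
Thresholds compare strictly (`>`).

Splits run first, then overlaps are recomputed and merges applied —
splits create the fragments merges must see, and on tissues where each
error is independent this order makes a second pass a no-op (idempotence
is asserted in tests). The watershed landscape is the boundary
probability restricted to the flagged cell's voxels inside its bounding
box padded by `bbox_pad = 1`; seeds are each nucleus's voxels intersected
with the cell; connectivity is the 6-neighborhood and anisotropy is
ignored inside the watershed. Cell voxels unreachable from any seed
(disconnected pockets) are attached to the nearest labeled voxel so the
cell is always fully repartitioned. Fragments take fresh IDs above the
global maximum; merges relabel to the smallest ID of the group. With
fewer than two effective seeds a split is a warning-level no-op.

The edit log records, per edit, the kind, IDs before/after, triggering
nuclei, bounding box and trigger fractions. Replaying the log reruns the
same deterministic operations with the recorded fragment IDs and
reproduces the output voxel-for-voxel, which keeps the log small (no voxel
data) yet auditable. Limitations carried over from the design: a missing
cell cannot be recovered (nothing seeds it), and errors in the nuclear
segmentation propagate — a falsely merged nucleus forces a wrong cell
merge, asserted as a designed-failure test.

## Synthetic tissue generator

The generator emulates the data regime the toolkit targets, not its
optics: no point-spread function, noise or intensity model. Cells are the
nearest-seed (Voronoi) partition, in physical coordinates, of an
ellipsoidal organ mask inscribed in the grid (semi-axes 0.48 × extent);
seed points are drawn with a greedy minimum-separation pass (0.7 × the
mean-cell-volume cube root) so cell sizes are realistically spread but not
degenerate. Default spacing is 0.25 µm isotropic, the usual resampling
target for this kind of confocal data. Concentric layers (outermost
first) are assigned by equal-count binning of the seeds' normalized
ellipsoidal radius.

Each nucleate cell gets one nucleus: the target voxel count
(per-cell ratio × cell size) of interior cell voxels nearest a jittered
center under a random per-axis ellipsoidal metric — a clipped ellipsoid
strictly inside the cell (one-voxel erosion), so nuclei of distinct cells
are disjoint by construction and linkage truth is exact. Per-cell target
ratios are drawn around the layer target with a 25% coefficient of
variation, matching the spread reported for real ovule layers
(s.d./mean ≈ 0.08/0.30), and clipped to [0.05, 0.6]; the defaults exercise
the published layer regime, 0.30 for the outer and 0.23 for the inner
layer, within the 0.15–0.30 band seen across tissues. The realized
centroid offset is recorded per cell so distance recovery has exact truth.
A stated fraction of cells (5% in the reference conditions) is generated
nucleus-free as airspace stand-ins.

The boundary map marks both voxels of every label-changing face (including
organ surface), optionally scales listed walls by `weak_factor` (0 removes
the wall — the faint-staining scenario), Gaussian-smooths with
σ = 0.7 voxels and renormalizes to peak 1. Corruptions: a false merge
relabels an adjacent mono-nucleate pair to one ID; a false split cuts a
mono-nucleate cell by a plane through its nucleus centroid with a random
normal, re-drawn until 40–60% of the nucleus lies on each side (so both
fragments clear the 0.33 merge trigger); every injected edit is recorded.
All outputs are pure functions of (parameters, seed).

Because walls in the synthetic boundary map sit exactly on the true label
boundaries, watershed corrections can recover the original partition
nearly voxel-perfectly; on real boundary predictions the recovered
interface is only as good as the network's wall estimate. Passing tests
therefore demonstrate the correctness of the bookkeeping, triggers,
matching and statistics — not segmentation accuracy on microscopy data.

## Problem sizes and numerical choices

Reference conditions: proofreading is exercised on a 128³ grid with 80
cells, 3 injected merges and 2 injected splits; N/C recovery on a
64×96×96 grid with 120 cells across two layers (≥50 linked pairs each) —
sizes at which every quantity is stable across seeds while the whole suite
runs in seconds. I/O stores labels as the narrowest sufficient unsigned
integer and probabilities as float32; HDF5 spacing uses the
`element_size_um` attribute, TIFF spacing ImageJ metadata or a JSON
description tag; explicit spacing always overrides file metadata and a
volume with neither is an error. Matching uses `scipy.optimize.
linear_sum_assignment`; watershed is `skimage.segmentation.watershed`.
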