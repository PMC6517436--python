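"""Voxel-wise statistical engine: correlation maps, p-values, cluster filtering.

Every subject's imaging parameter (local tissue volume or fat fraction) lives
on the shared reference grid, so each voxel carries n aligned observations
that can be correlated against any scalar covariate.  Findings are controlled
not by formal multiple-testing correction but by the reporting heuristic of
whole-body correlation mapping: a finding must be a connected cluster of
voxels with |r| above a threshold (default 0.50) whose p-values are uniformly
below threshold (default 0.05), must appear with the same sign in both sexes,
and must be robust under non-parametric (Spearman) correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .errors import ValidationError
from .grids import ImageGrid3D, ScalarVolume, _require_same_grid


@dataclass
class VolumeStack:
    """n aligned scalar volumes on a common grid, one per subject."""

    grid: ImageGrid3D
    data: np.ndarray  # (n, nx, ny, nz)
    ids: list[str]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[1:] != self.grid.shape:
            raise ValidationError("stack must have shape (n,) + grid dims")
        if data.shape[0] < 3:
            raise ValidationError("stack needs at least 3 subjects")
        if len(self.ids) != data.shape[0] or len(set(self.ids)) != len(self.ids):
            raise ValidationError("subject ids must be unique and match the stack")
        if not np.all(np.isfinite(data)):
            raise ValidationError("stack contains non-finite values")
        self.data = data

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @classmethod
    def from_volumes(cls, volumes: list[ScalarVolume], ids: list[str]) -> "VolumeStack":
        grid = volumes[0].grid
        for v in volumes[1:]:
            _require_same_grid(grid, v.grid, "volume stack")
        return cls(grid, np.stack([v.values for v in volumes]), list(ids))


@dataclass
class CorrelationMap:
    """Per-voxel correlation of an imaging parameter with one covariate.

    Voxels whose imaging series has zero variance (e.g. air) are undefined
    and carry NaN; they are excluded from clustering and get p = 1.
    """

    grid: ImageGrid3D
    r: np.ndarray
    n: int
    method: str  # 'pearson' or 'spearman'
    covariate: str

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.shape != self.grid.shape:
            raise ValidationError("correlation array shape does not match grid")
        defined = np.isfinite(r)
        if defined.any() and (np.abs(r[defined]) > 1 + 1e-12).any():
            raise ValidationError("correlations must lie in [-1, 1]")
        self.r = r

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.r)


def _corr_map(
    y: np.ndarray,
    x: np.ndarray,
    grid: ImageGrid3D,
    method: str,
    covariate: str,
    mask: np.ndarray | None,
) -> CorrelationMap:
    n = x.size
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    yc = y - y.mean(axis=0)
    sy = np.sqrt((yc**2).sum(axis=0))
    num = np.tensordot(xc, yc, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (sx * sy)
    r = np.where(sy > 0, np.clip(r, -1.0, 1.0), np.nan)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != grid.shape:
            raise ValidationError("analysis mask shape does not match grid")
        r = np.where(m, r, np.nan)
    return CorrelationMap(grid, r, n, method, covariate)


def _validate_covariate(stack: VolumeStack, covariate) -> np.ndarray:
    x = np.asarray(covariate, dtype=float)
    if x.ndim != 1 or x.size != stack.n:
        raise ValidationError("covariate length must equal the number of subjects")
    if not np.all(np.isfinite(x)):
        raise ValidationError("covariate contains non-finite values")
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant; correlation undefined")
    return x


def pearson_map(
    stack: VolumeStack, covariate, name: str = "covariate", mask: np.ndarray | None = None
) -> CorrelationMap:
    """Voxel-wise Pearson r of the n imaging values against the covariate.

    Voxels outside the optional analysis ``mask`` (typically the reference
    body mask — air carries no tissue to correlate) are marked undefined.
    """
    x = _validate_covariate(stack, covariate)
    return _corr_map(stack.data, x, stack.grid, "pearson", name, mask)


def spearman_map(
    stack: VolumeStack, covariate, name: str = "covariate", mask: np.ndarray | None = None
) -> CorrelationMap:
    """Voxel-wise Spearman rho: Pearson on mid-ranks (average ranks on ties)."""
    x = _validate_covariate(stack, covariate)
    ry = sstats.rankdata(stack.data, axis=0)
    rx = sstats.rankdata(x)
    return _corr_map(ry, rx, stack.grid, "spearman", name, mask)


def p_value_map(cmap: CorrelationMap) -> ScalarVolume:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df; undefined voxels get p = 1."""
    if cmap.n < 3:
        raise ValidationError("p-values require n >= 3")
    r = cmap.r
    p = np.ones(r.shape)
    defined = np.isfinite(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r[defined]) * np.sqrt((cmap.n - 2) / (1.0 - r[defined] ** 2))
    pv = 2.0 * sstats.t.sf(t, df=cmap.n - 2)
    # |r| = 1 is the p -> 0 limit; absorb the last-ulp rounding of exact fits
    pv[np.abs(r[defined]) >= 1.0 - 1e-15] = 0.0
    p[defined] = pv
    return ScalarVolume(cmap.grid, p)


@dataclass
class Cluster:
    """One connected supra-threshold component of a correlation map."""

    cluster_id: int
    sign: int  # +1 or -1
    voxels: np.ndarray  # (size, 3) integer indices
    size: int
    mean_r: float
    max_abs_r: float
    all_p_below: bool
    centroid_mm: tuple[float, float, float]
    sex_concordant: bool | None = None
    spearman_concordant: bool | None = None

    def mask(self, grid: ImageGrid3D) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m

    def flat_indices(self, grid: ImageGrid3D) -> np.ndarray:
        return np.ravel_multi_index(tuple(self.voxels.T), grid.shape)


@dataclass
class ClusterSet:
    grid: ImageGrid3D
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def total_mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        for c in self.clusters:
            m[tuple(c.voxels.T)] = True
        return m


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_clusters(
    rmap: CorrelationMap,
    pmap: ScalarVolume,
    r_thr: float = 0.50,
    p_thr: float = 0.05,
    min_size: int = 10,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of {|r| > r_thr}, split by sign.

    A component is retained only if it has at least ``min_size`` voxels and
    every member voxel has p < p_thr (the "uniformly significant anatomical
    structure" rule).  Undefined voxels never join a cluster.
    """
    _require_same_grid(rmap.grid, pmap.grid, "threshold_clusters")
    if connectivity not in _STRUCTURES:
        raise ValidationError("connectivity must be one of 6, 18, 26")
    structure = _STRUCTURES[connectivity]
    out = ClusterSet(rmap.grid)
    defined = rmap.defined_mask()
    next_id = 0
    for sign in (1, -1):
        supra = defined & ((rmap.r > r_thr) if sign > 0 else (rmap.r < -r_thr))
        labelled, ncomp = ndimage.label(supra, structure=structure)
        for comp in range(1, ncomp + 1):
            vox = np.argwhere(labelled == comp)
            if vox.shape[0] < min_size:
                continue
            sel = tuple(vox.T)
            if not np.all(pmap.values[sel] < p_thr):
                continue
            rvals = rmap.r[sel]
            centroid = rmap.grid.index_to_world(vox.mean(axis=0))
            out.clusters.append(
                Cluster(
                    cluster_id=next_id,
                    sign=sign,
                    voxels=vox,
                    size=int(vox.shape[0]),
                    mean_r=float(rvals.mean()),
                    max_abs_r=float(np.abs(rvals).max()),
                    all_p_below=True,
                    centroid_mm=tuple(float(c) for c in centroid),
                )
            )
            next_id += 1
    return out


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b, assume_unique=True).size
    return 2.0 * inter / (a.size + b.size)


def _retained(
    own: ClusterSet,
    other: ClusterSet,
    rho_map: CorrelationMap,
    overlap_thr: float,
    rho_thr: float,
) -> ClusterSet:
    out = ClusterSet(own.grid)
    other_flat = {
        s: [c.flat_indices(own.grid) for c in other.clusters if c.sign == s]
        for s in (1, -1)
    }
    for c in own.clusters:
        mine = c.flat_indices(own.grid)
        sex_ok = any(
            _dice(mine, o) >= overlap_thr for o in other_flat[c.sign]
        )
        rho = rho_map.r[tuple(c.voxels.T)]
        good = np.isfinite(rho) & (np.abs(rho) > rho_thr) & (np.sign(rho) == c.sign)
        rho_ok = bool(good.mean() >= 0.5)
        kept = Cluster(
            **{
                **c.__dict__,
                "sex_concordant": sex_ok,
                "spearman_concordant": rho_ok,
            }
        )
        if sex_ok and rho_ok:
            out.clusters.append(kept)
    return out


def concordance_filter(
    clusters_f: ClusterSet,
    clusters_m: ClusterSet,
    spearman_f: CorrelationMap,
    spearman_m: CorrelationMap,
    overlap_thr: float = 0.3,
    rho_thr: float = 0.5,
) -> tuple[ClusterSet, ClusterSet]:
    """Apply the sex- and Spearman-concordance rules to both sexes' clusters.

    A cluster survives iff (a) some opposite-sex cluster of the same sign
    overlaps it with Dice >= overlap_thr and (b) at least half of its voxels
    have |rho| > rho_thr with matching sign in its own sex's Spearman map.
    """
    for g in (clusters_m.grid, spearman_f.grid, spearman_m.grid):
        _require_same_grid(clusters_f.grid, g, "concordance_filter")
    return (
        _retained(clusters_f, clusters_m, spearman_f, overlap_thr, rho_thr),
        _retained(clusters_m, clusters_f, spearman_m, overlap_thr, rho_thr),
    )
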