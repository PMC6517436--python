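"""Three-step tissue-sequential registration to the reference coordinate system.

Whole-body water-fat volumes are aligned to the reference in three stages that
respect the very different elasticity of the tissues involved:

1. Articulated, piece-wise affine registration of the bone segments
   (least-squares alignment of landmark sets derived from each segment mask),
   blended into a dense initial displacement field.
2. Deformable registration of the water channels with the bone displacements
   frozen (lean tissue and organs carry the water signal).
3. Deformable registration of the fat channels, starting from the water-stage
   field, with bone and water-dominant lean tissue frozen.

The deformable engine is a multi-resolution demons-style gradient flow with
Gaussian regularisation of both the per-iteration update (fluid-like) and the
accumulated field (diffusion-like).  Constraints are hard-frozen: voxels
inside the (dilated) frozen mask keep their initialisation displacement
bit-exactly.  Registration is always reference <- subject (the reference is
the fixed image), matching the convention that all analysis happens in the
reference coordinate system.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    distance_transform_edt,
    gaussian_filter,
)

from .errors import (
    MissingSegmentError,
    NumericalFailureError,
    ValidationError,
)
from .fields import DeformationField, sample_displacement
from .grids import (
    ImageGrid3D,
    ScalarVolume,
    TissueLabelVolume,
    WaterFatVolume,
    sample_points,
)

# re-exported here because they belong to the registration tool-box
from .fields import compose_fields, estimate_inverse  # noqa: F401


@dataclass
class BoneSegmentTransform:
    """Affine map x -> A x + t (world mm) for one articulated bone segment."""

    segment_id: int
    A: np.ndarray  # (3, 3)
    t: np.ndarray  # (3,)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.linalg.det(self.A) <= 0:
            raise ValidationError(
                f"segment {self.segment_id}: affine must be orientation-preserving"
            )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.A.T + self.t


@dataclass(frozen=True)
class RegistrationConfig:
    pyramid_levels: int = 3
    iterations_per_level: int = 50
    update_smoothing_sd: float = 2.0  # mm, fluid-like regularisation
    field_smoothing_sd: float = 1.5  # mm, diffusion-like regularisation
    metric: str = "ssd"  # 'ssd' or 'ncc' (globally normalised ssd)
    step_size: float = 1.0
    convergence_tol: float = 1e-4  # relative metric change
    frozen_dilation: int = 1  # voxels of buffer around frozen masks

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        if self.update_smoothing_sd < 0 or self.field_smoothing_sd < 0:
            raise ValidationError("smoothing sds must be >= 0")
        if self.metric not in ("ssd", "ncc"):
            raise ValidationError("metric must be 'ssd' or 'ncc'")


# ---------------------------------------------------------------- bone step


def _mask_landmarks(mask: np.ndarray, grid: ImageGrid3D, segment_id: int):
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise MissingSegmentError(f"bone segment {segment_id} has an empty mask")
    pts = grid.index_to_world(idx)
    c = pts.mean(axis=0)
    x = pts - c
    cov = x.T @ x / idx.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, np.maximum(evals[order], 1e-9), evecs[:, order]


def _align_axes(ref_axes, subj_evals, subj_axes, degeneracy_tol: float = 0.15):
    """Resolve eigenvector sign/spin ambiguity against the reference axes.

    Nearly degenerate eigenvalue groups (rotationally symmetric bones) leave
    the in-plane spin of the principal axes arbitrary; within such a group the
    subject axes are replaced by the projections of the reference axes onto
    the group's subspace, so symmetric segments do not pick up spurious spin.
    """
    V = subj_axes.copy()
    groups, start = [], 0
    for i in range(1, 3):
        if abs(subj_evals[i] - subj_evals[i - 1]) > degeneracy_tol * subj_evals[i - 1]:
            groups.append(list(range(start, i)))
            start = i
    groups.append(list(range(start, 3)))
    for g in groups:
        if len(g) > 1:
            B = V[:, g]
            proj = B @ (B.T @ ref_axes[:, g])
            q, _ = np.linalg.qr(proj)
            V[:, g] = q
    for i in range(3):
        if float(V[:, i] @ ref_axes[:, i]) < 0:
            V[:, i] = -V[:, i]
    return V


def _segment_affine(ref_mask, subj_mask, ref_grid, subj_grid, segment_id):
    c_r, ev_r, ax_r = _mask_landmarks(ref_mask, ref_grid, segment_id)
    c_s, ev_s, ax_s = _mask_landmarks(subj_mask, subj_grid, segment_id)
    ax_s = _align_axes(ax_r, ev_s, ax_s)
    scale_r = np.sqrt(ev_r)
    scale_s = np.sqrt(ev_s)
    P = [c_r] + [c_r + s * scale_r[i] * ax_r[:, i] for i in range(3) for s in (1, -1)]
    Q = [c_s] + [c_s + s * scale_s[i] * ax_s[:, i] for i in range(3) for s in (1, -1)]
    P = np.asarray(P)
    Q = np.asarray(Q)
    H = np.hstack([P, np.ones((P.shape[0], 1))])
    sol, *_ = np.linalg.lstsq(H, Q, rcond=None)
    A = sol[:3].T
    t = sol[3]
    return BoneSegmentTransform(segment_id, A, t)


def _subject_bone_masks_from_water(
    ref_labels: TissueLabelVolume, subj_wf: WaterFatVolume, water_threshold: float
) -> dict[int, np.ndarray]:
    """Fallback subject skeleton by intensity thresholding of the water image.

    Bone is rendered as the brightest water structure in the phantom; each
    supra-threshold voxel is assigned to the reference segment whose mask is
    nearest in world space (adequate for the moderate articulations simulated).
    """
    water = subj_wf.water.values
    bone = water >= water_threshold * float(water.max())
    vox = np.argwhere(bone)
    if vox.shape[0] == 0:
        raise MissingSegmentError("no bone voxels found by water thresholding")
    pts = subj_wf.grid.index_to_world(vox)
    seg_ids = ref_labels.bone_segment_ids()
    ref_idx = ref_labels.grid.world_to_index(pts)
    coords = np.moveaxis(ref_idx, -1, 0)
    dists = np.empty((len(seg_ids), vox.shape[0]))
    from scipy.ndimage import map_coordinates

    for i, seg in enumerate(seg_ids):
        edt = distance_transform_edt(
            ref_labels.labels != seg, sampling=ref_labels.grid.spacing
        )
        dists[i] = map_coordinates(edt, coords, order=1, mode="nearest")
    nearest = np.argmin(dists, axis=0)
    masks = {}
    for i, seg in enumerate(seg_ids):
        m = np.zeros(subj_wf.grid.shape, dtype=bool)
        m[tuple(vox[nearest == i].T)] = True
        masks[seg] = m
    return masks


def register_bone_segments(
    ref_labels: TissueLabelVolume,
    ref_wf: WaterFatVolume,
    subj_wf: WaterFatVolume,
    subj_labels: TissueLabelVolume | None = None,
    water_threshold: float = 0.85,
) -> list[BoneSegmentTransform]:
    """One affine per articulated bone segment, from matched landmark sets.

    Landmarks are the segment centroid plus the six principal-axis endpoints
    (at one SD extent) of each mask.  Subject masks come from provided subject
    labels (the phantom pipeline supplies them, standing in for the bone
    pre-segmentation a real pipeline performs) or from water thresholding.
    """
    seg_ids = ref_labels.bone_segment_ids()
    if not seg_ids:
        raise MissingSegmentError("reference labels contain no bone segments")
    if subj_labels is not None:
        ref_masks = {seg: ref_labels.labels == seg for seg in seg_ids}
        subj_masks = {seg: subj_labels.labels == seg for seg in seg_ids}
        subj_grid = subj_labels.grid
    else:
        # without a subject segmentation, derive BOTH sides' masks by the same
        # intensity thresholding so landmark sets describe comparable subsets
        ref_masks = _subject_bone_masks_from_water(ref_labels, ref_wf, water_threshold)
        subj_masks = _subject_bone_masks_from_water(ref_labels, subj_wf, water_threshold)
        subj_grid = subj_wf.grid
    return [
        _segment_affine(ref_masks[seg], subj_masks[seg], ref_labels.grid, subj_grid, seg)
        for seg in seg_ids
    ]


def blend_segment_transforms(
    transforms: list[BoneSegmentTransform], ref_labels: TissueLabelVolume
) -> DeformationField:
    """Dense field from the piece-wise affines by inverse-distance blending.

    Displacement at x is the weight-normalised sum of each segment's affine
    displacement, with weights 1/(d_k + eps)^2 where d_k is the distance to
    segment k's mask; exact inside every segment mask.
    """
    if not transforms:
        raise MissingSegmentError("no segment transforms to blend")
    grid = ref_labels.grid
    x = grid.voxel_centers()
    flat = x.reshape(-1, 3)
    eps = 0.5  # mm, keeps weights finite at mask boundaries
    num = np.zeros_like(flat)
    den = np.zeros(flat.shape[0])
    disp = {}
    for tr in transforms:
        d = tr.apply(flat) - flat
        disp[tr.segment_id] = d
        mask = ref_labels.labels == tr.segment_id
        dist = distance_transform_edt(~mask, sampling=grid.spacing).reshape(-1)
        w = 1.0 / (dist + eps) ** 2
        num += w[:, None] * d
        den += w
    u = num / den[:, None]
    for tr in transforms:
        inside = (ref_labels.labels == tr.segment_id).reshape(-1)
        u[inside] = disp[tr.segment_id][inside]
    return DeformationField(grid, u.reshape(grid.shape + (3,)))


# ---------------------------------------------------------- deformable step


def _downsample_volume(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sm = gaussian_filter(vol.values, sigma=factor / 2.0)
    vals = sm[::factor, ::factor, ::factor]
    grid = ImageGrid3D(
        vals.shape,
        tuple(s * factor for s in vol.grid.spacing),
        vol.grid.origin,
    )
    return ScalarVolume(grid, vals)


def _upsample_field(u: np.ndarray, coarse: ImageGrid3D, fine: ImageGrid3D) -> np.ndarray:
    field = DeformationField(coarse, u)
    return sample_displacement(field, fine.voxel_centers())


def _normalize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / (sd if sd > 0 else 1.0)


def register_deformable(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    init: DeformationField | None = None,
    frozen_mask: np.ndarray | None = None,
    cfg: RegistrationConfig | None = None,
    log: list | None = None,
) -> DeformationField:
    """Multi-resolution demons-style deformable registration.

    Per level: the force (fixed - moving o phi) grad(fixed) / (|grad|^2 +
    diff^2 / K) is Gaussian-smoothed (update_smoothing_sd), added to the
    field, which is then Gaussian-smoothed (field_smoothing_sd); displacements
    inside the frozen mask are reset to their initialisation each iteration
    and bit-exactly at the end.  The best-metric field seen is returned, so
    the final similarity metric never exceeds the initial one.  Appends
    (level, iteration, metric) rows to ``log`` when provided.
    """
    cfg = cfg or RegistrationConfig()
    grid = fixed.grid
    if init is not None and init.grid != grid:
        raise ValidationError("init field must live on the fixed grid")
    u_init = init.u if init is not None else np.zeros(grid.shape + (3,))
    frozen = (
        np.asarray(frozen_mask, dtype=bool)
        if frozen_mask is not None
        else np.zeros(grid.shape, dtype=bool)
    )
    if cfg.frozen_dilation > 0 and frozen.any():
        frozen_dil = binary_dilation(frozen, iterations=cfg.frozen_dilation)
    else:
        frozen_dil = frozen

    if cfg.metric == "ncc":
        fixed = ScalarVolume(grid, _normalize(fixed.values))
        moving = ScalarVolume(moving.grid, _normalize(moving.values))

    factors = [2 ** (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]
    factors = [f for f in factors if all(d // f >= 4 for d in grid.dims)] or [1]

    u = None
    prev_grid = None
    for level, f in enumerate(factors):
        fixL = _downsample_volume(fixed, f)
        gL = fixL.grid
        maskL = frozen_dil[::f, ::f, ::f]
        initL = u_init[::f, ::f, ::f, :]
        if u is None:
            u = initL.copy()
        else:
            u = _upsample_field(u, prev_grid, gL)
        u[maskL] = initL[maskL]

        x = gL.voxel_centers()
        gradF = np.stack(np.gradient(fixL.values, *gL.spacing), axis=-1)
        gnorm2 = (gradF**2).sum(axis=-1)
        K = float(np.mean(gL.spacing)) ** 2
        sig_up = [cfg.update_smoothing_sd / s for s in gL.spacing]
        sig_fl = [cfg.field_smoothing_sd / s for s in gL.spacing]

        best_metric = np.inf
        best_u = None
        metric0 = None
        prev_metric = None
        for it in range(cfg.iterations_per_level):
            warped = sample_points(moving, x + u)
            diff = fixL.values - warped
            metric = float(np.mean(diff**2))
            if not np.isfinite(metric):
                raise NumericalFailureError(
                    f"non-finite metric at level {level}, iteration {it}"
                )
            if log is not None:
                log.append((level, it, metric))
            if metric < best_metric:
                best_metric = metric
                best_u = u.copy()
            if metric0 is None:
                metric0 = metric
            elif abs(prev_metric - metric) <= cfg.convergence_tol * max(metric0, 1e-30):
                break
            prev_metric = metric

            with np.errstate(divide="ignore", invalid="ignore"):
                scale = diff / (gnorm2 + diff**2 / K)
            scale[~np.isfinite(scale)] = 0.0
            force = cfg.step_size * scale[..., None] * gradF
            if cfg.update_smoothing_sd > 0:
                for c in range(3):
                    force[..., c] = gaussian_filter(force[..., c], sig_up)
            u = u + force
            if cfg.field_smoothing_sd > 0:
                for c in range(3):
                    u[..., c] = gaussian_filter(u[..., c], sig_fl)
            u[maskL] = initL[maskL]

        # final evaluation; keep the best field seen at this level
        warped = sample_points(moving, x + u)
        metric = float(np.mean((fixL.values - warped) ** 2))
        if metric > best_metric and best_u is not None:
            u = best_u
            metric = best_metric
        if log is not None:
            log.append((level, cfg.iterations_per_level, metric))
        prev_grid = gL

    if factors[-1] != 1:
        u = _upsample_field(u, prev_grid, grid)
    u[frozen_dil] = u_init[frozen_dil]
    return DeformationField(grid, u)


# ------------------------------------------------------------- full pipeline


def _water_dominant_mask(ref_wf: WaterFatVolume, labels: TissueLabelVolume) -> np.ndarray:
    """Lean, water-dominant tissue to freeze during the fat stage."""
    w, f = ref_wf.water.values, ref_wf.fat.values
    return (w > f) & (w > 0.4 * float(w.max())) & labels.body_mask()


def register_subject(
    reference_wf: WaterFatVolume,
    reference_labels: TissueLabelVolume,
    subject_wf: WaterFatVolume,
    cfg: RegistrationConfig | None = None,
    subject_labels: TissueLabelVolume | None = None,
    log: list | None = None,
) -> DeformationField:
    """The full three-step registration, returning the final dense field.

    Stage errors are annotated with the stage name.  The bone displacements
    are preserved bit-exactly through both deformable stages.
    """
    cfg = cfg or RegistrationConfig()
    stage = "bone"
    try:
        transforms = register_bone_segments(
            reference_labels, reference_wf, subject_wf, subject_labels
        )
        init = blend_segment_transforms(transforms, reference_labels)
        bone = reference_labels.bone_mask()
        stage = "water"
        f_water = register_deformable(
            reference_wf.water, subject_wf.water, init, bone, cfg, log
        )
        stage = "fat"
        lean = _water_dominant_mask(reference_wf, reference_labels)
        f_fat = register_deformable(
            reference_wf.fat, subject_wf.fat, f_water, bone | lean, cfg, log
        )
    except Exception as exc:
        raise type(exc)(f"registration stage '{stage}': {exc}") from exc
    return f_fat
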