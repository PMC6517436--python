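"""Morphometry of deformation fields: local tissue volume and registration quality.

The local tissue volume at a reference voxel is the Jacobian determinant of
the mapping phi(x) = x + u(x): J > 1 means the subject's tissue is locally
expanded relative to the reference, J < 1 contracted.  Registration quality
is summarised by the inverse-consistency error — the distance by which the
composition of a forward and a backward registration fails to return each
point to itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fields import compose_fields
from .grids import DeformationField, ImageGrid3D, ScalarVolume, _require_same_grid


@dataclass
class JacobianMap:
    """Local volume ratio det(I + grad u) per voxel (dimensionless)."""

    grid: ImageGrid3D
    j: np.ndarray

    def __post_init__(self):
        j = np.asarray(self.j, dtype=float)
        if j.shape != self.grid.shape:
            raise ValidationError("jacobian array shape does not match grid")
        if not np.all(np.isfinite(j)):
            raise ValidationError("jacobian map contains non-finite values")
        self.j = j


def jacobian_map(field: DeformationField) -> JacobianMap:
    """J(x) = det(I + grad u(x)), gradients by central differences in mm.

    Boundary voxels use one-sided differences; whole-body summaries should
    exclude them (the phantom body never touches the boundary).
    """
    if any(d < 3 for d in field.grid.dims):
        raise ValidationError("jacobian_map needs at least 3 voxels per axis")
    G = np.empty(field.grid.shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.u[..., i], *field.grid.spacing)
        for jax in range(3):
            G[..., i, jax] = grads[jax]
    for i in range(3):
        G[..., i, i] += 1.0
    return JacobianMap(field.grid, np.linalg.det(G))


def total_volume(jmap: JacobianMap, body_mask: np.ndarray) -> float:
    """Integral of J over the mask times voxel volume, in litres."""
    mask = np.asarray(body_mask, dtype=bool)
    if mask.shape != jmap.grid.shape:
        raise ValidationError("body mask shape does not match grid")
    if not mask.any():
        raise ValidationError("body mask is empty")
    return float(jmap.j[mask].sum() * jmap.grid.voxel_volume_mm3 / 1e6)


def inverse_consistency_map(
    fwd: DeformationField, bwd: DeformationField, body_mask: np.ndarray | None = None
) -> tuple[ScalarVolume, float]:
    """Per-voxel round-trip error ||phi_bwd(phi_fwd(x)) - x|| in mm.

    Returns the error map and its mean over ``body_mask`` (whole grid if None).
    """
    _require_same_grid(fwd.grid, bwd.grid, "inverse_consistency_map")
    comp = compose_fields(bwd, fwd)
    err = np.linalg.norm(comp.u, axis=-1)
    if body_mask is None:
        mean = float(err.mean())
    else:
        mask = np.asarray(body_mask, dtype=bool)
        if mask.shape != fwd.grid.shape:
            raise ValidationError("body mask shape does not match grid")
        if not mask.any():
            raise ValidationError("body mask is empty")
        mean = float(err[mask].mean())
    return ScalarVolume(fwd.grid, err), mean
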