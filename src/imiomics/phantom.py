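"""Deterministic body-like reference phantom.

The phantom stands in for the reference human of a whole-body cohort study:
an articulated skeleton (spine, pelvis, two femora, two arm bones) embedded in
muscle, with lungs, liver and visceral fat inside the torso, and two
concentric subcutaneous fat shells (superficial outer, deep inner) around it.
Geometry is defined in grid-normalised coordinates so the body fills any grid
of at least 32 x 24 x 64 voxels; the z axis runs foot -> head.

The water image is high in muscle, organs and bone marrow-free cortex
(bone is rendered brightest so a subject skeleton could also be recovered by
thresholding), the fat image is high in adipose labels, and both are near
zero in air.  Images are lightly smoothed (0.7 voxel Gaussian) so that
intensity gradients exist for demons-style registration; the construction is
fully deterministic.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .grids import (
    AIR,
    BONE_BASE,
    LIVER,
    LUNG,
    MUSCLE,
    SUBCUT_DEEP,
    SUBCUT_SUPERFICIAL,
    VISCERAL_FAT,
    ImageGrid3D,
    ScalarVolume,
    TissueLabelVolume,
    WaterFatVolume,
)

MIN_DIMS = (32, 24, 64)

# Articulated bone segments (six pieces).
SPINE = BONE_BASE + 0
PELVIS = BONE_BASE + 1
FEMUR_LEFT = BONE_BASE + 2
FEMUR_RIGHT = BONE_BASE + 3
ARM_LEFT = BONE_BASE + 4
ARM_RIGHT = BONE_BASE + 5

ALL_LABELS = (
    AIR,
    LUNG,
    LIVER,
    MUSCLE,
    SUBCUT_SUPERFICIAL,
    SUBCUT_DEEP,
    VISCERAL_FAT,
    SPINE,
    PELVIS,
    FEMUR_LEFT,
    FEMUR_RIGHT,
    ARM_LEFT,
    ARM_RIGHT,
)

# Per-tissue channel intensities (arbitrary units in [0, 1]).
WATER_INTENSITY = {
    AIR: 0.0,
    LUNG: 0.15,
    LIVER: 0.70,
    MUSCLE: 0.80,
    SUBCUT_SUPERFICIAL: 0.08,
    SUBCUT_DEEP: 0.09,
    VISCERAL_FAT: 0.10,
    "bone": 1.00,
}
FAT_INTENSITY = {
    AIR: 0.0,
    LUNG: 0.03,
    LIVER: 0.25,
    MUSCLE: 0.08,
    SUBCUT_SUPERFICIAL: 0.92,
    SUBCUT_DEEP: 0.88,
    VISCERAL_FAT: 0.85,
    "bone": 0.15,
}

_IMAGE_SMOOTH_VOXELS = 0.7


def _normalized_coords(grid: ImageGrid3D):
    axes = [(np.arange(d) + 0.5) / d for d in grid.dims]
    return np.meshgrid(*axes, indexing="ij")


def build_reference_phantom(grid: ImageGrid3D) -> tuple[TissueLabelVolume, WaterFatVolume]:
    """Construct the reference label volume and its water/fat image pair."""
    if any(d < m for d, m in zip(grid.dims, MIN_DIMS)):
        raise ValidationError(
            f"phantom grid {grid.dims} too small; minimum dims are {MIN_DIMS}"
        )
    xi, eta, zeta = _normalized_coords(grid)
    lab = np.zeros(grid.shape, dtype=np.int16)

    # Legs: two elliptic cylinders, superficial fat shell over a muscle core.
    for cx in (0.33, 0.67):
        r2 = ((xi - cx) / 0.13) ** 2 + ((eta - 0.5) / 0.16) ** 2
        leg = (r2 <= 1.0) & (zeta > 0.02) & (zeta <= 0.50)
        lab[leg] = MUSCLE
        lab[leg & (r2 > 0.60)] = SUBCUT_SUPERFICIAL

    # Torso: elliptic cylinder with two concentric subcutaneous shells over a
    # muscle wall; the interior below the diaphragm is visceral fat.
    rt2 = ((xi - 0.5) / 0.34) ** 2 + ((eta - 0.5) / 0.36) ** 2
    torso = (rt2 <= 1.0) & (zeta > 0.50) & (zeta <= 0.95)
    lab[torso] = MUSCLE
    lab[torso & (rt2 > 0.72)] = SUBCUT_SUPERFICIAL
    lab[torso & (rt2 <= 0.72) & (rt2 > 0.52)] = SUBCUT_DEEP
    interior = torso & (rt2 <= 0.34)
    lab[interior & (zeta > 0.52) & (zeta <= 0.80)] = VISCERAL_FAT

    # Liver (right upper abdomen) and two lungs, carved from the interior.
    liver = (
        ((xi - 0.60) / 0.15) ** 2
        + ((eta - 0.45) / 0.22) ** 2
        + ((zeta - 0.735) / 0.055) ** 2
    ) <= 1.0
    lab[liver & interior] = LIVER
    for cx in (0.40, 0.60):
        lung = (
            ((xi - cx) / 0.09) ** 2
            + ((eta - 0.5) / 0.18) ** 2
            + ((zeta - 0.865) / 0.065) ** 2
        ) <= 1.0
        lab[lung & interior] = LUNG

    # Arms: muscle columns flanking the torso.
    arm_masks = {}
    for cx, seg in ((0.10, ARM_LEFT), (0.90, ARM_RIGHT)):
        arm = (((xi - cx) / 0.06) ** 2 + ((eta - 0.5) / 0.10) ** 2 <= 1.0) & (
            zeta > 0.55
        ) & (zeta <= 0.92)
        lab[arm] = MUSCLE
        arm_masks[seg] = (cx, arm)

    # Bones last, overwriting whatever they pass through.
    spine = (((xi - 0.5) / 0.045) ** 2 + ((eta - 0.66) / 0.07) ** 2 <= 1.0) & (
        zeta > 0.52
    ) & (zeta <= 0.94)
    lab[spine & torso] = SPINE
    pelvis = (
        (np.abs(xi - 0.5) <= 0.20)
        & (np.abs(eta - 0.5) <= 0.08)
        & (zeta > 0.50)
        & (zeta <= 0.56)
    )
    lab[pelvis & torso] = PELVIS
    for cx, seg in ((0.33, FEMUR_LEFT), (0.67, FEMUR_RIGHT)):
        core = (((xi - cx) / 0.05) ** 2 + ((eta - 0.5) / 0.06) ** 2 <= 1.0) & (
            zeta > 0.05
        ) & (zeta <= 0.48)
        lab[core] = seg
    for seg, (cx, arm) in arm_masks.items():
        core = (((xi - cx) / 0.03) ** 2 + ((eta - 0.5) / 0.05) ** 2 <= 1.0) & (
            zeta > 0.57
        ) & (zeta <= 0.90)
        lab[core & arm] = seg

    labels = TissueLabelVolume(grid, lab)

    water = np.zeros(grid.shape)
    fat = np.zeros(grid.shape)
    for label in ALL_LABELS:
        key = "bone" if label >= BONE_BASE else label
        m = lab == label
        water[m] = WATER_INTENSITY[key]
        fat[m] = FAT_INTENSITY[key]
    water = np.clip(gaussian_filter(water, _IMAGE_SMOOTH_VOXELS), 0.0, None)
    fat = np.clip(gaussian_filter(fat, _IMAGE_SMOOTH_VOXELS), 0.0, None)

    wf = WaterFatVolume(ScalarVolume(grid, water), ScalarVolume(grid, fat))
    return labels, wf
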