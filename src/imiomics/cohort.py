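"""Synthetic whole-body cohort generator with a known, recoverable effect structure.

The generator emulates a population-based cohort of 50-year-olds imaged with
whole-body water-fat MRI and phenotyped by DXA:

* Covariates (height, fat mass, lean mass, waist/hip ratio) are drawn per sex
  from a multivariate normal whose marginal means and SDs match the study
  population (women: fat 26.7 (9.9) kg, lean 42.3 (4.7) kg, WHR 0.87 (0.07);
  men: fat 22.0 (8.8) kg, lean 60.2 (5.9) kg, WHR 0.93 (0.06); heights
  166.2 (6.6) / 179.2 (6.3) cm).  Weight is fat + lean + a fixed per-sex
  residual mass (bone mineral etc.) chosen so mean weight matches the
  population (71.8 / 85.7 kg).
* Each subject's anatomy is a smooth deformation of the reference phantom.
  Effects are specified on the log-Jacobian (local log volume ratio) per
  tissue: subcutaneous, visceral and liver expand with fat-mass z-score,
  lungs shrink with it, muscle and bone expand with lean-mass z-score, and
  upper-body fat carries extra expansion with WHR z-score.  The displacement
  realising those targets is the gradient of a Poisson potential whose
  divergence equals the target volume change (small-strain construction), so
  designed expansion is directly testable against the Jacobian map.
* Voxel fat fraction in adipose tissue increases with fat-mass z-score;
  water/fat channels carry additive Gaussian image noise.
* DXA readouts are the true masses under multiplicative lognormal measurement
  noise with the instrument's stated precision errors (CV 1.5% fat, 1.0% lean).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dstn, idstn
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ValidationError
from .fields import DeformationField, estimate_inverse
from .grids import (
    ADIPOSE_LABELS,
    LIVER,
    LUNG,
    MUSCLE,
    SUBCUTANEOUS_LABELS,
    VISCERAL_FAT,
    ImageGrid3D,
    ScalarVolume,
    TissueLabelVolume,
    WaterFatVolume,
    compute_fat_fraction,
    snap_near_integer,
)
from .phantom import build_reference_phantom

# Population marginals per sex: mean and SD of height (cm), fat mass (kg),
# lean mass (kg) and waist/hip ratio, plus mean weight (kg).
POPULATION_STATS = {
    "female": {
        "height": (166.2, 6.6),
        "fat_mass": (26.7, 9.9),
        "lean_mass": (42.3, 4.7),
        "whr": (0.87, 0.07),
        "weight_mean": 71.8,
    },
    "male": {
        "height": (179.2, 6.3),
        "fat_mass": (22.0, 8.8),
        "lean_mass": (60.2, 5.9),
        "whr": (0.93, 0.06),
        "weight_mean": 85.7,
    },
}

# Residual (non-fat, non-lean) mass reconciling mean weight with fat+lean means.
RESIDUAL_MASS_KG = {
    sex: s["weight_mean"] - s["fat_mass"][0] - s["lean_mass"][0]
    for sex, s in POPULATION_STATS.items()
}

# Within-sex correlations among (height, fat_mass, lean_mass, whr).  The study
# reports only marginals; these are a realistic, configurable invention.
COVARIATE_CORRELATION = np.array(
    [
        [1.0, 0.2, 0.5, 0.2],
        [0.2, 1.0, 0.2, 0.4],
        [0.5, 0.2, 1.0, 0.2],
        [0.2, 0.4, 0.2, 1.0],
    ]
)

HIP_BASE_CM = {"female": 102.0, "male": 100.0}


@dataclass(frozen=True)
class SubjectRecord:
    """Anthropometrics and body-composition covariates of one subject."""

    id: str
    sex: str
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    fat_mass: float  # kg
    lean_mass: float  # kg
    waist: float  # cm
    hip: float  # cm
    whr: float

    def __post_init__(self):
        if self.sex not in POPULATION_STATS:
            raise ValidationError(f"unknown sex {self.sex!r}")
        for name in ("height", "weight", "bmi", "fat_mass", "lean_mass", "waist", "hip", "whr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive for subject {self.id}")
        if abs(self.whr - self.waist / self.hip) > 1e-6:
            raise ValidationError("whr inconsistent with waist/hip")
        if abs(self.bmi - self.weight / (self.height / 100.0) ** 2) > 1e-3:
            raise ValidationError("bmi inconsistent with weight/height")


@dataclass(frozen=True)
class TissueEffects:
    """Per-tissue log-Jacobian effect sizes per covariate z-score unit.

    Chosen so that designed voxel-wise |r| comfortably exceeds the 0.5
    reporting threshold at cohort sizes around 150 per sex, and configurable.
    """

    subcutaneous: float = 0.12  # + per z_fat
    visceral: float = 0.10  # + per z_fat
    liver: float = 0.06  # + per z_fat
    lung: float = 0.08  # - per z_fat
    muscle: float = 0.08  # + per z_lean
    bone: float = 0.02  # + per z_lean
    upper_body_whr: float = 0.05  # + per z_whr, upper-body fat only


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a simulated cohort."""

    n_per_sex: int = 5
    seed: int = 0
    dims: tuple[int, int, int] = (48, 32, 96)
    spacing: tuple[float, float, float] = (2.07, 2.07, 8.0)
    noise_sd: float = 0.02  # additive channel noise, intensity units
    dxa_cv_fat: float = 0.015  # DXA fat-mass precision error
    dxa_cv_lean: float = 0.010  # DXA lean-mass precision error
    effects: TissueEffects = field(default_factory=TissueEffects)
    ff_slope: float = 0.05  # adipose fat-fraction shift per z_fat
    smoothing_sd_vox: float = 0.7  # smoothing of the log-Jacobian target, voxels
    render_images: bool = True

    def __post_init__(self):
        if self.n_per_sex < 0:
            raise ValidationError("n_per_sex must be >= 0")
        for name in ("noise_sd", "dxa_cv_fat", "dxa_cv_lean"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def grid(self) -> ImageGrid3D:
        return ImageGrid3D(self.dims, self.spacing)


@dataclass
class GroundTruth:
    """Per-subject simulation truth retained for parameter-recovery tests."""

    subject_id: str
    field: DeformationField  # reference -> subject
    inverse: DeformationField  # subject -> reference
    fat_fraction: ScalarVolume | None  # true (noise-free) subject fat fraction
    fat_mass: float  # kg, true
    lean_mass: float  # kg, true


@dataclass
class CohortSubject:
    record: SubjectRecord  # DXA-measured covariates
    wf: WaterFatVolume | None
    labels: TissueLabelVolume


@dataclass
class Cohort:
    spec: CohortSpec
    reference_labels: TissueLabelVolume
    reference_wf: WaterFatVolume
    subjects: list[CohortSubject]
    truth: list[GroundTruth]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


MASS_FLOOR_KG = 1.0


def _calibrate_truncated_marginal(mean: float, sd: float, floor: float):
    """Pre-truncation (mean, sd) whose floor-truncated normal has the target moments.

    Truncating a mass marginal at the physiologic floor removes lower-tail
    probability and would otherwise bias the sample mean upward by more than
    the calibration tolerance; this inverts the truncated-normal moment map so
    the delivered (post-truncation) marginals match the population table.
    """
    from scipy.optimize import fsolve
    from scipy.stats import truncnorm

    def resid(params):
        mu, sigma = params
        sigma = abs(sigma)
        a = (floor - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    mu, sigma = fsolve(resid, [mean, sd], full_output=False)
    return float(mu), float(abs(sigma))


def sample_covariates(n: int, sex: str, seed) -> list[SubjectRecord]:
    """Draw n subjects of one sex from the population model."""
    if sex not in POPULATION_STATS:
        raise ValidationError(f"unknown sex {sex!r}")
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = _as_rng(seed)
    stats = POPULATION_STATS[sex]
    means = np.array([stats[k][0] for k in ("height", "fat_mass", "lean_mass", "whr")])
    sds = np.array([stats[k][1] for k in ("height", "fat_mass", "lean_mass", "whr")])
    # adjust the mass marginals so the truncated draws match the table moments
    for i in (1, 2):
        means[i], sds[i] = _calibrate_truncated_marginal(means[i], sds[i], MASS_FLOOR_KG)
    cov = COVARIATE_CORRELATION * np.outer(sds, sds)

    records: list[SubjectRecord] = []
    prefix = sex[0]
    while len(records) < n:
        draw = rng.multivariate_normal(means, cov, size=max(n - len(records), 1))
        for height, fat, lean, whr in draw:
            # physiologic truncation by resampling
            if (
                fat <= MASS_FLOOR_KG
                or lean <= MASS_FLOOR_KG
                or height <= 100.0
                or not (0.5 < whr < 1.3)
            ):
                continue
            weight = fat + lean + RESIDUAL_MASS_KG[sex]
            hip = HIP_BASE_CM[sex] + 0.4 * (fat - stats["fat_mass"][0]) + rng.normal(0.0, 2.0)
            hip = max(hip, 70.0)
            waist = whr * hip
            records.append(
                SubjectRecord(
                    id=f"{prefix}{len(records):04d}",
                    sex=sex,
                    height=float(height),
                    weight=float(weight),
                    bmi=float(weight / (height / 100.0) ** 2),
                    fat_mass=float(fat),
                    lean_mass=float(lean),
                    waist=float(waist),
                    hip=float(hip),
                    whr=float(whr),
                )
            )
            if len(records) == n:
                break
    return records


def covariate_zscores(rec: SubjectRecord) -> tuple[float, float, float]:
    """(z_fat, z_lean, z_whr) of a record within its sex's population model."""
    stats = POPULATION_STATS[rec.sex]
    return (
        (rec.fat_mass - stats["fat_mass"][0]) / stats["fat_mass"][1],
        (rec.lean_mass - stats["lean_mass"][0]) / stats["lean_mass"][1],
        (rec.whr - stats["whr"][0]) / stats["whr"][1],
    )


def _upper_body_mask(labels: TissueLabelVolume) -> np.ndarray:
    """Body voxels in the upper 40% of the body's z extent."""
    body = labels.body_mask()
    zs = np.nonzero(body.any(axis=(0, 1)))[0]
    zcut = zs[0] + 0.6 * (zs[-1] - zs[0])
    upper = np.zeros_like(body)
    upper[:, :, int(np.ceil(zcut)) :] = True
    return body & upper


def designed_log_jacobian(
    rec: SubjectRecord, labels: TissueLabelVolume, spec: CohortSpec
) -> np.ndarray:
    """Smoothed per-voxel log-Jacobian target for one subject.

    This is the quantity the deformation construction aims to realise; tests
    compare jacobian_map output against exp() of this array in organ interiors.
    """
    z_fat, z_lean, z_whr = covariate_zscores(rec)
    e = spec.effects
    lab = labels.labels
    L = np.zeros(labels.grid.shape)
    L[np.isin(lab, SUBCUTANEOUS_LABELS)] += e.subcutaneous * z_fat
    L[lab == VISCERAL_FAT] += e.visceral * z_fat
    L[lab == LIVER] += e.liver * z_fat
    L[lab == LUNG] -= e.lung * z_fat
    L[lab == MUSCLE] += e.muscle * z_lean
    L[labels.bone_mask()] += e.bone * z_lean
    upper_fat = _upper_body_mask(labels) & labels.mask(*ADIPOSE_LABELS)
    L[upper_fat] += e.upper_body_whr * z_whr

    L = gaussian_filter(L, spec.smoothing_sd_vox)
    return L * _boundary_taper(labels.grid)


def _boundary_taper(grid: ImageGrid3D, margin: int = 3) -> np.ndarray:
    """Smooth window that is 0 on the outermost voxels and 1 in the interior."""
    ramps = []
    for d in grid.dims:
        r = np.ones(d)
        m = min(margin, (d - 1) // 2)
        edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(m + 1) / (m + 1)))
        r[: m + 1] = edge
        r[d - m - 1 :] = edge[::-1]
        ramps.append(r)
    return ramps[0][:, None, None] * ramps[1][None, :, None] * ramps[2][None, None, :]


def _solve_poisson_dirichlet(rhs: np.ndarray, spacing) -> np.ndarray:
    """Solve laplacian(psi) = rhs with psi = 0 just outside the grid (DST-I)."""
    n = rhs.shape
    lam = np.zeros(n)
    for ax, (d, h) in enumerate(zip(n, spacing)):
        k = np.arange(1, d + 1)
        lam_ax = (2.0 * np.cos(np.pi * k / (d + 1)) - 2.0) / h**2
        shape = [1, 1, 1]
        shape[ax] = d
        lam = lam + lam_ax.reshape(shape)
    coeff = dstn(rhs, type=1)
    return idstn(coeff / lam, type=1)


def covariate_deformation(
    rec: SubjectRecord, labels: TissueLabelVolume, spec: CohortSpec
) -> DeformationField:
    """Smooth reference->subject field realising the per-tissue volume targets.

    The target local volume ratio J = exp(L) is converted to a displacement by
    solving laplacian(psi) = J - 1 and taking u = grad(psi), for which
    div(u) = J - 1 and hence det(I + grad u) ~= J to second order in the
    effect sizes.  The field is tapered to zero at the grid boundary.
    """
    from .morphometry import jacobian_map  # local import to avoid a cycle

    L = designed_log_jacobian(rec, labels, spec)
    psi = _solve_poisson_dirichlet(np.expm1(L), labels.grid.spacing)
    u = np.stack(np.gradient(psi, *labels.grid.spacing), axis=-1)
    u *= _boundary_taper(labels.grid)[..., None]
    fld = DeformationField(labels.grid, u)
    jmin = float(jacobian_map(fld).j.min())
    if jmin <= 0:
        raise ValidationError(
            f"effect sizes produce a non-invertible field (min Jacobian {jmin:.3f})"
        )
    return fld


def warp_labels_to_subject(
    labels: TissueLabelVolume, inverse: DeformationField
) -> TissueLabelVolume:
    """Nearest-neighbour warp of the reference labels into subject space."""
    y = inverse.grid.voxel_centers() + inverse.u
    idx = snap_near_integer(labels.grid.world_to_index(y))
    coords = np.moveaxis(idx.reshape(-1, 3), -1, 0)
    lab = map_coordinates(labels.labels, coords, order=0, mode="constant", cval=0)
    return TissueLabelVolume(inverse.grid, lab.reshape(inverse.grid.shape))


def _render(
    reference_wf: WaterFatVolume,
    labels: TissueLabelVolume,
    field: DeformationField,
    rec: SubjectRecord,
    spec: CohortSpec,
    rng: np.random.Generator | None,
    inverse: DeformationField | None = None,
) -> tuple[WaterFatVolume, ScalarVolume, TissueLabelVolume]:
    if inverse is None:
        inverse = estimate_inverse(field)
    y = inverse.grid.voxel_centers() + inverse.u

    def _sample(vol: ScalarVolume) -> np.ndarray:
        idx = snap_near_integer(vol.grid.world_to_index(y))
        coords = np.moveaxis(idx.reshape(-1, 3), -1, 0)
        return map_coordinates(
            vol.values, coords, order=1, mode="constant", cval=0.0
        ).reshape(inverse.grid.shape)

    water = _sample(reference_wf.water)
    fat = _sample(reference_wf.fat)
    subj_labels = warp_labels_to_subject(labels, inverse)

    z_fat, _, _ = covariate_zscores(rec)
    shift = spec.ff_slope * z_fat
    if shift != 0.0:
        total = water + fat
        eps = 1e-6 * float(total.max()) if total.max() > 0 else 1e-6
        ff = np.zeros_like(total)
        m = total > eps
        ff[m] = fat[m] / total[m]
        adipose = subj_labels.mask(*ADIPOSE_LABELS)
        ff[adipose] = np.clip(ff[adipose] + shift, 0.0, 1.0)
        water = total * (1.0 - ff)
        fat = total * ff

    true_ff = compute_fat_fraction(
        WaterFatVolume(
            ScalarVolume(inverse.grid, water), ScalarVolume(inverse.grid, fat)
        )
    )
    if rng is not None and spec.noise_sd > 0:
        water = np.clip(water + rng.normal(0.0, spec.noise_sd, water.shape), 0.0, None)
        fat = np.clip(fat + rng.normal(0.0, spec.noise_sd, fat.shape), 0.0, None)
    wf = WaterFatVolume(ScalarVolume(inverse.grid, water), ScalarVolume(inverse.grid, fat))
    return wf, ScalarVolume(inverse.grid, true_ff.ff), subj_labels


def render_subject(
    reference_wf: WaterFatVolume,
    labels: TissueLabelVolume,
    field: DeformationField,
    rec: SubjectRecord,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    inverse: DeformationField | None = None,
) -> WaterFatVolume:
    """Render one subject's water/fat pair from the reference through the field.

    The subject image is the reference resampled at the inverse mapping,
    with the adipose fat fraction shifted by ff_slope * z_fat and additive
    Gaussian channel noise (skipped when ``rng`` is None).
    """
    wf, _, _ = _render(reference_wf, labels, field, rec, spec, rng, inverse)
    return wf


def simulate_dxa(
    fat_mass_true: float, lean_mass_true: float, spec: CohortSpec, rng
) -> tuple[float, float]:
    """DXA-like readout: multiplicative lognormal noise with the configured CVs."""
    if fat_mass_true <= 0 or lean_mass_true <= 0:
        raise ValidationError("true masses must be positive")
    rng = _as_rng(rng)
    out = []
    for true, cv in ((fat_mass_true, spec.dxa_cv_fat), (lean_mass_true, spec.dxa_cv_lean)):
        if cv == 0:
            out.append(float(true))
        else:
            sigma = np.sqrt(np.log1p(cv**2))
            out.append(float(true * np.exp(rng.normal(0.0, sigma))))
    return out[0], out[1]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the reference phantom plus a full two-sex cohort.

    Deterministic given ``spec.seed``; each subject's randomness is keyed by
    (seed, subject index) so results do not depend on generation order.
    """
    grid = spec.grid
    ref_labels, ref_wf = build_reference_phantom(grid)

    records: list[SubjectRecord] = []
    for i, sex in enumerate(("female", "male")):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + i]))
        records.extend(sample_covariates(spec.n_per_sex, sex, rng))

    subjects: list[CohortSubject] = []
    truth: list[GroundTruth] = []
    for k, rec in enumerate(records):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2000, k]))
        fld = covariate_deformation(rec, ref_labels, spec)
        inv = estimate_inverse(fld)
        if spec.render_images:
            wf, true_ff, subj_labels = _render(ref_wf, ref_labels, fld, rec, spec, rng, inv)
        else:
            wf, true_ff = None, None
            subj_labels = warp_labels_to_subject(ref_labels, inv)
        fat_meas, lean_meas = simulate_dxa(rec.fat_mass, rec.lean_mass, spec, rng)
        measured = replace(rec, fat_mass=fat_meas, lean_mass=lean_meas)
        subjects.append(CohortSubject(record=measured, wf=wf, labels=subj_labels))
        truth.append(
            GroundTruth(
                subject_id=rec.id,
                field=fld,
                inverse=inv,
                fat_fraction=true_ff,
                fat_mass=rec.fat_mass,
                lean_mass=rec.lean_mass,
            )
        )
    return Cohort(spec, ref_labels, ref_wf, subjects, truth)
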