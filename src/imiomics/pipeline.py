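"""End-to-end pipeline driver: simulate -> register -> morphometry -> stats -> report.

Every stage is idempotent: it checks for its artifacts on disk and recomputes
only what is missing, so a run can resume after interruption and individual
stages can be re-run from the CLI.  Stage failures raise PipelineError naming
the stage and, where applicable, the subject; the CLI maps that to a nonzero
exit status.

Artifact tree under ``out_dir``::

    config.yaml
    cohort/covariates.csv, reference_*.nii.gz, subjects/, truth/
    fields/<id>.nii.gz, convergence.csv
    maps/jacobian_<id>.nii.gz, r_/p_/rho_<imaging>_<covariate>_<sex>.nii.gz
    clusters/clusters.csv
    report/*.png
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cohort import Cohort, CohortSpec, generate_cohort
from .errors import PipelineError, ValidationError
from .grids import (
    ScalarVolume,
    TissueLabelVolume,
    WaterFatVolume,
    compute_fat_fraction,
    warp_to_reference,
)
from .morphometry import jacobian_map
from .registration import RegistrationConfig, register_subject
from .reporting import export_slice
from .stats import (
    VolumeStack,
    concordance_filter,
    p_value_map,
    pearson_map,
    spearman_map,
    threshold_clusters,
)

logger = logging.getLogger("imiomics")

STAGES = ("simulate", "register", "jacobian", "correlate", "cluster", "report")

COVARIATE_COLUMNS = (
    "id",
    "sex",
    "height",
    "weight",
    "bmi",
    "fat_mass",
    "lean_mass",
    "waist",
    "hip",
    "whr",
)


@dataclass
class RunConfig:
    out_dir: str
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    registration: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    r_threshold: float = 0.50
    p_threshold: float = 0.05
    min_cluster: int = 10
    overlap_threshold: float = 0.3
    rho_threshold: float = 0.5
    covariates: tuple[str, ...] = ("fat_mass", "lean_mass", "whr")
    imaging: tuple[str, ...] = ("volume", "fat_fraction")
    sexes: tuple[str, ...] = ("female", "male")
    use_registration: bool = True
    verbose: bool = False

    def __post_init__(self):
        if not 0 < self.r_threshold < 1:
            raise ValidationError("r_threshold must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must lie in (0, 1)")
        for c in self.covariates:
            if c not in COVARIATE_COLUMNS[2:]:
                raise ValidationError(f"unknown covariate {c!r}")
        for i in self.imaging:
            if i not in ("volume", "fat_fraction"):
                raise ValidationError(f"unknown imaging parameter {i!r}")


class _Paths:
    def __init__(self, out_dir):
        self.root = Path(out_dir)
        self.cohort = self.root / "cohort"
        self.subjects = self.cohort / "subjects"
        self.truth = self.cohort / "truth"
        self.fields = self.root / "fields"
        self.maps = self.root / "maps"
        self.clusters = self.root / "clusters"
        self.report = self.root / "report"

    def covariates_csv(self):
        return self.cohort / "covariates.csv"

    def subject_file(self, sid, what):
        return self.subjects / f"{sid}_{what}.nii.gz"

    def truth_field(self, sid):
        return self.truth / f"{sid}_field.nii.gz"

    def reg_field(self, sid):
        return self.fields / f"{sid}.nii.gz"

    def jacobian(self, sid):
        return self.maps / f"jacobian_{sid}.nii.gz"

    def stat_map(self, kind, imaging, covariate, sex):
        return self.maps / f"{kind}_{imaging}_{covariate}_{sex}.nii.gz"


def _fail(stage: str, subject: str | None, exc: Exception) -> PipelineError:
    who = f", subject {subject}" if subject else ""
    return PipelineError(f"stage '{stage}'{who}: {exc}")


def _stage_simulate(cfg: RunConfig, paths: _Paths) -> None:
    csv = paths.covariates_csv()
    if csv.exists():
        logger.info("simulate: cached (%s)", csv)
        return
    for d in (paths.cohort, paths.subjects, paths.truth):
        io.ensure_dir(d)
    cohort = generate_cohort(cfg.cohort)
    io.write_labels(cohort.reference_labels, paths.cohort / "reference_labels.nii.gz")
    io.write_volume(cohort.reference_wf.water, paths.cohort / "reference_water.nii.gz")
    io.write_volume(cohort.reference_wf.fat, paths.cohort / "reference_fat.nii.gz")
    rows = []
    for subj, truth in zip(cohort.subjects, cohort.truth):
        rec = subj.record
        rows.append({c: getattr(rec, c) for c in COVARIATE_COLUMNS})
        sid = rec.id
        if subj.wf is not None:
            io.write_volume(subj.wf.water, paths.subject_file(sid, "water"))
            io.write_volume(subj.wf.fat, paths.subject_file(sid, "fat"))
        io.write_labels(subj.labels, paths.subject_file(sid, "labels"))
        io.write_field(truth.field, paths.truth_field(sid))
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(csv, index=False)
    io.write_config(cfg.cohort, paths.cohort / "cohort_spec.yaml")


def _read_covariates(paths: _Paths) -> pd.DataFrame:
    return pd.read_csv(paths.covariates_csv())


def _load_reference(paths: _Paths):
    labels = io.read_labels(paths.cohort / "reference_labels.nii.gz")
    wf = WaterFatVolume(
        io.read_volume(paths.cohort / "reference_water.nii.gz"),
        io.read_volume(paths.cohort / "reference_fat.nii.gz"),
    )
    return labels, wf


def _load_subject(paths: _Paths, sid: str) -> tuple[WaterFatVolume, TissueLabelVolume]:
    wf = WaterFatVolume(
        io.read_volume(paths.subject_file(sid, "water")),
        io.read_volume(paths.subject_file(sid, "fat")),
    )
    labels = io.read_labels(paths.subject_file(sid, "labels"))
    return wf, labels


def _stage_register(cfg: RunConfig, paths: _Paths) -> None:
    io.ensure_dir(paths.fields)
    table = _read_covariates(paths)
    ref_labels, ref_wf = _load_reference(paths)
    conv_rows = []
    for sid in table["id"]:
        out = paths.reg_field(sid)
        if out.exists():
            continue
        if not cfg.use_registration:
            # analysis from retained simulation truth: copy the true field
            try:
                fld = io.read_field(paths.truth_field(sid))
            except Exception as exc:
                raise _fail("register", sid, exc)
            io.write_field(fld, out)
            continue
        try:
            subj_wf, subj_labels = _load_subject(paths, sid)
            log: list = []
            t0 = time.perf_counter()
            fld = register_subject(
                ref_wf, ref_labels, subj_wf, cfg.registration, subj_labels, log
            )
            logger.info(
                "register: %s done in %.1fs (%d iterations)",
                sid,
                time.perf_counter() - t0,
                len(log),
            )
            conv_rows.extend((sid, lv, it, m) for lv, it, m in log)
        except PipelineError:
            raise
        except Exception as exc:
            raise _fail("register", sid, exc)
        io.write_field(fld, out)
    if conv_rows:
        pd.DataFrame(
            conv_rows, columns=["id", "level", "iteration", "metric"]
        ).to_csv(paths.fields / "convergence.csv", index=False)


def _stage_jacobian(cfg: RunConfig, paths: _Paths) -> None:
    io.ensure_dir(paths.maps)
    table = _read_covariates(paths)
    for sid in table["id"]:
        out = paths.jacobian(sid)
        if out.exists():
            continue
        try:
            fld = io.read_field(paths.reg_field(sid))
            jm = jacobian_map(fld)
        except Exception as exc:
            raise _fail("jacobian", sid, exc)
        io.write_volume(ScalarVolume(jm.grid, jm.j), out)


def _fat_fraction_in_reference(paths: _Paths, sid: str) -> ScalarVolume:
    fld = io.read_field(paths.reg_field(sid))
    subj_wf, _ = _load_subject(paths, sid)
    water = warp_to_reference(subj_wf.water, fld)
    fat = warp_to_reference(subj_wf.fat, fld)
    return ScalarVolume(fld.grid, compute_fat_fraction(WaterFatVolume(water, fat)).ff)


def _stage_correlate(cfg: RunConfig, paths: _Paths) -> None:
    io.ensure_dir(paths.maps)
    table = _read_covariates(paths)
    body = io.read_labels(paths.cohort / "reference_labels.nii.gz").body_mask()
    for sex in cfg.sexes:
        sub = table[table["sex"] == sex]
        ids = list(sub["id"])
        if len(ids) < 3:
            raise _fail("correlate", None, ValidationError(f"need >= 3 {sex} subjects"))
        for imaging in cfg.imaging:
            targets = [
                paths.stat_map(kind, imaging, cov, sex)
                for cov in cfg.covariates
                for kind in ("r", "p", "rho")
            ]
            if all(t.exists() for t in targets):
                continue
            vols = []
            for sid in ids:
                try:
                    if imaging == "volume":
                        vols.append(io.read_volume(paths.jacobian(sid)))
                    else:
                        vols.append(_fat_fraction_in_reference(paths, sid))
                except Exception as exc:
                    raise _fail("correlate", sid, exc)
            stack = VolumeStack.from_volumes(vols, ids)
            for cov in cfg.covariates:
                x = sub[cov].to_numpy()
                rmap = pearson_map(stack, x, name=cov, mask=body)
                rho = spearman_map(stack, x, name=cov, mask=body)
                pmap = p_value_map(rmap)
                io.write_volume(
                    ScalarVolume(stack.grid, np.nan_to_num(rmap.r)),
                    paths.stat_map("r", imaging, cov, sex),
                )
                io.write_volume(pmap, paths.stat_map("p", imaging, cov, sex))
                io.write_volume(
                    ScalarVolume(stack.grid, np.nan_to_num(rho.r)),
                    paths.stat_map("rho", imaging, cov, sex),
                )


def _read_stat_maps(cfg, paths, imaging, cov, sex):
    from .stats import CorrelationMap

    r = io.read_volume(paths.stat_map("r", imaging, cov, sex))
    p = io.read_volume(paths.stat_map("p", imaging, cov, sex))
    rho = io.read_volume(paths.stat_map("rho", imaging, cov, sex))
    n = 3  # n is only needed for p computation, already materialised in p map
    rmap = CorrelationMap(r.grid, np.where(r.values == 0, np.nan, r.values), n, "pearson", cov)
    rhomap = CorrelationMap(
        rho.grid, np.where(rho.values == 0, np.nan, rho.values), n, "spearman", cov
    )
    return rmap, p, rhomap


def _stage_cluster(cfg: RunConfig, paths: _Paths) -> None:
    io.ensure_dir(paths.clusters)
    out = paths.clusters / "clusters.csv"
    if out.exists():
        return
    rows = []
    for imaging in cfg.imaging:
        for cov in cfg.covariates:
            per_sex = {}
            for sex in cfg.sexes:
                rmap, pmap, rho = _read_stat_maps(cfg, paths, imaging, cov, sex)
                cs = threshold_clusters(
                    rmap, pmap, cfg.r_threshold, cfg.p_threshold, cfg.min_cluster
                )
                per_sex[sex] = (cs, rho)
            if set(cfg.sexes) >= {"female", "male"}:
                kept_f, kept_m = concordance_filter(
                    per_sex["female"][0],
                    per_sex["male"][0],
                    per_sex["female"][1],
                    per_sex["male"][1],
                    cfg.overlap_threshold,
                    cfg.rho_threshold,
                )
                retained = {
                    "female": {c.cluster_id for c in kept_f.clusters},
                    "male": {c.cluster_id for c in kept_m.clusters},
                }
            else:
                retained = {s: None for s in cfg.sexes}
            for sex in cfg.sexes:
                for c in per_sex[sex][0].clusters:
                    keep = retained[sex]
                    rows.append(
                        {
                            "imaging": imaging,
                            "covariate": cov,
                            "sex": sex,
                            "cluster_id": c.cluster_id,
                            "sign": c.sign,
                            "size": c.size,
                            "mean_r": c.mean_r,
                            "max_abs_r": c.max_abs_r,
                            "centroid_x_mm": c.centroid_mm[0],
                            "centroid_y_mm": c.centroid_mm[1],
                            "centroid_z_mm": c.centroid_mm[2],
                            "retained": (None if keep is None else c.cluster_id in keep),
                        }
                    )
    pd.DataFrame(
        rows,
        columns=[
            "imaging",
            "covariate",
            "sex",
            "cluster_id",
            "sign",
            "size",
            "mean_r",
            "max_abs_r",
            "centroid_x_mm",
            "centroid_y_mm",
            "centroid_z_mm",
            "retained",
        ],
    ).to_csv(out, index=False)


def _stage_report(cfg: RunConfig, paths: _Paths) -> None:
    from .stats import CorrelationMap

    io.ensure_dir(paths.report)
    for imaging in cfg.imaging:
        for cov in cfg.covariates:
            for sex in cfg.sexes:
                png = paths.report / f"r_{imaging}_{cov}_{sex}_coronal.png"
                if png.exists():
                    continue
                r = io.read_volume(paths.stat_map("r", imaging, cov, sex))
                cmap = CorrelationMap(
                    r.grid, np.where(r.values == 0, np.nan, r.values), 3, "pearson", cov
                )
                export_slice(cmap, "coronal", r.grid.dims[1] // 2, png)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "register": _stage_register,
    "jacobian": _stage_jacobian,
    "correlate": _stage_correlate,
    "cluster": _stage_cluster,
    "report": _stage_report,
}


def run_stages(cfg: RunConfig, upto: str = "report") -> int:
    """Run the pipeline through ``upto`` (inclusive). Returns 0 on success."""
    if upto not in STAGES:
        raise ValidationError(f"unknown stage {upto!r}")
    if cfg.verbose:
        logging.basicConfig(level=logging.INFO)
    io.ensure_dir(cfg.out_dir)
    io.write_config(cfg.cohort, Path(cfg.out_dir) / "config.yaml")
    for stage in STAGES[: STAGES.index(upto) + 1]:
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](cfg, _Paths(cfg.out_dir))
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    return 0


def run_pipeline(cfg: RunConfig) -> int:
    """Execute the full pipeline; returns 0 on success, raises PipelineError on failure."""
    return run_stages(cfg, "report")
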