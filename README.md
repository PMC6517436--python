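# imiomics

Whole-body, voxel-wise image analysis of water-fat MRI against body-composition
phenotypes, exercised end to end on a synthetic phantom cohort.

## The problem

Conventional body-composition imaging quantifies predefined regions of interest
(liver fat, visceral fat area, thigh muscle volume, ...). Whole-body voxel-wise
analysis takes the opposite approach: every subject's whole-body scan is
deformably registered to one reference subject, so that each voxel of the
reference coordinate system carries a corresponding observation from every
subject in the cohort. Any scalar phenotype can then be correlated against
imaging parameters *at every voxel*, producing anatomical correlation maps with
no prior hypothesis about depots — at the cost of ~10⁷ statistical tests whose
false positives must be controlled by cluster- and concordance-based filtering
rather than formal correction.

This package implements that pipeline for researchers who want to prototype or
validate such analyses without access to a real cohort:

- **Registration** (`imiomics.registration`) — the three-step tissue-sequential
  scheme: (1) articulated piece-wise affine registration of bone segments from
  landmark sets, blended into a dense initialisation; (2) demons-style
  multi-resolution deformable registration of the water channels with bone
  displacements frozen; (3) the same on the fat channels with bone and
  water-dominant lean tissue frozen. The result is a dense displacement field
  u(x) with φ(x) = x + u(x) mapping reference points to subject points.
- **Morphometry** (`imiomics.morphometry`) — local tissue volume as the
  Jacobian determinant J(x) = det(I + ∇u(x)) (J > 1 local expansion, J < 1
  contraction), total volumes, and inverse-consistency error
  ‖φ_bwd(φ_fwd(x)) − x‖ as the registration-quality score.
- **Voxel statistics** (`imiomics.stats`) — per-voxel Pearson r and Spearman ρ
  of an imaging parameter (J or fat fraction) against a covariate, p-values via
  t = r√((n−2)/(1−r²)), 26-connected cluster thresholding (|r| > 0.50 with
  uniformly p < 0.05), and the concordance filter (sign-matched Dice overlap
  between the sexes' clusters plus Spearman robustness).
- **Synthetic cohort** (`imiomics.cohort`, `imiomics.phantom`) — a deterministic
  body-like phantom (articulated skeleton, lungs, liver, muscle, visceral fat,
  superficial/deep subcutaneous fat) and a generator that embeds a known,
  recoverable effect structure: subcutaneous/visceral/liver expansion and lung
  shrinkage with fat mass, muscle/bone expansion with lean mass, upper-body fat
  expansion with waist-hip ratio, adipose fat-fraction shifts with fat mass,
  image noise, and DXA-like covariate readouts with realistic precision error
  (CV 1.5% fat mass, 1.0% lean mass).

## Worked example

The `analysis/` scripts run the study end to end at desk scale (25 subjects per
sex, 32 × 24 × 64 voxels of 2.07 × 2.07 × 8.0 mm) and write their tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_registration_accuracy.py
python analysis/03_correlation_maps.py
python analysis/04_cluster_findings.py
```

`02_registration_accuracy.py` registers one rendered subject forward and
backward against the reference and prints:

```
mean ground-truth field error over the body: 4.377 mm
whole-body mean inverse consistency:         0.833 mm (benchmark < 5 mm)
```

i.e. the estimated field deviates from the generator's retained ground truth by
4.4 mm on average (voxels are up to 8 mm), and the composed forward/backward
registration returns body points to within 0.83 mm on average — well inside the
5 mm whole-body benchmark for this class of pipeline.

`03_correlation_maps.py` prints the mean correlation with fat mass per tissue:

```
imaging      fat_fraction        volume
sex                female   male female   male
tissue
liver               0.056 -0.010  0.965  0.960
lung               -0.018 -0.039 -0.872 -0.828
muscle              0.019 -0.003  0.441  0.324
subcutaneous        0.878  0.865  0.841  0.858
visceral_fat        0.931  0.921  0.871  0.912
```

reading: local *tissue volume* correlates positively with fat mass in the
subcutaneous, visceral and liver compartments and negatively in the lungs,
while voxel *fat fraction* correlates with fat mass only inside adipose tissue
— exactly the effect structure the generator embeds, recovered through the
maps. `04_cluster_findings.py` then applies the full reporting filter; the
retained findings include the subcutaneous-positive and lung-negative volume
clusters and adipose-confined fat-fraction clusters in both sexes.

A `imiomics` CLI exposes the same stages (`simulate`, `register`, `jacobian`,
`correlate`, `cluster`, `report`, `run-all`) over a YAML config.

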