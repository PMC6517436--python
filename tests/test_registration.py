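"""Three-step registration: articulated bone step, blending, demons, pipeline."""
import numpy as np
import pytest
from scipy.ndimage import binary_dilation, gaussian_filter

from imiomics.errors import MissingSegmentError
from imiomics.fields import estimate_inverse, identity_field
from imiomics.grids import (
    DeformationField,
    ImageGrid3D,
    ScalarVolume,
    TissueLabelVolume,
    WaterFatVolume,
)
from imiomics.registration import (
    BoneSegmentTransform,
    RegistrationConfig,
    blend_segment_transforms,
    register_bone_segments,
    register_deformable,
    register_subject,
)


def _translated(wf_or_labels, t):
    """Same voxel data with the origin shifted: the world-space translation of a volume."""
    g = wf_or_labels.grid
    g2 = ImageGrid3D(g.dims, g.spacing, tuple(np.asarray(g.origin) + np.asarray(t)))
    if isinstance(wf_or_labels, TissueLabelVolume):
        return TissueLabelVolume(g2, wf_or_labels.labels)
    return WaterFatVolume(
        ScalarVolume(g2, wf_or_labels.water.values),
        ScalarVolume(g2, wf_or_labels.fat.values),
    )


class TestBoneStep:
    def test_identity_subject_recovers_identity_transforms(self, phantom_small):
        labels, wf = phantom_small
        for tr in register_bone_segments(labels, wf, wf, subj_labels=labels):
            assert np.abs(tr.A - np.eye(3)).max() < 1e-3
            assert np.abs(tr.t).max() < 1e-3

    def test_global_translation_recovered_per_segment(self, phantom_small):
        labels, wf = phantom_small
        t = (8.0, 0.0, 0.0)
        for tr in register_bone_segments(
            labels, wf, _translated(wf, t), subj_labels=_translated(labels, t)
        ):
            assert np.abs(tr.t - np.array(t)).max() < 0.5
            assert np.abs(tr.A - np.eye(3)).max() < 1e-6

    def test_rotated_femur_recovered_others_unaffected(self, phantom_paperlike):
        labels, wf = phantom_paperlike
        g = labels.grid
        theta = np.deg2rad(10)
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        seg = 12  # one femur
        mask = labels.labels == seg
        pts = g.index_to_world(np.argwhere(mask))
        c = pts.mean(axis=0)
        lab2 = labels.labels.copy()
        lab2[mask] = 3
        nidx = np.round(g.world_to_index((pts - c) @ R.T + c)).astype(int)
        nidx = np.clip(nidx, 0, np.array(g.dims) - 1)
        lab2[tuple(nidx.T)] = seg
        rotated = TissueLabelVolume(g, lab2)
        transforms = register_bone_segments(labels, wf, wf, subj_labels=rotated)
        tr = next(t for t in transforms if t.segment_id == seg)
        # compare the action on the femur's long axis with the true rotation
        x = pts - c
        _, V = np.linalg.eigh(x.T @ x / len(x))
        long_axis = V[:, -1]
        got = tr.A @ long_axis
        got /= np.linalg.norm(got)
        angle = np.degrees(np.arccos(np.clip(abs(got @ (R @ long_axis)), -1, 1)))
        assert angle < 2.0
        for other in transforms:
            if other.segment_id != seg:
                assert np.abs(other.A - np.eye(3)).max() < 0.05

    def test_empty_segment_mask_raises(self, phantom_small):
        labels, wf = phantom_small
        broken = labels.labels.copy()
        broken[broken == 12] = 3
        with pytest.raises(MissingSegmentError):
            register_bone_segments(
                labels, wf, wf, subj_labels=TissueLabelVolume(labels.grid, broken)
            )

    def test_thresholding_fallback_finds_identity(self, phantom_small):
        labels, wf = phantom_small
        for tr in register_bone_segments(labels, wf, wf):
            assert np.abs(tr.t).max() < 3.0


class TestBlend:
    def test_identity_transforms_blend_to_zero_field(self, phantom_small):
        labels, _ = phantom_small
        trs = [
            BoneSegmentTransform(s, np.eye(3), np.zeros(3))
            for s in labels.bone_segment_ids()
        ]
        fld = blend_segment_transforms(trs, labels)
        assert np.abs(fld.u).max() < 1e-12

    def test_single_segment_affine_extends_everywhere(self, phantom_small):
        labels, _ = phantom_small
        A = np.eye(3) * 1.05
        t = np.array([1.0, 2.0, 3.0])
        fld = blend_segment_transforms([BoneSegmentTransform(10, A, t)], labels)
        x = labels.grid.voxel_centers().reshape(-1, 3)
        expected = x @ A.T + t - x
        assert np.abs(fld.u.reshape(-1, 3) - expected).max() < 1e-9

    def test_two_translated_segments_exact_at_their_masks(self, phantom_small):
        labels, _ = phantom_small
        ta, tb = np.array([3.0, 0, 0]), np.array([-2.0, 1.0, 0])
        trs = [
            BoneSegmentTransform(12, np.eye(3), ta),
            BoneSegmentTransform(13, np.eye(3), tb),
        ]
        fld = blend_segment_transforms(trs, labels)
        assert np.allclose(fld.u[labels.labels == 12], ta)
        assert np.allclose(fld.u[labels.labels == 13], tb)


class TestDeformable:
    def test_aligned_images_stay_near_identity(self, phantom_small):
        labels, wf = phantom_small
        f = register_deformable(wf.water, wf.water)
        assert np.abs(f.u).mean() < 0.25 * min(labels.grid.spacing)

    def test_translation_recovered_within_a_voxel(self, phantom_small):
        labels, wf = phantom_small
        moving = ScalarVolume(
            ImageGrid3D(labels.grid.dims, labels.grid.spacing, (6.0, 0.0, 0.0)),
            wf.water.values,
        )
        f = register_deformable(wf.water, moving)
        err = np.linalg.norm(f.u - np.array([6.0, 0, 0]), axis=-1)
        assert err[labels.body_mask()].mean() < min(labels.grid.spacing)

    def test_frozen_mask_preserves_init_bit_exactly(self, phantom_small):
        labels, wf = phantom_small
        init = identity_field(labels.grid)
        init.u[..., 0] = 1.23456789
        moving = ScalarVolume(
            ImageGrid3D(labels.grid.dims, labels.grid.spacing, (6.0, 0.0, 0.0)),
            wf.water.values,
        )
        cfg = RegistrationConfig()
        bone = labels.bone_mask()
        f = register_deformable(wf.water, moving, init, bone, cfg)
        dilated = binary_dilation(bone, iterations=cfg.frozen_dilation)
        assert np.array_equal(f.u[dilated], init.u[dilated])
        assert not np.allclose(f.u[~dilated], init.u[~dilated])

    def test_metric_never_ends_above_start(self, phantom_small):
        labels, wf = phantom_small
        moving = ScalarVolume(
            ImageGrid3D(labels.grid.dims, labels.grid.spacing, (4.0, 2.0, 0.0)),
            wf.water.values,
        )
        log: list = []
        register_deformable(wf.water, moving, log=log)
        by_level = {}
        for level, it, metric in log:
            by_level.setdefault(level, []).append(metric)
        for level, metrics in by_level.items():
            assert metrics[-1] <= metrics[0] * (1 + 1e-12), level


class TestRegisterSubject:
    def test_self_registration_is_near_identity(self, phantom_small):
        labels, wf = phantom_small
        f = register_subject(wf, labels, wf, subject_labels=labels)
        assert np.linalg.norm(f.u, axis=-1).mean() < 1.0

    def test_recovers_generator_ground_truth_field(self, make_record):
        from imiomics.cohort import CohortSpec, covariate_deformation, render_subject, warp_labels_to_subject
        from imiomics.phantom import build_reference_phantom

        spec = CohortSpec(dims=(32, 24, 64), noise_sd=0.0)
        labels, wf = build_reference_phantom(spec.grid)
        rec = make_record(z_fat=1.0, z_lean=0.5)
        fld = covariate_deformation(rec, labels, spec)
        inv = estimate_inverse(fld)
        subj = render_subject(wf, labels, fld, rec, spec, inverse=inv)
        subj_labels = warp_labels_to_subject(labels, inv)
        est = register_subject(wf, labels, subj, subject_labels=subj_labels)
        err = np.linalg.norm(est.u - fld.u, axis=-1)
        assert err[labels.body_mask()].mean() < 2 * max(labels.grid.spacing)

    def test_bone_displacements_survive_both_deformable_stages(self, phantom_small):
        labels, wf = phantom_small
        t = (4.0, 0.0, 0.0)
        subj = _translated(wf, t)
        subj_labels = TissueLabelVolume(
            ImageGrid3D(labels.grid.dims, labels.grid.spacing, t), labels.labels
        )
        transforms = register_bone_segments(labels, wf, subj, subj_labels=subj_labels)
        init = blend_segment_transforms(transforms, labels)
        f = register_subject(wf, labels, subj, subject_labels=subj_labels)
        bone = labels.bone_mask()
        assert np.array_equal(f.u[bone], init.u[bone])
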