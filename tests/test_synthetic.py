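"""Synthetic walker: presets, kinematics, rendering, corruption, cohorts."""

import numpy as np
import pytest
from scipy import stats
from skimage import measure

import gaitpath as gp
from gaitpath.errors import RenderError, ValidationError
from gaitpath.synthetic import PoseFrame, perturb_params


def _recentre(pose, x=80.0):
    dx = x - pose.joints["hip"][0]
    return PoseFrame({k: (px + dx, py) for k, (px, py) in pose.joints.items()})


class TestStylePresets:
    def test_normal_is_symmetric_and_upright(self):
        p = gp.style_preset("normal", 1)
        assert p.hip_amp_left == p.hip_amp_right
        assert p.knee_amp_left == p.knee_amp_right
        assert p.torso_lean == 0.0

    def test_class_signatures(self):
        normal = gp.style_preset("normal", 1)
        park = gp.style_preset("parkinsonian", 1)
        dip = gp.style_preset("diplegic", 1)
        hemi = gp.style_preset("hemiplegic", 1)
        neuro = gp.style_preset("neuropathic", 1)
        assert park.shuffle >= 0.5 and park.step_length < normal.step_length
        assert park.torso_lean > 0
        assert dip.torso_lean > 0
        assert dip.knee_amp_left < normal.knee_amp_left
        assert dip.knee_amp_right < normal.knee_amp_right
        assert hemi.hip_amp_left != hemi.hip_amp_right
        assert max(neuro.foot_lift_left, neuro.foot_lift_right) > 0

    @pytest.mark.parametrize("label", gp.CLASS_LABELS)
    def test_severity_two_deviates_further_from_normal(self, label):
        if label == "normal":
            return
        normal = gp.style_preset("normal", 1)
        s1, s2 = gp.style_preset(label, 1), gp.style_preset(label, 2)
        for name in ("step_length", "torso_lean", "hip_amp_left", "hip_amp_right",
                     "knee_amp_left", "knee_amp_right", "foot_lift_left",
                     "foot_lift_right", "shuffle"):
            d1 = abs(getattr(s1, name) - getattr(normal, name))
            d2 = abs(getattr(s2, name) - getattr(normal, name))
            if d1 > 0:
                assert d2 >= d1, f"{label}.{name}: severity 2 closer to normal"
        # at least one parameter strictly further
        assert any(
            abs(getattr(s2, n) - getattr(normal, n)) > abs(getattr(s1, n) - getattr(normal, n))
            for n in ("step_length", "hip_amp_left", "knee_amp_left", "shuffle", "torso_lean")
        )

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            gp.style_preset("limping", 1)


class TestKinematics:
    def test_legs_in_antiphase(self):
        p = gp.style_preset("normal", 1)
        a, b = gp.pose_at_phase(p, 0.2), gp.pose_at_phase(p, 0.7)
        ra, rb = a.joints["hip"][0], b.joints["hip"][0]
        for ja, jb in (("ankle_left", "ankle_right"), ("knee_left", "knee_right")):
            xa, ya = a.joints[ja]
            xb, yb = b.joints[jb]
            assert np.isclose(xa - ra, xb - rb, atol=1e-9)
            assert np.isclose(ya, yb, atol=1e-9)

    def test_phase_zero_is_double_support_maximum(self):
        p = gp.style_preset("normal", 1)
        seps = [
            abs(
                gp.pose_at_phase(p, i / 100).joints["ankle_left"][0]
                - gp.pose_at_phase(p, i / 100).joints["ankle_right"][0]
            )
            for i in range(100)
        ]
        assert seps[0] >= max(seps) - 1e-6

    def test_rigid_limb_lengths(self):
        p = gp.style_preset("neuropathic", 2)
        lengths = {
            phase: gp.pose_at_phase(p, phase).segment_length("hip", "knee_left")
            for phase in (0.0, 0.33, 0.77)
        }
        vals = list(lengths.values())
        assert max(vals) - min(vals) < 1e-6

    def test_ankles_at_or_above_ground(self):
        for label in gp.CLASS_LABELS:
            p = gp.style_preset(label, 2)
            for i in range(0, 100, 7):
                pose = gp.pose_at_phase(p, i / 100)
                assert pose.joints["ankle_left"][1] >= -1e-9
                assert pose.joints["ankle_right"][1] >= -1e-9

    def test_root_translation_linear_in_phase(self):
        p = gp.style_preset("normal", 1)
        x0 = gp.pose_at_phase(p, 0.0).joints["hip"][0]
        x_half = gp.pose_at_phase(p, 0.5).joints["hip"][0]
        assert np.isclose(x_half - x0, 0.5 * p.step_length * 2)


class TestRendering:
    def test_single_connected_component(self):
        p = gp.style_preset("normal", 1)
        for phase in (0.0, 0.25, 0.6, 0.85):
            sil = gp.render_silhouette(_recentre(gp.pose_at_phase(p, phase)), p, (120, 160))
            n = measure.label(sil.mask, connectivity=1, return_num=True)[1]
            assert n == 1

    def test_wider_limbs_strictly_increase_area(self):
        p = gp.style_preset("normal", 1)
        pose = _recentre(gp.pose_at_phase(p, 0.3))
        thin = gp.render_silhouette(pose, p, (120, 160))
        import dataclasses

        wide_params = dataclasses.replace(
            p, limb_widths={k: 2 * v for k, v in p.limb_widths.items()}
        )
        wide = gp.render_silhouette(pose, wide_params, (120, 160))
        assert wide.mask.sum() > thin.mask.sum()

    def test_mirror_equivariance(self):
        p = gp.style_preset("normal", 1)
        pose = _recentre(gp.pose_at_phase(p, 0.3))
        w = 161  # odd width so mirroring maps pixel centres exactly
        centre = (w - 1) / 2.0
        mirrored = PoseFrame(
            {k: (2 * centre - x, y) for k, (x, y) in pose.joints.items()}
        )
        a = gp.render_silhouette(pose, p, (120, w))
        b = gp.render_silhouette(mirrored, p, (120, w))
        assert np.array_equal(b.mask, a.mask[:, ::-1])

    def test_skeleton_is_thinner_than_silhouette(self):
        p = gp.style_preset("normal", 1)
        pose = _recentre(gp.pose_at_phase(p, 0.3))
        sil = gp.render_silhouette(pose, p, (120, 160))
        skel = gp.render_skeleton(pose, (120, 160))
        assert 0 < skel.mask.sum() < sil.mask.sum()

    def test_vertical_leg_rasterized_at_expected_length(self):
        p = gp.style_preset("normal", 1)
        pose = _recentre(gp.pose_at_phase(p, 0.25))  # legs nearly vertical
        skel = gp.render_skeleton(pose, (120, 160), line_width=2.0)
        rows = np.nonzero(skel.mask)[0]
        drawn = rows.max() - rows.min() + 1
        # hip->ankle (50) + torso/neck/head above: compare to joint extent
        ys = [y for _, y in pose.joints.values()]
        expected = max(ys) - min(ys)
        assert abs(drawn - expected) <= 2 + 2 * 7  # head radius allowance

    def test_canvas_too_small_raises(self):
        p = gp.style_preset("normal", 1)
        pose = gp.pose_at_phase(p, 0.0)
        with pytest.raises(RenderError):
            gp.render_silhouette(_recentre(pose, 25.0), p, (50, 50))


class TestGenerateSequence:
    def test_frame_count_and_boundaries_without_jitter(self):
        import dataclasses

        p = dataclasses.replace(gp.style_preset("normal", 1), cycle_frames=40,
                                cadence_jitter=0.0, limb_widths={})
        seq, bounds, skels = gp.generate_sequence(p, 3, seed=0, render_skeletons=False)
        assert len(seq) == 120
        assert bounds == [0, 40, 80, 120]

    def test_deterministic_under_seed(self):
        p = gp.style_preset("normal", 1)
        a = gp.generate_sequence(p, 2, seed=5, render_skeletons=False)
        b = gp.generate_sequence(p, 2, seed=5, render_skeletons=False)
        assert np.array_equal(a[0].masks, b[0].masks)
        assert a[1] == b[1]

    def test_feet_distance_peaks_near_half_cycle_boundaries(self, normal_walk):
        seq = normal_walk["seq"]
        p = normal_walk["params"]
        sig = gp.feet_distance_signal(seq)
        peaks = np.array(gp.detect_peaks(sig))
        for k in range(2 * 3 + 1):  # every half-cycle boundary
            target = k * p.cycle_frames / 2
            if target > len(seq) - 1:
                target = len(seq) - 1
            assert np.abs(peaks - target).min() <= 2

    def test_periodicity_via_autocorrelation(self, normal_walk):
        from gaitpath.cycles import estimate_period

        sig = gp.feet_distance_signal(normal_walk["seq"])
        x = sig.values - sig.values.mean()
        acf = np.correlate(x, x, mode="full")[x.size - 1 :]
        cf = normal_walk["params"].cycle_frames
        lag_window = acf[cf - 2 : cf + 3]
        # a local autocorrelation peak at one full cycle (+-1 frame)
        assert lag_window.max() >= acf[cf - 4 : cf + 5].max() - 1e-9


class TestCorrupt:
    def test_zero_noise_is_identity(self, normal_walk):
        seq = normal_walk["seq"]
        out = gp.corrupt(seq, gp.NoiseParams(0.0, 0.0, 0.0, seed=1))
        assert np.array_equal(out.masks, seq.masks)

    def test_flip_count_matches_binomial(self):
        mask = np.zeros((224, 224), np.uint8)
        seq = gp.SilhouetteSequence(frames=[gp.SilhouetteFrame(mask)])
        out = gp.corrupt(seq, gp.NoiseParams(flip_rate=0.01, seed=3))
        flips = int(out.frames[0].mask.sum())
        n, rate = 224 * 224, 0.01
        sigma = np.sqrt(n * rate * (1 - rate))
        assert abs(flips - n * rate) < 4 * sigma

    def test_deterministic_under_seed(self, normal_walk):
        noise = gp.NoiseParams(0.01, 1.0, 0.5, seed=9)
        a = gp.corrupt(normal_walk["seq"], noise)
        b = gp.corrupt(normal_walk["seq"], noise)
        assert np.array_equal(a.masks, b.masks)

    def test_flip_rate_bound_enforced(self):
        with pytest.raises(ValidationError):
            gp.NoiseParams(flip_rate=0.2)


class TestCohort:
    def test_counts_and_uniform_layout(self):
        cohort = gp.generate_cohort(
            2, classes=("normal", "parkinsonian"), severities=(1, 2),
            directions=("left_to_right", "right_to_left"), n_cycles=1, seed=4,
        )
        assert len(cohort) == 2 * 2 * 2 * 2

    def test_subjects_differ_under_same_master_seed(self):
        cohort = gp.generate_cohort(
            2, classes=("normal",), severities=(1,),
            directions=("left_to_right",), n_cycles=1, seed=4,
        )
        a, b = cohort[0].sequence, cohort[1].sequence
        assert a.subject_id != b.subject_id
        assert a.masks.shape != b.masks.shape or not np.array_equal(a.masks, b.masks)

    def test_dataset_round_trips_through_manifest(self, tmp_path):
        manifest = gp.generate_dataset(
            tmp_path / "ds", 1, classes=("normal", "diplegic"), severities=(1,),
            directions=("left_to_right",), n_cycles=1, seed=2,
        )
        seqs = gp.load_dataset(manifest)
        assert len(seqs) == 2
        assert {s.class_label for s in seqs} == {"normal", "diplegic"}
        assert all(len(s) > 0 for s in seqs)

    def test_parkinsonian_steps_narrower_than_normal(self):
        """Rank test on max feet distance across 10 paired synthetic subjects."""
        diffs = []
        for s in range(10):
            widths = {}
            for label in ("normal", "parkinsonian"):
                preset = gp.style_preset(label, 1)
                rng = np.random.default_rng(1000 + s)
                params = perturb_params(preset, rng)
                seq, _, _ = gp.generate_sequence(params, 1, seed=s, render_skeletons=False)
                sig = gp.feet_distance_signal(seq)
                widths[label] = sig.values.max()
            diffs.append(widths["normal"] - widths["parkinsonian"])
        assert stats.wilcoxon(diffs, alternative="greater").pvalue < 0.01
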