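"""Synthetic cohort generator: planted effects, motion, nuisance structure."""

import numpy as np
import pytest

import fcbiomarker as fb
from fcbiomarker.connectivity import frame_displacement, scrub_mask
from fcbiomarker.synthetic import (
    SyntheticCohortSpec,
    external_spec,
    generate_cohort,
    make_group_covariances,
    repair_correlation,
    simulate_motion,
    simulate_participant,
)


class TestGroupCovariances:
    def test_zero_effect_gives_identical_matrices(self):
        spec = SyntheticCohortSpec(
            n_per_group=4, n_rois=8, planted_edges=[(0, 1)], effect_delta=0.0, seed=1
        )
        a, b = make_group_covariances(spec)
        assert np.array_equal(a, b)

    def test_identity_baseline_forced_entries(self):
        spec = SyntheticCohortSpec(
            n_per_group=2, n_rois=4, planted_edges=[(0, 1)], effect_delta=0.3,
            base_density=0.0, seed=0,
        )
        a, b, report = make_group_covariances(spec, with_report=True)
        assert np.array_equal(a, np.eye(4))
        expected = np.eye(4)
        expected[0, 1] = expected[1, 0] = 0.3
        assert np.allclose(b, expected)
        assert report["max_distortion_patient"] == 0.0  # already PD, no repair

    def test_effect_calibration_monte_carlo(self):
        """Empirical FC difference on planted edges at 10,000 frames is
        within ±0.05 of the post-repair target."""
        planted = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9),
                   (10, 11), (12, 13), (14, 15), (16, 17), (18, 19)]
        spec = SyntheticCohortSpec(
            n_per_group=1, n_rois=30, planted_edges=planted, effect_delta=0.4, seed=4
        )
        a, b, report = make_group_covariances(spec, with_report=True)
        sa = simulate_participant(a, 10_000, 2.0, seed=1, ar_coef=0.0)
        sb = simulate_participant(b, 10_000, 2.0, seed=2, ar_coef=0.0)
        ca = np.corrcoef(sa.data, rowvar=False)
        cb = np.corrcoef(sb.data, rowvar=False)
        for (i, j), target in report["target_difference"].items():
            assert cb[i, j] - ca[i, j] == pytest.approx(target, abs=0.05)

    def test_unrepairable_delta_names_edges(self):
        spec = SyntheticCohortSpec(
            n_per_group=2, n_rois=4, planted_edges=[(0, 1)], effect_delta=0.6,
            base_density=0.0, seed=0,
        )
        # push the same edge again via nuisance shift to exceed |r| = 1
        spec.nv_edges = {"age": [((2, 3), 0.9)]}
        base = np.eye(4)
        base[2, 3] = base[3, 2] = 0.5
        from fcbiomarker.synthetic import _apply_edge_shifts

        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            _apply_edge_shifts(base, {(2, 3): 0.6})

    def test_repair_restores_positive_definiteness(self):
        rng = np.random.default_rng(5)
        raw = np.eye(6) + 0.6 * (lambda s: 0.5 * (s + s.T))(
            rng.standard_normal((6, 6))
        )
        np.fill_diagonal(raw, 1.0)
        repaired, distortion = repair_correlation(raw)
        assert np.linalg.eigvalsh(repaired).min() > 0
        assert np.allclose(np.diag(repaired), 1.0)
        assert distortion >= 0


class TestSimulateParticipant:
    def test_identity_covariance_uncorrelated(self):
        s = simulate_participant(np.eye(6), 50_000, 2.0, seed=0, ar_coef=0.0)
        corr = np.corrcoef(s.data, rowvar=False)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_seed_reproducibility(self):
        cov = np.eye(4)
        s1 = simulate_participant(cov, 100, 2.0, seed=7)
        s2 = simulate_participant(cov, 100, 2.0, seed=7)
        assert np.array_equal(s1.data, s2.data)

    @pytest.mark.parametrize("phi,expected", [(0.0, 0.0), (0.3, 0.3)])
    def test_autocorrelation_matches_ar_coefficient(self, phi, expected):
        s = simulate_participant(np.eye(3), 30_000, 2.0, seed=1, ar_coef=phi)
        x = s.data[:, 0]
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(expected, abs=0.02)

    def test_non_pd_covariance_rejected(self):
        bad = np.ones((3, 3))
        with pytest.raises(ValueError, match="positive definite"):
            simulate_participant(bad, 50, 2.0, seed=0)


class TestSimulateMotion:
    def test_no_spikes_no_jitter_flat_fd(self):
        trace, spikes = simulate_motion(50, 0.0, 1.0, seed=0, jitter_sd=0.0)
        assert spikes == []
        assert np.array_equal(frame_displacement(trace), np.zeros(49))

    def test_spike_transitions_exceed_threshold(self):
        trace, spikes = simulate_motion(200, 0.05, 1.0, seed=3, jitter_sd=0.0)
        assert spikes  # at this rate some spikes land
        fd = frame_displacement(trace)
        exceed = set(np.flatnonzero(fd > 0.5))
        expected = set()
        for t in spikes:
            expected |= {t - 1, t}  # transitions into and out of the spike
        # adjacent spikes cancel their shared transition; tolerate subsets
        assert exceed <= {e for t in spikes for e in (t - 1, t)}
        isolated = [t for t in spikes if t - 1 not in spikes and t + 1 not in spikes]
        for t in isolated:
            assert {t - 1, t} <= exceed
        mask = scrub_mask(fd)
        for t in isolated:
            assert not mask.retained[t]

    def test_seed_reproducibility(self):
        t1, s1 = simulate_motion(100, 0.05, 1.0, seed=5)
        t2, s2 = simulate_motion(100, 0.05, 1.0, seed=5)
        assert np.array_equal(t1.data, t2.data)
        assert s1 == s2

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            simulate_motion(10, 1.5, 1.0, seed=0)


class TestGenerateCohort:
    def test_empty_spec_gives_empty_cohort(self):
        participants, truth = generate_cohort(
            SyntheticCohortSpec(n_per_group=0, n_rois=6)
        )
        assert participants == []
        assert truth.group_assignment == {}

    def test_groups_balanced(self):
        participants, truth = generate_cohort(
            SyntheticCohortSpec(n_per_group=5, n_rois=6, n_frames=60, seed=2)
        )
        labels = list(truth.group_assignment.values())
        assert labels.count(0) == labels.count(1) == 5

    def test_determinism_bit_for_bit(self):
        spec = SyntheticCohortSpec(
            n_per_group=3, n_rois=6, n_frames=60,
            planted_edges=[(0, 1)], effect_delta=0.3, seed=9,
        )
        p1, t1 = generate_cohort(spec)
        p2, t2 = generate_cohort(spec)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.series.data, b.series.data)
            assert np.array_equal(a.motion.data, b.motion.data)
            assert np.array_equal(a.nuisance.data, b.nuisance.data)
            assert a.attributes == b.attributes
        assert t1.spike_frames == t2.spike_frames

    def test_nuisance_edge_correlates_with_age(self):
        """An age-linked edge shift shows up as a positive sample
        correlation between that edge's FC and age across participants."""
        spec = SyntheticCohortSpec(
            n_per_group=250, n_rois=6, n_frames=150,
            nv_edges={"age": [((2, 3), 0.25)]},
            nuisance_gain=0.0, motion_spike_prob=0.0, seed=13,
        )
        participants, _ = generate_cohort(spec)
        fcs, ages = [], []
        for p in participants:
            corr = np.corrcoef(p.series.data, rowvar=False)
            fcs.append(corr[2, 3])
            ages.append(p.attributes["age"])
        r = np.corrcoef(fcs, ages)[0, 1]
        assert r > 0.3

    def test_planted_nv_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SyntheticCohortSpec(
                n_per_group=2, n_rois=6,
                planted_edges=[(0, 1)],
                nv_edges={"age": [((1, 0), 0.2)]},
            )

    def test_attribute_schema(self):
        participants, truth = generate_cohort(
            SyntheticCohortSpec(n_per_group=3, n_rois=6, n_frames=60, seed=4)
        )
        expected = {
            "diagnosis", "age", "sex", "handedness",
            "med_anxiolytic", "med_antidepressant", "med_antipsychotic", "ybocs",
        }
        assert set(participants[0].attributes) == expected
        assert set(truth.attributes.columns) == expected

    def test_medication_only_in_patient_group(self):
        participants, _ = generate_cohort(
            SyntheticCohortSpec(n_per_group=40, n_rois=6, n_frames=60,
                                p_medicated=0.5, seed=6)
        )
        for p in participants:
            if p.attributes["diagnosis"] == 0:
                assert p.attributes["med_antidepressant"] == 0


def test_group_motion_comparison_is_computable():
    """Mean relative displacement and retained-frame counts compare across
    groups with a two-sample t-test (motion matched by construction)."""
    from fcbiomarker.connectivity import mean_relative_displacement
    from fcbiomarker.evaluation import two_sample_t

    participants, truth = generate_cohort(
        SyntheticCohortSpec(n_per_group=10, n_rois=6, n_frames=120, seed=17)
    )
    by_group = {0: [], 1: []}
    retained = {0: [], 1: []}
    for p in participants:
        g = truth.group_assignment[p.participant_id]
        by_group[g].append(mean_relative_displacement(p.motion).mean())
        fd = frame_displacement(p.motion)
        retained[g].append(scrub_mask(fd).n_retained)
    t, p_motion = two_sample_t(np.array(by_group[0]), np.array(by_group[1]))
    _, p_frames = two_sample_t(
        np.array(retained[0], float), np.array(retained[1], float)
    )
    assert np.isfinite(t)
    assert p_motion > 0.05  # groups share the motion model
    assert p_frames > 0.05


class TestExternalSpec:
    def test_shares_structure_different_sampling(self):
        base = SyntheticCohortSpec(
            n_per_group=4, n_rois=8, planted_edges=[(0, 1)], effect_delta=0.4, seed=3
        )
        ext = external_spec(base)
        assert ext.seed != base.seed
        assert ext.structure_seed == base.seed
        assert ext.site_noise_sd > 0
        assert ext.tr_seconds == pytest.approx(2.411)
        ca, cb = make_group_covariances(base)
        ea, eb = make_group_covariances(ext)
        assert np.array_equal(ca, ea)  # same shared correlation structure
        assert np.array_equal(cb, eb)


def test_cohort_written_and_read_back(tmp_path):
    spec = SyntheticCohortSpec(
        n_per_group=2, n_rois=5, n_frames=60, planted_edges=[(0, 1)],
        effect_delta=0.3, seed=8,
    )
    participants, truth = generate_cohort(spec)
    fb.io.write_cohort(tmp_path, participants, truth)
    loaded = fb.io.read_cohort(tmp_path)
    assert len(loaded) == 4
    for orig, back in zip(participants, loaded):
        assert back.participant_id == orig.participant_id
        assert np.allclose(back.series.data, orig.series.data, atol=1e-9)
        assert np.allclose(back.motion.data, orig.motion.data, atol=1e-9)
        assert back.attributes["diagnosis"] == orig.attributes["diagnosis"]
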