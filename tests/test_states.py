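"""Torsion/pucker classification, BI/BII assignment and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phosdyn as P
from phosdyn.states import BackboneSeries
from phosdyn.synthetic import EmissionSpec, StepDynamicsSpec
from phosdyn.topology import StepIdentity


def _series(eps, zeta, phase5=None, phase3=None):
    eps = np.atleast_2d(np.asarray(eps, dtype=float))
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if phase5 is None:
        phase5 = np.full_like(eps, 160.0)
    if phase3 is None:
        phase3 = np.full_like(eps, 160.0)
    phosphates = [StepIdentity(1, i + 2) for i in range(eps.shape[0])]
    return BackboneSeries(
        phosphates=phosphates,
        epsilon=eps,
        zeta=zeta,
        phase5=np.atleast_2d(phase5),
        phase3=np.atleast_2d(phase3),
    )


class TestWrapDelta:
    @pytest.mark.parametrize(
        "eps, zeta, expected",
        [(180.0, 270.0, -90.0), (270.0, 170.0, 100.0), (350.0, 10.0, -20.0)],
    )
    def test_canonical_values(self, eps, zeta, expected):
        assert P.wrap_delta(eps, zeta) == pytest.approx(expected)

    @given(
        st.floats(-720, 720, allow_nan=False),
        st.floats(-720, 720, allow_nan=False),
        st.integers(-2, 2),
        st.integers(-2, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_full_turns(self, eps, zeta, k1, k2):
        d0 = P.wrap_delta(eps, zeta)
        d1 = P.wrap_delta(eps + 360 * k1, zeta + 360 * k2)
        assert d1 == pytest.approx(d0, abs=1e-9)
        assert -180.0 <= d0 < 180.0


class TestCategoricalClassifiers:
    @pytest.mark.parametrize(
        "angle, expected",
        [(185.0, "t"), (300.0, "g-"), (60.0, "g+"), (130.0, "other"), (-60.0, "g-")],
    )
    def test_torsion_windows(self, angle, expected):
        assert P.classify_torsion(angle) == expected

    @pytest.mark.parametrize(
        "phase, expected",
        [(10.0, "north"), (330.0, "north"), (85.0, "east"), (150.0, "south"), (250.0, "other")],
    )
    def test_pucker_ranges_with_wrapped_north(self, phase, expected):
        assert P.classify_pucker(phase) == expected


class TestStateAssignment:
    def test_canonical_modes_at_both_cutoffs(self):
        series = _series([[180.0, 270.0]], [[270.0, 170.0]])  # delta -90, +100
        for cutoff in (0.0, 30.0):
            states = P.classify_backbone_state(series, cutoff)
            assert states.is_bii[0].tolist() == [False, True]

    def test_boundary_is_strict(self):
        series = _series([[195.0]], [[180.0]])  # delta = +15
        assert P.classify_backbone_state(series, 0.0).is_bii[0, 0]
        assert not P.classify_backbone_state(series, 30.0).is_bii[0, 0]
        # delta exactly at the cutoff is BI
        series_at = _series([[210.0]], [[180.0]])  # delta = +30
        assert not P.classify_backbone_state(series_at, 30.0).is_bii[0, 0]

    def test_ambiguous_mask_flags_trans_trans(self):
        series = _series([[185.0, 260.0]], [[170.0, 160.0]])
        states = P.classify_backbone_state(series, 0.0)
        assert states.ambiguous[0].tolist() == [True, False]

    def test_bii_percentage_counting(self):
        series = _series([[180.0] * 4], [[270.0] * 4])
        states = P.classify_backbone_state(series, 0.0)
        assert P.bii_percentage(states)[0] == 0.0
        alt = _series([[180.0, 270.0] * 3], [[270.0, 170.0] * 3])
        assert P.bii_percentage(P.classify_backbone_state(alt, 0.0))[0] == 50.0

    def test_stationary_chain_occupancy(self, oligo4):
        spec = StepDynamicsSpec(target_bii=0.3, persistence=0.99)
        latent = P.simulate_state_chains(oligo4, spec, 100_000, seed=7)
        occ = latent.is_bii.mean(axis=1)
        # binomial-with-autocorrelation standard error: neff = n(1-a)/(1+a)
        neff = 100_000 * 0.01 / 1.99
        se = np.sqrt(0.3 * 0.7 / neff)
        assert np.all(np.abs(occ - 0.3) < 3 * se)


class TestConvergence:
    def test_profile_flat_for_stationary_chain(self, oligo4):
        spec = StepDynamicsSpec(target_bii=0.4, persistence=0.9)
        latent = P.simulate_state_chains(oligo4, spec, 50_000, seed=3)
        checkpoints = np.array([10_000, 25_000, 50_000])
        prof = P.convergence_profile(latent, checkpoints)
        assert prof.shape == (18, 3)
        # autocorrelation-aware Monte-Carlo tolerance per checkpoint
        neff = checkpoints * (1 - 0.9) / (1 + 0.9)
        tol = 4 * 100 * np.sqrt(0.4 * 0.6 / neff)
        assert np.all(np.abs(prof - 40.0) < tol[None, :])

    def test_identical_windows_have_zero_difference(self):
        series = _series([[180.0, 270.0] * 10], [[270.0, 170.0] * 10])
        states = P.classify_backbone_state(series, 0.0)
        diff = P.window_difference(states, (0, 10), (10, 20))
        assert diff[0] == pytest.approx(0.0)

    def test_window_difference_detects_regime_change(self, oligo4):
        a = P.simulate_state_chains(oligo4, StepDynamicsSpec(0.1, 0.9), 50_000, seed=11)
        b = P.simulate_state_chains(oligo4, StepDynamicsSpec(0.5, 0.9), 50_000, seed=12)
        glued = P.StateSeries(
            phosphates=a.phosphates,
            is_bii=np.hstack([a.is_bii, b.is_bii]),
            cutoff=0.0,
        )
        diff = P.window_difference(glued, (0, 50_000), (50_000, 100_000))
        assert np.all(np.abs(diff - 40.0) < 5.0)

    def test_checkpoint_beyond_trajectory_rejected(self):
        series = _series([[180.0] * 4], [[270.0] * 4])
        states = P.classify_backbone_state(series, 0.0)
        with pytest.raises(ValueError):
            P.convergence_profile(states, [2, 10])


class TestCutoffSuggestion:
    def test_bimodal_mixture_valley_recovered(self):
        rng = np.random.default_rng(5)
        delta = np.concatenate(
            [rng.normal(-90, 15, 6000), rng.normal(100, 15, 3000)]
        )
        eps = np.full_like(delta, 180.0)
        series = _series([eps], [np.mod(eps - delta, 360.0)])
        sug = P.suggest_cutoff(series)
        assert not sug.ambiguous
        # deep valley between well separated modes sits near the midpoint
        assert -20.0 < sug.cutoff < 40.0
        lo, hi = sug.mode_positions
        assert abs(lo - (-90)) < 15 and abs(hi - 100) < 15

    def test_unimodal_is_ambiguous_with_zero_fallback(self):
        rng = np.random.default_rng(6)
        delta = rng.normal(-90, 12, 5000)
        eps = np.full_like(delta, 180.0)
        series = _series([eps], [np.mod(eps - delta, 360.0)])
        sug = P.suggest_cutoff(series)
        assert sug.ambiguous and sug.cutoff == 0.0

    def test_flat_valley_is_ambiguous(self):
        rng = np.random.default_rng(7)
        # broad overlapping modes plus 10% of the mass spread across the
        # intermediate -60..+70 region: no clear minimum between the peaks
        delta = np.concatenate(
            [
                rng.normal(-90, 60, 5400),
                rng.normal(100, 60, 3600),
                rng.uniform(-60, 70, 1000),
            ]
        )
        eps = np.full_like(delta, 180.0)
        series = _series([eps], [np.mod(eps - delta, 360.0)])
        sug = P.suggest_cutoff(series)
        assert sug.ambiguous and sug.cutoff == 0.0


class TestJointHistogram:
    def test_generator_defaults_leave_bii_north_cell_empty(self, oligo4):
        spec = StepDynamicsSpec(target_bii=0.4, persistence=0.9)
        series, latent = P.simulate_backbone(
            oligo4, spec, EmissionSpec.pmd_defaults(), 20_000, seed=8
        )
        states = P.classify_backbone_state(series, 0.0)
        *_, table = P.joint_state_pucker_histogram(series, states)
        assert table.loc["BII", "north"] == 0
        assert table.to_numpy().sum() == series.epsilon.size

    def test_single_frame_populates_one_bin(self):
        series = _series([[180.0]], [[270.0]], phase5=[[160.0]])
        states = P.classify_backbone_state(series, 0.0)
        H, *_ , table = P.joint_state_pucker_histogram(series, states)
        assert H.sum() == 1 and (H == 1).sum() == 1
        assert table.loc["BI", "south"] == 1


class TestCutoffMonotonicity:
    def test_bii_percent_nonincreasing_in_cutoff(self, oligo4):
        spec = StepDynamicsSpec(target_bii=0.3, persistence=0.95)
        series, _ = P.simulate_backbone(
            oligo4, spec, EmissionSpec.pmd_defaults(), 20_000, seed=9
        )
        cutoffs = [-40.0, -20.0, 0.0, 20.0, 40.0]
        means = [
            P.bii_percentage(P.classify_backbone_state(series, c)).mean()
            for c in cutoffs
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))
        # +/-20 deg around 0 moves the population by only a few percent
        assert abs(means[1] - means[2]) < 5.0
        assert abs(means[3] - means[2]) < 5.0
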