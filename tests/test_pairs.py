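"""Facing-pair combinations, transition census, independence framework."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phosdyn as P
from phosdyn.pairs import (
    ORDERED_LABELS,
    PairSeries,
    combination_populations,
    counting_identity_check,
    independence_predictions,
    independence_test,
    transition_census,
)
from phosdyn.states import StateSeries
from phosdyn.synthetic import StepDynamicsSpec
from phosdyn.topology import StepIdentity

CODE = {"BI.BI": 0, "BII.BI": 1, "BI.BII": 2, "BII.BII": 3}


def _pair_series(*label_rows):
    codes = np.array([[CODE[l] for l in row] for row in label_rows], dtype=np.uint8)
    steps = [
        (StepIdentity(1, k + 2, "NN"), StepIdentity(2, 20 - k, "NN"))
        for k in range(codes.shape[0])
    ]
    return PairSeries(steps=steps, codes=codes)


class TestCombine:
    def test_ordered_and_pooled_labels(self, oligo4):
        # strand1 BI, strand2 BII on every frame for every step
        pairs = P.enumerate_complementary_steps(oligo4)
        phosphates = [s for pair in pairs for s in pair]
        is_bii = np.array([[p.strand == 2] for p in phosphates])
        states = StateSeries(phosphates=phosphates, is_bii=is_bii, cutoff=0.0)
        ps = P.combine_states(states, oligo4)
        assert np.all(ps.codes == CODE["BI.BII"])
        assert np.all(ps.pooled_codes == 1)

    def test_all_bi_trajectories_give_pure_bi_bi(self, oligo4):
        latent = P.simulate_state_chains(
            oligo4, StepDynamicsSpec(target_bii=0.0), 100, seed=0
        )
        ps = P.combine_states(latent, oligo4)
        pops = combination_populations(ps)
        assert np.all(pops.bi_bi == 100.0)

    def test_symmetric_half_occupancy_gives_quarter_corners(self, oligo4):
        latent = P.simulate_state_chains(
            oligo4, StepDynamicsSpec(target_bii=0.5, persistence=0.9), 100_000, seed=1
        )
        ps = P.combine_states(latent, oligo4)
        for code in range(4):
            frac = (ps.codes == code).mean()
            assert frac == pytest.approx(0.25, abs=0.02)

    def test_frame_count_mismatch_rejected(self, oligo4):
        pairs = P.enumerate_complementary_steps(oligo4)
        phosphates = [s for pair in pairs[:1] for s in pair]
        states = StateSeries(
            phosphates=phosphates, is_bii=np.zeros((2, 5), dtype=bool), cutoff=0.0
        )
        states.is_bii = [np.zeros(5, bool), np.zeros(4, bool)]  # force raggedness
        with pytest.raises(ValueError):
            P.combine_states(states, oligo4)


class TestPopulations:
    def test_hand_counted_percentages(self):
        ps = _pair_series(["BI.BI", "BI.BII", "BII.BII", "BI.BII"])
        pops = combination_populations(ps)
        assert (pops.bi_bi[0], pops.hybrid[0], pops.bii_bii[0]) == (25.0, 50.0, 25.0)

    def test_pure_bii_bii(self):
        ps = _pair_series(["BII.BII"] * 3)
        pops = combination_populations(ps)
        assert (pops.bi_bi[0], pops.hybrid[0], pops.bii_bii[0]) == (0.0, 0.0, 100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        labels = [[ORDERED_LABELS[i].replace(".", ".") for i in rng.integers(0, 4, 50)]
                  for _ in range(5)]
        ps = _pair_series(*labels)
        pops = combination_populations(ps)
        assert np.allclose(pops.bi_bi + pops.hybrid + pops.bii_bii, 100.0)


class TestTransitionCensus:
    def test_enumerated_sequence(self):
        ps = _pair_series(["BI.BI", "BI.BII", "BII.BII", "BI.BII", "BI.BI"])
        c = transition_census(ps)
        assert c.counts.tolist() == [2, 2, 0, 0]
        assert c.total == 4

    def test_hybrid_swap_is_type_three(self):
        c = transition_census(_pair_series(["BI.BII", "BII.BI"]))
        assert c.counts.tolist() == [0, 0, 1, 0]

    def test_homogeneous_jump_is_type_four(self):
        c = transition_census(_pair_series(["BI.BI", "BII.BII", "BI.BI"]))
        assert c.counts.tolist() == [0, 0, 0, 2]

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30), st.integers(0, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_scan(self, seq, _salt):
        ps = _pair_series([ORDERED_LABELS[i] for i in seq])
        c = transition_census(ps)
        # independent brute-force enumeration over consecutive frames
        expected = [0, 0, 0, 0]
        pooled = {0: 0, 1: 1, 2: 1, 3: 2}
        for a, b in zip(seq, seq[1:]):
            if a == b:
                continue
            pa, pb = pooled[a], pooled[b]
            if {pa, pb} == {0, 1}:
                expected[0] += 1
            elif {pa, pb} == {1, 2}:
                expected[1] += 1
            elif pa == 1 and pb == 1:
                expected[2] += 1
            else:
                expected[3] += 1
        assert c.counts.tolist() == expected
        assert c.total == sum(expected)


class TestIndependencePredictions:
    def test_worked_asymmetric_step(self):
        # the asymmetric CpG step: 79% and 42% individual BII
        pops = independence_predictions(0.79, 0.42)
        assert pops.bii_bii[0] == pytest.approx(33.18, abs=0.01)
        assert pops.hybrid[0] == pytest.approx(54.64, abs=0.01)
        assert pops.bi_bi[0] == pytest.approx(12.18, abs=0.01)

    @pytest.mark.parametrize(
        "p, expected", [(0.0, (100.0, 0.0, 0.0)), (1.0, (0.0, 0.0, 100.0))]
    )
    def test_degenerate_endpoints(self, p, expected):
        pops = independence_predictions(p, p)
        assert (pops.bi_bi[0], pops.hybrid[0], pops.bii_bii[0]) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_predictions_satisfy_counting_identity(self, p_i, p_j):
        pops = independence_predictions(p_i, p_j)
        lhs = pops.hybrid[0] + 2 * pops.bii_bii[0]
        assert lhs == pytest.approx(100 * (p_i + p_j), abs=1e-9)


class TestCountingIdentity:
    def test_hand_series(self):
        # frames: (BI,BII), (BII,BII): hybrid=0.5, bb=0.5, p_i=0.5, p_j=1.0
        ps = _pair_series(["BI.BII", "BII.BII"])
        assert counting_identity_check(ps)[0] == pytest.approx(0.0, abs=1e-15)

    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=60),
        st.integers(1, 4),
    )
    @settings(max_examples=250, deadline=None)
    def test_identity_is_exact_on_random_series(self, seq, n_rows):
        rows = [[ORDERED_LABELS[i] for i in seq]] * n_rows
        ps = _pair_series(*rows)
        res = counting_identity_check(ps)
        assert np.all(np.abs(res) < 1e-12)


class TestIndependenceDiagnostic:
    def test_factorized_counts_give_perfect_correlation(self):
        # constructed exactly factorised frame sets for several marginals
        rows = []
        for n1 in (1, 2, 5):
            for n2 in (1, 3, 6):
                n = 10
                row = []
                for x in (0, 1):
                    for y in (0, 1):
                        cx = n1 if x else n - n1
                        cy = n2 if y else n - n2
                        row += [x + 2 * y] * (cx * cy)
                rows.append([ORDERED_LABELS[c] for c in row])
        ps = _pair_series(*rows)
        rep = independence_test(ps)
        assert rep.corr_hybrid == pytest.approx(1.0, abs=1e-12)
        assert rep.corr_bii_bii == pytest.approx(1.0, abs=1e-12)
        for s in rep.per_step:
            assert s.empirical_bii_bii == pytest.approx(s.predicted_bii_bii, abs=1e-12)

    def test_degenerate_steps_are_excluded_and_reported(self):
        ps = _pair_series(
            ["BI.BI"] * 10,
            ["BI.BII", "BII.BI"] * 5,
            ["BI.BI", "BII.BII"] * 5,
        )
        rep = independence_test(ps)
        assert rep.per_step[0].degenerate
        assert rep.per_step[0].step[0].label() in rep.excluded_steps
        assert rep.n_steps_used == 2

    def test_positive_association_degrades_prediction(self, oligo4):
        spec = StepDynamicsSpec(
            target_bii=0.4, persistence=0.95, cross_strand_association=2.0
        )
        latent = P.simulate_state_chains(oligo4, spec, 100_000, seed=3)
        ps = P.combine_states(latent, oligo4)
        rep = independence_test(ps)
        for s in rep.per_step:
            assert s.empirical_bii_bii > s.predicted_bii_bii
            assert np.log(s.odds_ratio) > 2 * s.log_or_se  # advisory flag fires


class TestShrinkingError:
    def test_bii_bii_estimation_error_shrinks_with_n(self, oligo4):
        spec = StepDynamicsSpec(target_bii=0.5, persistence=0.9)
        errs = []
        for n, seed in ((4000, 21), (256_000, 22)):
            latent = P.simulate_state_chains(oligo4, spec, n, seed)
            ps = P.combine_states(latent, oligo4)
            bb = (ps.pooled_codes == 2).mean(axis=1)
            errs.append(np.abs(bb - 0.25).mean())
        # 64x more frames: mean absolute error should drop markedly (~8x)
        assert errs[1] < errs[0] / 3
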