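"""Fuzzification, rule firing, defuzzification and pair scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micfuzzy import (
    FuzzyConfig,
    defuzzify,
    infer_target_level,
    input_membership,
    mic_matrix,
    regulatory_effect,
    score_all_pairs,
    score_pair,
    select_regulators,
)
from micfuzzy.fuzzy import (
    NoFireWarning,
    PairScore,
    _predict_series,
    firing_variance,
    fuzzy_step,
    trajectory_mse,
)
from micfuzzy.mic import candidate_set

CFG = FuzzyConfig()


class TestInputMembership:
    def test_worked_example(self):
        lo, me, hi = input_membership(0.4)
        assert lo == pytest.approx(0.2)
        assert me == pytest.approx(0.8)
        assert hi == 0.0

    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, (1, 0, 0)), (0.5, (0, 1, 0)), (1.0, (0, 0, 1)), (0.75, (0, 0.5, 0.5))],
    )
    def test_vertices_and_interpolation(self, x, expected):
        assert input_membership(x) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            input_membership(1.2)

    def test_partition_of_unity_on_grid(self):
        grid = np.linspace(0, 1, 1001)
        sums = np.array([sum(input_membership(x)) for x in grid])
        assert np.max(np.abs(sums - 1.0)) < 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_partition_of_unity_everywhere(self, x):
        assert sum(input_membership(x)) == pytest.approx(1.0, abs=1e-12)


class TestRegulatoryEffect:
    def test_scaling_cancels_rrs(self):
        out = regulatory_effect(np.array([0.0, 0.5, 1.0]), 0.8)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_zero_rrs_annihilates(self):
        with pytest.warns(UserWarning, match="zero regulatory"):
            out = regulatory_effect(np.array([0.2, 0.9]), 0.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_rrs_rejected(self):
        with pytest.raises(ValueError):
            regulatory_effect(np.array([0.5]), 1.5)


class TestInference:
    def test_quoted_rule_fires_alone(self):
        agg, firing = infer_target_level(1.0, 0.0)
        expected = np.zeros((3, 3))
        expected[2, 0] = 1.0  # (High activator, Low repressor)
        np.testing.assert_array_equal(firing, expected)
        # aggregate is exactly the VH output triangle
        np.testing.assert_allclose(agg, CFG.output_grid()[4])

    def test_medium_medium_single_rule(self):
        agg, firing = infer_target_level(0.5, 0.5)
        assert firing[1, 1] == 1.0
        assert firing.sum() == 1.0
        np.testing.assert_allclose(agg, CFG.output_grid()[2])

    def test_four_rules_fire_at_0p4(self):
        _, firing = infer_target_level(0.4, 0.4)
        expect = np.zeros((3, 3))
        expect[0, 0] = 0.2
        expect[0, 1] = 0.2
        expect[1, 0] = 0.2
        expect[1, 1] = 0.8
        np.testing.assert_allclose(firing, expect, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infer_target_level(-0.1, 0.5)


class TestDefuzzify:
    def test_symmetric_aggregate_centers(self):
        u = CFG.universe
        agg = np.minimum(u, 1 - u)
        assert defuzzify(agg) == pytest.approx(0.5, abs=1e-12)

    def test_vh_triangle_centroid(self):
        agg = CFG.output_grid()[4]
        assert defuzzify(agg) == pytest.approx((0.75 + 1 + 1) / 3, abs=CFG.defuzz_resolution)

    def test_no_fire_fallback(self):
        with pytest.warns(NoFireWarning):
            assert defuzzify(np.zeros_like(CFG.universe)) == 0.5

    def test_no_fire_impossible_under_default_config(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 200)
        r = rng.uniform(0, 1, 200)
        _, _, no_fire = _predict_series(a, r, CFG)
        assert no_fire == 0


class TestOutputSurface:
    def test_monotone_in_activator(self):
        grid = np.linspace(0, 1, 21)
        for rep in grid:
            outs = [fuzzy_step(a, rep) for a in grid]
            assert all(b - a >= -1e-9 for a, b in zip(outs, outs[1:]))

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        for a, r in rng.uniform(0, 1, (50, 2)):
            s = fuzzy_step(a, r) + fuzzy_step(r, a)
            assert s == pytest.approx(1.0, abs=2 * CFG.defuzz_resolution)


class TestScores:
    def test_trajectory_mse_per_point_denominator(self):
        assert trajectory_mse([0.5, 0.7], [0.6, 0.7]) == pytest.approx(0.005)

    def test_trajectory_mse_empty_rejected(self):
        with pytest.raises(ValueError):
            trajectory_mse([], [])

    def test_even_firing_has_zero_variance(self):
        assert firing_variance(np.full(9, 7)) == 0.0
        assert firing_variance([0, 0, 0, 0, 0, 0, 0, 0, 9]) > 0

    def test_perfect_prediction_zeroes_rs(self):
        # a noiseless planted pair is reproduced exactly, so MSE and RS
        # vanish regardless of the firing variance
        from micfuzzy import generate_network, simulate_expression

        net = generate_network(6, density=2, seed=11)
        ds = simulate_expression(net, timepoints=11, series=2, noise_sd=0.0, seed=11)
        m = mic_matrix(ds)
        tgt = net.gene_universe[0]
        roles = net.regulators_of(tgt)
        ps = score_pair(ds, m, tgt, roles["+"], roles["-"])
        assert ps.mse < 1e-12
        assert ps.rs < 1e-12

    def test_distinct_genes_required(self, tiny_ds):
        m = mic_matrix(tiny_ds)
        with pytest.raises(ValueError, match="distinct"):
            score_pair(tiny_ds, m, "G1", "G2", "G2")


class TestScoreAllPairs:
    @pytest.fixture()
    def scored(self, dream_shaped):
        _, ds = dream_shaped
        m = mic_matrix(ds)
        cand = candidate_set(m, "G1", mode="mean")
        return score_all_pairs(ds, m, "G1", cand), cand

    def test_ordered_pair_count(self, scored):
        scores, cand = scored
        assert len(scores) == len(cand) * (len(cand) - 1)

    def test_nrs_endpoints(self, scored):
        scores, _ = scored
        nrs = [s.nrs for s in scores]
        rs = [s.rs for s in scores]
        assert min(nrs) == 0.0 and max(nrs) == 1.0
        assert scores[int(np.argmin(rs))].nrs == 0.0

    def test_single_candidate_yields_nothing(self, dream_shaped, caplog):
        _, ds = dream_shaped
        m = mic_matrix(ds)
        from micfuzzy.mic import CandidateSet

        lone = CandidateSet(target="G1", candidates=[("G2", 0.9)],
                            threshold_used=0.9, threshold_mode="fixed")
        with caplog.at_level("INFO", logger="micfuzzy.fuzzy"):
            assert score_all_pairs(ds, m, "G1", lone) == []
        assert "no activator-repressor pair" in caplog.text


def _pair(target, a, r, rs, nrs):
    return PairScore(target=target, activator=a, repressor=r, predicted=[],
                     mse=rs, firing_counts=np.zeros(9), variance=1.0, rs=rs, nrs=nrs)


class TestSelectRegulators:
    def test_nrs_threshold_keeps_low_scores(self):
        scores = [
            _pair("T", "A", "B", 0.001, 0.0),
            _pair("T", "B", "C", 0.002, 0.02),
            _pair("T", "C", "A", 0.05, 0.5),
        ]
        sel = select_regulators(scores, mode="nrs_threshold", nrs_threshold=0.03)
        assert {(e.regulator, e.sign) for e in sel} == {("A", "+"), ("B", "-"), ("C", "-")}

    def test_top_k_count(self):
        scores = [_pair("T", f"A{i}", f"B{i}", 0.01 * i, 0.1 * i) for i in range(10)]
        sel = select_regulators(scores, mode="top_k", k=3)
        regs = {e.regulator for e in sel}
        assert regs == {"A0", "B0", "A1", "B1", "A2", "B2"}

    def test_role_conflict_resolved_to_lowest_rs(self):
        scores = [
            _pair("T", "G", "X", 0.1, 0.0),  # G as activator, lower rs
            _pair("T", "Y", "G", 0.3, 1.0),  # G as repressor
        ]
        sel = select_regulators(scores, mode="nrs_threshold", nrs_threshold=1.0)
        roles = {e.regulator: e.sign for e in sel}
        assert roles["G"] == "+"
        assert sum(1 for e in sel if e.regulator == "G") == 1

    def test_missing_mode_parameter(self):
        scores = [_pair("T", "A", "B", 0.1, 0.0)]
        with pytest.raises(ValueError):
            select_regulators(scores, mode="nrs_threshold")
        with pytest.raises(ValueError):
            select_regulators(scores, mode="top_k")


class TestFuzzyConfig:
    def test_save_load_round_trip(self, tmp_path):
        p = tmp_path / "f.cfg"
        CFG.save(p)
        assert FuzzyConfig.load(p) == CFG

    def test_shipped_default_file_matches_defaults(self):
        assert FuzzyConfig.load(FuzzyConfig.default_file()) == CFG

    def test_non_monotone_rule_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            FuzzyConfig(rule_matrix=((2, 1, 0), (1, 2, 1), (4, 3, 2)))

    def test_digest_stable_and_sensitive(self):
        assert CFG.digest() == FuzzyConfig().digest()
        other = FuzzyConfig(defuzz_resolution=0.002)
        assert other.digest() != CFG.digest()
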