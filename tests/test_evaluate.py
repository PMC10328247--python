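"""Network assembly, confusion counting and topology metrics."""

import numpy as np
import pytest

from micfuzzy import (
    assemble_network,
    combinatorial_reduction,
    confusion,
    metrics,
    sign_accuracy,
)
from micfuzzy.evaluate import InferredNetwork, read_network, write_network
from micfuzzy.fuzzy import SignedRegulator
from micfuzzy.io import GoldStandard


def edge(reg, tgt, sign="+", rs=0.1, nrs=0.0):
    return SignedRegulator(regulator=reg, target=tgt, sign=sign, rs=rs, nrs=nrs)


def net_from(edges, universe):
    return assemble_network(edges, universe)


# Synthetic stand-in for a small bacterial stress-response module: an
# 8-gene universe with 9 known regulations, against which a prediction
# with 6 correct and 8 spurious edges is compared.
SOS_GENES = [f"g{i}" for i in range(8)]
SOS_GOLD = {
    ("g0", "g1"), ("g0", "g2"), ("g0", "g3"), ("g0", "g4"),
    ("g0", "g5"), ("g0", "g6"), ("g0", "g7"), ("g1", "g0"), ("g2", "g0"),
}
SOS_PREDICTED = (
    [("g0", "g1"), ("g0", "g2"), ("g0", "g3"), ("g0", "g4"), ("g0", "g5"), ("g1", "g0")]
    + [("g3", "g4"), ("g4", "g3"), ("g5", "g6"), ("g6", "g5"),
       ("g7", "g1"), ("g1", "g7"), ("g2", "g3"), ("g3", "g2")]
)


class TestAssemble:
    def test_union_of_selections(self):
        sel = {"T1": [edge("A", "T1"), edge("B", "T1", "-")],
               "T2": [edge("A", "T2"), edge("C", "T2", "-")]}
        net = assemble_network(sel, ["A", "B", "C", "T1", "T2"])
        assert len(net.edges) == 4

    def test_equal_sign_duplicates_keep_min_rs(self):
        net = net_from([edge("A", "T", "+", rs=0.5), edge("A", "T", "+", rs=0.2)],
                       ["A", "T"])
        assert net.edges[("A", "T")].rs == 0.2

    def test_conflicting_signs_resolved_with_warning(self):
        with pytest.warns(UserWarning, match="conflicting signs"):
            net = net_from([edge("A", "T", "+", rs=0.5), edge("A", "T", "-", rs=0.2)],
                           ["A", "T"])
        assert net.edges[("A", "T")].sign == "-"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            net_from([edge("A", "A")], ["A"])


class TestConfusion:
    def test_exact_match(self):
        gold = GoldStandard(edges={("A", "B")}, gene_universe=["A", "B", "C"])
        net = net_from([edge("A", "B")], ["A", "B", "C"])
        tp, fp, tn, fn = confusion(net, gold)
        assert (tp, fp, fn) == (1, 0, 0)
        assert tn == 3 * 2 - 1

    def test_empty_network(self):
        gold = GoldStandard(edges={("A", "B"), ("B", "C")}, gene_universe=["A", "B", "C"])
        net = InferredNetwork(gene_universe=["A", "B", "C"])
        tp, fp, tn, fn = confusion(net, gold)
        assert (tp, fp, fn) == (0, 0, 2)

    def test_sos_counts(self):
        gold = GoldStandard(edges=set(SOS_GOLD), gene_universe=SOS_GENES)
        net = net_from([edge(r, t) for r, t in SOS_PREDICTED], SOS_GENES)
        assert confusion(net, gold) == (6, 8, 39, 3)

    def test_invariant_under_gene_reordering(self):
        gold = GoldStandard(edges=set(SOS_GOLD), gene_universe=SOS_GENES)
        net1 = net_from([edge(r, t) for r, t in SOS_PREDICTED], SOS_GENES)
        reordered = list(reversed(SOS_GENES))
        gold2 = GoldStandard(edges=set(SOS_GOLD), gene_universe=reordered)
        net2 = net_from([edge(r, t) for r, t in SOS_PREDICTED], reordered)
        assert confusion(net1, gold) == confusion(net2, gold2)

    def test_universe_mismatch_rejected(self):
        gold = GoldStandard(edges=set(), gene_universe=["A", "B"])
        net = InferredNetwork(gene_universe=["A", "C"])
        with pytest.raises(ValueError, match="universe"):
            confusion(net, gold)


class TestMetrics:
    def test_sos_arithmetic(self):
        rep = metrics((6, 8, 39, 3))
        assert rep.precision == pytest.approx(0.4286, abs=1e-4)
        assert rep.tpr == pytest.approx(0.6667, abs=1e-4)
        assert rep.f_score == pytest.approx(0.5217, abs=1e-4)
        assert rep.structural_accuracy == pytest.approx(45 / 56)

    def test_perfect_prediction_all_ones(self):
        rep = metrics((9, 0, 47, 0))
        for name in ("precision", "tpr", "specificity", "f_score", "ss_mean",
                     "mcc", "structural_accuracy"):
            assert getattr(rep, name) == pytest.approx(1.0)
        assert rep.fpr == 0.0

    def test_gold_as_network_scores_perfectly(self):
        gold = GoldStandard(edges=set(SOS_GOLD), gene_universe=SOS_GENES)
        net = net_from([edge(r, t) for r, t in SOS_GOLD], SOS_GENES)
        rep = metrics(confusion(net, gold))
        assert rep.f_score == 1.0 and rep.mcc == 1.0

    def test_random_predictions_have_near_zero_mcc(self):
        # permuting predicted edges detaches them from the truth; the MCC
        # of a matched-marginal random predictor centers on zero
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        pairs = [(a, b) for a in genes for b in genes if a != b]
        gold_idx = rng.choice(len(pairs), size=40, replace=False)
        gold = GoldStandard(edges={pairs[i] for i in gold_idx}, gene_universe=genes)
        mccs = []
        for _ in range(100):
            pred_idx = rng.choice(len(pairs), size=40, replace=False)
            net = net_from([edge(*pairs[i]) for i in pred_idx], genes)
            mccs.append(metrics(confusion(net, gold)).mcc)
        assert abs(np.mean(mccs)) < 0.05

    def test_zero_denominator_flagged(self):
        rep = metrics((0, 0, 10, 5))
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics((0, 0, 0, 0))

    def test_ss_mean_variants(self):
        counts = (6, 8, 39, 3)
        tpr, spec = 6 / 9, 39 / 47
        assert metrics(counts, "harmonic").ss_mean == pytest.approx(
            2 * tpr * spec / (tpr + spec))
        assert metrics(counts, "geometric").ss_mean == pytest.approx(
            np.sqrt(tpr * spec))
        assert metrics(counts, "arithmetic").ss_mean == pytest.approx(
            (tpr + spec) / 2)

    def test_metrics_in_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = tuple(int(v) for v in rng.integers(0, 30, 4))
            if sum(counts) == 0:
                continue
            rep = metrics(counts)
            d = rep.as_dict()
            for k in ("precision", "tpr", "fpr", "specificity", "f_score",
                      "ss_mean", "structural_accuracy"):
                assert 0.0 <= d[k] <= 1.0
            assert -1.0 <= rep.mcc <= 1.0


class TestSignAccuracy:
    def test_counts_only_recovered_true_edges(self):
        truth = {("A", "T"): "+", ("B", "T"): "-"}
        net = net_from([edge("A", "T", "+"), edge("B", "T", "+"), edge("C", "T", "-")],
                       ["A", "B", "C", "T"])
        assert sign_accuracy(net, truth) == pytest.approx(0.5)

    def test_nan_when_no_true_edge_recovered(self):
        net = net_from([edge("C", "T")], ["A", "C", "T"])
        assert np.isnan(sign_accuracy(net, {("A", "T"): "+"}))


class TestCombinatorialReduction:
    def test_no_filtering_is_zero(self):
        assert combinatorial_reduction([9] * 10, 10) == pytest.approx(0.0)

    def test_empty_or_singleton_sets_are_total(self):
        assert combinatorial_reduction([0, 1, 0, 1], 4) == pytest.approx(100.0)

    def test_mid_scale_arithmetic(self):
        assert combinatorial_reduction([15] * 50, 50) == pytest.approx(91.0714, abs=1e-4)

    def test_bounded_between_0_and_100(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            sizes = rng.integers(0, n, size=n)
            r = combinatorial_reduction([int(s) for s in sizes], n)
            assert 0.0 <= r <= 100.0

    def test_small_universe_rejected(self):
        with pytest.raises(ValueError):
            combinatorial_reduction([1], 2)


class TestNetworkFiles:
    def test_round_trip(self, tmp_path):
        net = net_from([edge("A", "T", "+", 0.1, 0.0), edge("B", "T", "-", 0.2, 1.0)],
                       ["A", "B", "T"])
        p = tmp_path / "net.tsv"
        write_network(net, p)
        back = read_network(p, gene_universe=["A", "B", "T"])
        assert back.edge_set == net.edge_set
        assert back.edges[("A", "T")].sign == "+"
        assert back.edges[("B", "T")].rs == pytest.approx(0.2)
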