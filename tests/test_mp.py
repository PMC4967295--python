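import math

import numpy as np
import pytest

from fmodscreen import (DrugSignature, GeneModule, WeightedGeneNetwork,
                        mutual_predictability, retrieval_auc, seed_scores)

from conftest import random_network
from oracles import brute_force_seed_scores, pairwise_auc, trapezoid_auc


class TestSeedScores:
    def test_direct_sum_of_link_weights(self):
        net = WeightedGeneNetwork(
            [("A", "C", 0.5), ("B", "C", 0.3), ("A", "D", 0.2)],
            nodes=["A", "B", "C", "D", "E"])
        sv = seed_scores(net, {"A", "B"}, {"C", "D", "E"})
        assert sv.scores == pytest.approx({"C": 0.8, "D": 0.2, "E": 0.0})

    def test_no_seed_connection_scores_zero(self):
        net = WeightedGeneNetwork([("A", "B", 0.9)], nodes=["A", "B", "E"])
        assert seed_scores(net, {"A"}, {"B", "E"}).scores["E"] == 0.0

    def test_universe_must_exclude_seeds(self):
        net = WeightedGeneNetwork([("A", "B", 0.9)])
        with pytest.raises(ValueError, match="exclude seeds"):
            seed_scores(net, {"A"}, {"A", "B"})

    @pytest.mark.parametrize("seed", range(5))
    def test_against_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_nodes=50, edge_prob=0.12)
        genes = sorted(net.nodes)
        seeds = set(rng.choice(genes, size=5, replace=False))
        universe = [g for g in genes if g not in seeds]
        sv = seed_scores(net, seeds, universe)
        oracle = brute_force_seed_scores(net.edges(), seeds, universe)
        for g in universe:
            assert sv.scores[g] == pytest.approx(oracle[g], abs=1e-12)


class TestRetrievalAuc:
    def test_perfect_separation(self):
        from fmodscreen.mp import SeedScoreVector
        sv = SeedScoreVector(("a", "b", "c", "d"),
                             np.array([4.0, 3.0, 1.0, 0.0]), frozenset("s"))
        assert retrieval_auc(sv, {"a", "b"}) == 1.0

    def test_all_tied_is_half(self):
        from fmodscreen.mp import SeedScoreVector
        sv = SeedScoreVector(("a", "b", "c"), np.zeros(3), frozenset("s"))
        assert retrieval_auc(sv, {"b"}) == 0.5

    def test_middle_positive(self):
        from fmodscreen.mp import SeedScoreVector
        sv = SeedScoreVector(("C", "D", "E"),
                             np.array([0.8, 0.2, 0.0]), frozenset("s"))
        assert retrieval_auc(sv, {"D"}) == 0.5  # beats E, loses to C

    def test_degenerate_positive_sets(self):
        from fmodscreen.mp import SeedScoreVector
        sv = SeedScoreVector(("a", "b"), np.array([1.0, 0.0]), frozenset("s"))
        with pytest.raises(ValueError):
            retrieval_auc(sv, set())
        with pytest.raises(ValueError):
            retrieval_auc(sv, {"a", "b"})

    def test_random_positives_mean_half(self):
        """E[AUC] = 0.5 for random positive sets; 1000 draws, 3 SE."""
        from fmodscreen.mp import SeedScoreVector
        rng = np.random.default_rng(0)
        values = rng.normal(size=40)
        sv = SeedScoreVector(tuple(f"g{i}" for i in range(40)), values,
                             frozenset("s"))
        aucs = []
        for _ in range(1000):
            pos = set(rng.choice(sv.genes, size=8, replace=False))
            aucs.append(retrieval_auc(sv, pos))
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / math.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se

    @pytest.mark.parametrize("seed", range(10))
    def test_against_pairwise_and_trapezoid_oracles(self, seed):
        from fmodscreen.mp import SeedScoreVector
        rng = np.random.default_rng(100 + seed)
        n = 30
        # duplicate-heavy scores to exercise tie handling
        values = rng.choice([0.0, 0.0, 0.25, 0.5, 1.0, 2.0], size=n)
        genes = tuple(f"g{i}" for i in range(n))
        sv = SeedScoreVector(genes, values.astype(float), frozenset("s"))
        pos = set(rng.choice(genes, size=6, replace=False))
        got = retrieval_auc(sv, pos)
        scores = dict(zip(genes, values))
        assert got == pytest.approx(pairwise_auc(scores, pos), abs=1e-12)
        assert got == pytest.approx(trapezoid_auc(scores, pos), abs=1e-12)


def planted_module_net(rng, n_genes=60, module=20):
    genes = [f"g{i}" for i in range(n_genes)]
    edges = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            both_in = i < module and j < module
            p = 0.7 if both_in else 0.03
            if rng.random() < p:
                w = rng.beta(8, 2) if both_in else rng.beta(2, 8)
                edges[(genes[i], genes[j])] = float(max(w, 1e-9))
    return (WeightedGeneNetwork([(a, b, w) for (a, b), w in edges.items()],
                                nodes=genes), genes)


class TestMutualPredictability:
    def test_geometric_mean_arithmetic(self):
        assert math.sqrt(0.8 * 0.9) == pytest.approx(0.8485, abs=5e-4)

    def test_planted_halves_score_high_and_beat_random(self):
        """Two halves of one dense planted module yield MP above a
        random drug set of the same size in >= 95/100 paired draws."""
        rng = np.random.default_rng(1234)
        wins = 0
        for _ in range(100):
            net, genes = planted_module_net(rng)
            mag = GeneModule(frozenset(genes[:2]), frozenset(genes[:10]),
                             "up", 1, 10)
            drg = DrugSignature("c", "p", "down", tuple(genes[10:20]))
            rand_genes = tuple(
                rng.choice(genes[20:], size=10, replace=False))
            rand = DrugSignature("c", "p", "down", rand_genes)
            mp_planted = mutual_predictability(net, mag, drg).mp
            mp_rand = mutual_predictability(net, mag, rand).mp
            wins += mp_planted > mp_rand
        assert wins >= 95

    def test_mp_is_geometric_mean_and_bounded(self):
        rng = np.random.default_rng(5)
        net, genes = planted_module_net(rng)
        mag = GeneModule(frozenset(genes[:2]), frozenset(genes[:10]),
                         "up", 1, 10)
        drg = DrugSignature("c", "p", "down", tuple(genes[10:20]))
        r = mutual_predictability(net, mag, drg)
        assert r.mp == pytest.approx(
            math.sqrt(r.auc_m_to_d * r.auc_d_to_m), abs=1e-12)
        assert min(r.auc_m_to_d, r.auc_d_to_m) <= r.mp \
            <= max(r.auc_m_to_d, r.auc_d_to_m)
        assert 0.0 <= r.mp <= 1.0

    def test_label_invariance(self):
        """Relabeling genes consistently leaves MP unchanged."""
        rng = np.random.default_rng(9)
        net, genes = planted_module_net(rng, n_genes=40, module=12)
        perm = dict(zip(genes, rng.permutation(genes)))
        net2 = WeightedGeneNetwork(
            [(perm[a], perm[b], w) for a, b, w in net.edges()],
            nodes=[perm[g] for g in genes])
        mag = GeneModule(frozenset(genes[:2]), frozenset(genes[:6]), "up", 1, 6)
        mag2 = GeneModule(frozenset(perm[g] for g in mag.seeds),
                          frozenset(perm[g] for g in mag.members), "up", 1, 6)
        drg = DrugSignature("c", "p", "down", tuple(genes[6:12]))
        drg2 = DrugSignature("c", "p", "down", tuple(perm[g] for g in drg.genes))
        r1 = mutual_predictability(net, mag, drg)
        r2 = mutual_predictability(net2, mag2, drg2)
        assert r1.mp == pytest.approx(r2.mp, abs=1e-12)

    def test_degenerate_reported_missing_not_zero(self):
        net = WeightedGeneNetwork([("A", "B", 0.9)], nodes=["A", "B"])
        mag = GeneModule(frozenset("A"), frozenset("AB"), "up", 1, 1)
        drg = DrugSignature("c", "p", "down", ("A", "B"))
        r = mutual_predictability(net, mag, drg)
        assert r.is_missing and r.mp is None and r.reason

    def test_off_network_positives_kept_at_zero(self):
        net = WeightedGeneNetwork(
            [("A", "B", 0.9), ("A", "C", 0.1)], nodes=["A", "B", "C", "D"])
        mag = GeneModule(frozenset("A"), frozenset("A"), "up", 1, 1)
        drg = DrugSignature("c", "p", "down", ("B", "ZZZ"))
        r = mutual_predictability(net, mag, drg)
        assert not r.is_missing
        r2 = mutual_predictability(net, mag, drg,
                                   drop_nonnetwork_positives=True)
        assert r2.auc_m_to_d >= r.auc_m_to_d  # zero-scored ZZZ dragged AUC
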