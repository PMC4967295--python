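import dataclasses
import math

import numpy as np
import pytest

from fmodscreen import (CompoundProfile, MPResult, RankedExpressionProfile,
                        call_candidates, both_direction_overlap,
                        rank_compounds, ranked_list_auc, recall_enrichment,
                        score_compound, optimize_parameters)
from fmodscreen.disease import build_mag
from fmodscreen.screen import RankedCompoundList, drg_direction

from conftest import study_config
from oracles import exact_hypergeom_tail, positional_auc


def mp(cid, mpval, p=None, fdr=None, reason=None, pid="p1"):
    return MPResult(cid, pid, "UCDB", mp=mpval, p_value=p, fdr=fdr,
                    reason=reason)


class TestScoreCompound:
    def test_max_over_profiles(self, bundle, thresholded, pathway_genes):
        mag = build_mag(thresholded, bundle.seeds, bundle.disease_profile,
                        bundle.truth["m_star"], "up", 1, pathway_genes)
        cid = bundle.effective[0]
        res = score_compound(thresholded, mag, bundle.compounds[cid],
                             bundle.truth["k_star"], "UCDB")
        per_profile = []
        for prof in bundle.compounds[cid]:
            r = score_compound(thresholded, mag, [prof],
                               bundle.truth["k_star"], "UCDB")
            per_profile.append(r.mp)
        assert res.mp == max(per_profile)

    def test_direction_pairing_enforced(self, bundle, thresholded,
                                        pathway_genes):
        assert drg_direction("UCDB") == "down"
        assert drg_direction("DCUB") == "up"
        mag_up = build_mag(thresholded, bundle.seeds, bundle.disease_profile,
                           25, "up", 1, pathway_genes)
        cid = bundle.effective[0]
        with pytest.raises(ValueError, match="direction"):
            score_compound(thresholded, mag_up, bundle.compounds[cid],
                           30, "DCUB")

    def test_single_profile_is_returned(self, bundle, thresholded,
                                        pathway_genes):
        mag = build_mag(thresholded, bundle.seeds, bundle.disease_profile,
                        25, "up", 1, pathway_genes)
        cid = bundle.effective[0]
        prof = bundle.compounds[cid][0]
        res = score_compound(thresholded, mag, [prof], 30, "UCDB")
        assert res.profile_id == prof.profile_id


class TestRankCompounds:
    def test_tie_breaks_and_missing_last(self):
        records = [mp("b", 0.7, p=0.2), mp("a", 0.9, p=0.01),
                   mp("c", 0.7, p=0.05),
                   mp("z", None, reason="degenerate")]
        ranked = rank_compounds(records, 5, 10, "UCDB")
        assert ranked.compound_order() == ["a", "c", "b"]
        assert ranked.records[-1].compound_id == "z"
        assert ranked.records[-1].is_missing

    def test_order_independent_of_input_order(self):
        rng = np.random.default_rng(0)
        records = [mp(f"c{i}", float(v))
                   for i, v in enumerate(rng.uniform(size=20))]
        a = rank_compounds(list(records), 5, 10, "UCDB").compound_order()
        rng.shuffle(records)
        b = rank_compounds(records, 5, 10, "UCDB").compound_order()
        assert a == b

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            rank_compounds([mp("a", None, reason="x")], 5, 10, "UCDB")


class TestRankedListAuc:
    def test_all_positives_on_top(self):
        assert ranked_list_auc(["p1", "p2", "n1", "n2"], {"p1", "p2"}) == 1.0

    def test_alternating(self):
        assert ranked_list_auc(["p1", "n1", "p2", "n2"], {"p1", "p2"}) == 0.75

    def test_reversal_complements(self):
        order = [f"c{i}" for i in range(12)]
        pos = {"c0", "c3", "c7"}
        a = ranked_list_auc(order, pos)
        b = ranked_list_auc(order[::-1], pos)
        assert a + b == pytest.approx(1.0)

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(4)
        order = [f"c{i}" for i in range(25)]
        for _ in range(20):
            pos = set(rng.choice(order, size=5, replace=False))
            labels = [c in pos for c in order]
            assert ranked_list_auc(order, pos) == \
                pytest.approx(positional_auc(labels), abs=1e-12)

    def test_permuted_labels_mean_half(self):
        rng = np.random.default_rng(4)
        order = [f"c{i}" for i in range(30)]
        aucs = []
        for _ in range(1000):
            pos = set(rng.choice(order, size=6, replace=False))
            aucs.append(ranked_list_auc(order, pos))
        aucs = np.array(aucs)
        se = aucs.std(ddof=1) / math.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 3 * se

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            ranked_list_auc(["a", "b"], {"a", "b"})


class TestRecallEnrichment:
    @pytest.mark.parametrize("N, sig, lab, ov, printed", [
        (3678, 2435, 20, 20, 2.5e-4),
        (4228, 1668, 11, 9, 5.3e-3),
    ])
    def test_published_style_counts(self, N, sig, lab, ov, printed):
        assert recall_enrichment(N, sig, lab, ov) == \
            pytest.approx(printed, rel=0.05)

    @pytest.mark.parametrize("N, sig, lab, ov", [
        (3678, 2435, 20, 20), (4228, 1668, 11, 9), (3678, 1875, 20, 19),
        (4228, 2500, 11, 10), (100, 40, 12, 9),
    ])
    def test_matches_exact_enumeration(self, N, sig, lab, ov):
        assert recall_enrichment(N, sig, lab, ov) == \
            pytest.approx(exact_hypergeom_tail(N, sig, lab, ov), abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert recall_enrichment(100, 50, 10, 0) == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            recall_enrichment(100, 50, 10, 11)


class TestCallCandidates:
    def _list(self, fdrs):
        records = [mp(f"c{i}", 1.0 - i * 0.01, p=0.01, fdr=f)
                   for i, f in enumerate(fdrs)]
        return RankedCompoundList(records, 5, 10, "UCDB")

    def test_strict_cutoff(self):
        ranked = self._list([0.01, 0.04, 0.06, 0.2, 0.5, 1.0])
        report = call_candidates(ranked, 0.05)
        assert len(report.called) == 2

    def test_cutoff_one_calls_everything_below_one(self):
        ranked = self._list([0.01, 0.2, 0.99])
        assert len(call_candidates(ranked, 1.0).called) == 3

    def test_label_cross_tab(self):
        ranked = self._list([0.01, 0.04, 0.5])
        report = call_candidates(ranked, 0.05, {"fda": ["c0", "c2"]})
        assert report.label_counts["fda"] == 1
        assert report.label_totals["fda"] == 2
        assert 0 < report.enrichment_p["fda"] <= 1

    def test_both_direction_overlap(self):
        a = call_candidates(self._list([0.01, 0.04, 0.5]), 0.05)
        b = call_candidates(self._list([0.01, 0.5, 0.01]), 0.05)
        assert both_direction_overlap(a, b) == 1
        assert both_direction_overlap(a, b, {"c0", "zz"}) == 1

    def test_missing_fdr_errors(self):
        ranked = RankedCompoundList([mp("a", 0.9)], 5, 10, "UCDB")
        with pytest.raises(ValueError):
            call_candidates(ranked, 0.05)


class TestOptimizeParameters:
    def test_single_cell_grid_returns_it(self, bundle, thresholded,
                                         pathway_genes):
        cfg = study_config(0, m_values=[25], k_step=10, k_floor=30,
                           k_window=5, n_reps=50, n_reps_auc=50)
        res = optimize_parameters(thresholded, bundle.seeds,
                                  bundle.disease_profile, pathway_genes,
                                  bundle.compounds, bundle.effective, cfg)
        assert (res.best_m, res.best_k) == (25, 30)
        assert len(res.auc_table) == 1

    def test_equal_auc_ties_break_to_smaller_m(self, bundle, thresholded,
                                               pathway_genes):
        # m=25 and m=26 admit the same module (pathway filter caps the
        # membership), so their AUCs tie exactly; smaller m must win
        cfg = study_config(0, m_values=[26, 25], k_step=10, k_floor=30,
                           k_window=5, n_reps=50, n_reps_auc=50)
        res = optimize_parameters(thresholded, bundle.seeds,
                                  bundle.disease_profile, pathway_genes,
                                  bundle.compounds, bundle.effective, cfg)
        aucs = res.auc_table.groupby("m")["auc"].max()
        assert aucs[25] == aucs[26]
        assert res.best_m == 25

    def test_annotated_list_carries_p_and_fdr(self, bundle, thresholded,
                                              pathway_genes):
        cfg = study_config(0, m_values=[25], k_step=10, k_floor=30,
                           k_window=5, n_reps=100, n_reps_auc=50)
        res = optimize_parameters(thresholded, bundle.seeds,
                                  bundle.disease_profile, pathway_genes,
                                  bundle.compounds, bundle.effective, cfg)
        for r in res.best_list.ranked:
            assert r.p_value is not None and r.fdr is not None
        fdrs = [r.fdr for r in res.best_list.ranked]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
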