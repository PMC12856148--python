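"""PSM-level metrics, stratification, tool combination, misassignment census."""

import numpy as np
import pandas as pd
import pytest

from saavbench.catalog import CognatePair, saav_call
from saavbench.evaluation import (
    combine_tool_candidates,
    compute_metrics,
    evaluate_per_sample,
    f1_score,
    gold_truth_saavs,
    match_candidates_to_gold,
    misassignment_census,
    peptides_match,
    rank_sum_compare,
    stratify_by_saav,
)
from saavbench.gold import GoldStandardSet


def cand_frame(rows):
    cols = ["sample_id", "spectrum_id", "tool", "peptide", "delta_mass", "site",
            "from_aa", "to_aa", "variant_peptide"]
    return pd.DataFrame(rows, columns=cols)


def gold_set(keys, provenance="t"):
    gs = GoldStandardSet(provenance=provenance)
    for sample, spec, pep in keys:
        gs.keys.setdefault(sample, set()).add((spec, pep))
    return gs


class TestMatching:
    def test_x_matches_ile_or_leu_at_variant_site(self):
        assert peptides_match("AKHPMDTEXTK", "AKHPMDTEITK")
        assert peptides_match("AKHPMDTEXTK", "AKHPMDTELTK")
        assert not peptides_match("AKHPMDTEKTK", "AKHPMDTEITK")
        assert not peptides_match("AKHPMDTEXT", "AKHPMDTEITK")

    def test_match_is_psm_level(self):
        gold = gold_set([("s1", "sp7", "AKHPMDTEITK")])
        hit = cand_frame([("s1", "sp7", "t", "AKHPMDTEVTK", 14.0157, 9, "V", "X", "AKHPMDTEXTK")])
        miss = cand_frame([("s1", "sp8", "t", "AKHPMDTEVTK", 14.0157, 9, "V", "X", "AKHPMDTEXTK")])
        assert len(match_candidates_to_gold(hit, gold)) == 1
        assert len(match_candidates_to_gold(miss, gold)) == 0


class TestF1:
    @pytest.mark.parametrize(
        "p, s, expected", [(0.5, 0.5, 0.5), (1.0, 0.0, 0.0), (0.692, 0.483, 0.5689)]
    )
    def test_examples(self, p, s, expected):
        assert f1_score(p, s) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)


class TestComputeMetrics:
    def _one_third_case(self):
        gold = gold_set(
            [("s1", "sp1", "ILDELTK"), ("s1", "sp2", "ILDELTK"), ("s1", "sp3", "ILDELTK")]
        )
        cands = cand_frame(
            [
                ("s1", "sp1", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK"),
                ("s1", "sp8", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK"),
                ("s1", "sp9", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK"),
            ]
        )
        return cands, gold

    def test_one_third_everywhere(self):
        cands, gold = self._one_third_case()
        m = compute_metrics(cands, gold, gold, "s1")
        assert m.precision == pytest.approx(1 / 3)
        assert m.sensitivity == pytest.approx(1 / 3)
        assert m.f1 == pytest.approx(1 / 3)

    def test_perfect_recovery(self):
        gold = gold_set([("s1", "sp1", "ILDELTK")])
        cands = cand_frame([("s1", "sp1", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK")])
        m = compute_metrics(cands, gold, gold, "s1")
        assert (m.precision, m.sensitivity, m.f1) == (1.0, 1.0, 1.0)

    def test_empty_candidates_leave_precision_undefined(self):
        gold = gold_set([("s1", "sp1", "ILDELTK")])
        m = compute_metrics(cand_frame([]), gold, gold, "s1")
        assert m.precision is None
        assert m.sensitivity == 0.0
        assert m.f1 is None

    def test_duplicate_candidate_rows_do_not_change_metrics(self):
        cands, gold = self._one_third_case()
        doubled = pd.concat([cands, cands], ignore_index=True)
        a = compute_metrics(cands, gold, gold, "s1")
        b = compute_metrics(doubled, gold, gold, "s1")
        assert (a.precision, a.sensitivity) == (b.precision, b.sensitivity)

    def test_mixed_mode_uses_both_gold_sets(self):
        inter = gold_set([("s1", "sp1", "ILDELTK")])
        union = gold_set([("s1", "sp1", "ILDELTK"), ("s1", "sp2", "ILDELTK")])
        cands = cand_frame(
            [
                ("s1", "sp1", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK"),
                ("s1", "sp2", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK"),
            ]
        )
        m = compute_metrics(cands, inter, union, "s1", gold_mode="mixed")
        assert m.sensitivity == 1.0  # sp1 over |intersection| = 1
        assert m.precision == 1.0  # both candidates in the union


class TestStratify:
    def test_per_saav_counts_and_partition(self):
        pairs = [
            CognatePair("G1", "AKHPMDTEVTK", "AKHPMDTEITK", 9, saav_call("V", "I")),
            CognatePair("G2", "AAADTTTK", "AAAETTTK", 4, saav_call("D", "E")),
        ]
        gold = gold_set([("s1", "sp1", "AKHPMDTEITK"), ("s1", "sp2", "AAAETTTK")])
        cands = cand_frame(
            [
                ("s1", "sp1", "t", "AKHPMDTEVTK", 14.0157, 9, "V", "X", "AKHPMDTEXTK"),
                ("s1", "sp2", "t", "AAADTTTK", 14.0157, 4, "D", "E", "AAAETTTK"),
                ("s1", "sp9", "t", "AAADTTTK", 14.0157, 4, "D", "E", "AAAETTTK"),
            ]
        )
        table = stratify_by_saav(cands, gold, pairs).set_index("saav")
        assert table.loc["V>X", "precision"] == 1.0
        assert table.loc["V>X", "sensitivity"] == 1.0
        assert table.loc["D>E", "precision"] == pytest.approx(0.5)
        # per-SAAV TP counts partition the overall TP count
        assert table["n_true_positive"].sum() == len(match_candidates_to_gold(cands, gold))

    def test_wrong_call_scores_zero_both_ways(self):
        pairs = [CognatePair("G1", "AKHPMDTEVTK", "AKHPMDTEITK", 9, saav_call("V", "I"))]
        gold = gold_set([("s1", "sp1", "AKHPMDTEITK")])
        cands = cand_frame(
            [("s1", "sp1", "t", "AKHPMDTEVTK", 14.0157, 6, "D", "E", "AKHPMETEVTK")]
        )
        table = stratify_by_saav(cands, gold, pairs).set_index("saav")
        assert table.loc["D>E", "precision"] == 0.0
        assert table.loc["V>X", "sensitivity"] == 0.0


class TestCombineTools:
    def _sets(self):
        k1 = ("s1", "sp1", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK")
        k2 = ("s1", "sp2", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK")
        k3 = ("s1", "sp3", "t", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK")
        return {"A": cand_frame([k1, k2]), "B": cand_frame([k2, k3])}

    def test_union_and_intersection(self):
        sets = self._sets()
        union = combine_tool_candidates(sets, "union")
        inter = combine_tool_candidates(sets, "intersection")
        assert set(union["spectrum_id"]) == {"sp1", "sp2", "sp3"}
        assert set(inter["spectrum_id"]) == {"sp2"}
        assert set(inter["tools"]) == {"A;B"}

    def test_same_spectrum_different_variants_not_in_intersection(self):
        a = cand_frame([("s1", "sp1", "A", "VLDELTK", 14.0157, 1, "V", "X", "XLDELTK")])
        b = cand_frame([("s1", "sp1", "B", "AAADTTTK", 14.0157, 4, "D", "E", "AAAETTTK")])
        inter = combine_tool_candidates({"A": a, "B": b}, "intersection")
        assert len(inter) == 0

    def test_union_sensitivity_dominates_each_tool(self):
        sets = self._sets()
        gold = gold_set(
            [("s1", f"sp{i}", "ILDELTK") for i in (1, 2, 3)]
        )
        union = combine_tool_candidates(sets, "union")
        per_tool = [
            compute_metrics(df, gold, gold, "s1").sensitivity for df in sets.values()
        ]
        combined = compute_metrics(union, gold, gold, "s1").sensitivity
        assert combined >= max(per_tool)

    def test_single_tool_is_an_error(self):
        with pytest.raises(ValueError):
            combine_tool_candidates({"A": cand_frame([])}, "union")


class TestMisassignmentCensus:
    def test_de_call_absorbing_isobaric_true_saavs(self):
        """A preset D→E caller on +14.0157 spectra whose true SAAVs are V→I
        or N→Q shows up as census cells with zero mass-shift difference."""
        truth = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "spectrum_id": ["sp1", "sp2"],
                "from_aa": ["V", "N"],
                "to_aa": ["I", "Q"],
                "site": [9, 2],
            }
        )
        false_cands = cand_frame(
            [
                ("s1", "sp1", "t", "AKHPMDTEVTK", 14.0157, 6, "D", "E", "AKHPMETEVTK"),
                ("s1", "sp2", "t", "ANDDTTTK", 14.0157, 3, "D", "E", "ANEDTTTK"),
            ]
        )
        census = misassignment_census(false_cands, truth)
        cells = {
            (r.called_saav, r.true_saav): r.delta_mass_shift
            for r in census.itertuples(index=False)
        }
        assert cells[("D>E", "V>X")] == 0.0
        assert cells[("D>E", "N>Q")] == 0.0

    def test_empty_input_gives_empty_table(self):
        assert misassignment_census(cand_frame([]), pd.DataFrame()).empty


class TestOnSimulatedData:
    def test_mixed_mode_relations_per_sample(self, small_sim):
        """Intersection gold is contained in each tool's gold which is
        contained in the union; sensitivity against the intersection is at
        least the sensitivity against the union."""
        from saavbench.gold import build_gold_standard, mix_gold_standards
        from saavbench.openparse import (
            accepted_candidates,
            assign_saav_table,
            filter_localized_psms,
            normalize_psm_table,
        )

        sim = small_sim
        ga = build_gold_standard(
            sim.closed_psms[sim.closed_psms.tool == "toolA"], sim.pairs, "toolA"
        )
        gb = build_gold_standard(
            sim.closed_psms[sim.closed_psms.tool == "toolB"], sim.pairs, "toolB"
        )
        inter = mix_gold_standards(ga, gb, "intersection")
        union = mix_gold_standards(ga, gb, "union")
        for s in union.sample_ids():
            assert inter.get(s) <= ga.get(s) <= union.get(s)
            assert inter.get(s) <= gb.get(s) <= union.get(s)
        cand = accepted_candidates(
            assign_saav_table(
                filter_localized_psms(
                    normalize_psm_table(sim.open_psms["open_a"]), "generic"
                )
            )
        )
        tp_inter = match_candidates_to_gold(cand, inter)
        tp_union = match_candidates_to_gold(cand, union)
        # true positives against the strict gold are a subset of those
        # against the lenient gold
        assert tp_inter <= tp_union
        for s in inter.sample_ids():
            m = compute_metrics(cand, inter, union, s, gold_mode="mixed")
            assert m.n_true_positive_sensitivity <= m.n_true_positive

    def test_gold_truth_annotation_covers_gold(self, small_sim):
        from saavbench.gold import build_gold_standard

        gs = build_gold_standard(
            small_sim.closed_psms[small_sim.closed_psms.tool == "toolA"],
            small_sim.pairs,
            "toolA",
        )
        truth = gold_truth_saavs(gs, small_sim.pairs)
        assert len(truth) == gs.n_total()


def test_rank_sum_compare_two_sided():
    stat, p = rank_sum_compare([1, 2, 3, 4], [10, 11, 12, 13])
    assert p < 0.05
    with pytest.raises(ValueError):
        rank_sum_compare([], [1.0])
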