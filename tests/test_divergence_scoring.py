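import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import straight_line_divergence_score

from kinevo.divergence_scoring import (CladeComparison, DivergenceScoreTable,
                                       ancestral_agreement, call_switches,
                                       category_tests, divergence_scores,
                                       frequently_switching,
                                       recent_conservation, rescaled_matrix,
                                       select_focal_clade,
                                       select_sister_clade)
from kinevo.alphabet import AA_INDEX, AMINO_ACIDS
from kinevo.io_formats import (AncestralStateTable, FunctionalCategoryMap,
                               SequenceLabels, parse_tree)

MATRIX = rescaled_matrix()


def _onehot(res):
    v = np.zeros(20)
    v[AA_INDEX[res]] = 1.0
    return v


class TestRecentConservation:
    def test_identical_tryptophans_hit_matrix_maximum(self):
        assert recent_conservation("WWWW", MATRIX) == pytest.approx(1.0)

    def test_hand_arithmetic_rree(self):
        # BLOSUM62: R-R = 5, R-E = 0, E-E = 5; rescaled (v+4)/15 over 6 pairs
        expected = (2 * (5 + 4) / 15 + 4 * (0 + 4) / 15) / 6
        assert recent_conservation("RREE", MATRIX) == pytest.approx(expected)

    def test_gap_pairs_contribute_zero(self):
        # pairs: (W,W)=1 and two gap pairs contributing 0, over 3 pairs
        assert recent_conservation("WW-", MATRIX) == pytest.approx(1 / 3)

    def test_fewer_than_two_residues_undefined(self):
        assert recent_conservation("W--", MATRIX) is None
        assert recent_conservation("---", MATRIX) is None


class TestAncestralAgreement:
    def test_matching_residues(self):
        post = np.zeros(20)
        post[AA_INDEX["R"]] = 0.97
        post[AA_INDEX["K"]] = 0.03
        ac, p = ancestral_agreement("R", "R", post)
        assert (ac, p) == (1, pytest.approx(0.97))

    def test_differing_residues(self):
        post = np.zeros(20)
        post[AA_INDEX["E"]] = 0.98
        post[AA_INDEX["R"]] = 0.02
        ac, p = ancestral_agreement("R", "E", post)
        assert ac == -1
        assert p == pytest.approx(0.98)

    def test_contradictory_table_zeroes_the_weight(self):
        ac, p = ancestral_agreement("R", "E", _onehot("R"))
        assert (ac, p) == (-1, pytest.approx(0.0))

    def test_ancestral_gap_never_matches(self):
        ac, p = ancestral_agreement("-", "R", _onehot("R"))
        assert ac == -1
        assert p == pytest.approx(1.0)

    @given(p_b=st.floats(0, 1), ac_match=st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_score_monotone_in_confidence(self, p_b, ac_match):
        # with AC = -1, raising p(AC) raises S; with AC = +1 it lowers S
        rc = 0.5
        ac = 1 if ac_match else -1
        s_lo = rc - ac * (p_b * 0.5)
        s_hi = rc - ac * p_b
        if ac == -1:
            assert s_hi >= s_lo
        else:
            assert s_hi <= s_lo


def _toy_comparison_inputs(make_aln, rng, n_a=4, n_b=4, n_cols=20):
    ids_a = [f"a{i}" for i in range(n_a)]
    ids_b = [f"b{i}" for i in range(n_b)]
    rows = {i: "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(n_cols))
            for i in ids_a + ids_b}
    aln = make_aln(rows)
    entries = {}
    for node in ("ancA", "ancB"):
        for col in range(n_cols):
            alpha = np.full(20, 0.2)
            post = rng.dirichlet(alpha)
            entries[(node, col)] = (AMINO_ACIDS[int(np.argmax(post))], post)
    anc = AncestralStateTable(entries)
    comp = CladeComparison(
        focal="FAM", level="family",
        clade_a_node="ancA", clade_a_leaves=frozenset(ids_a),
        clade_b_node="ancB", clade_b_leaves=frozenset(ids_b),
        ancestor_a="ancA", ancestor_b="ancB", purity=1.0, coverage=1.0)
    return comp, aln, anc, ids_a


class TestDivergenceScores:
    def test_forced_arithmetic_extremes(self, make_aln):
        # conserved + identical certain ancestors -> 0;
        # conserved + certain fixed difference -> 2
        aln = make_aln({"a0": "WW", "a1": "WW", "b0": "WW", "b1": "WW"})
        entries = {
            ("ancA", 0): ("W", _onehot("W")),
            ("ancB", 0): ("W", _onehot("W")),
            ("ancA", 1): ("W", _onehot("W")),
            ("ancB", 1): ("R", _onehot("R")),
        }
        comp = CladeComparison(
            focal="FAM", level="family",
            clade_a_node="ancA", clade_a_leaves=frozenset(["a0", "a1"]),
            clade_b_node="ancB", clade_b_leaves=frozenset(["b0", "b1"]),
            ancestor_a="ancA", ancestor_b="ancB")
        table = divergence_scores(comp, aln, AncestralStateTable(entries))
        s = table.scores.set_index("column")["s"]
        assert s[0] == pytest.approx(0.0)
        assert s[1] == pytest.approx(2.0)

    def test_matches_straight_line_reimplementation(self, make_aln, rng):
        comp, aln, anc, ids_a = _toy_comparison_inputs(make_aln, rng, n_cols=50)
        table = divergence_scores(comp, aln, anc)
        seqs = dict(aln.sequences)
        for row in table.scores.itertuples(index=False):
            col = int(row.column)
            expected = straight_line_divergence_score(
                [seqs[i][col] for i in sorted(ids_a)],
                anc.residue("ancA", col), anc.residue("ancB", col),
                anc.posterior("ancB", col), MATRIX)
            assert row.s == pytest.approx(expected, abs=1e-12)

    def test_scores_within_range_and_recompose(self, make_aln, rng):
        comp, aln, anc, _ = _toy_comparison_inputs(make_aln, rng)
        table = divergence_scores(comp, aln, anc)
        s = table.scores
        assert ((s["s"] >= -1) & (s["s"] <= 2)).all()
        np.testing.assert_allclose(s["rc"] - s["ac"] * s["p_ac"], s["s"],
                                   atol=1e-15)

    def test_missing_ancestral_entry_skips_column(self, make_aln, rng):
        comp, aln, anc, _ = _toy_comparison_inputs(make_aln, rng, n_cols=10)
        del anc.entries[("ancB", 3)]
        table = divergence_scores(comp, aln, anc)
        assert 3 not in set(table.scores["column"])
        assert len(table.scores) == 9


def _score_table(scores_by_column, anc_a="ancA", anc_b="ancB"):
    """Build a valid table with the requested S values (all in [-1, 2])."""
    values = list(scores_by_column.values())
    assert all(-1 <= v <= 2 for v in values)
    rc = [min(max(v, 0.0), 1.0) for v in values]
    ac = [-1 if v >= r else 1 for v, r in zip(values, rc)]
    p_ac = [abs(v - r) for v, r in zip(values, rc)]
    assert all(0 <= p <= 1 for p in p_ac)
    df = pd.DataFrame({
        "column": list(scores_by_column),
        "domain_position": [c + 1 for c in scores_by_column],
        "rc": rc,
        "ac": ac,
        "p_ac": p_ac,
        "s": values,
    })
    comp = CladeComparison(
        focal="FAM", level="family", ancestor_a=anc_a, ancestor_b=anc_b,
        clade_a_node=anc_a, clade_b_node=anc_b)
    return DivergenceScoreTable(comp, df)


class TestSwitchCalling:
    def test_all_equal_scores_yield_no_switches(self):
        tb = _score_table({c: 0.5 for c in range(20)})
        profile = call_switches([tb], "family", n_positions=20)
        assert sum(profile.counts.values()) == 0

    def test_duplicate_ancestor_pairs_counted_once(self):
        tb1 = _score_table({c: c / 10 for c in range(10)})
        tb2 = _score_table({c: c / 10 for c in range(10)})  # same ancestors
        profile = call_switches([tb1, tb2], "family", n_positions=10)
        solo = call_switches([tb1], "family", n_positions=10)
        assert profile.counts == solo.counts

    def test_quantile_arithmetic_1_to_100(self):
        # pooled scores (1..100)/50: the linear-interpolation 95th
        # percentile is 95.05/50; strictly above -> the 5 top columns
        tables = [_score_table({c: (i * 25 + c + 1) / 50 for c in range(25)},
                               anc_a=f"A{i}", anc_b=f"B{i}")
                  for i in range(4)]
        profile = call_switches(tables, "family", n_positions=25)
        assert profile.threshold == pytest.approx(95.05 / 50)
        assert sum(profile.counts.values()) == 5

    def test_concatenating_with_itself_changes_nothing(self):
        tb = _score_table({c: c / 30 for c in range(30)})
        once = call_switches([tb], "family", n_positions=30)
        twice = call_switches([tb, tb], "family", n_positions=30)
        assert once.counts == twice.counts


class TestFrequentlySwitching:
    def test_all_zero_counts_empty(self):
        from kinevo.divergence_scoring import SwitchProfile
        profile = SwitchProfile("family", {p: 0 for p in range(1, 11)},
                                0.0, 1)
        assert frequently_switching(profile) == set()

    def test_strict_exceedance_semantics(self):
        from kinevo.divergence_scoring import SwitchProfile
        # make the 90th percentile exactly 7: 220 low counts, then 7s and 8s
        counts = {}
        for p in range(1, 221):
            counts[p] = 1
        for p in range(221, 242):
            counts[p] = 7
        for p in range(242, 247):
            counts[p] = 8
        profile = SwitchProfile("family", counts, 0.0, 1)
        thr = np.percentile(list(counts.values()), 90)
        assert thr == pytest.approx(7.0)
        frequent = frequently_switching(profile)
        assert frequent == {p for p in range(242, 247)}  # 8s in, 7s out

    def test_toy_profile_hand_quantile(self):
        from kinevo.divergence_scoring import SwitchProfile
        counts = dict(zip(range(1, 11), [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]))
        profile = SwitchProfile("family", counts, 0.0, 1)
        # 90th percentile of 0..9 (linear interpolation) = 8.1
        assert frequently_switching(profile) == {10}


class TestCategoryTests:
    def _inputs(self, n=10, frequent=None, categories=None):
        cats = categories or {p: ("proximal" if p <= 4 else "other")
                              for p in range(1, n + 1)}
        cmap = FunctionalCategoryMap(cats, n_positions=n)
        from kinevo.divergence_scoring import SwitchProfile
        counts = {p: (10 if p <= 4 else 1) for p in range(1, n + 1)}
        profile = SwitchProfile("family", counts, 0.0, 1)
        return profile, frequent or set(), cmap

    def test_fisher_matches_exact_hypergeometric(self):
        # table (3,1;1,5): one-sided p = 25/210
        profile, _, cmap = self._inputs()
        frequent = {1, 2, 3, 5}  # 3 named + 1 other
        report = category_tests(profile, frequent, cmap)
        assert report["fisher_table"] == [[3, 1], [1, 5]]
        assert report["fisher_p"] == pytest.approx(25 / 210, abs=1e-12)

    def test_identical_count_distributions_give_half(self):
        n = 12
        cats = {p: ("proximal" if p <= 6 else "other")
                for p in range(1, n + 1)}
        cmap = FunctionalCategoryMap(cats, n_positions=n)
        from kinevo.divergence_scoring import SwitchProfile
        counts = {p: (p - 1) % 6 for p in range(1, n + 1)}
        profile = SwitchProfile("family", counts, 0.0, 1)
        report = category_tests(profile, {1}, cmap)
        assert report["mannwhitney_p"] == pytest.approx(0.5, abs=0.05)

    def test_perfect_concentration_is_significant(self):
        n = 20
        cats = {p: ("proximal" if p <= 10 else "other")
                for p in range(1, n + 1)}
        cmap = FunctionalCategoryMap(cats, n_positions=n)
        from kinevo.divergence_scoring import SwitchProfile
        counts = {p: (5 if p <= 10 else 0) for p in range(1, n + 1)}
        profile = SwitchProfile("family", counts, 0.0, 1)
        frequent = set(range(1, 9))  # all frequent positions are proximal
        report = category_tests(profile, frequent, cmap)
        assert report["fisher_p"] < 0.05


class TestCladeSelection:
    def _tree_and_labels(self):
        t = parse_tree(
            "(((f1:1,f2:1)P1:1,((f3:1,f4:1)P2:1,(f5:1,x1:1)P3:1)P4:1)FC:1,"
            "((g1:1,g2:1)Q1:1,(g3:1,(g4:1,g5:1)Q3:1)Q2:1)GC:1)R;")
        labels = {}
        for i in range(1, 6):
            labels[f"f{i}"] = SequenceLabels("sp", "GRP", "FAM_F")
            labels[f"g{i}"] = SequenceLabels("sp", "GRP", "FAM_G")
        labels["x1"] = SequenceLabels("sp", "GRP", "FAM_X")
        return t, labels

    def test_monophyletic_family(self):
        t, labels = self._tree_and_labels()
        comp = select_focal_clade(t, labels, "FAM_G", "family")
        assert comp.clade_a_node == "GC"
        assert comp.purity == 1.0
        assert comp.coverage == 1.0

    def test_spurious_below_15_percent_tolerated(self):
        # 1 spurious of 12 leaves (8.3% < 15%) keeps the MRCA clade
        t = parse_tree(
            "((" + ",".join(f"f{i}:1" for i in range(1, 12)) + ",x1:1)FC:1,"
            "(g1:1,g2:1,g3:1,g4:1,g5:1)GC:1)R;")
        labels = {f"f{i}": SequenceLabels("sp", "GRP", "FAM_F")
                  for i in range(1, 12)}
        labels["x1"] = SequenceLabels("sp", "GRP", "FAM_X")
        labels.update({f"g{i}": SequenceLabels("sp", "GRP", "FAM_G")
                       for i in range(1, 6)})
        comp = select_focal_clade(t, labels, "FAM_F", "family")
        assert comp.clade_a_node == "FC"
        assert comp.purity == pytest.approx(11 / 12)

    def test_spurious_over_15_percent_descends_to_pure_subclade(self):
        t, labels = self._tree_and_labels()
        # FAM_F's MRCA (FC) holds x1: 1/6 spurious (16.7% >= 15%)
        comp = select_focal_clade(t, labels, "FAM_F", "family")
        # largest fully pure subclade is P1+P2's parent? P1 holds f1,f2;
        # P2 holds f3,f4; the largest pure subtree is one of the pairs
        assert comp.purity == 1.0
        assert len(comp.clade_a_leaves) == 2

    def test_sister_selection_and_size_rule(self):
        t, labels = self._tree_and_labels()
        comp = select_focal_clade(t, labels, "FAM_G", "family")
        comp = select_sister_clade(t, comp, labels)
        assert comp.clade_b_node == "FC"
        assert comp.scorable  # both clades >= 5
        assert comp.ancestor_a == "GC"
        assert comp.ancestor_b == "FC"

    def test_small_sister_unscorable(self):
        t = parse_tree(
            "((f1:1,f2:1,f3:1,f4:1,f5:1)FC:1,(g1:1,g2:1,g3:1)GC:1)R;")
        labels = {f"f{i}": SequenceLabels("sp", "GRP", "FAM_F")
                  for i in range(1, 6)}
        labels.update({f"g{i}": SequenceLabels("sp", "GRP", "FAM_G")
                       for i in range(1, 4)})
        comp = select_focal_clade(t, labels, "FAM_F", "family")
        comp = select_sister_clade(t, comp, labels)
        assert not comp.scorable
        assert "5-sequence" in comp.reason

    def test_subfamily_sister_must_share_family(self):
        t = parse_tree(
            "((a1:1,a2:1,a3:1,a4:1,a5:1)AC:1,(b1:1,b2:1,b3:1,b4:1,b5:1)BC:1)R;")
        labels = {}
        for i in range(1, 6):
            labels[f"a{i}"] = SequenceLabels("sp", "GRP", "FAM1", "SUB_A")
            labels[f"b{i}"] = SequenceLabels("sp", "GRP", "FAM2", "SUB_B")
        comp = select_focal_clade(t, labels, "SUB_A", "subfamily")
        comp = select_sister_clade(t, comp, labels)
        assert not comp.scorable
        assert "FAM2" in comp.reason

    def test_no_focal_label_raises(self):
        t, labels = self._tree_and_labels()
        with pytest.raises(ValueError):
            select_focal_clade(t, labels, "NOPE", "family")
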