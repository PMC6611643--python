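import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import binomial_upper_tail

from kinevo.io_formats import PhosphoSiteCollection
from kinevo.motif_analysis import (CLASSICAL_MOTIFS, MotifPattern,
                                   canonical_motif, discover_motifs,
                                   filter_motifs, generate_background,
                                   match_motif, parse_motif,
                                   phosphoproteome_coverage,
                                   superset_binomial)
from kinevo.synthetic_data import PhosphoproteomeSpec, simulate_phosphoproteome


def _site(centre="S", **residues_at):
    chars = ["A"] * 15
    chars[7] = centre
    for pos, res in residues_at.items():
        chars[7 + int(pos)] = res
    return "".join(chars)


class TestPatternNotation:
    @pytest.mark.parametrize("text", [
        "S/T-P", "R-x-x-S/T", "S/T-x-x-D/E", "R-R-x-S/T", "S/T-P-x-K",
        "R-x-x-S/T-L/I/V",
    ])
    def test_round_trip(self, text):
        assert parse_motif(text).to_string() == text

    def test_centre_is_first_st_token(self):
        m = parse_motif("S/T-P")
        assert m.as_dict == {1: frozenset("P")}

    def test_invalid_without_centre(self):
        with pytest.raises(ValueError):
            parse_motif("R-x-x-P")


class TestMatching:
    def test_proline_directed(self):
        assert match_motif(parse_motif("S/T-P"), "AAAAAAASPAAAAAA")
        assert not match_motif(parse_motif("S/T-P"), "AAAAAAASAAAAAAA")

    def test_class_semantics_at_minus3(self):
        m = parse_motif("R-x-x-S/T")
        assert match_motif(m, _site(**{"-3": "R"}))
        assert not match_motif(m, _site(**{"-3": "K"}))
        assert match_motif(parse_motif("R/K-x-x-S/T"), _site(**{"-3": "K"}))

    def test_padding_matches_nothing(self):
        m = parse_motif("R-x-x-S/T")
        padded = "____" + "R__" + "S" + "AAAAAAA"
        assert len(padded) == 15
        assert match_motif(m, padded)  # R present at -3 despite padding
        all_pad_flank = "____" + "___" + "S" + "AAAAAAA"
        assert not match_motif(m, all_pad_flank)  # pad at -3 never matches

    def test_hand_count_over_toy_set(self):
        sites = [
            _site(**{"-3": "R"}),            # match
            _site(**{"-3": "R", "1": "P"}),  # match
            _site(**{"-3": "K"}),            # no
            _site("T", **{"-3": "R"}),       # match
            _site(),                         # no
            _site(**{"3": "R"}),             # no (R at +3, not -3)
        ]
        m = parse_motif("R-x-x-S/T")
        assert sum(match_motif(m, s) for s in sites) == 3


class TestBackground:
    def test_identical_flanks_shuffle_to_themselves(self):
        coll = PhosphoSiteCollection("sp", ["AAAAAAASAAAAAAA"])
        back = generate_background(coll, shuffles_per_site=5, seed=1)
        assert back.sites == ["AAAAAAASAAAAAAA"] * 5

    def test_size_is_ten_per_site(self):
        coll = PhosphoSiteCollection(
            "sp", [_site(**{"-3": "R"}), _site(**{"1": "P"})])
        back = generate_background(coll, seed=0)
        assert len(back) == 20

    def test_flank_multiset_conserved_per_site(self):
        coll = PhosphoSiteCollection("sp", ["ACDEFGHSIKLMNPQ"])
        back = generate_background(coll, shuffles_per_site=10, seed=3)
        for b in back.sites:
            assert b[7] == "S"
            assert sorted(b[:7] + b[8:]) == sorted("ACDEFGHIKLMNPQ")

    def test_deterministic_under_seed(self):
        coll = PhosphoSiteCollection("sp", [_site(**{"-3": "R", "2": "K"})])
        b1 = generate_background(coll, seed=9)
        b2 = generate_background(coll, seed=9)
        assert b1.sites == b2.sites

    def test_pooled_composition_matches_foreground(self):
        spec = PhosphoproteomeSpec(species="sp", n_sites=1000, seed=5)
        coll = simulate_phosphoproteome(spec)
        back = generate_background(coll, seed=6)
        for pos in (-3, 1, 5):
            fg = np.mean([s[7 + pos] == "A" for s in coll.sites])
            bg = np.mean([s[7 + pos] == "A" for s in back.sites])
            # flank composition pooled across positions is exchangeable
            overall = np.mean([c == "A" for s in coll.sites
                               for c in s[:7] + s[8:]])
            assert abs(bg - overall) < 0.01


class TestSupersetBinomial:
    def _collections(self, n_fore_match, n_fore, n_back_match, n_back):
        fore = [_site(**{"-3": "R"})] * n_fore_match + \
            [_site(**{"-3": "D", "5": "CDEFG"[i % 5]}) for i in
             range(n_fore - n_fore_match)]
        back = [_site(**{"-3": "R", "6": "ACDEF"[i % 5]})
                for i in range(n_back_match)] + \
            [_site(**{"-3": "G", "6": "ACDEF"[i % 5]})
             for i in range(n_back - n_back_match)]
        return (PhosphoSiteCollection("sp", fore, unique=False),
                PhosphoSiteCollection("sp", back, unique=False))

    def test_zero_foreground_matches_give_one(self):
        fore, back = self._collections(0, 10, 10, 50)
        res = superset_binomial(parse_motif("R-x-x-S/T"), fore, back)
        assert res.k == 0
        assert res.p_value == 1.0

    def test_exact_tail_arithmetic(self):
        # single-constraint motif: superset is the bare centre, so
        # n = 10 foreground sites, p0 = 10/50 = 0.2, k = 5
        fore, back = self._collections(5, 10, 10, 50)
        res = superset_binomial(parse_motif("R-x-x-S/T"), fore, back)
        assert (res.k, res.n, res.p0) == (5, 10, 0.2)
        assert res.p_value == pytest.approx(
            binomial_upper_tail(5, 10, 0.2), abs=1e-12)
        assert res.p_value == pytest.approx(0.0327934976, abs=1e-9)

    def test_saturated_null_gives_one(self):
        fore, back = self._collections(10, 10, 50, 50)
        res = superset_binomial(parse_motif("R-x-x-S/T"), fore, back)
        assert res.p0 == 1.0
        assert res.p_value == 1.0

    def test_superset_is_most_frequent_single_removal(self):
        # motif R-x-x-S/T-P: removing +1 leaves R-x-x-S/T (rare in back);
        # removing -3 leaves S/T-P (frequent) -> chosen superset
        fore = PhosphoSiteCollection(
            "sp", [_site(**{"-3": "R", "1": "P"})], unique=False)
        back_sites = [_site(**{"1": "P", "4": "ACDEFGHIKL"[i % 10]})
                      for i in range(30)] + [_site(**{"-3": "R"})]
        back = PhosphoSiteCollection("sp", back_sites, unique=False)
        res = superset_binomial(parse_motif("R-x-x-S/T-P"), fore, back)
        assert res.superset.to_string() == "S/T-P"

    def test_untestable_when_superset_unmatched(self):
        fore = PhosphoSiteCollection("sp", [_site(**{"-3": "R"})],
                                     unique=False)
        back = PhosphoSiteCollection("sp", ["_" * 7 + "S" + "_" * 7],
                                     unique=False)
        res = superset_binomial(parse_motif("R-x-x-S/T-P"), fore, back)
        assert not res.testable

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_k_and_p0(self, data):
        n_back = 50
        m1 = data.draw(st.integers(1, n_back - 1))
        m2 = data.draw(st.integers(m1, n_back - 1))
        k1 = data.draw(st.integers(1, 10))
        k2 = data.draw(st.integers(k1, 10))
        motif = parse_motif("R-x-x-S/T")
        # p monotone decreasing in k at fixed p0
        f1, b = self._collections(k1, 10, m1, n_back)
        f2, _ = self._collections(k2, 10, m1, n_back)
        p_k1 = superset_binomial(motif, f1, b).p_value
        p_k2 = superset_binomial(motif, f2, b).p_value
        assert p_k2 <= p_k1 + 1e-12
        # p monotone increasing in p0 at fixed k
        _, b2 = self._collections(k1, 10, m2, n_back)
        p_m2 = superset_binomial(motif, f1, b2).p_value
        assert p_m2 >= p_k1 - 1e-12


class TestDiscovery:
    def test_implanted_motif_recovered(self):
        motif = parse_motif("S/T-P-x-K")
        spec = PhosphoproteomeSpec(species="sp", n_sites=2000,
                                   motif_mixture=[(motif, 0.5)], seed=21)
        coll = simulate_phosphoproteome(spec)
        back = generate_background(coll, seed=22)
        found = discover_motifs(coll, back)
        wanted = set(motif.constraints)
        assert any(wanted <= set(m.constraints) for m in found)

    def test_pure_implant_clean_background(self):
        sites = list({_site(**{"1": "P", "3": "K",
                               "-5": "ACDEFGHIKLMNPQRSTVWY"[i % 20],
                               "5": "ACDEFGHIKLMNPQRSTVWY"[(i * 7) % 20]})
                      for i in range(200)})
        coll = PhosphoSiteCollection("sp", sites)
        back = generate_background(coll, seed=2)
        found = discover_motifs(coll, back)
        assert found, "expected at least one motif"
        top = found[0].as_dict
        assert top.get(1) == frozenset("P")
        assert top.get(3) == frozenset("K")

    def test_min_occurrences_unreachable_emits_nothing(self):
        coll = PhosphoSiteCollection("sp", [_site(**{"1": "P"})])
        back = generate_background(coll, seed=0)
        assert discover_motifs(coll, back, min_occurrences=5) == []

    def test_every_emitted_motif_meets_occurrence_rule(self):
        spec = PhosphoproteomeSpec(
            species="sp", n_sites=1500,
            motif_mixture=[(parse_motif("R-x-x-S/T"), 0.3)], seed=31)
        coll = simulate_phosphoproteome(spec)
        back = generate_background(coll, seed=32)
        from kinevo.motif_analysis import match_mask, site_matrix
        mat = site_matrix(coll.sites)
        for m in discover_motifs(coll, back, min_occurrences=20):
            assert match_mask(m, mat).sum() >= 20


class TestFiltering:
    def test_synonym_merging(self):
        a = parse_motif("R-x-x-S/T")
        b = parse_motif("K-x-x-S/T")
        assert canonical_motif(a) == canonical_motif(b)
        assert canonical_motif(a).to_string() == "R/K-x-x-S/T"

    def test_prevalence_and_discard_rules(self):
        fungi = [f"fungus{i}" for i in range(19)]
        metazoa = [f"animal{i}" for i in range(12)]
        excavates = ["exc0", "exc1", "exc2"]
        clades = {s: "fungi" for s in fungi}
        clades |= {s: "metazoa" for s in metazoa}
        clades |= {s: "excavates" for s in excavates}
        clades |= {"amoeba": "amoebozoa", "hetero": "heterokonts"}

        keep_third = parse_motif("S/T-P-x-K")       # 7 of 19 fungi
        too_rare = parse_motif("S/T-x-x-x-N")       # 5 of 19 fungi
        keep_excavate = parse_motif("G-x-S/T")      # 2 of 3 excavates
        st_addition = parse_motif("S/T-P-x-S")      # classical + S
        ck2_extension = parse_motif("S/T-D-D-D")    # CK2 + D/E additions
        amoeba_only = parse_motif("N-x-S/T")

        per_species = {s: [] for s in clades}
        for s in fungi[:7]:
            per_species[s].append(keep_third)
        for s in fungi[:5]:
            per_species[s].append(too_rare)
        for s in excavates[:2]:
            per_species[s].append(keep_excavate)
        for s in fungi[:10]:
            per_species[s].append(st_addition)
            per_species[s].append(ck2_extension)
        per_species["amoeba"].append(amoeba_only)

        catalog = filter_motifs(per_species, clades)
        retained = {m.to_string() for m in catalog.retained}
        # retained motifs are reported in canonical (synonym-class) form
        assert retained == {"S/T-P-x-R/K", "G-x-S/T"}
        reasons = {e.motif.to_string(): e.discard_reason
                   for e in catalog.entries if e.discard_reason}
        assert "S/T addition" in reasons["S/T-P-x-S"]
        assert "CK2" in reasons[canonical_motif(ck2_extension).to_string()]
        assert "singleton" in reasons["N-x-S/T"]
        assert "prevalence" in reasons["S/T-x-x-x-N"]

    def test_unassigned_species_raises(self):
        with pytest.raises(KeyError, match="mystery"):
            filter_motifs({"mystery": []}, {})


class TestCoverage:
    def test_arithmetic(self):
        sites = [_site(**{"1": "P", "3": "K"})] * 6 + [_site()] * 4
        coll = PhosphoSiteCollection("sp", sites, unique=False)
        cov = phosphoproteome_coverage([parse_motif("S/T-P-x-K")], coll)
        assert cov == pytest.approx(60.0)

    def test_single_constraint_ineligible(self):
        sites = [_site(**{"1": "G"})] * 10
        coll = PhosphoSiteCollection("sp", sites, unique=False)
        cov = phosphoproteome_coverage([parse_motif("G-S/T")], coll)
        assert cov == 0.0

    def test_classical_single_constraint_exceptions(self):
        sites = [_site(**{"1": "P"})] * 5 + [_site(**{"-3": "R"})] * 5
        coll = PhosphoSiteCollection("sp", sites, unique=False)
        cov = phosphoproteome_coverage(
            [parse_motif("S/T-P"), parse_motif("R-x-x-S/T")], coll)
        assert cov == pytest.approx(100.0)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            phosphoproteome_coverage(
                [parse_motif("S/T-P")],
                PhosphoSiteCollection("sp", [], unique=False))
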