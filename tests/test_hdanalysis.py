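"""Coordinate mapping, conservation, consensus, identity, codon reachability."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from hypothesis import given
from hypothesis import strategies as st

from prdlike import hdanalysis
from prdlike.hdanalysis import (
    Alignment,
    CombinationScreen,
    ConservationScheme,
    HomeodomainAnnotation,
    classify_hd_type,
    codon_paths,
    column_conservation,
    combination_screen,
    consensus,
    identity_matrix,
    map_coordinates,
    percent_identity,
    round_half_up,
)

HD = "EKRPRTAFSSEQLARLKREFNENRYLTERRRQQLSSELGLNEAQIKIWFKNKRAKIKKST"


class TestCoordinates:
    """Human LEUTX numbering: homeodomain residue 1 is protein residue 8,
    fixed by the K57A (full-length) to K50A (homeodomain) correspondence."""

    ANN = HomeodomainAnnotation("human_LEUTX", 8, HD)

    def test_k57_is_homeodomain_position_50(self):
        assert map_coordinates(self.ANN, 57, "protein_to_hd") == 50

    def test_a61_is_homeodomain_position_54(self):
        assert map_coordinates(self.ANN, 61, "protein_to_hd") == 54

    def test_round_trip_exact(self):
        assert map_coordinates(self.ANN, 1, "hd_to_protein") == 8
        for hd in (1, 25, 60):
            p = map_coordinates(self.ANN, hd, "hd_to_protein")
            assert map_coordinates(self.ANN, p, "protein_to_hd") == hd

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_coordinates(self.ANN, 7, "protein_to_hd")
        with pytest.raises(ValueError):
            map_coordinates(self.ANN, 61, "hd_to_protein")


class TestHdType:
    def test_k50(self):
        assert classify_hd_type(HomeodomainAnnotation("t", 1, HD)) == "K50"

    def test_n50_like_elephant_paralog(self):
        seq = HD[:49] + "N" + HD[50:]
        assert classify_hd_type(HomeodomainAnnotation("t", 1, seq)) == "N50"

    @pytest.mark.parametrize("r50,expected", [("Q", "Q50"), ("R", "R50"), ("W", "other")])
    def test_other_types(self, r50, expected):
        seq = HD[:49] + r50 + HD[50:]
        assert classify_hd_type(HomeodomainAnnotation("t", 1, seq)) == expected

    def test_gap_at_50_is_other_with_warning(self):
        seq = HD[:49] + "-" + HD[50:]
        with pytest.warns(UserWarning):
            assert classify_hd_type(HomeodomainAnnotation("t", 1, seq)) == "other"


class TestConservation:
    def test_identical_column_is_star(self):
        aln = Alignment([("a", "R"), ("b", "R"), ("c", "R")])
        assert column_conservation(aln) == "*"

    def test_isoleucine_valine_column_is_colon(self):
        # normalized Gonnet PAM250 I-V score: s(I,V)/max(s(I,I), s(V,V))
        g = substitution_matrices.load("GONNET1992")
        expected = g["I", "V"] / max(g["I", "I"], g["V", "V"])
        assert 0.5 < expected < 1.0
        aln = Alignment([("a", "I"), ("b", "V")])
        assert column_conservation(aln) == ":"

    def test_position50_like_mixed_column_not_star(self):
        col = "K" * 5 + "R" + "Q" * 2
        aln = Alignment([(f"t{i}", c) for i, c in enumerate(col)])
        assert column_conservation(aln) != "*"

    def test_gap_column_blank(self):
        aln = Alignment([("a", "R-"), ("b", "RK")])
        assert column_conservation(aln) == "* "

    def test_row_order_invariance(self):
        rows = [("a", "IKWF"), ("b", "VRWY"), ("c", "LKWF")]
        sym = column_conservation(Alignment(rows))
        assert column_conservation(Alignment(rows[::-1])) == sym
        assert column_conservation(Alignment([rows[1], rows[0], rows[2]])) == sym


class TestConsensus:
    def test_unanimous_residue(self):
        aln = Alignment([(f"t{i}", "K") for i in range(10)])
        assert consensus(aln) == "K"

    def test_ninety_percent_boundary(self):
        aln = Alignment([(f"t{i}", "K") for i in range(9)] + [("t9", "R")])
        assert consensus(aln) == "K"  # 9/10 meets the 90% level exactly

    def test_class_symbol_for_aliphatic_split(self):
        aln = Alignment([(f"t{i}", "I") for i in range(5)] + [(f"u{i}", "V") for i in range(5)])
        assert consensus(aln) == "l"  # I+V jointly reach the level: aliphatic

    def test_no_consensus_dot(self):
        aln = Alignment([("a", "K"), ("b", "D"), ("c", "W"), ("d", "G")])
        assert consensus(aln) == "."

    def test_level_one_equals_residue_iff_invariant(self):
        scheme = ConservationScheme(consensus_level=1.0)
        invariant = Alignment([("a", "W"), ("b", "W")])
        assert consensus(invariant, scheme) == "W"
        varied = Alignment([("a", "W"), ("b", "F")])
        assert consensus(varied, scheme) in ("a", ".")  # aromatic class or none


class TestIdentity:
    def test_self_identity_100(self):
        assert percent_identity("ACDEF", "ACDEF") == 100.0

    def test_four_of_five(self):
        assert percent_identity("ACDEF", "ACDEG") == 80.0

    def test_gap_modes(self):
        a, b = "AC-EF", "ACDEF"
        assert percent_identity(a, b, gap_mode="exclude") == 100.0
        assert percent_identity(a, b, gap_mode="mismatch") == pytest.approx(400 / 5)

    def test_double_gap_columns_always_ignored(self):
        assert percent_identity("A-C", "A-C", gap_mode="mismatch") == 100.0

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("--", "AA", gap_mode="exclude")

    def test_half_up_rounding(self):
        assert round_half_up(66.5) == 67
        assert round_half_up(66.49) == 66

    @given(st.integers(0, 2**31 - 1))
    def test_matrix_symmetric_diag100_bounded(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"t{i}", "".join(rng.choice(list("ACDEFGHIKL-"), size=12)))
            for i in range(4)
        ]
        # guarantee at least one comparable column
        rows = [(t, "W" + s) for t, s in rows]
        mat = identity_matrix(Alignment(rows))
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 100.0)
        assert (mat.values >= 0).all() and (mat.values <= 100).all()


def oracle_single_base_paths():
    """Brute force over all 61 sense codons x 9 single-base mutations."""
    fwd = standard_dna_table.forward_table
    paths = {}
    for codon, aa in fwd.items():
        for i, base in enumerate(codon):
            for alt in "ACGT":
                if alt == base:
                    continue
                mut = codon[:i] + alt + codon[i + 1 :]
                if mut not in fwd:
                    continue
                cls = "transition" if {base, alt} in ({"A", "G"}, {"C", "T"}) else "transversion"
                paths.setdefault((aa, fwd[mut]), []).append((codon, mut, i + 1, cls))
    return paths


class TestCodonPaths:
    def test_matches_bruteforce_for_every_amino_acid_pair(self):
        oracle = oracle_single_base_paths()
        aas = sorted(set(standard_dna_table.forward_table.values()))
        for a, b in itertools.product(aas, aas):
            paths, _ = codon_paths(a, b)
            got = sorted((p.codon_from, p.codon_to, p.changed_position, p.substitution_class)
                         for p in paths)
            assert got == sorted(oracle.get((a, b), []))

    def test_transition_transversion_totals(self):
        # summed over all ordered amino-acid pairs, the package's path counts
        # must partition the sense->sense subset of the 61 x 9 single-base
        # mutations exactly as brute force does (each base offers 1 transition
        # and 2 transversions, so the full mutation set splits 183:366)
        fwd = standard_dna_table.forward_table
        oracle_ts = oracle_tv = 0
        full_ts = full_tv = 0
        for codon in fwd:
            for i, base in enumerate(codon):
                for alt in "ACGT":
                    if alt == base:
                        continue
                    is_ts = {base, alt} in ({"A", "G"}, {"C", "T"})
                    full_ts += is_ts
                    full_tv += not is_ts
                    if codon[:i] + alt + codon[i + 1 :] in fwd:
                        oracle_ts += is_ts
                        oracle_tv += not is_ts
        assert (full_ts, full_tv) == (61 * 3, 61 * 6)
        aas = sorted(set(fwd.values()))
        tot_ts = tot_tv = 0
        for a, b in itertools.product(aas, aas):
            _, summary = codon_paths(a, b)
            tot_ts += summary["n_transition"]
            tot_tv += summary["n_transversion"]
        assert (tot_ts, tot_tv) == (oracle_ts, oracle_tv)

    def test_ala_to_val_four_transition_only_paths(self):
        paths, summary = codon_paths("A", "V")
        assert len(paths) == 4
        assert all(p.changed_position == 2 and p.substitution_class == "transition" for p in paths)
        assert summary["reachable_by_transition_only"] is True

    def test_ile_to_thr_reachable_by_transition(self):
        paths, summary = codon_paths("I", "T")
        assert paths and all(p.changed_position == 2 for p in paths)
        assert summary["reachable_by_transition"] is True

    def test_lys_to_ala_unreachable_in_one_step(self):
        paths, summary = codon_paths("K", "A")
        assert paths == []
        assert summary["reachable_by_single_change"] is False

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            codon_paths("*", "A")


class TestCombinationScreen:
    def _ann(self, i, r47, r54):
        seq = HD[:46] + r47 + HD[47:53] + r54 + HD[54:]
        return HomeodomainAnnotation(f"t{i}", 1, seq)

    def test_absent_i47_v54_combination_detected(self):
        anns = (
            [self._ann(i, "I", "A") for i in range(5)]
            + [self._ann(5 + i, "T", "A") for i in range(2)]
            + [self._ann(7 + i, "T", "V") for i in range(6)]
        )
        screen = combination_screen(anns)
        assert screen.contingency == {("I", "A"): 5, ("T", "A"): 2, ("T", "V"): 6}
        assert ("I", "V") in screen.absent_pairs

    def test_single_taxon_one_cell_no_absent(self):
        screen = combination_screen([self._ann(0, "I", "A")])
        assert screen.contingency == {("I", "A"): 1}
        assert screen.absent_pairs == []

    def test_all_identical(self):
        screen = combination_screen([self._ann(i, "T", "V") for i in range(7)])
        assert screen.contingency == {("T", "V"): 7}
        assert sum(screen.contingency.values()) == 7
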