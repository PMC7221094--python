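"""Conservation scoring, ancestral consensus, and signature detection."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from tbpsig import (
    AlignmentSpec,
    AncestralSet,
    ancestral_consensus,
    ancestral_set_by_superkingdom,
    column_nbs,
    conservation_fraction,
    lobe_specific_signatures,
    modal_residue,
    normalized_pair_score,
    profile_stats,
    simulate_alignment,
    universal_signatures,
)
from tbpsig.errors import (
    AlignmentShapeError,
    ContextError,
    DegenerateProfileError,
    InsufficientDepthError,
)
from tbpsig.msa import AMINO_ACIDS

from conftest import make_alignment

# Independent oracle path: Biopython's own BLOSUM62 array, looked up directly.
_B62 = substitution_matrices.load("BLOSUM62")


def oracle_pair(a: str, b: str) -> float | None:
    if a in "-X" or b in "-X":
        return None
    return _B62[a, b] / max(_B62[a, a], _B62[b, b])


def oracle_column_nbs(column: str) -> float | None:
    """Brute-force double loop over all unordered pairs."""
    scores = [
        oracle_pair(a, b) for a, b in itertools.combinations(column, 2)
    ]
    scores = [s for s in scores if s is not None]
    k = sum(1 for ch in column if ch not in "-X")
    if k < 2 or k < 0.5 * len(column):
        return None
    return sum(scores) / len(scores)


class TestNormalizedPairScore:
    def test_identical_residue_scores_one(self):
        assert normalized_pair_score("W", "W") == 1.0

    def test_glu_asp_is_one_third(self):
        assert normalized_pair_score("E", "D") == pytest.approx(2 / 6)

    @pytest.mark.parametrize("pair", [("A", "-"), ("-", "A"), ("X", "W"), ("-", "-")])
    def test_gap_and_unknown_unscorable(self, pair):
        assert normalized_pair_score(*pair) is None

    def test_all_pairs_within_unit_interval(self):
        for a, b in itertools.combinations_with_replacement(AMINO_ACIDS, 2):
            v = normalized_pair_score(a, b)
            assert -1 <= v <= 1
            assert (v == 1.0) == (a == b)  # BLOSUM62 diagonal dominance


class TestColumnNBS:
    def test_identical_column(self):
        assert column_nbs("FFF") == 1.0

    def test_mixed_column_matches_enumeration(self):
        # pairs (E,E)=1, (E,D)=1/3, (E,D)=1/3
        assert column_nbs("EED") == pytest.approx((1 + 1 / 3 + 1 / 3) / 3)

    def test_gap_excluded_and_pairs_renormalised(self):
        assert column_nbs("E-D") == pytest.approx(1 / 3)

    def test_mostly_gapped_column_unscorable(self):
        assert column_nbs("E---D") is None
        assert column_nbs("---") is None

    def test_single_residue_depth_error(self):
        with pytest.raises(InsufficientDepthError):
            column_nbs("E")

    @settings(max_examples=80, deadline=None)
    @given(st.text(alphabet=AMINO_ACIDS + "-X", min_size=2, max_size=30))
    def test_matches_brute_force_oracle(self, column):
        expected = oracle_column_nbs(column)
        got = column_nbs(column)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)
            assert -1 <= got <= 1


class TestProfileStats:
    def test_fully_conserved_alignment(self):
        aln = make_alignment(["MKVD", "MKVD", "MKVD"])
        prof = profile_stats(aln)
        assert prof.mean_nbs == 1.0 and prof.sd_nbs == 0.0
        assert prof.n_scorable == 4

    def test_matches_hand_computation_on_toy_columns(self):
        aln = make_alignment(["MEFA", "MEYA", "MDFC"])
        prof = profile_stats(aln)
        expected = [oracle_column_nbs(aln.column(j)) for j in range(4)]
        np.testing.assert_allclose(prof.per_column, expected)
        assert prof.mean_nbs == pytest.approx(np.mean(expected))
        assert prof.sd_nbs == pytest.approx(np.std(expected))

    def test_all_gap_column_excluded_from_stats(self):
        aln = make_alignment(["M-D", "M-D", "M-D"])
        prof = profile_stats(aln)
        assert math.isnan(prof.per_column[1])
        assert prof.n_scorable == 2 and prof.mean_nbs == 1.0

    def test_degenerate_profile_raises(self):
        aln = make_alignment(["--", "--"])
        with pytest.raises(DegenerateProfileError):
            profile_stats(aln)

    def test_mean_of_column_subset(self):
        aln = make_alignment(["MEFA", "MEYA", "MDFC"])
        prof = profile_stats(aln)
        expected = np.mean([prof.per_column[0], prof.per_column[2]])
        assert prof.mean_of([0, 2]) == pytest.approx(expected)


class TestAncestralConsensus:
    def test_majority_residue(self):
        assert ancestral_consensus(make_alignment(["E", "E", "D"])) == "E"

    def test_tie_breaks_lexicographically(self):
        assert ancestral_consensus(make_alignment(["E", "D"])) == "D"

    def test_gap_majority_gives_gap(self):
        assert ancestral_consensus(make_alignment(["-", "-", "K"])) == "-"

    def test_import_validates_length(self):
        aln = make_alignment(["MKV", "MKV"])
        assert ancestral_consensus(aln, method="import", imported="MK-") == "MK-"
        with pytest.raises(AlignmentShapeError):
            ancestral_consensus(aln, method="import", imported="MKVD")

    def test_per_superkingdom_reconstruction(self):
        aln = make_alignment(
            [("EK", "o1", "archaea", "single"), ("EK", "o2", "archaea", "single"),
             ("DK", "o3", "bacteria", "single"), ("DR", "o4", "bacteria", "single"),
             ("EK", "o5", "eukaryote", "single"), ("ER", "o6", "eukaryote", "single")]
        )
        anc = ancestral_set_by_superkingdom(aln)
        assert anc.sequences == {"archaea": "EK", "bacteria": "DK", "eukaryote": "EK"}


class TestUniversalSignatures:
    def test_uniform_toy_profile_flags_nothing(self):
        # four identical columns (NBS 1) and one (A,A,V): NBS = (1+0+0)/3.
        anc = AncestralSet(
            sequences={"archaea": "AAAAA", "bacteria": "AAAAA", "eukaryote": "AAAAV"},
            method="consensus",
        )
        values = [1.0, 1.0, 1.0, 1.0, (1 + 0 + 0) / 3]
        threshold = np.mean(values) + np.std(values)
        assert 1.0 <= threshold  # hence nothing can strictly exceed it
        assert universal_signatures(anc).universal == frozenset()

    def test_identical_ancestors_flag_nothing(self):
        anc = AncestralSet(
            sequences={"archaea": "MKVD", "bacteria": "MKVD", "eukaryote": "MKVD"},
            method="consensus",
        )
        assert universal_signatures(anc).universal == frozenset()

    def test_single_hyperconserved_column_flagged(self):
        # column 2 identical across ancestors; the rest mutually dissimilar
        anc = AncestralSet(
            sequences={"archaea": "EKWGP", "bacteria": "GPWKE", "eukaryote": "KGWPD"},
            method="consensus",
        )
        assert universal_signatures(anc).universal == frozenset({2})

    def test_requires_exactly_three_ancestors(self):
        anc = AncestralSet(sequences={"archaea": "MK", "bacteria": "MK"}, method="c")
        with pytest.raises(ContextError):
            universal_signatures(anc)

    def test_planted_recovery_through_full_pipeline(self):
        planted = [3, 11, 27]
        theta = np.where(np.isin(np.arange(40), planted), 0.0, 0.8)
        div = np.where(np.isin(np.arange(40), planted), 0.0, 1.0)
        spec = AlignmentSpec(
            n_seqs={"archaea": 100, "bacteria": 100, "eukaryote": 100},
            n_columns=40, theta=theta, lineage_divergence=div, seed=5,
        )
        anc = ancestral_set_by_superkingdom(simulate_alignment(spec))
        assert sorted(universal_signatures(anc).universal) == planted


class TestLobeSpecificSignatures:
    def _pair(self, c_rows, n_rows):
        return (make_alignment(c_rows, lobe="C"), make_alignment(n_rows, lobe="N"))

    def test_ratio_rule(self):
        # column 0: C conserved (NBS 1), N diverged; column 1 diverged in both
        c_aln, n_aln = self._pair(["EG", "EK", "EG", "EP"], ["KG", "GP", "PE", "EK"])
        sigs = lobe_specific_signatures(c_aln, n_aln)
        c_flags = {(s.column, s.rule_tag) for s in sigs.lobe_specific if s.lobe == "C"}
        assert (0, "ratio") in c_flags

    def test_residue_switch_rule(self):
        # both lobes fully conserved at column 0 but as E vs K; ratio 1 < 1.5
        c_aln, n_aln = self._pair(["EG", "EK", "ED"], ["KG", "KD", "KW"])
        sigs = lobe_specific_signatures(c_aln, n_aln)
        c_flags = {(s.column, s.rule_tag) for s in sigs.lobe_specific if s.lobe == "C"}
        n_flags = {(s.column, s.rule_tag) for s in sigs.lobe_specific if s.lobe == "N"}
        assert (0, "residue-switch") in c_flags
        assert (0, "residue-switch") in n_flags

    def test_below_mean_column_never_flagged(self):
        # column 1 is the diverged one in the C lobe: below the C mean
        c_aln, n_aln = self._pair(["EG", "EK", "EP"], ["EE", "EE", "EE"])
        sigs = lobe_specific_signatures(c_aln, n_aln)
        assert all(s.column != 1 for s in sigs.lobe_specific if s.lobe == "C")

    def test_shared_modal_residue_is_not_a_switch(self):
        # column 0 conserved as E in both lobes: ratio fails, modal equal
        c_aln, n_aln = self._pair(["EG", "EK", "ED"], ["EG", "ED", "EW"])
        sigs = lobe_specific_signatures(c_aln, n_aln)
        assert all(s.column != 0 for s in sigs.lobe_specific)

    def test_width_mismatch_raises(self):
        with pytest.raises(AlignmentShapeError):
            lobe_specific_signatures(
                make_alignment(["EG"]), make_alignment(["EGA"])
            )

    def test_huge_ratio_reduces_to_residue_switch_rule(self):
        c_aln, n_aln = self._pair(["EG", "EK", "ED"], ["KG", "KD", "KW"])
        sigs = lobe_specific_signatures(c_aln, n_aln, ratio=1e9)
        tags = {s.rule_tag for s in sigs.lobe_specific}
        assert tags <= {"residue-switch"}

    def test_invariant_under_sequence_reordering(self):
        rng = np.random.default_rng(0)
        spec_c = AlignmentSpec(n_seqs={"eukaryote": 10}, n_columns=12, theta=0.4, seed=1, lobe="C")
        spec_n = AlignmentSpec(n_seqs={"eukaryote": 10}, n_columns=12, theta=0.4, seed=2, lobe="N")
        c_aln, n_aln = simulate_alignment(spec_c), simulate_alignment(spec_n)
        shuffled = make_alignment(
            [(s.residues, s.organism, s.superkingdom, s.lobe)
             for s in rng.permutation(np.array(c_aln.sequences, dtype=object))]
        )
        a = lobe_specific_signatures(c_aln, n_aln)
        b = lobe_specific_signatures(shuffled, n_aln)
        assert {(s.column, s.lobe, s.rule_tag) for s in a.lobe_specific} == \
               {(s.column, s.lobe, s.rule_tag) for s in b.lobe_specific}

    def test_planted_recovery(self):
        planted = [1, 7, 20]
        theta = np.where(np.isin(np.arange(30), planted), 0.0, 0.8)
        c_aln = simulate_alignment(
            AlignmentSpec(n_seqs={"eukaryote": 100}, n_columns=30, theta=theta, seed=3, lobe="C"))
        n_aln = simulate_alignment(
            AlignmentSpec(n_seqs={"eukaryote": 100}, n_columns=30, theta=0.8, seed=4, lobe="N"))
        sigs = lobe_specific_signatures(c_aln, n_aln)
        assert sorted(s.column for s in sigs.lobe_specific if s.lobe == "C") == planted


class TestConservationFraction:
    def test_ninety_percent_phe(self):
        assert conservation_fraction("F" * 9 + "Y", "F") == pytest.approx(0.9)

    def test_all_gap_column(self):
        assert conservation_fraction("---", "F") == 0.0

    def test_gaps_count_in_denominator(self):
        assert conservation_fraction("FF-F", "F") == pytest.approx(0.75)


def test_modal_residue_tie_break():
    assert modal_residue("EDED") == ("D", frozenset({"D", "E"}))
    assert modal_residue("---") == (None, frozenset())
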