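"""Substitution-similarity vectors, Pearson PC, and the permutation null."""

import itertools
import logging

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tbpsig import (
    AlignmentSpec,
    CouplingSpec,
    bh_adjust,
    coevolution_scan,
    pair_alignments,
    pearson_pc,
    permutation_pvalue,
    simulate_coevolving_pair,
    substitution_vector,
)
from tbpsig.errors import (
    InsufficientPairsError,
    ParameterError,
    TargetColumnError,
    UndefinedCorrelationError,
)

from conftest import make_alignment

_B62 = substitution_matrices.load("BLOSUM62")


def _aln(rows_with_orgs, lobe="single", sk="virus"):
    return make_alignment(
        [(res, org, sk, lobe) for res, org in rows_with_orgs]
    )


class TestPairing:
    def test_all_organisms_shared(self):
        a = _aln([("MK", f"v{i}") for i in range(4)])
        b = _aln([("DE", f"v{i}") for i in range(4)])
        pa = pair_alignments(a, b)
        assert pa.n_pairs == 4
        assert pa.pairing == tuple(sorted(pa.pairing))

    def test_unpaired_sequences_dropped_with_warning(self, caplog):
        a = _aln([("MK", f"v{i}") for i in range(5)])
        b = _aln([("DE", f"v{i}") for i in range(4)])
        with caplog.at_level(logging.WARNING):
            pa = pair_alignments(a, b)
        assert pa.n_pairs == 4
        assert sum("dropped" in r.message for r in caplog.records) == 1

    def test_too_few_shared_organisms(self):
        a = _aln([("MK", "v1"), ("MK", "v2"), ("MK", "v5")])
        b = _aln([("DE", "v1"), ("DE", "v2"), ("DE", "v9")])
        with pytest.raises(InsufficientPairsError):
            pair_alignments(a, b)

    def test_paired_columns_follow_organism_order(self):
        a = _aln([("AK", "v2"), ("CK", "v1")])
        b = _aln([("GD", "v1"), ("TD", "v2"), ("WW", "v3")])
        a = _aln([("AK", "v2"), ("CK", "v1"), ("EK", "v3")])
        pa = pair_alignments(a, b)
        assert pa.column_a(0) == "CAE"  # v1, v2, v3
        assert pa.column_b(0) == "GTW"


class TestSubstitutionVector:
    def test_identical_triplet(self):
        np.testing.assert_array_equal(substitution_vector("AAA"), [1.0, 1.0, 1.0])

    def test_length_is_n_choose_2(self):
        assert substitution_vector("AAAAA").size == 10

    def test_matches_published_matrix_lookups(self):
        got = substitution_vector("EDKQ")
        expected = [
            _B62[a, b] / max(_B62[a, a], _B62[b, b])
            for a, b in itertools.combinations("EDKQ", 2)
        ]
        np.testing.assert_allclose(got, expected)

    def test_gap_entries_missing(self):
        v = substitution_vector("A-C")
        assert np.isnan(v[0]) and np.isnan(v[2]) and np.isfinite(v[1])


class TestPearsonPC:
    def test_self_correlation(self):
        v = substitution_vector("EDKQ")
        assert pearson_pc(v, v) == pytest.approx(1.0)

    def test_antisymmetry(self):
        v = substitution_vector("EDKQ")
        assert pearson_pc(v, -v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([0.1, -0.3, 0.5, 0.2, -0.1, 0.9])
        y = np.array([0.2, -0.1, 0.4, 0.0, 0.1, 0.7])
        assert pearson_pc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_symmetric_and_affine_invariant(self):
        x = np.array([0.1, -0.3, 0.5, 0.2])
        y = np.array([0.4, 0.0, 0.3, -0.2])
        assert pearson_pc(x, y) == pytest.approx(pearson_pc(y, x))
        assert pearson_pc(2 * x + 1, 2 * y + 1) == pytest.approx(pearson_pc(x, y))

    def test_missing_entries_dropped_pairwise(self):
        x = np.array([0.1, np.nan, 0.5, 0.2, -0.4])
        y = np.array([0.2, 0.3, np.nan, 0.0, -0.5])
        keep = [0, 3, 4]
        assert pearson_pc(x, y) == pytest.approx(
            np.corrcoef(x[keep], y[keep])[0, 1]
        )

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_pc(np.ones(6), np.arange(6.0))

    def test_too_few_joint_entries_raises(self):
        x = np.array([0.1, np.nan, np.nan, 0.4])
        y = np.array([0.2, 0.3, 0.4, 0.1])
        with pytest.raises(UndefinedCorrelationError):
            pearson_pc(x, y)


class TestPermutationTest:
    def test_identical_distinct_columns_give_pc_one_and_small_p(self):
        col = "ACDEFGHI"  # 8 distinct residues
        res = permutation_pvalue(col, col, n_perm=1000, seed=11)
        assert res.pc == pytest.approx(1.0)
        assert res.count_ge <= 5  # only near-identity permutations tie
        assert res.format_p().startswith("<") or res.p_value <= 0.005

    def test_constant_column_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            permutation_pvalue("AAAA", "ACDE", n_perm=10, seed=0)

    def test_invalid_n_perm(self):
        with pytest.raises(ParameterError):
            permutation_pvalue("ACDE", "ACDE", n_perm=0, seed=0)

    def test_seeded_reproducibility(self):
        a = permutation_pvalue("ACDEFG", "ACDEFH", n_perm=500, seed=42)
        b = permutation_pvalue("ACDEFG", "ACDEFH", n_perm=500, seed=42)
        assert a == b
        c = permutation_pvalue("ACDEFG", "ACDEFH", n_perm=500, seed=43)
        assert c.pc == a.pc  # observed statistic independent of the seed

    def test_pc_invariant_under_joint_sequence_reordering(self):
        a, b = "ACDEFG", "MKWYTS"
        perm = [3, 1, 5, 0, 2, 4]
        ra = permutation_pvalue(a, b, n_perm=10, seed=0)
        rb = permutation_pvalue(
            "".join(a[i] for i in perm), "".join(b[i] for i in perm),
            n_perm=10, seed=0,
        )
        assert ra.pc == pytest.approx(rb.pc)

    def test_plus_one_estimator(self):
        res = permutation_pvalue("ACDEFGHI", "ACDEFGHI", n_perm=100, seed=1,
                                 plus_one=True)
        assert res.count_ge >= 1 and res.n_perm == 101
        assert res.p_value > 0

    def test_gapped_columns_use_joint_valid_entries(self):
        res = permutation_pvalue("ACDEF-", "MKW-TS", n_perm=50, seed=2)
        # pairs touching a gap in either column are excluded
        assert res.n_pairs_used == 6


class TestScan:
    def _coupled_pair(self, seed=0, kappa=1.0):
        spec_a = AlignmentSpec(n_seqs={"virus": 16}, n_columns=6, theta=0.5, seed=seed)
        spec_b = AlignmentSpec(n_seqs={"virus": 16}, n_columns=6, theta=0.5,
                               seed=seed + 10_000)
        return simulate_coevolving_pair(
            spec_a, spec_b, CouplingSpec(pairs=((1, 4, kappa),))
        )

    def test_one_result_per_partner_column(self):
        pa = self._coupled_pair()
        results = coevolution_scan(pa, target_col=1, n_perm=20, seed=0)
        assert len(results) == pa.family_b.n_columns

    def test_planted_coupling_ranks_first_by_pc(self):
        pa = self._coupled_pair(seed=3)
        results = coevolution_scan(pa, target_col=1, n_perm=20, seed=0)
        pcs = [(-np.inf if r is None else r.pc) for r in results]
        assert int(np.argmax(pcs)) == 4

    def test_scan_against_own_alignment_has_self_pc_one(self):
        pa = self._coupled_pair(seed=5)
        self_pa = type(pa)(
            family_a=pa.family_a, family_b=pa.family_a,
            pairing=tuple((a, a) for a, _ in pa.pairing),
        )
        results = coevolution_scan(self_pa, target_col=2, n_perm=10, seed=0)
        assert results[2].pc == pytest.approx(1.0)

    def test_unscorable_target_raises(self):
        rows = [("A" + "ACDEFG"[i], f"v{i}") for i in range(6)]
        a = _aln(rows)
        pa = pair_alignments(a, a)
        with pytest.raises(TargetColumnError):
            coevolution_scan(pa, target_col=0, n_perm=10, seed=0)


def test_bh_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), expected)
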