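"""Determinism and limiting behaviour of the synthetic-data generators."""

import numpy as np
import pytest

from tbpsig import (
    AlignmentSpec,
    CouplingSpec,
    Region,
    VariantSpec,
    column_nbs,
    pearson_pc,
    profile_stats,
    simulate_alignment,
    simulate_coevolving_pair,
    simulate_variant_table,
    substitution_vector,
    write_lobe_alignment,
)
from tbpsig.errors import ParameterError
from tbpsig.matrices import blosum62
from tbpsig.msa import AMINO_ACIDS


class TestAlignmentGenerator:
    def test_theta_zero_is_perfectly_conserved(self):
        spec = AlignmentSpec(n_seqs={"eukaryote": 6}, n_columns=8, theta=0.0, seed=1)
        aln = simulate_alignment(spec)
        for j in range(8):
            assert len(set(aln.column(j))) == 1
            assert column_nbs(aln.column(j)) == 1.0

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        spec = AlignmentSpec(n_seqs={"virus": 5}, n_columns=10, theta=0.6, seed=9)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_lobe_alignment(simulate_alignment(spec), p1)
        write_lobe_alignment(simulate_alignment(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        spec = AlignmentSpec(n_seqs={"virus": 5}, n_columns=10, theta=0.6, seed=9)
        other = AlignmentSpec(n_seqs={"virus": 5}, n_columns=10, theta=0.6, seed=10)
        assert simulate_alignment(spec) != simulate_alignment(other)

    def test_metadata_assigned_per_spec(self):
        spec = AlignmentSpec(n_seqs={"archaea": 2, "virus": 3}, n_columns=4,
                             theta=0.5, lobe="C", seed=0)
        aln = simulate_alignment(spec)
        sks = [s.superkingdom for s in aln]
        assert sks.count("archaea") == 2 and sks.count("virus") == 3
        assert all(s.lobe == "C" for s in aln)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            simulate_alignment(AlignmentSpec(n_seqs={"virus": 1}, n_columns=5))
        with pytest.raises(ParameterError):
            simulate_alignment(
                AlignmentSpec(n_seqs={"virus": 3}, n_columns=5, theta=1.5)
            )

    def test_high_theta_matches_background_pair_score(self):
        # theta=1, uniform background: residues are iid uniform over the 19
        # non-ancestral residues; the expected column NBS is the mean
        # normalised score over that pair distribution.
        spec = AlignmentSpec(n_seqs={"eukaryote": 400}, n_columns=30,
                             theta=1.0, seed=4)
        prof = profile_stats(simulate_alignment(spec))
        table = blosum62().normalized_table
        expectations = []
        for anc in range(20):
            others = [i for i in range(20) if i != anc]
            expectations.append(np.mean([table[a, b] for a in others for b in others]))
        expected = np.mean(expectations)
        assert prof.mean_nbs == pytest.approx(expected, abs=0.03)

    def test_lineage_divergence_separates_superkingdoms(self):
        spec = AlignmentSpec(
            n_seqs={"archaea": 4, "bacteria": 4, "eukaryote": 4},
            n_columns=12, theta=0.0, lineage_divergence=1.0, seed=2,
        )
        aln = simulate_alignment(spec)
        table = blosum62().normalized_table
        for j in range(12):
            by_sk = {}
            for s in aln:
                by_sk.setdefault(s.superkingdom, set()).add(s.residues[j])
            residues = [next(iter(v)) for v in by_sk.values()]
            assert all(len(v) == 1 for v in by_sk.values())  # theta=0 within
            assert len(set(residues)) == 3  # mutually distinct ancestors
            for a in residues:
                for b in residues:
                    if a != b:
                        ia, ib = AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)
                        assert table[ia, ib] <= 0.3  # non-conservative


class TestCoevolvingPair:
    def test_kappa_one_couples_substitution_patterns(self):
        wins = 0
        for seed in range(20):
            pa = simulate_coevolving_pair(
                AlignmentSpec(n_seqs={"virus": 16}, n_columns=6, theta=0.5, seed=seed),
                AlignmentSpec(n_seqs={"virus": 16}, n_columns=6, theta=0.5,
                              seed=seed + 5_000),
                CouplingSpec(pairs=((0, 3, 1.0),)),
            )
            target = substitution_vector(pa.column_a(0))
            pcs = []
            for j in range(6):
                try:
                    pcs.append(pearson_pc(target, substitution_vector(pa.column_b(j))))
                except Exception:
                    pcs.append(-np.inf)
            wins += int(max(range(6), key=lambda j: pcs[j]) == 3)
        assert wins >= 19

    def test_median_pc_monotone_in_coupling(self):
        def median_pc(kappa):
            values = []
            for seed in range(20):
                pa = simulate_coevolving_pair(
                    AlignmentSpec(n_seqs={"virus": 14}, n_columns=2, theta=0.5, seed=seed),
                    AlignmentSpec(n_seqs={"virus": 14}, n_columns=2, theta=0.5,
                                  seed=seed + 7_000),
                    CouplingSpec(pairs=((0, 0, kappa),)),
                )
                try:
                    values.append(pearson_pc(
                        substitution_vector(pa.column_a(0)),
                        substitution_vector(pa.column_b(0)),
                    ))
                except Exception:
                    pass
            return np.median(values)

        medians = [median_pc(k) for k in (0.0, 0.5, 1.0)]
        assert medians[0] <= medians[1] <= medians[2]
        assert medians[2] > 0.5

    def test_seed_determinism(self):
        args = (
            AlignmentSpec(n_seqs={"virus": 6}, n_columns=4, theta=0.5, seed=3),
            AlignmentSpec(n_seqs={"virus": 6}, n_columns=4, theta=0.5, seed=8),
            CouplingSpec(pairs=((1, 2, 0.7),)),
        )
        assert simulate_coevolving_pair(*args) == simulate_coevolving_pair(*args)

    def test_mismatched_rosters_rejected(self):
        with pytest.raises(ParameterError):
            simulate_coevolving_pair(
                AlignmentSpec(n_seqs={"virus": 5}, n_columns=4),
                AlignmentSpec(n_seqs={"virus": 6}, n_columns=4),
            )

    def test_out_of_range_coupling_rejected(self):
        with pytest.raises(ParameterError):
            simulate_coevolving_pair(
                AlignmentSpec(n_seqs={"virus": 5}, n_columns=4),
                AlignmentSpec(n_seqs={"virus": 5}, n_columns=4),
                CouplingSpec(pairs=((1, 9, 0.5),)),
            )


class TestVariantGenerator:
    def _spec(self, seed=0, rates=None):
        regions = (Region("hot", 1, 100), Region("cold", 101, 200))
        return VariantSpec(
            protein="TBP", protein_length=200, regions=regions,
            rates=rates or {"hot": {"natural": 0.5, "cancer": 2.0},
                            "cold": {"natural": 0.5, "cancer": 0.5}},
            seed=seed,
        )

    def test_zero_rates_give_empty_table(self):
        spec = self._spec(rates={"hot": {"natural": 0.0, "cancer": 0.0}})
        assert simulate_variant_table(spec) == []

    def test_seed_determinism(self):
        assert simulate_variant_table(self._spec(3)) == simulate_variant_table(self._spec(3))

    def test_positions_respect_region_bounds(self):
        records = simulate_variant_table(self._spec(1))
        hot = [r for r in records if r.position <= 100]
        cold = [r for r in records if r.position > 100]
        assert hot and cold
        assert all(1 <= r.position <= 200 for r in records)

    def test_region_beyond_protein_rejected(self):
        with pytest.raises(ParameterError):
            VariantSpec(
                protein="TBP", protein_length=50,
                regions=(Region("r", 1, 100),), rates={}, seed=0,
            ).validate()
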