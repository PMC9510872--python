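import numpy as np
import pytest

from anchorfill.satellite import (
    CEN180_CONSENSUS,
    SatelliteConsensus,
    build_monomer_alignment,
    cluster_monomers,
    find_monomers,
    identity_heatmap,
)
from anchorfill.seqio import Sequence, reverse_complement


def _mutate_positions(seq, positions):
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


@pytest.fixture(scope="module")
def cen180():
    return SatelliteConsensus.cen180()


class TestFindMonomers:
    def test_single_embedded_consensus(self, cen180, make_dna):
        genome = Sequence(
            "g", make_dna(500, seed=1) + CEN180_CONSENSUS + make_dna(500, seed=2)
        )
        monomers = find_monomers([genome], cen180)
        assert len(monomers) == 1
        assert monomers[0].length == 178
        assert monomers[0].identity_to_consensus == 1.0

    def test_mutated_tandem_array_fully_recovered(self, cen180, make_dna):
        rng = np.random.default_rng(3)
        copies = [
            _mutate_positions(
                CEN180_CONSENSUS, rng.choice(178, size=3, replace=False)
            )
            for _ in range(100)
        ]
        genome = Sequence(
            "g", make_dna(400, seed=4) + "".join(copies) + make_dna(400, seed=5)
        )
        monomers = find_monomers([genome], cen180)
        assert len(monomers) == 100
        assert all(165 <= m.length <= 185 for m in monomers)

    def test_pure_array_tiles_without_gaps(self, cen180, make_dna):
        genome = Sequence(
            "g", make_dna(300, seed=6) + CEN180_CONSENSUS * 50 + make_dna(300, seed=7)
        )
        monomers = find_monomers([genome], cen180)
        assert len(monomers) == 50
        for a, b in zip(monomers, monomers[1:]):
            assert b.locus.start - a.locus.end <= 2

    def test_truncated_copy_excluded_by_coverage(self, cen180, make_dna):
        truncated = CEN180_CONSENSUS[: int(0.8 * 178)]
        genome = Sequence(
            "g", make_dna(500, seed=8) + truncated + make_dna(500, seed=9)
        )
        assert find_monomers([genome], cen180) == []

    def test_strand_invariance(self, cen180, make_dna):
        genome = Sequence(
            "g", make_dna(400, seed=10) + CEN180_CONSENSUS * 5 + make_dna(400, seed=11)
        )
        fwd = find_monomers([genome], cen180)
        rc = find_monomers([Sequence("g", reverse_complement(genome.seq))], cen180)
        assert len(fwd) == len(rc)
        L = len(genome.seq)
        mirrored = sorted((L - m.locus.end, L - m.locus.start) for m in rc)
        assert mirrored == [(m.locus.start, m.locus.end) for m in fwd]
        assert all(m.strand == "-" for m in rc)
        # consensus-oriented sequences are identical either way
        assert sorted(m.sequence for m in fwd) == sorted(m.sequence for m in rc)


class TestMonomerAlignment:
    def test_identical_monomers_ungapped(self, cen180, make_dna):
        genome = Sequence("g", make_dna(300, seed=12) + CEN180_CONSENSUS * 4)
        monomers = find_monomers([genome], cen180)
        matrix = build_monomer_alignment(monomers, cen180)
        assert matrix.n_columns == 178
        assert all(row == CEN180_CONSENSUS for row in matrix.rows)

    def test_deletion_produces_gap_columns(self, cen180, make_dna):
        deleted = CEN180_CONSENSUS[:60] + CEN180_CONSENSUS[62:]
        genome = Sequence(
            "g",
            make_dna(300, seed=13)
            + CEN180_CONSENSUS
            + deleted
            + CEN180_CONSENSUS
            + make_dna(300, seed=14),
        )
        monomers = find_monomers([genome], cen180)
        matrix = build_monomer_alignment(monomers, cen180)
        gapped = [r for r in matrix.rows if "-" in r]
        assert len(gapped) == 1
        assert gapped[0].count("-") == 2
        assert gapped[0].replace("-", "") == deleted

    def test_planted_column_variants_recovered(self, cen180, make_dna):
        sites = [10, 50, 120]
        variant = _mutate_positions(CEN180_CONSENSUS, sites)
        genome = Sequence(
            "g", make_dna(300, seed=15) + variant * 3 + CEN180_CONSENSUS * 3
        )
        monomers = find_monomers([genome], cen180)
        matrix = build_monomer_alignment(monomers, cen180)
        for row in matrix.rows[:3]:
            for s in sites:
                assert row[s] == variant[s] != CEN180_CONSENSUS[s]

    def test_row_degap_reproduces_monomer(self, cen180, default_bundle):
        monomers = find_monomers([default_bundle.truth_genome], cen180)[:50]
        matrix = build_monomer_alignment(monomers, cen180)
        def is_subsequence(sub, full):
            it = iter(full)
            return all(c in it for c in sub)

        for row, m in zip(matrix.rows, matrix.monomers):
            # gap removal recovers the monomer minus collapsed insertions
            degapped = row.replace("-", "")
            assert is_subsequence(degapped, m.sequence)
            assert len(degapped) >= len(m.sequence) - 10


class TestClustering:
    def _two_cluster_matrix(self, cen180, n_per=100, seed=16):
        rng = np.random.default_rng(seed)
        sites = rng.choice(178, size=20, replace=False)
        va = _mutate_positions(CEN180_CONSENSUS, sites[:10])
        vb = _mutate_positions(CEN180_CONSENSUS, sites[10:])
        copies = []
        for v in (va, vb):
            for _ in range(n_per):
                noise = rng.choice(178, size=rng.integers(0, 3), replace=False)
                copies.append(_mutate_positions(v, noise))
        genome = Sequence("g", "ACGT" * 100 + "".join(copies) + "ACGT" * 100)
        monomers = find_monomers([genome], cen180)
        return build_monomer_alignment(monomers, cen180), n_per

    def test_two_planted_clusters_recovered(self, cen180):
        matrix, n_per = self._two_cluster_matrix(cen180)
        result = cluster_monomers(matrix, seed=17)
        assert result.k_star == 2
        labels = result.labels
        truth = np.array([0] * n_per + [1] * n_per)[: len(labels)]
        agreement = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agreement >= 0.99

    def test_same_seed_reproducible(self, cen180):
        matrix, _ = self._two_cluster_matrix(cen180)
        a = cluster_monomers(matrix, seed=18)
        b = cluster_monomers(matrix, seed=18)
        assert a.k_star == b.k_star
        assert np.array_equal(a.labels, b.labels)
        assert a.bic == b.bic

    def test_row_permutation_changes_only_labeling(self, cen180):
        matrix, _ = self._two_cluster_matrix(cen180, n_per=50)
        rng = np.random.default_rng(19)
        perm = rng.permutation(len(matrix.rows))
        import copy

        permuted = copy.copy(matrix)
        permuted.rows = [matrix.rows[i] for i in perm]
        permuted.monomers = [matrix.monomers[i] for i in perm]
        a = cluster_monomers(matrix, seed=20)
        b = cluster_monomers(permuted, seed=20)
        assert a.k_star == b.k_star
        # partition equality up to relabeling
        from collections import Counter

        pairs = Counter(zip(a.labels[perm].tolist(), b.labels.tolist()))
        assert len(pairs) == a.k_star

    def test_identical_rows_degenerate(self, cen180, make_dna):
        genome = Sequence("g", make_dna(200, seed=21) + CEN180_CONSENSUS * 12)
        monomers = find_monomers([genome], cen180)
        matrix = build_monomer_alignment(monomers, cen180)
        result = cluster_monomers(matrix, k_range=range(2, 11), seed=22)
        assert result.degenerate
        assert result.k_star == 2
        assert len(set(result.labels.tolist())) == 1

    def test_loglik_nondecreasing_and_bic_turns_up(self, cen180):
        matrix, _ = self._two_cluster_matrix(cen180)
        result = cluster_monomers(matrix, k_range=range(2, 7), seed=23)
        lls = [result.log_likelihood[k] for k in sorted(result.log_likelihood)]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6 * abs(a)
        ks = sorted(result.bic)
        assert result.bic[ks[-1]] > min(result.bic.values())


class TestIdentityHeatmap:
    def test_homogeneous_array_all_ones(self):
        n = 2000 // 178 + 1
        region = Sequence("r", CEN180_CONSENSUS * (12 * 4))
        mat = identity_heatmap(region, window=2000)
        assert np.allclose(mat, 1.0, atol=1e-9)

    def test_divergent_arrays_block_structure(self):
        rng = np.random.default_rng(24)
        sites = rng.choice(178, size=9, replace=False)  # ~5% of the unit
        variant = _mutate_positions(CEN180_CONSENSUS, sites)
        window = 2000
        region = Sequence(
            "r", CEN180_CONSENSUS * 23 + variant * 23
        )  # two windows per array
        mat = identity_heatmap(region, window=window)
        assert mat[0, 1] > 0.99 and mat[2, 3] > 0.99  # within-array
        assert mat[0, 2] == pytest.approx(1 - 9 / 178, abs=0.01)  # across

    def test_random_region_no_offdiagonal_signal(self, make_dna):
        region = Sequence("r", make_dna(10_000, seed=25))
        mat = identity_heatmap(region, window=5000)
        assert mat[0, 1] == 0.0
        assert np.allclose(np.diag(mat), 1.0)

    def test_too_short_region_rejected(self, make_dna):
        with pytest.raises(ValueError):
            identity_heatmap(Sequence("r", make_dna(5000)), window=5000)
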