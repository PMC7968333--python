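"""Relationship matrices, single-step H inverse and genotype QC."""

import numpy as np
import pandas as pd
import pytest

from reactnorm.kinship import (
    A_submatrix,
    Kinship,
    Pedigree,
    PedigreeError,
    blend_tune_G,
    h_inverse,
    hwe_pvalues,
    inbreeding,
    make_A,
    make_A_inverse,
    qc_genotypes,
    vanraden_G,
)
from reactnorm.validation import dense_H


class TestPedigree:
    def test_from_frame_topological_sort(self):
        df = pd.DataFrame(
            {"id": [3, 1, 2], "sire": [1, 0, 0], "dam": [2, 0, 0]}
        )
        ped = Pedigree.from_frame(df)
        pos = {a: i for i, a in enumerate(ped.ids)}
        assert pos[1] < pos[3] and pos[2] < pos[3]

    def test_loop_detected(self):
        df = pd.DataFrame({"id": [1, 2], "sire": [2, 1], "dam": [0, 0]})
        with pytest.raises(PedigreeError, match="loop"):
            Pedigree.from_frame(df)

    def test_roundtrip_frame(self, trio_pedigree):
        df = trio_pedigree.to_frame()
        ped2 = Pedigree.from_frame(df)
        assert np.array_equal(ped2.ids, trio_pedigree.ids)


class TestNumeratorRelationship:
    def test_parent_offspring_half(self, trio_pedigree):
        A = make_A(trio_pedigree)
        assert A[0, 2] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_fullsib_mating_inbreeding(self, fullsib_mating_pedigree):
        A = make_A(fullsib_mating_pedigree)
        # full sibs: a = 0.5; their offspring has F = 0.25
        assert A[2, 3] == pytest.approx(0.5)
        assert A[4, 4] == pytest.approx(1.25)
        F = inbreeding(fullsib_mating_pedigree)
        assert F[4] == pytest.approx(0.25)

    def test_entries_bounded_and_psd(self, rng, make_pedigree):
        ped = make_pedigree(60)
        A = make_A(ped)
        assert np.all(A >= 0) and np.all(A <= 2.0)
        assert np.linalg.eigvalsh(A).min() > 0

    def test_inverse_consistent_with_tabular(self, rng, make_pedigree):
        ped = make_pedigree(80)
        A = make_A(ped)
        A_inv, logdet = make_A_inverse(ped)
        assert np.allclose(A_inv.toarray() @ A, np.eye(80), atol=1e-8)
        assert logdet == pytest.approx(np.linalg.slogdet(A)[1])

    def test_submatrix_matches_tabular(self, rng, make_pedigree):
        ped = make_pedigree(70)
        idx = np.sort(rng.choice(70, 20, replace=False))
        A = make_A(ped)
        assert np.allclose(A_submatrix(ped, idx), A[np.ix_(idx, idx)], atol=1e-10)

    def test_matches_gene_dropping_ibd(self, rng, make_pedigree):
        """A equals Monte-Carlo identity-by-descent from gene dropping."""
        ped = make_pedigree(25, n_founders=6)
        n, reps = ped.n, 200_000
        # drop one bi-allelic founder-unique locus per replicate, vectorised
        founders = np.where(ped.sire_idx < 0)[0]
        hap = np.zeros((2, n, reps), dtype=np.int32)
        labels = np.arange(2 * len(founders))
        for k, f in enumerate(founders):
            hap[0, f] = 2 * k
            hap[1, f] = 2 * k + 1
        for i in range(n):
            for h, p in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
                if p >= 0:
                    pick = rng.integers(2, size=reps)
                    hap[h, i] = hap[pick, p, np.arange(reps)]
        A = make_A(ped)
        take = rng.choice(n, size=12, replace=False)
        for i in take[:6]:
            for j in take[6:]:
                # a_ij = 2 * kinship = (1/2) sum over the four haplotype pairs
                a_mc = np.mean(
                    (hap[0, i] == hap[0, j]).astype(int) + (hap[0, i] == hap[1, j])
                    + (hap[1, i] == hap[0, j]) + (hap[1, i] == hap[1, j])
                ) / 2.0
                assert a_mc == pytest.approx(A[i, j], abs=0.02)


class TestGenomicRelationship:
    def test_single_snp_closed_form(self):
        # p = 0.5: M = (-1, +1), denominator 2pq = 0.5 -> diagonal 2
        g = np.array([[0], [2]])
        G0, freqs, scale = vanraden_G(g, freqs=np.array([0.5]))
        assert scale == pytest.approx(0.5)
        assert np.allclose(G0, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_individuals(self, rng, make_pedigree):
        g = rng.integers(0, 3, size=(1, 50))
        g = np.vstack([g, g])
        G0, _, _ = vanraden_G(g)
        assert G0[0, 1] == pytest.approx(G0[0, 0])

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            vanraden_G(np.zeros((4, 3)))

    def test_mean_diagonal_tracks_one(self, rng):
        # with frequencies from the sample, mean diag of G0 ~ 1 + mean inbreeding
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(100, 200))
        G0, freqs, scale = vanraden_G(g)
        M = g - 2 * freqs
        expected = np.mean(np.sum(M**2, axis=1)) / scale
        assert np.mean(np.diag(G0)) == pytest.approx(expected)
        assert abs(np.mean(np.diag(G0)) - 1.0) < 0.1


class TestBlendTune:
    def test_identity_when_scales_match(self, rng, make_pedigree):
        ped = make_pedigree(40)
        A22 = make_A(ped)
        G, (alpha, beta) = blend_tune_G(A22.copy(), A22, omega=0.05)
        assert alpha == pytest.approx(0.0, abs=1e-10)
        assert beta == pytest.approx(1.0)
        assert np.allclose(G, A22)

    def test_omega_one_returns_A22(self, rng, make_pedigree):
        g = rng.binomial(2, 0.4, size=(30, 100))
        G0, _, _ = vanraden_G(g)
        ped = make_pedigree(30)
        A22 = make_A(ped)
        G, _ = blend_tune_G(G0, A22, omega=1.0)
        assert np.allclose(G, A22)

    def test_blended_positive_definite(self, rng, make_pedigree):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 120), size=(40, 120))
        G0, _, _ = vanraden_G(g)
        ped = make_pedigree(40)
        A22 = make_A(ped)
        G, _ = blend_tune_G(G0, A22, omega=0.05)
        assert np.linalg.eigvalsh(G).min() > 0

    def test_moments_match_after_tuning(self, rng, make_pedigree):
        g = rng.binomial(2, rng.uniform(0.2, 0.5, 150), size=(35, 150))
        G0, _, _ = vanraden_G(g)
        ped = make_pedigree(35)
        A22 = make_A(ped)
        G, (alpha, beta) = blend_tune_G(G0, A22, omega=0.0)
        off = ~np.eye(35, dtype=bool)
        assert np.mean(np.diag(G)) == pytest.approx(np.mean(np.diag(A22)))
        assert np.mean(G[off]) == pytest.approx(np.mean(A22[off]))


class TestHInverse:
    def test_no_genotyped_animals_returns_A_inverse(self, rng, make_pedigree):
        ped = make_pedigree(30)
        A_inv, _ = make_A_inverse(ped)
        H_inv = h_inverse(A_inv, np.empty((0, 0)), np.empty((0, 0)), np.array([], dtype=int))
        assert (H_inv != A_inv.tocsc()).nnz == 0

    def test_G_equal_A22_collapses_to_A_inverse(self, rng, make_pedigree):
        ped = make_pedigree(40)
        A = make_A(ped)
        A_inv, _ = make_A_inverse(ped)
        gidx = np.arange(10, 25)
        A22 = A[np.ix_(gidx, gidx)]
        H_inv = h_inverse(A_inv, A22, A22.copy(), gidx)
        assert np.allclose(H_inv.toarray(), A_inv.toarray(), atol=1e-8)

    def test_matches_dense_oracle(self, rng, make_pedigree):
        """H^-1 equals the inverse of the explicitly assembled H."""
        ped = make_pedigree(120)
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(40, 300))
        gidx = np.sort(rng.choice(120, 40, replace=False))
        A = make_A(ped)
        A22 = A[np.ix_(gidx, gidx)]
        G0, _, _ = vanraden_G(g)
        G, _ = blend_tune_G(G0, A22, omega=0.05)
        H_inv = h_inverse(make_A_inverse(ped)[0], A22, G, gidx).toarray()
        H = dense_H(A, G, gidx)
        assert np.max(np.abs(H_inv - np.linalg.inv(H))) < 1e-8

    def test_single_step_kinship_logdet(self, rng, make_pedigree):
        ped = make_pedigree(50)
        g = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(15, 200))
        gidx = np.sort(rng.choice(50, 15, replace=False))
        kin = Kinship.single_step(ped, ped.ids[gidx], g)
        A = make_A(ped)
        A22 = A[np.ix_(gidx, gidx)]
        G0, _, _ = vanraden_G(g)
        G, _ = blend_tune_G(G0, A22)
        H = dense_H(A, G, gidx)
        assert kin.logdet == pytest.approx(np.linalg.slogdet(H)[1])
        assert np.allclose(kin.inv.toarray(), np.linalg.inv(H), atol=1e-7)


class TestQc:
    def _map(self, m, chrom=None):
        return pd.DataFrame(
            {"snp": [f"s{j}" for j in range(m)],
             "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
             "bp": np.arange(1, m + 1) * 1000}
        )

    def test_low_maf_removed(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, size=(n, 2))
        g[:, 1] = rng.binomial(2, 0.04, size=n)  # MAF ~ 0.04
        out, m, ids, rep = qc_genotypes(g, self._map(2), hwe_p=0.0)
        assert rep.removed["maf"] >= 1
        assert m["snp"].tolist() == ["s0"]

    def test_monomorphic_removed(self, rng):
        g = np.column_stack([rng.binomial(2, 0.4, 100), np.zeros(100, int)])
        out, m, ids, rep = qc_genotypes(g, self._map(2), hwe_p=0.0)
        assert "s1" not in m["snp"].tolist()

    def test_planted_violations_counted(self, rng):
        """1000 SNPs with 30 planted violations -> 970 survive."""
        n, m = 400, 1000
        p = rng.uniform(0.2, 0.5, m)
        g = rng.binomial(2, p, size=(n, m)).astype(float)
        bad_maf = np.arange(0, 10)
        bad_miss = np.arange(10, 20)
        bad_hwe = np.arange(20, 30)
        g[:, bad_maf] = rng.binomial(2, 0.01, size=(n, 10))
        g[: int(0.2 * n), bad_miss] = -1
        # worst HWE violation: all heterozygotes
        g[:, bad_hwe] = 1
        out, mp, ids, rep = qc_genotypes(g, self._map(m))
        assert rep.n_snps_out == 970
        assert rep.removed["maf"] == 10
        assert rep.removed["missing_rate"] == 10
        assert rep.removed["hwe"] == 10

    def test_individual_call_rate(self, rng):
        g = rng.binomial(2, 0.4, size=(50, 100)).astype(float)
        g[0, :50] = -1  # 50% call rate
        out, m, ids, rep = qc_genotypes(g, self._map(100), hwe_p=0.0)
        assert rep.removed["individual_call_rate"] == 1
        assert 0 not in ids

    def test_non_autosomal_removed(self, rng):
        g = rng.binomial(2, 0.4, size=(100, 3))
        chrom = np.array(["1", "X", "2"])
        out, m, ids, rep = qc_genotypes(g, self._map(3, chrom), hwe_p=0.0)
        assert rep.removed["non_autosomal"] == 1
        assert "X" not in m["chrom"].astype(str).tolist()

    def test_hwe_pvalue_uniform_under_null(self, rng):
        g = rng.binomial(2, 0.4, size=(500, 300))
        p = hwe_pvalues(g)
        assert (p <= 1e-5).mean() < 0.01
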