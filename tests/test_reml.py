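"""REML machinery: dense-oracle equality, closed forms, recovery, equivalences."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from reactnorm.kinship import Kinship, make_A
from reactnorm.reml import (
    AnimalModel,
    CovarianceStructure,
    IdentifiabilityError,
    ReactionNormModel,
    coefficient_of_variation,
    genetic_correlation,
    genetic_variance_at,
    heritability,
    intercept_slope_correlation,
)
from reactnorm.validation import dense_reml_loglike, loglike_oracle_gap, theta_sigma


# ---------------------------------------------------------------------------
# closed-form genetic parameters from reference components
# ---------------------------------------------------------------------------

class TestClosedForms:
    @pytest.mark.parametrize(
        "sa,se,expected",
        [(794.40, 4035.00, 0.16), (190.42, 2740.10, 0.06), (6.61e-3, 2.16e-1, 0.03)],
    )
    def test_heritability_reference_pairs(self, sa, se, expected):
        assert round(heritability(sa, se), 2) == expected

    def test_coefficient_of_variation(self):
        assert round(coefficient_of_variation(29.25, 55.17), 2) == 1.89

    @pytest.mark.parametrize(
        "s00,s11,s01,expected",
        [
            (2735.10, 1.37, -51.60, -0.84),
            (1073.60, 0.78, -26.15, -0.90),
            (1591.40, 1.24, -41.85, -0.94),
            (1.01e-2, 1.60e-5, -3.35e-4, -0.83),
            (963.72, 0.96, -14.05, -0.46),
        ],
    )
    def test_intercept_slope_correlation(self, s00, s11, s01, expected):
        cov = CovarianceStructure(s00, s11, s01, 1.0)
        r, _ = intercept_slope_correlation(cov)
        assert round(r, 2) == expected

    def test_variance_function(self):
        cov = CovarianceStructure(3950.90, 2.06, -81.46, 3194.70)
        v75 = genetic_variance_at(75.0, cov)
        assert v75 == pytest.approx(3950.90 + 150 * (-81.46) + 5625 * 2.06)
        assert genetic_variance_at(0.0, cov) == pytest.approx(3950.90)
        cov0 = CovarianceStructure(10.0, 4.0, 0.0, 1.0)
        assert genetic_variance_at(1.0, cov0) == pytest.approx(14.0)

    def test_genetic_correlation_limits(self):
        cov = CovarianceStructure(100.0, 5.0, -10.0, 50.0)
        assert genetic_correlation(0.3, 0.3, cov) == pytest.approx(1.0)
        r = genetic_correlation(0.0, 1.0, cov)
        assert -1.0 <= r <= 1.0


# ---------------------------------------------------------------------------
# likelihood oracle and fitting
# ---------------------------------------------------------------------------

def _small_rnm(rng, n=40, theta=(50.0, -3.0, 8.0, 30.0)):
    from conftest import _random_pedigree

    ped = _random_pedigree(rng, n)
    A = make_A(ped)
    kin = Kinship.from_pedigree(ped)
    x = rng.uniform(0, 1, n)
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float), x])
    L = np.linalg.cholesky(np.kron(theta_sigma(np.asarray(theta)), A))
    u = L @ rng.standard_normal(2 * n)
    y = X @ np.array([5.0, 1.0, 2.0]) + u[:n] + x * u[n:] \
        + rng.normal(0, np.sqrt(theta[3]), n)
    model = ReactionNormModel(y, sp.csr_matrix(X), np.arange(n), kin, eg=x)
    return model, A, X, y, x


class TestLikelihood:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_dense_oracle(self, seed):
        """Sparse-MME restricted logL equals the direct dense likelihood."""
        assert loglike_oracle_gap(seed) < 1e-6

    def test_backends_agree(self, rng):
        model, A, X, y, x = _small_rnm(rng)
        theta = np.array([50.0, -3.0, 8.0, 30.0])
        dense = ReactionNormModel(y, sp.csr_matrix(X), np.arange(len(y)),
                                  model.kinship, eg=x, backend="dense")
        sparse = ReactionNormModel(y, sp.csr_matrix(X), np.arange(len(y)),
                                   model.kinship, eg=x, backend="sparse")
        assert dense.loglike(theta) == pytest.approx(sparse.loglike(theta), abs=1e-8)

    def test_animal_model_matches_dense_oracle(self, rng):
        from conftest import _random_pedigree

        n = 35
        ped = _random_pedigree(rng, n)
        A = make_A(ped)
        kin = Kinship.from_pedigree(ped)
        X = np.column_stack([np.ones(n), rng.uniform(0, 1, n)])
        sa, se = 40.0, 25.0
        u = np.linalg.cholesky(sa * A) @ rng.standard_normal(n)
        y = X @ np.array([3.0, 1.0]) + u + rng.normal(0, np.sqrt(se), n)
        model = AnimalModel(y, sp.csr_matrix(X), np.arange(n), kin)
        ll = model.loglike(np.array([sa, se]))
        # dense oracle: RNM oracle with slope terms zeroed
        oracle = dense_reml_loglike(y, X, A, np.zeros(n), (sa, 0.0, 0.0, se))
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_aic_reconstructs_from_parts(self, rng):
        model, *_ = _small_rnm(rng)
        res = model.fit(compute_se=False)
        assert res.aic == pytest.approx(-2 * res.loglike + 2 * 4)
        assert res.k == 4

    def test_identifiability_error_for_constant_gradient(self, rng):
        n = 30
        from conftest import _random_pedigree

        ped = _random_pedigree(rng, n)
        kin = Kinship.from_pedigree(ped)
        X = sp.csr_matrix(np.ones((n, 1)))
        y = rng.normal(size=n)
        with pytest.raises(IdentifiabilityError):
            ReactionNormModel(y, X, np.arange(n), kin, eg=np.full(n, 0.7))


class TestFitBehaviour:
    def test_recovers_truth_within_coverage(self, rng):
        """Estimates land within ~2 SE of the generating components."""
        from conftest import _random_pedigree

        # a family-structured pedigree with strong signal
        n_sires, dps = 40, 20
        n = n_sires * dps
        sire_idx = np.array([-1] * n_sires + list(np.repeat(np.arange(n_sires), dps)))
        dam_idx = np.full(n_sires + n, -1)
        from reactnorm.kinship import Pedigree

        ped = Pedigree(np.arange(1, n_sires + n + 1), sire_idx, dam_idx)
        kin = Kinship.from_pedigree(ped)
        theta = np.array([400.0, -120.0, 100.0, 600.0])
        a_s = np.linalg.cholesky(theta_sigma(theta)) @ rng.standard_normal((2, n_sires))
        ms = np.linalg.cholesky(0.75 * theta_sigma(theta))
        pos = np.arange(n_sires, n_sires + n)
        a = 0.5 * a_s[:, sire_idx[pos]] + ms @ rng.standard_normal((2, n))
        x = rng.uniform(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        y = 100.0 + 3 * x + a[0] + x * a[1] + rng.normal(0, np.sqrt(theta[3]), n)
        model = ReactionNormModel(y, sp.csr_matrix(X), pos, kin, eg=x)
        res = model.fit()
        ses = res.params.se
        se_vec = np.array([ses["sigma_a0_sq"], ses["sigma_a0a1"],
                           ses["sigma_a1_sq"], ses["sigma_e_sq"]])
        assert np.all(np.abs(res.theta - theta) < 3.0 * se_vec)
        assert res.converged

    def test_slope_test_arithmetic(self):
        cov = CovarianceStructure(971.97, 0.53, -9.62, 3413.70,
                                  param_cov=np.diag([62.74, 1.41, 0.05, 45.80]) ** 2)
        res = _StubRes(cov)
        z = cov.sigma_a1_sq / cov.se["sigma_a1_sq"]
        assert z == pytest.approx(10.6, rel=1e-6)
        from scipy.stats import norm

        assert norm.sf(z) < 0.05

    def test_heritability_bounds_and_se(self, rng):
        model, *_ = _small_rnm(rng)
        res = model.fit()
        grid = np.linspace(0, 1, 11)
        h2, se = res.heritability_at(grid)
        assert np.all(h2 >= 0) and np.all(h2 <= 1)
        assert se is not None and np.all(se >= 0)
        h0, _ = res.heritability_at(0.0)
        cov = res.params
        assert h0 == pytest.approx(
            cov.sigma_a0_sq / (cov.sigma_a0_sq + cov.sigma_e_sq))


class _StubRes:
    def __init__(self, cov):
        self.params = cov


class TestPevAccuracy:
    def test_gebv_at_zero_is_intercept(self, rng):
        model, *_ = _small_rnm(rng)
        res = model.fit(compute_se=False)
        assert np.allclose(res.gebv_at(0.0), res.a0)

    def test_pev_positive_and_accuracy_limits(self, rng):
        model, *_ = _small_rnm(rng)
        res = model.fit(compute_se=False)
        animals = np.arange(10)
        pev = res.pev_at(0.5, animals)
        assert np.all(pev > 0)
        acc = res.accuracy_at(0.5, animals)
        assert np.all((acc >= 0) & (acc < 1))
        v = res.genetic_variance_at(0.5)
        # accuracy formula: PEV equal to v(x) -> accuracy 0
        assert np.sqrt(max(0.0, 1 - v / v)) == 0.0

    def test_pev_matches_dense_mme_inverse(self, rng):
        model, *_ = _small_rnm(rng)
        res = model.fit(compute_se=False)
        C, rhs, *_ = model._assemble(model._to_internal(res.theta))
        Cinv = np.linalg.inv(C.toarray())
        p, N = model.p, model.N
        c = model.center
        Binv = np.array([[1.0, -c], [0.0, 1.0]])
        blocks = res._pev_block(np.arange(5))
        for a in range(5):
            raw = Binv @ np.array(
                [[Cinv[p + a, p + a], Cinv[p + a, p + N + a]],
                 [Cinv[p + N + a, p + a], Cinv[p + N + a, p + N + a]]]) @ Binv.T
            assert blocks[a] == pytest.approx(raw, rel=1e-6)


class TestResidualHomogeneity:
    def _fit(self, rng, inflate_top=1.0, dps=20, split=0.3):
        n_sires = 30
        n = n_sires * dps
        from reactnorm.kinship import Pedigree

        sire_idx = np.array([-1] * n_sires + list(np.repeat(np.arange(n_sires), dps)))
        ped = Pedigree(np.arange(1, n_sires + n + 1), sire_idx,
                       np.full(n_sires + n, -1))
        kin = Kinship.from_pedigree(ped)
        pos = np.arange(n_sires, n_sires + n)
        a_s = rng.normal(0, 20, n_sires)
        a = 0.5 * a_s[sire_idx[pos]] + rng.normal(0, np.sqrt(0.75) * 20, n)
        x = rng.uniform(0, 1, n)
        e_sd = np.where(pd.Series(x).rank(pct=True) > split,
                        np.sqrt(inflate_top), 1.0) * 25
        y = 50.0 + a + rng.normal(0, 1, n) * e_sd
        X = np.column_stack([np.ones(n), x])
        model = ReactionNormModel(y, sp.csr_matrix(X), pos, kin, eg=x)
        return model.fit(compute_se=False)

    def test_partition_boundaries_at_10_and_30_percentiles(self, rng):
        res = self._fit(rng)
        table, ratio = res.residual_homogeneity(min_records=50, method="residual")
        assert table["n"].sum() == res.model.nobs
        assert table["n"].tolist() == [60, 120, 420]

    def test_sensitivity_to_planted_heteroskedasticity(self, rng):
        """Per-subset refits separate a homoskedastic fit from a planted
        2x residual inflation; equal-thirds subsets give each refit
        enough records for a stable residual-variance estimate."""
        thirds = (1 / 3, 2 / 3)
        res = self._fit(rng, inflate_top=1.0, dps=150, split=2 / 3)
        _, ratio_h = res.residual_homogeneity(bounds=thirds, min_records=100)
        assert ratio_h < 1.3
        res2 = self._fit(rng, inflate_top=2.0, dps=150, split=2 / 3)
        _, ratio_p = res2.residual_homogeneity(bounds=thirds, min_records=100)
        assert ratio_p > 1.5

    def test_small_subset_warns(self, rng):
        res = self._fit(rng)
        with pytest.warns(UserWarning, match="records"):
            res.residual_homogeneity(min_records=200, method="residual")


class TestGblupSnpBlupEquivalence:
    def test_gebv_match_marker_model(self, rng):
        """GBLUP with VanRaden G equals ridge SNP-BLUP predictions."""
        n, m = 150, 200
        p_freq = rng.uniform(0.1, 0.5, m)
        g = rng.binomial(2, p_freq, size=(n, m)).astype(float)
        from reactnorm.gwas import center_genotypes
        from reactnorm.kinship import vanraden_G

        M, freqs, scale = center_genotypes(g)
        u_true = rng.normal(0, np.sqrt(30.0 / scale), m)
        y = 10.0 + M @ u_true + rng.normal(0, np.sqrt(20.0), n)
        G0, _, _ = vanraden_G(g)
        G = G0 + 1e-8 * np.eye(n)
        kin = Kinship.from_grm(G, np.arange(n))
        X = sp.csr_matrix(np.ones((n, 1)))
        res = AnimalModel(y, X, np.arange(n), kin).fit(compute_se=False)
        sa, se = res.sigma_a_sq, res.sigma_e_sq
        # SNP-BLUP with matching per-marker variance sa/scale
        lam = se / (sa / scale)
        ones = np.ones((n, 1))
        top = np.hstack([ones.T @ ones, ones.T @ M])
        bottom = np.hstack([M.T @ ones, M.T @ M + lam * np.eye(m)])
        coef = np.linalg.solve(np.vstack([top, bottom]),
                               np.concatenate([ones.T @ y, M.T @ y]))
        ghat_snp = M @ coef[1:]
        r = np.corrcoef(ghat_snp, res.ebv)[0, 1]
        assert r > 0.999


class TestCriticalPeriodScan:
    def test_true_window_ranks_first(self):
        """The AIC scan picks the generating critical period."""
        from reactnorm.gradients import EGSpec, daily_summaries, eg_values, scan_critical_period
        from reactnorm.phenotypes import derive_traits, edit_filters
        from reactnorm.simulate import SimConfig, simulate_all

        cfg = SimConfig(
            n_sires=40, daughters_per_sire=15, n_snps=10,
            architecture="polygenic", dams_known=False,
            n_herds=3, years=(2012, 2012), seed=31,
            eg_spec=EGSpec("prop", (-90, -30)),
            variance_components={
                "AFC": (400.0, 900.0, -300.0, 900.0),
                "IFL": (218.16, 0.25, -1.80, 2456.90),
                "CR": (1.01e-2, 1.60e-5, -3.35e-4, 1.99e-1),
            },
        )
        ped, geno, snp_map, weather, records, tv = simulate_all(cfg)
        table, _ = derive_traits(records)
        table, _ = edit_filters(table)
        daily = daily_summaries(weather)
        kin = Kinship.from_pedigree(ped)

        def fitter(x):
            df = table.assign(x=x)
            return ReactionNormModel.from_dataframe(
                df, "AFC", "x", kin, factors=("hym",)).fit(compute_se=False)

        windows = [(-90, -30), (-30, 30), (-10, 60), (0, 60), (-90, -60)]
        scan = scan_critical_period(
            "prop", windows, daily, table["first_service_date"], fitter)
        assert (int(scan.iloc[0]["start"]), int(scan.iloc[0]["end"])) == (-90, -30)
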