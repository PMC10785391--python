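import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvrpipe import a_matrix, simulate_study
from cnvrpipe.association import test_cnvr as gls_test_cnvr
from cnvrpipe.association import (
    AEigen,
    AssociationResult,
    MonomorphicRegionError,
    VarianceComponents,
    bonferroni,
    estimate_variance_components,
    run_association,
)
from cnvrpipe.simulate import SimulationConfig


def mme_solution(y, g, A, vc):
    """Independent oracle: Henderson's mixed-model equations.

    Solves [X'X  X'Z; Z'X  Z'Z + A^-1 * lambda] [b; u] = [X'y; Z'y]
    with Z = I and lambda = sigma2_e / sigma2_u, and reads the fixed
    effect and its sampling variance from the inverted coefficient
    matrix — a different route than the V^-1-based GLS under test.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), g])
    lam = vc.sigma2_e / vc.sigma2_u
    Ainv = np.linalg.inv(A)
    top = np.hstack([X.T @ X, X.T])
    bottom = np.hstack([X, np.eye(n) + Ainv * lam])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, y])
    Cinv = np.linalg.inv(lhs)
    sol = Cinv @ rhs
    beta = sol[1]
    se = np.sqrt(Cinv[1, 1] * vc.sigma2_e)
    return beta, se


@pytest.fixture(scope="module")
def herd():
    cfg = SimulationConfig(
        n_founders=40, n_generations=2, offspring_per_mating=2,
        chromosome_lengths={"1": 50_000_000}, n_regions=5,
        group_effect_sd=0.0, sigma2_u=1.0, sigma2_e=1.0, seed=5,
    )
    study = simulate_study(cfg)
    A, ids = a_matrix(study.pedigree)
    return study, A, ids


class TestVarianceComponents:
    def test_loglik_monotone_nondecreasing(self, herd):
        study, A, ids = herd
        vc = estimate_variance_components(study.phenotypes["y"].to_numpy(), A)
        trace = np.array(vc.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_identity_a_with_no_genetic_signal(self, rng):
        # independent records: total variance lands in the two components,
        # and their sum tracks the sample variance
        y = rng.normal(0, 2.0, 200)
        vc = estimate_variance_components(y, np.eye(200))
        assert vc.sigma2_u + vc.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_small_recovery(self, herd, rng):
        study, A, ids = herd
        n = len(ids)
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        eig = AEigen(A)
        estimates = []
        for _ in range(30):
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)
            vc = estimate_variance_components(y, eig)
            estimates.append([vc.sigma2_u, vc.sigma2_e])
        mean = np.mean(estimates, axis=0)
        se = np.std(estimates, axis=0) / np.sqrt(len(estimates))
        assert abs(mean[0] - 1.0) < 4 * se[0] + 0.05
        assert abs(mean[1] - 1.0) < 4 * se[1] + 0.05

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            AEigen(bad)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            estimate_variance_components(np.ones(5), np.eye(5))


class TestCnvrTest:
    def test_reduces_to_ols_t_test(self, rng):
        """With sigma2_u = 0 and the OLS residual MS as sigma2_e, the GLS
        result equals the closed-form simple-regression t-test."""
        n = 50
        g = np.where(rng.random(n) < 0.3, 1.0, 0.0)
        y = 0.5 * g + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), g])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta_ols = XtX_inv @ X.T @ y
        resid = y - X @ beta_ols
        mse = resid @ resid / (n - 2)
        se_ols = np.sqrt(mse * XtX_inv[1, 1])
        t_ols = beta_ols[1] / se_ols
        p_ols = 2 * stats.t.sf(abs(t_ols), n - 2)

        vc = VarianceComponents(0.0, mse, True, 1)
        res = gls_test_cnvr(y, g, np.eye(n), vc)
        assert res.beta == pytest.approx(beta_ols[1], abs=1e-12)
        assert res.se == pytest.approx(se_ols, abs=1e-12)
        assert res.t == pytest.approx(t_ols, abs=1e-10)
        assert res.p == pytest.approx(p_ols, abs=1e-12)

    def test_matches_mixed_model_equations(self, herd, rng):
        study, A, ids = herd
        n = len(ids)
        y = study.phenotypes["y"].to_numpy()
        g = np.where(rng.random(n) < 0.2, -1.0, 0.0)
        vc = VarianceComponents(1.3, 0.9, True, 1)
        res = gls_test_cnvr(y, g, A, vc)
        beta_mme, se_mme = mme_solution(y, g, A, vc)
        assert res.beta == pytest.approx(beta_mme, abs=1e-8)
        assert res.se == pytest.approx(se_mme, abs=1e-8)

    def test_t_and_df_conventions(self, rng):
        n = 30
        g = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y = rng.normal(size=n)
        res = gls_test_cnvr(y, g, np.eye(n), VarianceComponents(0.0, 1.0, True, 1))
        assert res.t == pytest.approx(res.beta / res.se)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), n - 2))

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicRegionError):
            gls_test_cnvr(np.ones(20), np.zeros(20), np.eye(20),
                      VarianceComponents(0.0, 1.0, True, 1))

    def test_effect_recovery_noise_free(self):
        n = 20
        g = np.array([-1.0, 0.0, 1.0, 0.0] * 5)
        y = 2.0 * g
        res = gls_test_cnvr(y + 1e-9, g, np.eye(n), VarianceComponents(0.0, 1.0, True, 1))
        assert res.beta == pytest.approx(2.0, abs=1e-6)


class TestBonferroni:
    def make_results(self, ps):
        return [AssociationResult(f"CNVR{i+1}", "y", 100, 0.1, 0.1, 1.0, p)
                for i, p in enumerate(ps)]

    def test_single_test(self):
        results, thr = bonferroni(self.make_results([0.04]), alpha=0.05)
        assert thr == pytest.approx(0.05)
        assert results[0].significant

    def test_study_scale_threshold(self):
        results, thr = bonferroni(self.make_results([1e-5, 1e-3]), alpha=0.05, m=561)
        assert thr == pytest.approx(8.9127e-5, rel=1e-4)
        assert [r.significant for r in results] == [True, False]

    def test_equality_not_significant(self):
        results, thr = bonferroni(self.make_results([0.05]), alpha=0.05, m=1)
        assert not results[0].significant

    def test_flag_count_monotone_in_m(self):
        ps = [0.001, 0.01, 0.02, 0.04]
        counts = []
        for m in (1, 5, 50, 500):
            results, _ = bonferroni(self.make_results(ps), alpha=0.05, m=m)
            counts.append(sum(r.significant for r in results))
        assert counts == sorted(counts, reverse=True)


class TestRunAssociation:
    def test_monomorphic_only_gives_empty_table(self, herd):
        study, A, ids = herd
        genotypes = pd.DataFrame(
            0, index=pd.Index(ids, name="sample_id"), columns=["CNVR1"], dtype=np.int8
        )
        phen = study.phenotypes.set_index("animal_id")[["y"]]
        table, meta = run_association(genotypes, phen, A, ids)
        assert len(table) == 0
        assert meta["skipped"][0]["reason"] == "monomorphic"

    def test_deterministic(self, herd):
        study, A, ids = herd
        genotypes = study.genotypes
        phen = study.phenotypes.set_index("animal_id")[["y"]]
        t1, _ = run_association(genotypes, phen, A, ids)
        t2, _ = run_association(genotypes, phen, A, ids)
        pd.testing.assert_frame_equal(t1, t2)

    def test_animals_without_phenotype_dropped(self, herd):
        study, A, ids = herd
        phen = study.phenotypes.set_index("animal_id")[["y"]].copy()
        phen.iloc[:10] = np.nan
        table, meta = run_association(study.genotypes, phen, A, ids)
        assert (table["n"] == len(ids) - 10).all()

    def test_power_causal_region_attains_smallest_p(self):
        """With beta = 1 residual SD at carrier frequency 0.1 and n=600,
        the causal region yields the smallest p among 50 candidate
        regions in at least 95% of 200 replicates."""
        cfg = SimulationConfig(seed=31, group_effect_sd=0.0, sigma2_u=1.0, sigma2_e=1.0)
        ped = simulate_study(cfg).pedigree.head(600)
        A, ids = a_matrix(ped)
        n = len(ids)
        eig = AEigen(A)
        L = np.linalg.cholesky(A + 1e-9 * np.eye(n))
        rng = np.random.default_rng(31)
        R, n_regions, beta = 200, 50, 1.0
        wins = 0
        for _ in range(R):
            G = np.where(rng.random((n, n_regions)) < 0.1, 1.0, 0.0)
            while (np.ptp(G, axis=0) == 0).any():
                G = np.where(rng.random((n, n_regions)) < 0.1, 1.0, 0.0)
            y = beta * G[:, 0] + L @ rng.standard_normal(n) + rng.standard_normal(n)
            vc = estimate_variance_components(y, eig)
            ps = [gls_test_cnvr(y, G[:, j], eig, vc).p for j in range(n_regions)]
            wins += int(np.argmin(ps) == 0)
        assert wins / R >= 0.95

    def test_causal_region_found(self):
        cfg = SimulationConfig(
            n_founders=60, n_generations=2, offspring_per_mating=3,
            chromosome_lengths={"1": 80_000_000}, n_regions=10,
            carrier_freq_range=(0.15, 0.3), effect_sizes={"TR3": 1.5},
            group_effect_sd=0.0, sigma2_u=1.0, sigma2_e=1.0, seed=9,
        )
        study = simulate_study(cfg)
        A, ids = a_matrix(study.pedigree)
        phen = study.phenotypes.set_index("animal_id")[["y"]]
        table, meta = run_association(study.genotypes, phen, A, ids)
        best = table.nsmallest(1, "p").iloc[0]
        assert best["region_id"] == "TR3"
        assert best["significant"]
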