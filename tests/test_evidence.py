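"""Bayesian GLM posterior, analytic and cross-validated model evidence."""

import numpy as np
import pytest
from scipy.special import gammaln

from cvbms import cohort, designs, evidence
from cvbms.evidence import (BayesianGLM, NormalGammaParams, cv_log_model_evidence,
                            log_bayes_factor, log_family_evidence,
                            log_model_evidence)


def quadrature_lme(X, y, mu0, L0, a0, b0, nb=301, nt=300):
    """Independent oracle: dense trapezoid integration over (beta, tau).

    Integrates likelihood x normal prior (given tau) x gamma prior on a 3-D
    grid; only valid for p = 2 designs.
    """
    n, p = X.shape
    bh, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = np.sum((y - X @ bh) ** 2) / (n - p)
    sd = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
    g1 = np.linspace(bh[0] - 10 * sd[0], bh[0] + 10 * sd[0], nb)
    g2 = np.linspace(bh[1] - 10 * sd[1], bh[1] + 10 * sd[1], nb)
    B1, B2 = np.meshgrid(g1, g2, indexing="ij")
    Bs = np.stack([B1.ravel(), B2.ravel()])
    R = y[:, None] - X @ Bs
    rss = np.einsum("ij,ij->j", R, R)
    dB = Bs - mu0[:, None]
    prB = np.einsum("ij,ij->j", dB, L0 @ dB)
    taus = np.exp(np.linspace(np.log(1e-4), np.log(40 / s2), nt))
    lt = np.log(taus)[:, None]
    lj = ((n / 2) * lt - (taus[:, None] / 2) * rss[None, :]
          - (n / 2) * np.log(2 * np.pi)
          + 0.5 * np.linalg.slogdet(L0)[1] + lt - np.log(2 * np.pi)
          - (taus[:, None] / 2) * prB[None, :]
          + a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * lt - b0 * taus[:, None])
    m = lj.max()
    dens = np.exp(lj - m).reshape(nt, nb, nb)
    inner = np.trapezoid(np.trapezoid(dens, dx=g2[1] - g2[0], axis=2),
                         dx=g1[1] - g1[0], axis=1)
    return m + np.log(np.trapezoid(inner, taus))


class TestConjugateFit:
    def test_noise_free_recovery(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        beta = np.array([2.0, -1.5])
        res = BayesianGLM(X @ beta, X).fit()
        np.testing.assert_allclose(res.params, beta, atol=1e-10)

    def test_tight_prior_dominates_data(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = rng.standard_normal(30)
        b0 = np.array([5.0, 5.0])
        prior = NormalGammaParams(mu=b0, Lambda=1e10 * np.eye(2), a=2.0, b=1.0)
        res = BayesianGLM(y, X).fit(prior)
        np.testing.assert_allclose(res.params, b0, atol=1e-3)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, x])
        with pytest.raises(ValueError, match="collinear"):
            BayesianGLM(rng.standard_normal(20), X, names=["c", "x1", "x2"]).fit()

    def test_posterior_calibration_monte_carlo(self, rng):
        """mu within 3 posterior SDs of beta in >= 99% of repetitions."""
        n, p, reps = 200, 3, 500
        hits = 0
        for _ in range(reps):
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            beta = rng.normal(0, 2, p)
            y = X @ beta + rng.normal(0, 1.5, n)
            res = BayesianGLM(y, X).fit()
            hits += np.all(np.abs(res.params - beta) <= 3 * res.param_sd())
        assert hits / reps >= 0.99

    def test_summary_lists_regressors(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        res = BayesianGLM(rng.standard_normal(30), X, names=["const", "x"]).fit()
        assert "const" in res.summary() and "x" in res.summary()


class TestLogModelEvidence:
    def test_matches_brute_force_quadrature(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, -0.5]) + rng.normal(0, 0.8, n)
        prior = NormalGammaParams(mu=np.zeros(2), Lambda=np.eye(2), a=2.0, b=1.0)
        analytic = float(log_model_evidence(X, y, prior)[0])
        numeric = quadrature_lme(X, y, np.zeros(2), np.eye(2), 2.0, 1.0)
        assert abs(analytic - numeric) < 1e-3

    def test_improper_prior_rejected(self, rng):
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="proper"):
            log_model_evidence(X, rng.standard_normal(10),
                               NormalGammaParams.noninformative(1))

    def test_occam_penalty_for_duplicated_column(self, rng):
        """Evidence does not reward a redundant regressor, on average."""
        wins = 0
        for _ in range(20):
            n = 40
            x = rng.standard_normal(n)
            y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
            X1 = np.column_stack([np.ones(n), x])
            X2 = np.column_stack([np.ones(n), x, rng.standard_normal(n)])
            p1 = NormalGammaParams(np.zeros(2), np.eye(2), 2.0, 1.0)
            p2 = NormalGammaParams(np.zeros(3), np.eye(3), 2.0, 1.0)
            wins += (float(log_model_evidence(X1, y, p1)[0])
                     > float(log_model_evidence(X2, y, p2)[0]))
        assert wins >= 14

    def test_occams_hill_over_prior_scale(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 1.0]) + rng.normal(0, 0.5, n)

        def ev(scale):
            prior = NormalGammaParams(np.zeros(2), np.eye(2) / scale, 2.0, 1.0)
            return float(log_model_evidence(X, y, prior)[0])

        assert ev(1.0) > ev(1e-6) and ev(1.0) > ev(1e6)


class TestCvLme:
    def test_column_permutation_invariance(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        a = float(cv_log_model_evidence(X, y)[0])
        b = float(cv_log_model_evidence(X[:, [2, 0, 1]], y)[0])
        assert a == pytest.approx(b, abs=1e-8)

    def test_fold_too_short_rejected(self, rng):
        X = rng.standard_normal((10, 9))
        with pytest.raises(ValueError, match="fold"):
            cv_log_model_evidence(X, rng.standard_normal(10), n_folds=5)

    def test_model_recovery_baseline_vs_memory(self, hc_events, rng):
        """Data without memory effect prefer the baseline model; data with an
        arcsine-shaped effect prefer the parametric memory model."""
        ev, ret = hc_events["events"], hc_events["retrieval"]
        motion = np.cumsum(rng.normal(0, 0.02, (206, 6)), axis=0)
        space = designs.model_space()
        Xb = designs.build_design(ev, motion, space["GLM_TD_0x1"], 206, 2.58).values
        Xm = designs.build_design(ev, motion, space["GLM_1t-a"], 206, 2.58,
                                  retrieval=ret).values
        diffs_null, diffs_mem = [], []
        for _ in range(12):
            noise = rng.normal(0, 1, 206)
            y0 = 100 + 1.0 * Xb[:, 0] + noise
            ym = 100 + 1.0 * Xm[:, 0] + 0.6 * Xm[:, 1] + noise
            diffs_null.append(float(cv_log_model_evidence(Xb, y0)[0])
                              - float(cv_log_model_evidence(Xm, y0)[0]))
            diffs_mem.append(float(cv_log_model_evidence(Xm, ym)[0])
                             - float(cv_log_model_evidence(Xb, ym)[0]))
        assert np.mean(diffs_null) > 0
        assert np.mean(diffs_mem) > 0


class TestFamilyEvidenceAndBayesFactor:
    def test_singleton_family(self):
        assert log_family_evidence({"a": 1.7}, ["a"]) == pytest.approx(1.7)

    def test_equal_members(self):
        assert log_family_evidence({"a": -3.0, "b": -3.0}, ["a", "b"]) \
            == pytest.approx(-3.0)

    def test_log_mean_exp_example(self):
        assert log_family_evidence({"a": 0.0, "b": np.log(3)}, ["a", "b"]) \
            == pytest.approx(np.log(2))

    def test_family_between_min_and_max(self, rng):
        lmes = {f"m{i}": float(v) for i, v in enumerate(rng.normal(0, 5, 6))}
        lfe = log_family_evidence(lmes, list(lmes))
        assert min(lmes.values()) <= lfe <= max(lmes.values())

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            log_family_evidence({"a": 1.0}, [])

    def test_bayes_factor_difference_and_antisymmetry(self):
        assert log_bayes_factor(2.0, 2.0) == 0.0
        assert log_bayes_factor(5.0, 2.0) == -log_bayes_factor(2.0, 5.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            log_bayes_factor(np.nan, 0.0)


class TestWhitening:
    def test_ar1_estimate_recovers_coefficient(self, rng):
        n, rho = 4000, 0.35
        e = np.zeros(n)
        z = rng.standard_normal(n)
        for t in range(1, n):
            e[t] = rho * e[t - 1] + np.sqrt(1 - rho ** 2) * z[t]
        X = np.ones((n, 1))
        assert abs(evidence.estimate_ar1(X, e) - rho) < 0.03

    def test_whitening_removes_autocorrelation(self, rng):
        n, rho = 4000, 0.5
        e = np.zeros((n, 1))
        z = rng.standard_normal(n)
        for t in range(1, n):
            e[t] = rho * e[t - 1] + np.sqrt(1 - rho ** 2) * z[t]
        w = evidence.ar1_whiten(e, rho)[:, 0]
        r1 = np.sum(w[1:] * w[:-1]) / np.sum(w * w)
        assert abs(r1) < 0.05


class TestFirstLevel:
    def test_occam_on_noise_only_voxels(self, small_cohort):
        """On null voxels, the modal per-voxel winner is a most parsimonious
        model (fewest task regressors)."""
        counts = {}
        task_cols = {m.name: designs._n_task_columns(m)
                     for m in designs.enumerate_models()}
        min_cols = min(task_cols.values())
        for sub in small_cohort["subjects"].values():
            emap = evidence.run_first_level(sub, None, n_folds=2)
            gt = small_cohort["manifest"]["ground_truth"]["HC"]
            null_idx = gt.regions["null"]
            names = list(emap.values)
            arr = emap.array(names)[:, null_idx]
            for w in np.argmax(arr, axis=0):
                counts[names[w]] = counts.get(names[w], 0) + 1
        modal = max(counts, key=counts.get)
        assert task_cols[modal] == min_cols

    def test_nonestimable_model_recorded_as_nan(self, small_cohort):
        sub = dict(next(iter(small_cohort["subjects"].values())))
        ev_table = sub["events"].copy()
        novel = ev_table["trial_type"] == "novel"
        ev_table.loc[novel, "response"] = np.where(
            ev_table.loc[novel, "response"] >= 3, 5.0, 1.0)
        sub["events"] = ev_table
        emap = evidence.run_first_level(sub, ["GLM_5", "GLM_TD_0x1"], n_folds=2)
        assert np.all(np.isnan(emap.values["GLM_5"]))
        assert np.all(np.isfinite(emap.values["GLM_TD_0x1"]))
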