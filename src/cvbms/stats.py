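"""Group-level statistics downstream of the model-selection maps.

Covers the classical and Bayesian analyses run on per-subject log Bayes
factor (LBF) maps and demographic tables: supra-threshold voxel counting,
ANCOVA for group effects with nuisance covariates, default-prior (JZS)
Bayesian two-sample t-tests, balanced support-vector classification,
chi-square and summary-statistics ANOVA for demographic tables, the
repeated-measures number-of-regressors trend analysis, and permutation-based
familywise-error-corrected second-level tests (a substitute for
random-field-theory correction, exact under sign-flip exchangeability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, stats

__all__ = [
    "BFResult",
    "ClassificationResult",
    "StatMapResult",
    "RegressorCountResult",
    "count_suprathreshold",
    "voxel_count_table",
    "ancova_group_effect",
    "jzs_ttest",
    "svm_classify",
    "chi_square_independence",
    "anova_from_summaries",
    "two_sample_t_from_summaries",
    "regressor_count_anova",
    "second_level_ftest",
    "bf_to_lbf",
]


def bf_to_lbf(bf) -> float:
    """Bayes-factor threshold -> log Bayes factor cutoff (natural log)."""
    bf = np.asarray(bf, dtype=float)
    if np.any(bf <= 0):
        raise ValueError("Bayes factors must be positive")
    out = np.log(bf)
    return float(out) if out.ndim == 0 else out


def count_suprathreshold(lbf_map, threshold, mask=None, scale: str = "lbf") -> int:
    """Number of in-mask voxels with LBF strictly above the threshold.

    ``scale="bf"`` interprets the threshold as a Bayes factor and converts
    it by natural log.
    """
    lbf = np.asarray(lbf_map, dtype=float).ravel()
    if mask is None:
        mask = np.ones(lbf.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.shape != lbf.shape:
        raise ValueError(f"mask shape {mask.shape} does not match map {lbf.shape}")
    thr = bf_to_lbf(threshold) if scale == "bf" else float(threshold)
    vals = lbf[mask]
    return int(np.sum(vals > thr))


def voxel_count_table(lbf_maps: dict, thresholds, mask=None) -> pd.DataFrame:
    """Counts per subject, contrast and threshold, as a tidy table.

    ``lbf_maps``: subject -> {contrast name -> LBF map}.
    """
    rows = []
    for subject, contrasts in lbf_maps.items():
        for contrast, lbf in contrasts.items():
            for thr in thresholds:
                rows.append({
                    "subject": subject, "contrast": contrast,
                    "lbf_threshold": float(thr),
                    "count": count_suprathreshold(lbf, thr, mask=mask),
                })
    return pd.DataFrame(rows)


def ancova_group_effect(data: pd.DataFrame, dv: str, group: str = "group",
                        covariates=(), categorical=("site", "gender")):
    """Partial F-test for the group factor in a linear model with covariates.

    Returns (F, (df_num, df_den), p).  Covariates listed in ``categorical``
    are dummy-coded; aliased (perfectly collinear) covariates are rejected
    with their name.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    terms = [f"C({group})"]
    for c in covariates:
        terms.append(f"C({c})" if c in categorical else c)
    formula = f"{dv} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [model.exog_names[i] for i in
               np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max())]
        raise ValueError(f"aliased design columns: {bad}")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc[f"C({group})"]
    df_num = int(row["df"])
    df_den = int(table.loc["Residual", "df"])
    return float(row["F"]), (df_num, df_den), float(row["PR(>F)"])


@dataclass(frozen=True)
class BFResult:
    """Default-prior Bayesian t-test outcome."""

    bf01: float
    delta_med: float
    t: float
    df: int

    def __post_init__(self):
        if self.bf01 <= 0:
            raise ValueError("bf01 must be positive")


def _jzs_bf10(t: float, n_eff: float, nu: int, r: float) -> float:
    """JZS Bayes factor 10 by quadrature over the g-prior mixture.

    The Cauchy(0, r) prior on the standardized effect is the scale mixture
    g ~ InvGamma(1/2, r^2/2) of Zellner g-priors; integrating g gives

        BF10 = [int (1+Ng)^-1/2 (1 + t^2/((1+Ng) nu))^-(nu+1)/2 p(g) dg]
               / (1 + t^2/nu)^-(nu+1)/2.
    """
    logden = -(nu + 1) / 2.0 * np.log1p(t * t / nu)

    def integrand(g):
        logk = (-0.5 * np.log1p(n_eff * g)
                - (nu + 1) / 2.0 * np.log1p(t * t / ((1 + n_eff * g) * nu))
                - logden)
        return np.exp(logk) * stats.invgamma.pdf(g, 0.5, scale=r * r / 2.0)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(val)


def _posterior_delta_median(t: float, n_eff: float, nu: int, r: float) -> float:
    """Median of the effect-size posterior under the Cauchy prior.

    Under the alternative, t | delta follows a noncentral t with df nu and
    noncentrality delta * sqrt(n_eff); the posterior over delta is that
    likelihood times the Cauchy(0, r) prior, evaluated on a dense grid.
    """
    d = t / np.sqrt(n_eff)
    half = max(6.0 / np.sqrt(nu), 1.0)
    grid = np.linspace(min(-1.5, d - half * 4), max(1.5, d + half * 4), 4001)
    logpost = (stats.nct.logpdf(t, nu, grid * np.sqrt(n_eff))
               + stats.cauchy.logpdf(grid, scale=r))
    post = np.exp(logpost - logpost.max())
    cdf = integrate.cumulative_trapezoid(post, grid, initial=0)
    cdf /= cdf[-1]
    return float(np.interp(0.5, cdf, grid))


def jzs_ttest(sample_1, sample_2, scale: float = np.sqrt(2) / 2) -> BFResult:
    """Two-sample Bayesian t-test with the default Cauchy prior (JZS).

    Reports BF01 (evidence for the null of no difference) and the posterior
    median standardized effect size; the sign convention is
    mean(sample_1) - mean(sample_2).
    """
    x1 = np.asarray(sample_1, dtype=float)
    x2 = np.asarray(sample_2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x1) == 0 and np.var(x2) == 0:
        raise ValueError("zero variance in both samples")
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / nu
    n_eff = n1 * n2 / (n1 + n2)
    t = (x1.mean() - x2.mean()) / np.sqrt(sp2 / n_eff)
    bf10 = _jzs_bf10(t, n_eff, nu, scale)
    delta = _posterior_delta_median(t, n_eff, nu, scale)
    return BFResult(bf01=1.0 / bf10, delta_med=delta, t=float(t), df=nu)


@dataclass(frozen=True)
class ClassificationResult:
    """Balanced-subsample SVM classification summary."""

    balanced_accuracy: float
    ci90: tuple
    n_subsamples: int
    accuracies: np.ndarray = field(repr=False, default=None)


def svm_classify(features, labels, C: float = 1.0, k_folds: int = 10,
                 n_subsamples: int = 1000, seed: int | None = None) -> ClassificationResult:
    """Balanced binary SVM classification with repeated subsampling.

    For each subsample, an equal number of subjects per class (the size of
    the smaller class) is drawn without replacement, a linear support-vector
    classifier (standardized features, C as given) is evaluated with
    stratified k-fold cross-validation, and the balanced accuracy recorded.
    The summary is the mean across subsamples with the 5th/95th percentile
    interval.
    """
    from sklearn.metrics import balanced_accuracy_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    idx = [np.flatnonzero(y == c) for c in classes]
    n_per = min(len(i) for i in idx)
    if n_per == 0:
        raise ValueError("both classes must be non-empty")
    if k_folds > n_per:
        raise ValueError(f"k_folds={k_folds} exceeds smallest class size {n_per}")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_subsamples)
    for s in range(n_subsamples):
        sel = np.concatenate([rng.choice(i, n_per, replace=False) for i in idx])
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True,
                             random_state=int(rng.integers(2 ** 31)))
        pred = cross_val_predict(clf, X[sel], y[sel], cv=cv)
        accs[s] = balanced_accuracy_score(y[sel], pred)
    return ClassificationResult(
        balanced_accuracy=float(accs.mean()),
        ci90=(float(np.percentile(accs, 5)), float(np.percentile(accs, 95))),
        n_subsamples=n_subsamples, accuracies=accs)


def chi_square_independence(table):
    """Pearson chi-square test of independence (no continuity correction).

    Returns (chi2, df, p).
    """
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res[0]), int(res[2]), float(res[1])


def anova_from_summaries(ns, means, sds):
    """One-way ANOVA from per-group (n, mean, SD) summaries.

    Uses the exact between/within sum-of-squares decomposition, so the
    result equals the raw-data ANOVA when summaries are exact.
    Returns (F, (df_between, df_within), p).
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(ns) < 2:
        raise ValueError("need at least two groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(~np.isfinite(sds)):
        raise ValueError("missing SD")
    gm = np.sum(ns * means) / ns.sum()
    ss_b = np.sum(ns * (means - gm) ** 2)
    ss_w = np.sum((ns - 1) * sds ** 2)
    df_b, df_w = len(ns) - 1, int(ns.sum()) - len(ns)
    F = (ss_b / df_b) / (ss_w / df_w)
    return float(F), (df_b, df_w), float(stats.f.sf(F, df_b, df_w))


def two_sample_t_from_summaries(n1, m1, s1, n2, m2, s2):
    """Pooled two-sample t from summary statistics: (t, df, p)."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), int(df), float(2 * stats.t.sf(abs(t), df))


@dataclass
class RegressorCountResult:
    """Repeated-measures trend analysis of LBF over regressor counts."""

    levels: tuple
    trend_t: np.ndarray               # per voxel, linear contrast over levels
    memory_t: np.ndarray              # per voxel, mean LBF vs 0
    trend_p: np.ndarray
    memory_p: np.ndarray
    conjunction_p: np.ndarray         # minimum-statistic conjunction
    n_subjects: int
    lbf: np.ndarray = field(repr=False, default=None)

    def extract(self, voxel: int, ci: float = 0.90):
        """Per-level mean LBF at a voxel with a t-based confidence interval."""
        vals = self.lbf[:, :, voxel]
        n = vals.shape[0]
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(n)
        q = stats.t.ppf(0.5 + ci / 2, n - 1)
        return pd.DataFrame({"n_regressors": self.levels, "mean_lbf": mean,
                             "ci_low": mean - q * se, "ci_high": mean + q * se})


def regressor_count_anova(lbf, levels=(1, 2, 3, 5)) -> RegressorCountResult:
    """Within-subject linear-trend test of LBF versus number of regressors.

    ``lbf``: (N, L, V) per-subject LBF maps of memory-model families with
    ``levels[l]`` regressors against the baseline model; only subjects with
    all L maps may be included (the five-regressor model requires the full
    response range).  The linear contrast uses centered level weights; the
    memory-effect test is the one-sample test of the per-subject mean LBF;
    the conjunction requires both at their respective significance (max p).
    """
    lbf = np.asarray(lbf, dtype=float)
    if lbf.ndim == 2:
        lbf = lbf[:, :, None]
    if lbf.shape[1] != len(levels):
        raise ValueError(f"expected {len(levels)} levels, got {lbf.shape[1]}")
    if np.any(~np.isfinite(lbf)):
        raise ValueError("missing level maps: include only subjects with all levels")
    n = lbf.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    w = np.asarray(levels, dtype=float)
    w = w - w.mean()

    scale = np.abs(lbf).max() + 1.0

    def one_sample_t(vals):
        se = vals.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            # se below numerical noise of the inputs counts as exactly zero
            return np.where(se > 1e-12 * scale, vals.mean(axis=0) / se, 0.0)

    contrast = np.einsum("l,nlv->nv", w, lbf)
    t_trend = one_sample_t(contrast)
    t_mem = one_sample_t(lbf.mean(axis=1))
    p_trend = 2 * stats.t.sf(np.abs(t_trend), n - 1)
    p_mem = 2 * stats.t.sf(np.abs(t_mem), n - 1)
    return RegressorCountResult(
        levels=tuple(levels), trend_t=t_trend, memory_t=t_mem,
        trend_p=p_trend, memory_p=p_mem,
        conjunction_p=np.maximum(p_trend, p_mem), n_subjects=n, lbf=lbf)


@dataclass
class StatMapResult:
    """Second-level one-sample test with familywise correction."""

    t: np.ndarray
    f: np.ndarray
    p_fwe: np.ndarray
    significant: np.ndarray
    alpha: float
    cluster_k: int
    method: str
    n_permutations: int = 0


def second_level_ftest(contrast_maps, grid_shape=None, alpha: float = 0.05,
                       cluster_k: int = 10, n_permutations: int = 10000,
                       method: str = "permutation",
                       seed: int | None = None) -> StatMapResult:
    """Voxel-wise one-sample test of a group mean contrast against zero.

    The F statistic is the squared one-sample t (two-sided).  Familywise
    error is controlled by the sign-flip permutation distribution of the
    maximum statistic (``method="permutation"``, exact under symmetric
    errors) or by Bonferroni (``method="bonferroni"``).  Significant voxels
    in clusters smaller than ``cluster_k`` (face connectivity on
    ``grid_shape``) are suppressed.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim != 2:
        maps = maps.reshape(maps.shape[0], -1)
    n, V = maps.shape
    if n < 2:
        raise ValueError("need at least two subjects")

    def tstat(data, axis=0):
        se = data.std(axis=axis, ddof=1) / np.sqrt(n)
        mean = data.mean(axis=axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(se > 0, mean / se, 0.0)

    t = tstat(maps)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_permutations)
        done = 0
        while done < n_permutations:  # chunked to bound memory
            b = min(500, n_permutations - done)
            signs = rng.choice([-1.0, 1.0], size=(b, n))
            tb = tstat(signs[:, :, None] * maps[None, :, :], axis=1)
            null_max[done:done + b] = np.abs(tb).max(axis=1)
            done += b
        p = (1 + np.sum(null_max[:, None] >= np.abs(t)[None, :], axis=0)) / (n_permutations + 1)
    elif method == "bonferroni":
        p = np.clip(2 * stats.t.sf(np.abs(t), n - 1) * V, 0, 1)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    sig = p <= alpha
    if grid_shape is not None and cluster_k > 1 and sig.any():
        lab, nlab = ndimage.label(sig.reshape(grid_shape))
        keep = np.zeros_like(sig)
        for i in range(1, nlab + 1):
            comp = (lab == i)
            if comp.sum() >= cluster_k:
                keep |= comp.ravel()
        sig = keep
    return StatMapResult(t=t, f=t ** 2, p_fwe=p, significant=sig, alpha=alpha,
                         cluster_k=cluster_k, method=method,
                         n_permutations=n_permutations if method == "permutation" else 0)
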