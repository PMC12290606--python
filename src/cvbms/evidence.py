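"""Voxel-wise Bayesian GLM estimation and cross-validated log model evidence.

The per-voxel model is the conjugate normal--gamma linear model: with data
y (n x 1), design X (n x p), noise precision tau and weights beta,

    y | beta, tau ~ N(X beta, tau^-1 I)
    beta | tau    ~ N(mu0, (tau Lambda0)^-1)
    tau           ~ Gamma(a0, b0)        (shape/rate)

whose posterior is again normal--gamma with

    Lambda_n = X'X + Lambda0
    mu_n     = Lambda_n^-1 (X'y + Lambda0 mu0)
    a_n      = a0 + n/2
    b_n      = b0 + (y'y + mu0' Lambda0 mu0 - mu_n' Lambda_n mu_n) / 2

and analytic log marginal likelihood (the log model evidence, LME)

    log p(y) = -n/2 log(2 pi) + 1/2 (log|Lambda0| - log|Lambda_n|)
               + a0 log b0 - a_n log b_n + log G(a_n) - log G(a0).

The non-informative limit (Lambda0 = 0, a0 = b0 = 0) yields the
least-squares estimate as posterior mean but an undefined evidence; it is
used only as the starting prior for cross-validation.  The cross-validated
LME (cvLME) splits the session into contiguous folds, turns the posterior
from the training folds into a proper prior, evaluates the analytic log
evidence of the held-out fold under that prior, and sums over folds.  Serial
correlation is handled by AR(1) prewhitening with a global coefficient
pooled over voxels, applied identically to all models of a subject so that
evidence differences remain comparable.

All computations are vectorized over voxels: the precision matrices depend
only on the design, so per-voxel work reduces to quadratic forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import designs

__all__ = [
    "NormalGammaParams",
    "BayesianGLM",
    "BayesianGLMResults",
    "EvidenceMap",
    "log_model_evidence",
    "cv_log_model_evidence",
    "log_family_evidence",
    "log_bayes_factor",
    "estimate_ar1",
    "ar1_whiten",
    "run_first_level",
    "intersection_mask",
]


@dataclass
class NormalGammaParams:
    """Normal-gamma prior/posterior over (weights, noise precision).

    ``mu``: p (or p x V) weight mean; ``Lambda``: p x p precision-like
    matrix (shared across voxels); ``a``/``b``: gamma shape and rate, ``b``
    scalar or per voxel.
    """

    mu: np.ndarray
    Lambda: np.ndarray
    a: float
    b: np.ndarray | float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        if not np.allclose(self.Lambda, self.Lambda.T):
            raise ValueError("Lambda must be symmetric")

    @property
    def is_proper(self) -> bool:
        if self.a <= 0 or np.any(np.asarray(self.b) <= 0):
            return False
        try:
            np.linalg.cholesky(self.Lambda)
        except np.linalg.LinAlgError:
            return False
        return True

    @classmethod
    def noninformative(cls, p: int) -> "NormalGammaParams":
        return cls(mu=np.zeros(p), Lambda=np.zeros((p, p)), a=0.0, b=0.0)


def _check_design(X: np.ndarray, labels=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    return X


def _named_collinear(X, labels):
    """Identify columns involved in a rank deficiency, for error messages."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, R = np.linalg.qr(X)
    dep = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max())
    if labels is None:
        labels = [f"col_{i}" for i in range(X.shape[1])]
    return [labels[i] for i in dep]


def _update(X, Y, prior: NormalGammaParams):
    """Conjugate update, vectorized over columns of Y (n x V)."""
    n = X.shape[0]
    Ln = X.T @ X + prior.Lambda
    mu0 = prior.mu if prior.mu.ndim == 2 else prior.mu[:, None]
    rhs = X.T @ Y + prior.Lambda @ np.broadcast_to(mu0, (X.shape[1], Y.shape[1]))
    try:
        mun = np.linalg.solve(Ln, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError("rank-deficient design: singular normal equations") from e
    an = prior.a + n / 2.0
    yy = np.einsum("ij,ij->j", Y, Y)
    m0Lm0 = np.einsum("ij,ij->j", np.broadcast_to(mu0, rhs.shape),
                      prior.Lambda @ np.broadcast_to(mu0, rhs.shape))
    mnLmn = np.einsum("ij,ij->j", mun, Ln @ mun)
    bn = np.asarray(prior.b) + 0.5 * (yy + m0Lm0 - mnLmn)
    return NormalGammaParams(mu=mun, Lambda=Ln, a=an, b=bn)


class BayesianGLM:
    """Conjugate Bayesian linear model for one design and one or many voxels.

    Parameters
    ----------
    endog : array (n,) or (n, V) — time series, one column per voxel.
    exog : array (n, p) or :class:`~cvbms.designs.DesignMatrix`.
    names : optional column labels (taken from the DesignMatrix if given).
    """

    def __init__(self, endog, exog, names=None):
        if isinstance(exog, designs.DesignMatrix):
            names = list(exog.column_labels)
            exog = exog.values
        self.exog = _check_design(exog)
        y = np.asarray(endog, dtype=float)
        self._scalar = y.ndim == 1
        self.endog = y[:, None] if self._scalar else y
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.names = names

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, prior: NormalGammaParams | None = None) -> "BayesianGLMResults":
        """Posterior over weights and noise precision.

        With no (or a non-informative) prior, the posterior mean equals the
        least-squares estimate; the design must then be full rank.
        """
        p = self.exog.shape[1]
        if prior is None:
            prior = NormalGammaParams.noninformative(p)
        informative = prior.is_proper
        if not informative:
            bad = _named_collinear(self.exog, self.names)
            if bad:
                raise ValueError(
                    f"rank-deficient design with non-informative prior; "
                    f"collinear columns: {bad}")
        post = _update(self.exog, self.endog, prior)
        return BayesianGLMResults(self, prior, post, scalar=self._scalar)

    def log_evidence(self, prior: NormalGammaParams):
        """Analytic log marginal likelihood under a proper prior."""
        out = log_model_evidence(self.exog, self.endog, prior)
        return float(out[0]) if self._scalar else out

    def cv_log_evidence(self, n_folds: int = 2):
        out = cv_log_model_evidence(self.exog, self.endog, n_folds)
        return float(out[0]) if self._scalar else out


@dataclass
class BayesianGLMResults:
    """Posterior summary of a fitted :class:`BayesianGLM`."""

    model: BayesianGLM
    prior: NormalGammaParams
    posterior: NormalGammaParams
    scalar: bool = True

    @property
    def params(self):
        mu = self.posterior.mu
        return mu[:, 0] if self.scalar else mu

    @property
    def sigma2_mean(self):
        """Posterior mean of the noise variance (b / (a - 1) for a > 1)."""
        a, b = self.posterior.a, np.asarray(self.posterior.b)
        out = np.where(a > 1, b / (a - 1), np.nan)
        return float(out[0]) if self.scalar else out

    def param_sd(self):
        """Posterior SD of each weight (multivariate t marginals)."""
        a, b = self.posterior.a, np.atleast_1d(self.posterior.b)
        Linv_diag = np.diag(np.linalg.inv(self.posterior.Lambda))
        var = Linv_diag[:, None] * (b[None, :] / a) * (a / max(a - 1, 1e-12))
        sd = np.sqrt(var)
        return sd[:, 0] if self.scalar else sd

    def summary(self) -> str:
        import io
        buf = io.StringIO()
        names = self.model.names or [f"x{i}" for i in range(self.model.exog.shape[1])]
        mu = np.atleast_2d(self.posterior.mu.T)
        sd = np.atleast_2d(self.param_sd().T) if self.scalar else None
        buf.write("Bayesian GLM (normal-gamma posterior)\n")
        buf.write(f"  n = {self.model.nobs}, p = {len(names)}, "
                  f"a_n = {self.posterior.a:.2f}\n")
        if self.scalar:
            buf.write(f"  {'regressor':<20}{'post. mean':>12}{'post. SD':>12}\n")
            for nm, m, s in zip(names, mu[0], sd[0]):
                buf.write(f"  {nm:<20}{m:>12.4f}{s:>12.4f}\n")
        else:
            buf.write(f"  fitted jointly over {mu.shape[0]} voxels\n")
        return buf.getvalue()


def log_model_evidence(X, Y, prior: NormalGammaParams) -> np.ndarray:
    """Closed-form log marginal likelihood of Y (n x V) under a proper prior."""
    X = _check_design(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not prior.is_proper:
        raise ValueError("log model evidence requires a proper (informative) prior")
    n = X.shape[0]
    post = _update(X, Y, prior)
    sign0, logdet0 = np.linalg.slogdet(prior.Lambda)
    sign1, logdet1 = np.linalg.slogdet(post.Lambda)
    b0 = np.broadcast_to(np.asarray(prior.b, dtype=float), (Y.shape[1],))
    return (-n / 2.0 * np.log(2 * np.pi)
            + 0.5 * (logdet0 - logdet1)
            + prior.a * np.log(b0) - post.a * np.log(post.b)
            + gammaln(post.a) - gammaln(prior.a))


def cv_log_model_evidence(X, Y, n_folds: int = 2) -> np.ndarray:
    """Cross-validated LME: out-of-sample evidence summed over contiguous folds.

    For each fold, the posterior obtained from all other folds (starting
    from the non-informative prior) serves as the prior under which the
    analytic log evidence of the held-out fold is evaluated.
    """
    X = _check_design(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    n, p = X.shape
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    folds = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_folds)]
    total = np.zeros(Y.shape[1])
    for i, hold in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        if train.size <= p:
            raise ValueError(
                f"fold {i}: training complement has {train.size} rows for "
                f"{p} columns")
        prior = _update(X[train], Y[train], NormalGammaParams.noninformative(p))
        if not prior.is_proper:
            bad = _named_collinear(X[train], None)
            raise ValueError(f"training complement rank-deficient (fold {i}): {bad}")
        total += log_model_evidence(X[hold], Y[hold], prior)
    return total


def log_family_evidence(lmes, family=None) -> np.ndarray | float:
    """Log family evidence: log-mean-exp of member LMEs (uniform prior).

    ``lmes`` may be a mapping name -> LME (scalar or per-voxel array) with
    ``family`` a set of member names, or directly an array whose first axis
    indexes members.
    """
    if isinstance(lmes, dict):
        if not family:
            raise ValueError("empty model family")
        missing = [m for m in family if m not in lmes]
        if missing:
            raise ValueError(f"family members without evidence: {missing}")
        arr = np.stack([np.asarray(lmes[m], dtype=float) for m in family])
    else:
        arr = np.asarray(lmes, dtype=float)
        if arr.shape[0] == 0:
            raise ValueError("empty model family")
    k = arr.shape[0]
    m = arr.max(axis=0)
    out = m + np.log(np.exp(arr - m).sum(axis=0)) - np.log(k)
    return float(out) if out.ndim == 0 else out


def log_bayes_factor(lme1, lme2):
    """Log Bayes factor for model/family 1 over 2: difference of evidences."""
    a1, a2 = np.asarray(lme1, dtype=float), np.asarray(lme2, dtype=float)
    if not (np.all(np.isfinite(a1)) and np.all(np.isfinite(a2))):
        raise ValueError("log evidences must be finite")
    out = a1 - a2
    return float(out) if out.ndim == 0 else out


def estimate_ar1(X, Y) -> float:
    """Global AR(1) coefficient from pooled least-squares residuals."""
    X = _check_design(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta
    num = np.sum(E[1:] * E[:-1])
    den = np.sum(E * E)
    return float(np.clip(num / den if den > 0 else 0.0, 0.0, 0.99))


def ar1_whiten(A, rho: float) -> np.ndarray:
    """Apply the exact AR(1) inverse-square-root transform to rows of A.

    Row 0 is scaled by sqrt(1 - rho^2); row t becomes A[t] - rho A[t-1].
    Unit-variance innovations are preserved so evidences stay on one scale.
    """
    A = np.asarray(A, dtype=float)
    W = np.empty_like(A)
    W[0] = np.sqrt(1.0 - rho ** 2) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


@dataclass
class EvidenceMap:
    """Per-voxel (cv)LME values per model for one subject."""

    values: dict                      # model name -> (V,) array
    mask: np.ndarray = field(repr=False)
    grid_shape: tuple = ()

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {np.asarray(v).shape for v in self.values.values()}
        if len(shapes) > 1:
            raise ValueError("models must share one voxel grid")

    def array(self, models) -> np.ndarray:
        return np.stack([np.asarray(self.values[m], dtype=float) for m in models])

    def family_evidence(self, family_members) -> np.ndarray:
        return log_family_evidence(self.values, family_members)


def intersection_mask(bold_list, threshold: float = 0.5) -> np.ndarray:
    """Voxels with mean signal above ``threshold`` x grand mean in all subjects."""
    mask = None
    for bold in bold_list:
        flat = np.asarray(bold, dtype=float).reshape(-1, bold.shape[-1])
        mean = flat.mean(axis=1)
        m = mean > threshold * mean.mean()
        mask = m if mask is None else (mask & m)
    return mask


def run_first_level(subject: dict, model_names=None, n_folds: int = 2,
                    mask=None, drift: bool = True, seed: int = 0) -> EvidenceMap:
    """cvLME maps for one subject across the model space.

    Estimates a global AR(1) coefficient from the baseline model's pooled
    residuals, prewhitens data and all designs identically, and computes the
    cvLME of every requested (and estimable) model; non-estimable models are
    recorded as NaN.
    """
    space = designs.model_space()
    names = list(space) if model_names is None else list(model_names)
    events, motion = subject["events"], subject["motion"]
    bold = np.asarray(subject["bold"], dtype=float)
    n_scans = bold.shape[-1]
    tr = subject.get("tr", 2.58)
    Y = bold.reshape(-1, n_scans).T                      # n x V
    if mask is None:
        mask = np.ones(Y.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    Ym = Y[:, mask]

    base = designs.build_design(events, motion, space[designs.BASELINE_MODEL],
                                n_scans, tr, retrieval=subject.get("retrieval"),
                                drift=drift, seed=seed)
    rho = estimate_ar1(base.values, Ym)
    Yw = ar1_whiten(Ym, rho)

    values = {}
    for name in names:
        spec = space[name]
        try:
            dm = designs.build_design(events, motion, spec, n_scans, tr,
                                      retrieval=subject.get("retrieval"),
                                      drift=drift, seed=seed)
        except designs.EstimabilityError:
            values[name] = np.full(Y.shape[1], np.nan)
            continue
        Xw = ar1_whiten(dm.values, rho)
        try:
            lme = cv_log_model_evidence(Xw, Yw, n_folds)
        except ValueError:
            # e.g. a memory category confined to one fold: not cross-validatable
            values[name] = np.full(Y.shape[1], np.nan)
            continue
        full = np.full(Y.shape[1], np.nan)
        full[mask] = lme
        values[name] = full
    grid = bold.shape[:-1]
    return EvidenceMap(values=values, mask=mask, grid_shape=grid)
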