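"""Random-effects Bayesian model selection over subjects' log evidences.

Treats the model (or model family) generating each subject's data as a
random effect: population model frequencies r follow a Dirichlet(alpha)
distribution, each subject's generating model is a draw from r, and the
observed per-subject log model evidences enter through the likelihood.  The
variational fixed point alternates

    g_nm  propto  exp( LME_nm + psi(alpha_m) - psi(sum_k alpha_k) )
    alpha = alpha0 + sum_n g_n.

``g`` are posterior model attributions per subject, ``alpha`` the Dirichlet
posterior over frequencies.  The likeliest frequency (LF) of model m is the
mode of its marginal Beta(alpha_m, sum(alpha) - alpha_m) distribution; the
selected-model map reports, per voxel, the model with the highest LF.

Everything is vectorized over voxels: inputs may be (N, M) for a single
location or (N, M, V) for a map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = [
    "GroupBMS",
    "DirichletResults",
    "SelectedModelMap",
    "rfx_bms",
    "likeliest_frequency",
    "selected_model_map",
]


class GroupBMS:
    """Random-effects BMS model over an evidence matrix.

    Parameters
    ----------
    lme : array (N, M) or (N, M, V): per-subject, per-model log evidences
        (cvLME, or cvLFE when candidates are families).
    model_names : optional labels for the M candidates.
    """

    def __init__(self, lme, model_names=None):
        lme = np.asarray(lme, dtype=float)
        if lme.ndim == 2:
            lme = lme[:, :, None]
            self._map = False
        elif lme.ndim == 3:
            self._map = True
        else:
            raise ValueError("lme must be (N, M) or (N, M, V)")
        if not np.all(np.isfinite(lme)):
            raise ValueError("log evidences must be finite")
        if lme.shape[0] < 1 or lme.shape[1] < 2:
            raise ValueError("need at least 1 subject and 2 models")
        self.lme = lme
        self.model_names = (list(model_names) if model_names is not None
                            else [f"model_{i + 1}" for i in range(lme.shape[1])])

    def fit(self, alpha0=None, tol: float = 1e-6, max_iter: int = 200) -> "DirichletResults":
        """Iterate the variational fixed point to convergence.

        ``alpha0`` defaults to the flat Dirichlet (all ones).  Convergence:
        max |delta alpha| < tol, or ``max_iter`` sweeps (non-converged voxels
        are counted in the results).
        """
        N, M, V = self.lme.shape
        if alpha0 is None:
            alpha0 = np.ones(M)
        alpha0 = np.asarray(alpha0, dtype=float)
        alpha = np.broadcast_to(alpha0[:, None], (M, V)).copy()
        n_iter = 0
        delta = np.inf
        for n_iter in range(1, max_iter + 1):
            ln_u = self.lme + (digamma(alpha) - digamma(alpha.sum(axis=0)))[None]
            ln_u -= ln_u.max(axis=1, keepdims=True)
            u = np.exp(ln_u)
            g = u / u.sum(axis=1, keepdims=True)
            new = alpha0[:, None] + g.sum(axis=0)
            delta = np.abs(new - alpha).max()
            alpha = new
            if delta < tol:
                break
        return DirichletResults(
            model=self, alpha=alpha if self._map else alpha[:, 0],
            alpha0=alpha0, g=g if self._map else g[:, :, 0],
            n_iter=n_iter, max_delta=float(delta), converged=bool(delta < tol))


@dataclass
class DirichletResults:
    """Dirichlet posterior over model frequencies with subject attributions."""

    model: GroupBMS
    alpha: np.ndarray
    alpha0: np.ndarray
    g: np.ndarray = field(repr=False)
    n_iter: int = 0
    max_delta: float = np.nan
    converged: bool = True

    @property
    def frequency_mean(self) -> np.ndarray:
        """Posterior mean frequencies alpha / sum(alpha)."""
        return self.alpha / self.alpha.sum(axis=0, keepdims=True)

    def likeliest_frequency(self, method: str = "beta-mode") -> np.ndarray:
        return likeliest_frequency(self.alpha, method=method)

    def summary(self) -> str:
        import io
        buf = io.StringIO()
        a = self.alpha if self.alpha.ndim == 1 else self.alpha.mean(axis=1)
        lf = self.likeliest_frequency()
        lf = lf if lf.ndim == 1 else lf.mean(axis=1)
        fm = self.frequency_mean
        fm = fm if fm.ndim == 1 else fm.mean(axis=1)
        buf.write("Random-effects BMS (variational Dirichlet posterior)\n")
        buf.write(f"  N = {self.model.lme.shape[0]} subjects, "
                  f"M = {len(a)} candidates, iterations = {self.n_iter}, "
                  f"converged = {self.converged}\n")
        buf.write(f"  {'candidate':<16}{'alpha':>10}{'mean freq':>12}{'LF':>10}\n")
        for nm, al, f, l in zip(self.model.model_names, a, fm, lf):
            buf.write(f"  {nm:<16}{al:>10.3f}{f:>12.3f}{l:>10.3f}\n")
        return buf.getvalue()

    def plot_frequencies(self, ax=None):
        """Bar plot of posterior mean frequencies with LF markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fm = self.frequency_mean
        fm = fm if fm.ndim == 1 else fm.mean(axis=1)
        lf = self.likeliest_frequency()
        lf = lf if lf.ndim == 1 else lf.mean(axis=1)
        x = np.arange(len(fm))
        ax.bar(x, fm, label="posterior mean frequency")
        ax.plot(x, lf, "k_", markersize=18, label="likeliest frequency")
        ax.set_xticks(x, self.model.model_names, rotation=45, ha="right")
        ax.set_ylabel("model frequency")
        ax.legend()
        return ax


def rfx_bms(lme, alpha0=None, model_names=None, **kwargs) -> DirichletResults:
    """Convenience wrapper: ``GroupBMS(lme).fit(alpha0)``."""
    return GroupBMS(lme, model_names=model_names).fit(alpha0=alpha0, **kwargs)


def likeliest_frequency(alpha, method: str = "beta-mode") -> np.ndarray:
    """Mode of each model's marginal frequency distribution.

    ``beta-mode`` (default): mode of Beta(alpha_m, sum - alpha_m), i.e.
    (alpha_m - 1) / (sum - 2) when alpha_m > 1 and sum > 2, with the
    posterior mean as fallback where the mode is not interior.
    ``joint-mode``: component of the joint Dirichlet mode,
    (alpha_m - 1) / (sum - M).
    """
    alpha = np.asarray(alpha, dtype=float)
    s = alpha.sum(axis=0, keepdims=True)
    mean = alpha / s
    if method == "beta-mode":
        with np.errstate(invalid="ignore", divide="ignore"):
            mode = (alpha - 1.0) / (s - 2.0)
        ok = (alpha > 1.0) & (s > 2.0)
        return np.clip(np.where(ok, mode, mean), 0.0, 1.0)
    if method == "joint-mode":
        M = alpha.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            mode = (alpha - 1.0) / (s - M)
        ok = (alpha > 1.0) & (s > M)
        return np.clip(np.where(ok, mode, mean), 0.0, 1.0)
    raise ValueError(f"unknown LF method {method!r}")


@dataclass
class SelectedModelMap:
    """Per-voxel winning candidate and its likeliest frequency."""

    winner: np.ndarray                # integer index per voxel
    lf: np.ndarray                    # winner's likeliest frequency per voxel
    labels: tuple
    n_ties: int = 0

    def winner_labels(self) -> np.ndarray:
        out = np.empty(self.winner.shape, dtype=object)
        flat = np.asarray(self.labels, dtype=object)
        valid = self.winner >= 0
        out[valid] = flat[self.winner[valid]]
        return out


def selected_model_map(results: DirichletResults, labels=None,
                       lf_method: str = "beta-mode") -> SelectedModelMap:
    """Winner = argmax likeliest frequency per voxel (ties -> lowest index)."""
    lf = results.likeliest_frequency(method=lf_method)
    if lf.ndim == 1:
        lf = lf[:, None]
    if lf.size == 0:
        raise ValueError("empty mask: no voxels to select over")
    winner = np.argmax(lf, axis=0)
    n_ties = int(np.sum((lf == lf.max(axis=0, keepdims=True)).sum(axis=0) > 1))
    win_lf = np.take_along_axis(lf, winner[None], axis=0)[0]
    return SelectedModelMap(
        winner=winner, lf=win_lf,
        labels=tuple(labels if labels is not None else results.model.model_names),
        n_ties=n_ties)
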