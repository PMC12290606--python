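"""Recognition-confidence behavior: response profiles, probability curves and
subsequent-memory modulators.

During encoding, participants view novel scene photographs and two
pre-familiarized "master" images; in a later recognition test every novel
image ("old") and a set of unseen foils ("new") receives a confidence rating
on a 5-point scale from 1 = "sure new" over 3 = "don't know" to 5 = "sure
old".  This module turns those ratings into

* a :class:`ResponseProfile` (counts of each rating for old and new items),
* empirical probability curves — P(rating | old) ("inverse probability") and
  P(old | rating) ("conditional probability"),
* trial-wise parametric modulators for the six single-modulator
  subsequent-memory GLMs (three theoretical transformations of the rating,
  three empirical, data-derived ones), and
* categorical remembered/forgotten labels for the categorical memory GLMs.

All theoretical modulators are odd functions of ``rating - 3`` with endpoints
-1 and +1; empirical modulators are probabilities affinely rescaled to
[-1, +1] so that all six modulator types share a scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ResponseProfile",
    "ModulatorSeries",
    "MemoryCategorization",
    "response_profile",
    "inverse_probability",
    "conditional_probability",
    "logistic_modulator",
    "theoretical_modulator",
    "categorize_responses",
    "modulator_series",
    "MODULATOR_KINDS",
    "CATEGORIZATION_SCHEMES",
]

RESPONSES = np.arange(1, 6)

#: theoretical (a-priori) modulator transformations
MODULATOR_KINDS = ("linear", "arcsine", "sine")

#: categorization schemes: two-category with neutral-as-forgotten (2nf),
#: neutral-as-remembered (2nr), neutral split by response frequencies (2ns),
#: three-category (3) and the five-response identity (5)
CATEGORIZATION_SCHEMES = ("2nf", "2nr", "2ns", "3", "5")

#: Paper-internal naming of the empirical modulators is ambiguous between the
#: figure caption and the results text; the default follows the figure
#: convention (ip = P(response | old), cp = P(old | response)).  Setting this
#: flag swaps the assignment.
SWAP_EMPIRICAL_NAMING = False


@dataclass(frozen=True)
class ResponseProfile:
    """Counts of recognition responses 1..5, split by item status."""

    counts_old: np.ndarray
    counts_new: np.ndarray

    def __post_init__(self):
        for name in ("counts_old", "counts_new"):
            c = np.asarray(getattr(self, name), dtype=int)
            if c.shape != (5,):
                raise ValueError(f"{name} must be a 5-vector, got shape {c.shape}")
            if (c < 0).any():
                raise ValueError(f"{name} contains negative counts")
            object.__setattr__(self, name, c)

    @property
    def n_old(self) -> int:
        return int(self.counts_old.sum())

    @property
    def n_new(self) -> int:
        return int(self.counts_new.sum())


@dataclass(frozen=True)
class ModulatorSeries:
    """Per-novel-trial parametric modulator values for one memory model."""

    model_name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("modulator values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MemoryCategorization:
    """Per-novel-trial categorical label under one collapsing scheme."""

    scheme: str
    labels: np.ndarray = field(repr=False)

    @property
    def categories(self) -> tuple:
        return _scheme_categories(self.scheme)


def _check_responses(responses) -> np.ndarray:
    r = np.asarray(responses)
    if r.size and (not np.issubdtype(r.dtype, np.number) or
                   np.any((r < 1) | (r > 5) | (r != np.round(r)))):
        bad = r[(r < 1) | (r > 5)] if np.issubdtype(r.dtype, np.number) else r
        raise ValueError(f"responses must be integers in 1..5, got {bad[:5]!r}")
    return r.astype(int)


def response_profile(responses, is_old) -> ResponseProfile:
    """Count responses 1..5 separately for old and new retrieval items."""
    r = _check_responses(responses)
    old = np.asarray(is_old, dtype=bool)
    if r.shape != old.shape:
        raise ValueError("responses and is_old must have the same length")
    counts_old = np.bincount(r[old], minlength=6)[1:6]
    counts_new = np.bincount(r[~old], minlength=6)[1:6]
    return ResponseProfile(counts_old, counts_new)


def inverse_probability(profile: ResponseProfile) -> np.ndarray:
    """P(response = y | item old): old-item counts normalized to sum 1."""
    if profile.n_old == 0:
        raise ValueError("inverse probability undefined: no old items")
    return profile.counts_old / profile.n_old


def conditional_probability(profile: ResponseProfile, fill: float = 0.5) -> np.ndarray:
    """P(item old | response = y) per response, empty cells imputed with `fill`.

    A response level never given to any retrieval item carries no information
    about oldness, hence the uninformative default of 0.5.
    """
    tot = profile.counts_old + profile.counts_new
    out = np.full(5, float(fill))
    nz = tot > 0
    out[nz] = profile.counts_old[nz] / tot[nz]
    return out


def logistic_modulator(responses, is_old, clip: float = 1e-3) -> np.ndarray:
    """Fitted P(old | response y) from a logistic regression of oldness on
    the (numeric) response, evaluated at y = 1..5.

    Falls back to clipped empirical conditional probabilities under complete
    separation, where the ML estimate diverges.
    """
    r = _check_responses(responses).astype(float)
    old = np.asarray(is_old, dtype=float)
    if old.sum() == 0 or old.sum() == old.size:
        raise ValueError("logistic fit requires both old and new items")
    import statsmodels.api as sm

    X = sm.add_constant(r)
    grid = sm.add_constant(RESPONSES.astype(float))
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(old, X).fit(disp=0)
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params[1]) > 50:
            raise ValueError("separation")
        return fit.predict(grid)
    except Exception:
        prof = response_profile(responses, is_old)
        return np.clip(conditional_probability(prof), clip, 1 - clip)


def theoretical_modulator(response, kind: str):
    """A-priori transformation of the rating to [-1, +1].

    linear: (y-3)/2 — equidistant steps; arcsine: asin((y-3)/2)*2/pi —
    down-weights the "probably" ratings 2/4 relative to the "sure" ratings;
    sine: sin(pi*(y-3)/4) — up-weights them.  All are odd around y = 3 and
    hit -1/+1 at y = 1/5.
    """
    y = _check_responses(np.atleast_1d(response)).astype(float)
    x = (y - 3.0) / 2.0
    if kind == "linear":
        out = x
    elif kind == "arcsine":
        out = np.arcsin(x) * 2.0 / np.pi
    elif kind == "sine":
        out = np.sin(x * np.pi / 2.0)
    else:
        raise ValueError(f"unknown modulator kind {kind!r}; expected one of {MODULATOR_KINDS}")
    return out if np.ndim(response) else float(out[0])


def _scheme_categories(scheme: str) -> tuple:
    if scheme in ("2nf", "2nr", "2ns"):
        return ("forgotten", "remembered")
    if scheme == "3":
        return ("new", "dont_know", "old")
    if scheme == "5":
        return ("1", "2", "3", "4", "5")
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {CATEGORIZATION_SCHEMES}")


def categorize_responses(responses, scheme: str, seed: int | None = None) -> MemoryCategorization:
    """Collapse ratings into memory categories.

    2nf/2nr/2ns map {4,5} to remembered and {1,2} to forgotten; neutral
    "don't know" ratings (3) are routed per scheme: nf = forgotten,
    nr = remembered, ns = random split proportional to the subject's own
    remembered/forgotten frequencies (seeded).  Scheme 3 collapses "probably"
    and "sure" ratings into old/new around a don't-know category; scheme 5
    keeps all five ratings.
    """
    r = _check_responses(responses)
    _scheme_categories(scheme)  # validates the name
    labels = np.empty(r.shape, dtype=object)
    if scheme == "5":
        labels[:] = r.astype(str)
    elif scheme == "3":
        labels[np.isin(r, (1, 2))] = "new"
        labels[r == 3] = "dont_know"
        labels[np.isin(r, (4, 5))] = "old"
    else:
        labels[np.isin(r, (1, 2))] = "forgotten"
        labels[np.isin(r, (4, 5))] = "remembered"
        neutral = r == 3
        if scheme == "2nf":
            labels[neutral] = "forgotten"
        elif scheme == "2nr":
            labels[neutral] = "remembered"
        else:  # 2ns: split proportional to non-neutral frequencies
            n_rem = int(np.isin(r, (4, 5)).sum())
            n_for = int(np.isin(r, (1, 2)).sum())
            p_rem = n_rem / (n_rem + n_for) if (n_rem + n_for) else 0.5
            rng = np.random.default_rng(seed)
            draw = rng.random(int(neutral.sum())) < p_rem
            labels[neutral] = np.where(draw, "remembered", "forgotten")
    return MemoryCategorization(scheme=scheme, labels=labels)


def _empirical_curve(which: str, responses, is_old) -> np.ndarray:
    """Empirical modulator curve per response 1..5, on the probability scale."""
    prof = response_profile(responses, is_old)
    if which == "cp":
        return conditional_probability(prof)
    if which == "ip":
        return inverse_probability(prof)
    if which == "lr":
        return logistic_modulator(responses, is_old)
    raise ValueError(which)


def modulator_series(novel_responses, model_name: str,
                     retrieval_responses=None, retrieval_is_old=None) -> ModulatorSeries:
    """Per-trial modulator values for one of the six parametric memory models.

    ``model_name`` is one of ``1t-l``, ``1t-a``, ``1t-s`` (theoretical, no
    retrieval data needed beyond the trial's own later rating) or ``1e-cp``,
    ``1e-ip``, ``1e-lr`` (empirical: curves estimated from the full retrieval
    outcome including new-item foils, then rescaled to [-1, +1] via
    ``v -> 2 v - 1``).
    """
    r = _check_responses(novel_responses)
    name = model_name.removeprefix("GLM_")
    theory = {"1t-l": "linear", "1t-a": "arcsine", "1t-s": "sine"}
    if name in theory:
        values = theoretical_modulator(r, theory[name])
    elif name in ("1e-cp", "1e-ip", "1e-lr"):
        if retrieval_responses is None or retrieval_is_old is None:
            raise ValueError("empirical modulators need retrieval responses and old/new labels")
        which = name.split("-")[1]
        if SWAP_EMPIRICAL_NAMING and which in ("cp", "ip"):
            which = {"cp": "ip", "ip": "cp"}[which]
        curve = _empirical_curve(which, retrieval_responses, retrieval_is_old)
        values = 2.0 * curve[r - 1] - 1.0
    else:
        raise ValueError(f"unknown parametric memory model {model_name!r}")
    return ModulatorSeries(model_name=model_name, values=np.asarray(values, dtype=float))


def modulator_table(novel_responses, retrieval_responses, retrieval_is_old) -> pd.DataFrame:
    """All six modulator series as a tidy table (trial, model, value)."""
    frames = []
    for name in ("1t-l", "1t-a", "1t-s", "1e-cp", "1e-ip", "1e-lr"):
        s = modulator_series(novel_responses, name, retrieval_responses, retrieval_is_old)
        frames.append(pd.DataFrame({
            "trial": np.arange(len(s.values)),
            "model": name,
            "value": s.values,
        }))
    return pd.concat(frames, ignore_index=True)


def plot_response_profile(profile: ResponseProfile, ax=None):
    """Bar plot of P(response | old) and P(old | response) side by side."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w = 0.4
    ax.bar(RESPONSES - w / 2, inverse_probability(profile), width=w,
           label="P(response | old)")
    ax.bar(RESPONSES + w / 2, conditional_probability(profile), width=w,
           label="P(old | response)")
    ax.set_xlabel("recognition-confidence response")
    ax.set_ylabel("probability")
    ax.legend()
    return ax
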