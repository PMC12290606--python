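"""The 19-model first-level GLM space and design-matrix construction.

Every model is a variation of a baseline GLM with a novelty regressor (novel
scene images), a master regressor (pre-familiarized repeated images), six
head-motion regressors, discrete-cosine drift regressors and a constant.

Variations of no interest cross three binary choices — event duration
(actual 2.5 s trials vs. point events), modeling novel and master images
separately vs. collapsed, and splitting indoor/outdoor scenes vs. collapsed
— giving 8 models named ``GLM_{TD|PE}_{0|00}x{1|2}``.  Subsequent-memory
models modify the baseline (trial duration, separate novelty, collapsed
scenes) by replacing the novelty regressor with 2, 3 or 5 categorical
regressors (``GLM_2nf/2nr/2ns``, ``GLM_3``, ``GLM_5``) or by adding a single
parametric modulator of the novelty regressor (theoretical: ``GLM_1t-l/a/s``;
empirical: ``GLM_1e-cp/ip/lr``), for 8 + 5 + 3 + 3 = 19 models in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "EstimabilityError",
    "enumerate_models",
    "model_space",
    "families",
    "hrf_regressor",
    "cosine_drift",
    "build_design",
    "estimable",
    "BASELINE_MODEL",
]

BASELINE_MODEL = "GLM_TD_0x1"

#: microtime bins per scan used for HRF convolution
OVERSAMPLING = 16

#: high-pass drift cutoff in seconds (discrete-cosine basis)
DRIFT_CUTOFF = 128.0


class EstimabilityError(ValueError):
    """A model's design cannot be estimated for this subject's events."""


@dataclass(frozen=True)
class ModelSpec:
    """One of the 19 first-level GLMs.

    ``memory_mode`` is ``None`` for the models of no interest,
    ``("categorical", scheme)`` or ``("parametric", modulator)`` for the
    subsequent-memory models, which are all built on the baseline basis
    (trial duration, separate novelty, collapsed scenes).
    """

    name: str
    duration_mode: str            # "trial" | "point"
    novelty_split: bool           # separate novelty/master regressors
    scene_split: bool             # separate indoor/outdoor regressors
    memory_mode: tuple | None
    family_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.memory_mode is not None and (
            self.duration_mode != "trial" or not self.novelty_split or self.scene_split
        ):
            raise ValueError("memory models must use the baseline basis "
                             "(trial duration, separate novelty, collapsed scenes)")


@dataclass(frozen=True)
class DesignMatrix:
    """Realized design: n_scans x p values with column labels."""

    values: np.ndarray = field(repr=False)
    column_labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.column_labels):
            raise ValueError("values shape does not match column labels")
        object.__setattr__(self, "values", v)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_labels))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def enumerate_models() -> list[ModelSpec]:
    """The full 19-model space with family tags.

    Family tags of the no-interest crossing (GLMs_TD/PE, GLMs_0/00,
    GLMs_x1/x2) are assigned within the 8 no-interest models, so that each of
    those families has 4 members and family comparisons are balanced.
    Memory families: GLMs_2 (3 two-category models), GLMs_1t and GLMs_1e
    (3 each), GLMs_1 = their union (6), GLMs_12 = GLMs_1 + GLMs_2 (9).
    """
    specs = []
    for dur, dtag in (("trial", "TD"), ("point", "PE")):
        for nov, ntag in ((True, "0"), (False, "00")):
            for scene, stag in ((False, "x1"), (True, "x2")):
                tags = {f"GLMs_{dtag}", f"GLMs_{ntag}", f"GLMs_{stag}"}
                specs.append(ModelSpec(
                    name=f"GLM_{dtag}_{ntag}{stag}",
                    duration_mode=dur, novelty_split=nov, scene_split=scene,
                    memory_mode=None, family_tags=frozenset(tags)))
    for scheme in ("2nf", "2nr", "2ns"):
        specs.append(ModelSpec(
            name=f"GLM_{scheme}", duration_mode="trial", novelty_split=True,
            scene_split=False, memory_mode=("categorical", scheme),
            family_tags=frozenset({"GLMs_2", "GLMs_12"})))
    for scheme in ("3", "5"):
        specs.append(ModelSpec(
            name=f"GLM_{scheme}", duration_mode="trial", novelty_split=True,
            scene_split=False, memory_mode=("categorical", scheme),
            family_tags=frozenset()))
    for mod, sub in (("1t-l", "1t"), ("1t-a", "1t"), ("1t-s", "1t"),
                     ("1e-cp", "1e"), ("1e-ip", "1e"), ("1e-lr", "1e")):
        specs.append(ModelSpec(
            name=f"GLM_{mod}", duration_mode="trial", novelty_split=True,
            scene_split=False, memory_mode=("parametric", mod),
            family_tags=frozenset({f"GLMs_{sub}", "GLMs_1", "GLMs_12"})))
    return specs


def model_space() -> dict[str, ModelSpec]:
    return {m.name: m for m in enumerate_models()}


def families() -> dict[str, list[str]]:
    """Mapping family tag -> member model names."""
    fams: dict[str, list[str]] = {}
    for m in enumerate_models():
        for tag in m.family_tags:
            fams.setdefault(tag, []).append(m.name)
    return {k: sorted(v) for k, v in sorted(fams.items())}


def model_space_table() -> pd.DataFrame:
    """Listing of the model space (name, families, task-column count)."""
    rows = []
    for m in enumerate_models():
        rows.append({
            "name": m.name,
            "families": ",".join(sorted(m.family_tags)),
            "n_task_columns": _n_task_columns(m),
        })
    return pd.DataFrame(rows)


def _n_task_columns(spec: ModelSpec) -> int:
    if spec.memory_mode is None:
        per_cond = 2 if spec.scene_split else 1
        return per_cond * (2 if spec.novelty_split else 1)
    kind, arg = spec.memory_mode
    if kind == "categorical":
        return len(behavior._scheme_categories(arg)) + 1  # + master
    return 3  # novelty, modulated novelty, master


def hrf_regressor(onsets, durations, amplitudes, n_scans: int, tr: float,
                  oversampling: int = OVERSAMPLING) -> np.ndarray:
    """Convolved event regressor sampled at scan times.

    Boxcars (sticks for zero duration) scaled by per-event amplitudes are
    convolved with the canonical double-gamma haemodynamic response on a fine
    time grid and resampled at ``t = 0, tr, 2 tr, ...``.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape).copy()
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape).copy()
    if onsets.size == 0:
        return np.zeros(n_scans)
    if np.any(durations < 0):
        raise ValueError("negative event duration")
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("non-finite event amplitude")
    total = n_scans * tr
    if np.any(onsets < 0) or np.any(onsets + durations > total):
        raise ValueError(f"event outside the scan window [0, {total:.2f}] s")
    from nilearn.glm.first_level.hemodynamic_models import compute_regressor

    frame_times = np.arange(n_scans) * tr
    cond = np.vstack([onsets, durations, amplitudes])
    reg, _ = compute_regressor(cond, "glover", frame_times, oversampling=oversampling)
    return reg[:, 0]


def cosine_drift(n_scans: int, tr: float, cutoff: float = DRIFT_CUTOFF) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (without the constant term).

    Number of columns K = floor(2 * T / cutoff) with T the run duration, the
    convention of standard fMRI analysis packages for a 1/cutoff Hz high-pass.
    """
    n_col = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_scans))
            for k in range(1, n_col + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


def _novel_mask(events: pd.DataFrame) -> np.ndarray:
    return (events["trial_type"] == "novel").to_numpy()


def _task_columns(events: pd.DataFrame, spec: ModelSpec, n_scans: int, tr: float,
                  retrieval: pd.DataFrame | None, seed: int):
    """Build the task regressors (labels, columns) for one model."""
    onset = events["onset"].to_numpy(dtype=float)
    dur = events["duration"].to_numpy(dtype=float)
    if spec.duration_mode == "point":
        dur = np.zeros_like(dur)
    novel = _novel_mask(events)
    indoor = (events["subtype"] == "indoor").to_numpy()

    def col(mask, amplitudes=None):
        amp = np.ones(int(mask.sum())) if amplitudes is None else amplitudes
        return hrf_regressor(onset[mask], dur[mask], amp, n_scans, tr)

    labels, cols = [], []
    if spec.memory_mode is None:
        conds = ([("novelty", novel), ("master", ~novel)] if spec.novelty_split
                 else [("events", np.ones_like(novel, dtype=bool))])
        for cname, cmask in conds:
            if spec.scene_split:
                for sname, smask in (("indoor", indoor), ("outdoor", ~indoor)):
                    labels.append(f"{cname}_{sname}")
                    cols.append(col(cmask & smask))
            else:
                labels.append(cname)
                cols.append(col(cmask))
        return labels, cols

    responses = events.loc[novel, "response"].to_numpy()
    if np.any(pd.isna(responses)):
        raise ValueError("novel trials without a memory response")
    responses = responses.astype(int)
    kind, arg = spec.memory_mode
    if kind == "categorical":
        cat = behavior.categorize_responses(responses, arg, seed=seed)
        for c in cat.categories:
            sel = np.zeros_like(novel)
            sel[np.flatnonzero(novel)[cat.labels == c]] = True
            if not sel.any():
                raise EstimabilityError(
                    f"{spec.name}: category {c!r} has no trials for this subject")
            labels.append(f"memory_{c}")
            cols.append(col(sel))
    else:
        if retrieval is not None:
            series = behavior.modulator_series(
                responses, arg,
                retrieval_responses=retrieval["response"].to_numpy(),
                retrieval_is_old=(retrieval["status"] == "old").to_numpy())
        else:
            series = behavior.modulator_series(responses, arg)
        centered = series.values - series.values.mean()
        if np.allclose(centered, 0.0):
            raise EstimabilityError(
                f"{spec.name}: modulator constant across trials (degenerate)")
        labels.append("novelty")
        cols.append(col(novel))
        labels.append(f"novelty_x_{arg}")
        cols.append(col(novel, amplitudes=centered))
    labels.append("master")
    cols.append(col(~novel))
    return labels, cols


def build_design(events: pd.DataFrame, motion, spec: ModelSpec,
                 n_scans: int, tr: float, retrieval: pd.DataFrame | None = None,
                 drift: bool = True, seed: int = 0) -> DesignMatrix:
    """Realize a model as a design matrix for one subject.

    Parameters
    ----------
    events : table with columns onset, duration, trial_type (novel/master),
        subtype (indoor/outdoor) and response (1..5, NA for master trials).
    motion : n_scans x 6 head-motion parameters.
    retrieval : table with columns status (old/new) and response, needed by
        the empirical parametric models (1e-*).
    drift : include the discrete-cosine high-pass basis (128 s cutoff);
        identical across models so that model comparisons stay fair.
    seed : RNG seed for the frequency-proportional neutral split of GLM_2ns.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_scans, 6):
        raise ValueError(f"motion must be {n_scans} x 6, got {motion.shape}")
    labels, cols = _task_columns(events, spec, n_scans, tr, retrieval, seed)
    X = [np.column_stack(cols), motion]
    labels += [f"motion_{i}" for i in range(1, 7)]
    if drift:
        D = cosine_drift(n_scans, tr)
        X.append(D)
        labels += [f"drift_{i}" for i in range(1, D.shape[1] + 1)]
    X.append(np.ones((n_scans, 1)))
    labels.append("constant")
    values = np.column_stack(X)
    task = values[:, :len(cols)]
    dead = np.flatnonzero(~task.any(axis=0))
    if dead.size:
        raise EstimabilityError(
            f"{spec.name}: all-zero task columns {[labels[i] for i in dead]}")
    return DesignMatrix(values=values, column_labels=tuple(labels))


def estimable(spec: ModelSpec, events: pd.DataFrame, seed: int = 0) -> bool:
    """Can this model be estimated from this subject's events?

    Categorical models need at least one trial in every category (the
    five-category model only exists for subjects using the full response
    range); parametric models need a non-constant modulator.
    """
    novel = _novel_mask(events)
    if spec.memory_mode is None:
        return bool(novel.any()) and (spec.novelty_split is False or bool((~novel).any()))
    responses = events.loc[novel, "response"].dropna().astype(int).to_numpy()
    if responses.size == 0:
        return False
    kind, arg = spec.memory_mode
    if kind == "parametric":
        return np.unique(responses).size >= 2
    cat = behavior.categorize_responses(responses, arg, seed=seed)
    return all((cat.labels == c).any() for c in cat.categories)
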