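"""Synthetic cohort generator with known voxel-wise ground truth.

Emulates the structure of a multi-group visual memory-encoding fMRI study:
each subject sees 88 novel scene photographs (44 indoor, 44 outdoor) and 44
repetitions of two pre-familiarized "master" images within a single 206-scan
session (TR 2.58 s), then rates all old images plus new foils on a 5-point
recognition-confidence scale.  Diagnostic groups (HC, SCD, MCI, AD, AD-rel)
are graded both behaviorally — the coupling between rating and item oldness
declines from healthy controls towards Alzheimer's disease — and in their
BOLD effect sizes (novelty effects shrink, memory effects vanish in AD).

The voxel grid is partitioned into four regions with distinct generative
models: ``novelty_only`` (novel > master activation, no memory effect),
``novelty_plus_memory`` (novelty plus an arcsine-transformed subsequent
memory modulation), ``deactivation`` (novelty-locked deactivation) and
``null`` (noise only).  The true generative design uses the same HRF and
design conventions as the analysis side, so that with vanishing noise the
first-level estimates recover the true amplitudes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import designs

__all__ = [
    "BehaviorProfile",
    "CohortSpec",
    "GroundTruth",
    "simulate_behavior",
    "simulate_bold",
    "simulate_cohort",
    "load_subject",
    "load_cohort",
    "DEFAULT_PROFILES",
    "DEFAULT_EFFECT_SIZES",
    "GROUPS",
    "REGIONS",
]

GROUPS = ("HC", "SCD", "MCI", "AD", "AD-rel")
REGIONS = ("novelty_only", "novelty_plus_memory", "deactivation", "null")

#: generative model per region (label "noise_only" marks pure-noise voxels)
REGION_MODELS = {
    "novelty_only": "GLM_TD_0x1",
    "novelty_plus_memory": "GLM_1t-a",
    "deactivation": "GLM_TD_0x1",
    "null": "noise_only",
}


@dataclass(frozen=True)
class BehaviorProfile:
    """Response-probability vectors P(rating | old) and P(rating | new)."""

    p_response_given_old: np.ndarray
    p_response_given_new: np.ndarray
    name: str = ""

    def __post_init__(self):
        for attr in ("p_response_given_old", "p_response_given_new"):
            p = np.asarray(getattr(self, attr), dtype=float)
            who = f" for group {self.name!r}" if self.name else ""
            if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"invalid probability vector {attr}{who}: "
                    "must be 5 non-negative entries summing to 1")
            object.__setattr__(self, attr, p)


# Group-graded behavior: hit rate P(rating 4-5 | old) falls from ~0.75 in
# healthy controls (and SCD / AD relatives, behaviorally indistinguishable)
# to ~0.55 in MCI and ~0.40 (near guessing) in AD.
DEFAULT_PROFILES = {
    "HC": BehaviorProfile((0.05, 0.08, 0.12, 0.25, 0.50),
                          (0.45, 0.25, 0.15, 0.10, 0.05), "HC"),
    "SCD": BehaviorProfile((0.06, 0.09, 0.12, 0.26, 0.47),
                           (0.43, 0.25, 0.16, 0.10, 0.06), "SCD"),
    "MCI": BehaviorProfile((0.10, 0.15, 0.20, 0.25, 0.30),
                           (0.35, 0.24, 0.19, 0.13, 0.09), "MCI"),
    "AD": BehaviorProfile((0.15, 0.20, 0.25, 0.22, 0.18),
                          (0.25, 0.22, 0.23, 0.17, 0.13), "AD"),
    "AD-rel": BehaviorProfile((0.05, 0.08, 0.12, 0.25, 0.50),
                              (0.45, 0.25, 0.15, 0.10, 0.05), "AD-rel"),
}

# BOLD amplitudes (signal units against noise SD 1): novelty effects are
# reduced in MCI and markedly diminished in AD; the subsequent-memory
# modulation is preserved in SCD/AD-rel, weak in MCI and absent in AD.
DEFAULT_EFFECT_SIZES = {
    "HC": {"novelty_only": {"novelty": 1.0},
           "novelty_plus_memory": {"novelty": 1.0, "memory": 0.5},
           "deactivation": {"novelty": -0.8}, "null": {}},
    "SCD": {"novelty_only": {"novelty": 1.0},
            "novelty_plus_memory": {"novelty": 1.0, "memory": 0.5},
            "deactivation": {"novelty": -0.8}, "null": {}},
    "MCI": {"novelty_only": {"novelty": 0.8},
            "novelty_plus_memory": {"novelty": 0.8, "memory": 0.15},
            "deactivation": {"novelty": -0.6}, "null": {}},
    "AD": {"novelty_only": {"novelty": 0.5},
           "novelty_plus_memory": {"novelty": 0.5, "memory": 0.0},
           "deactivation": {"novelty": -0.4}, "null": {}},
    "AD-rel": {"novelty_only": {"novelty": 1.0},
               "novelty_plus_memory": {"novelty": 1.0, "memory": 0.5},
               "deactivation": {"novelty": -0.8}, "null": {}},
}

DEFAULT_DEMOGRAPHICS = {
    "HC": {"age_mean": 69.3, "age_sd": 5.5, "p_male": 0.38},
    "SCD": {"age_mean": 70.4, "age_sd": 5.9, "p_male": 0.55},
    "MCI": {"age_mean": 73.0, "age_sd": 5.1, "p_male": 0.47},
    "AD": {"age_mean": 72.6, "age_sd": 5.4, "p_male": 0.38},
    "AD-rel": {"age_mean": 65.9, "age_sd": 4.7, "p_male": 0.39},
}

N_SITES = 8
BASELINE_SIGNAL = 100.0


def default_region_layout(grid_shape) -> dict[str, np.ndarray]:
    """Partition the grid into four equal slabs along the first axis."""
    nx = grid_shape[0]
    idx = np.arange(int(np.prod(grid_shape))).reshape(grid_shape)
    bounds = np.linspace(0, nx, 5).astype(int)
    return {r: idx[bounds[i]:bounds[i + 1]].ravel()
            for i, r in enumerate(REGIONS)}


@dataclass
class CohortSpec:
    """Full configuration of one synthetic cohort."""

    group_sizes: dict
    grid_shape: tuple = (12, 12, 4)
    n_scans: int = 206
    tr: float = 2.58
    n_novel: int = 88
    n_master: int = 44
    n_new_foils: int = 44
    trial_duration: float = 2.5
    iti_range: tuple = (3.2, 3.8)
    t_start: float = 8.0
    region_layout: dict | None = None
    effect_sizes: dict | None = None
    behavior_profiles: dict | None = None
    noise: dict = field(default_factory=lambda: {"sigma": 1.0, "ar1": 0.3})
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        if not (0 <= self.noise["ar1"] < 1):
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.region_layout is None:
            self.region_layout = default_region_layout(self.grid_shape)
        else:
            self.region_layout = {k: np.asarray(v, dtype=int)
                                  for k, v in self.region_layout.items()}
        flat = np.concatenate([v for v in self.region_layout.values()]) \
            if self.region_layout else np.array([], dtype=int)
        if flat.size != np.unique(flat).size:
            raise ValueError("regions must be disjoint")
        if self.effect_sizes is None:
            self.effect_sizes = DEFAULT_EFFECT_SIZES
        if self.behavior_profiles is None:
            self.behavior_profiles = DEFAULT_PROFILES
        n_trials = self.n_novel + self.n_master
        worst_end = (self.t_start + (n_trials - 1) * self.iti_range[1]
                     + self.trial_duration)
        if worst_end > self.n_scans * self.tr:
            raise ValueError(
                f"{n_trials} trials cannot fit within {self.n_scans * self.tr:.1f} s "
                f"(worst-case end {worst_end:.1f} s)")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def subjects(self) -> list[tuple[str, str]]:
        out, i = [], 0
        for g in GROUPS:
            for _ in range(self.group_sizes.get(g, 0)):
                i += 1
                out.append((f"sub-{i:02d}", g))
        return out


@dataclass
class GroundTruth:
    """Generative model label and true amplitudes for every voxel."""

    grid_shape: tuple
    regions: dict                    # region name -> flat voxel indices
    effects: dict                    # region name -> {regressor: amplitude}

    def labels(self) -> np.ndarray:
        lab = np.empty(int(np.prod(self.grid_shape)), dtype=object)
        lab[:] = "noise_only"
        for r, idx in self.regions.items():
            lab[idx] = REGION_MODELS[r]
        return lab

    def region_of(self) -> np.ndarray:
        reg = np.empty(int(np.prod(self.grid_shape)), dtype=object)
        reg[:] = "null"
        for r, idx in self.regions.items():
            reg[idx] = r
        return reg

    def to_json(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "regions": {k: np.asarray(v).tolist() for k, v in self.regions.items()},
            "effects": self.effects,
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        return cls(grid_shape=tuple(d["grid_shape"]),
                   regions={k: np.asarray(v, dtype=int) for k, v in d["regions"].items()},
                   effects=d["effects"])


def simulate_behavior(profile: BehaviorProfile, n_old: int, n_new: int,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw recognition responses for old and new retrieval items.

    Returns a table with columns ``status`` (old/new) and ``response``
    (1..5), old items first; draws are independent across items.
    """
    if n_old < 0 or n_new < 0:
        raise ValueError("item counts must be non-negative")
    rng = np.random.default_rng(seed)
    r_old = rng.choice(5, size=n_old, p=profile.p_response_given_old) + 1
    r_new = rng.choice(5, size=n_new, p=profile.p_response_given_new) + 1
    return pd.DataFrame({
        "status": ["old"] * n_old + ["new"] * n_new,
        "response": np.concatenate([r_old, r_new]),
    })


def make_events(spec: CohortSpec, responses_old: np.ndarray,
                rng: np.random.Generator) -> pd.DataFrame:
    """Randomized trial schedule: onsets, types and later memory responses.

    Trial order is a uniform shuffle of the condition labels; onset-to-onset
    intervals are drawn uniformly from ``spec.iti_range`` so that all trials
    fit inside the scan window.
    """
    half_nov, half_mas = spec.n_novel // 2, spec.n_master // 2
    types = (["novel"] * spec.n_novel) + (["master"] * spec.n_master)
    subtypes = (["indoor"] * half_nov + ["outdoor"] * (spec.n_novel - half_nov)
                + ["indoor"] * half_mas + ["outdoor"] * (spec.n_master - half_mas))
    order = rng.permutation(len(types))
    n = len(types)
    itis = rng.uniform(*spec.iti_range, size=n - 1)
    onsets = spec.t_start + np.concatenate([[0.0], np.cumsum(itis)])
    ev = pd.DataFrame({
        "onset": np.round(onsets, 3),
        "duration": spec.trial_duration,
        "trial_type": np.asarray(types, dtype=object)[order],
        "subtype": np.asarray(subtypes, dtype=object)[order],
        "response": np.nan,
    })
    novel_rows = np.flatnonzero((ev["trial_type"] == "novel").to_numpy())
    if len(responses_old) != len(novel_rows):
        raise ValueError("one old-item response per novel trial required")
    ev.loc[novel_rows, "response"] = responses_old.astype(float)
    return ev


def _true_signal(events: pd.DataFrame, truth: GroundTruth,
                 n_scans: int, tr: float) -> np.ndarray:
    """Noise-free signal per voxel (V x n_scans), from the generative models."""
    space = designs.model_space()
    signal = np.zeros((int(np.prod(truth.grid_shape)), n_scans))
    for region, idx in truth.regions.items():
        effects = truth.effects.get(region, {})
        if not effects or REGION_MODELS[region] == "noise_only":
            continue
        spec = space[REGION_MODELS[region]]
        labels, cols = designs._task_columns(events, spec, n_scans, tr, None, 0)
        amp = {"novelty": effects.get("novelty", 0.0),
               "novelty_x_1t-a": effects.get("memory", 0.0),
               "master": effects.get("master", 0.0)}
        sig = sum(amp.get(lab, 0.0) * c for lab, c in zip(labels, cols))
        signal[idx] = sig
    return signal


def simulate_bold(events: pd.DataFrame, truth: GroundTruth, noise: dict,
                  n_scans: int, tr: float, seed: int | None = None):
    """Forward model: convolved design times true amplitudes plus AR(1) noise.

    Returns (4D BOLD array over the truth's grid, n_scans x 6 motion table).
    Motion parameters are smooth low-amplitude random walks and do not enter
    the signal (they are nuisance regressors on the analysis side only).
    """
    total = n_scans * tr
    if np.any(events["onset"] + events["duration"] > total):
        raise ValueError("event beyond the end of the scan window")
    rng = np.random.default_rng(seed)
    V = int(np.prod(truth.grid_shape))
    signal = _true_signal(events, truth, n_scans, tr)
    sigma, rho = float(noise["sigma"]), float(noise["ar1"])
    eps = np.zeros((V, n_scans))
    if sigma > 0:
        z = rng.standard_normal((V, n_scans))
        eps[:, 0] = sigma * z[:, 0]
        innov = sigma * np.sqrt(1.0 - rho ** 2)
        for t in range(1, n_scans):
            eps[:, t] = rho * eps[:, t - 1] + innov * z[:, t]
    data = (BASELINE_SIGNAL + signal + eps).reshape(*truth.grid_shape, n_scans)
    steps = np.concatenate([rng.normal(0, 0.02, (n_scans, 3)),
                            rng.normal(0, 5e-4, (n_scans, 3))], axis=1)
    motion = np.cumsum(steps, axis=0)
    return data, motion


def simulate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a complete synthetic dataset to ``out_dir``.

    One directory per subject (events.tsv, retrieval.tsv, bold.nii,
    motion.txt), a participants.tsv, the serialized ground truth per group
    and the cohort configuration.  Fully deterministic given ``spec.seed``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValueError(f"cannot create output directory {out}: {e}") from e
    root = np.random.SeedSequence(spec.seed)
    site_rng, demo_rng = [np.random.default_rng(s) for s in root.spawn(2)]
    subj_seeds = root.spawn(len(spec.subjects))

    rows = []
    truths = {}
    for (sid, group), sseq in zip(spec.subjects, subj_seeds):
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        rng_beh, rng_ev, rng_bold = [np.random.default_rng(s) for s in sseq.spawn(3)]
        profile = spec.behavior_profiles[group]
        retrieval = simulate_behavior(profile, spec.n_novel, spec.n_new_foils,
                                      seed=rng_beh.integers(2 ** 31))
        old_resp = retrieval.loc[retrieval["status"] == "old", "response"].to_numpy()
        events = make_events(spec, old_resp, rng_ev)
        if group not in truths:
            truths[group] = GroundTruth(grid_shape=spec.grid_shape,
                                        regions=spec.region_layout,
                                        effects=spec.effect_sizes[group])
        data, motion = simulate_bold(events, truths[group], spec.noise,
                                     spec.n_scans, spec.tr,
                                     seed=rng_bold.integers(2 ** 31))
        events.to_csv(sdir / "events.tsv", sep="\t", index=False, na_rep="NA")
        retrieval.to_csv(sdir / "retrieval.tsv", sep="\t", index=False)
        np.savetxt(sdir / "motion.txt", motion, fmt="%.6f")
        nib.save(nib.Nifti1Image(data.astype(np.float32), np.diag([3, 3, 3, 1])),
                 sdir / "bold.nii")
        demo = DEFAULT_DEMOGRAPHICS[group]
        rows.append({
            "id": sid, "group": group,
            "age": float(np.clip(np.round(
                demo_rng.normal(demo["age_mean"], demo["age_sd"]), 1), 55, 90)),
            "gender": "m" if demo_rng.random() < demo["p_male"] else "f",
            "site": int(site_rng.integers(1, N_SITES + 1)),
            "education_years": float(np.clip(np.round(
                demo_rng.normal(14, 3), 1), 8, 22)),
            "employment_years": float(np.clip(np.round(
                demo_rng.normal(30, 10), 1), 0, 50)),
        })
    participants = pd.DataFrame(rows)
    participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    gt = {g: t.to_json() for g, t in truths.items()}
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    cfg = {
        "group_sizes": spec.group_sizes, "grid_shape": list(spec.grid_shape),
        "n_scans": spec.n_scans, "tr": spec.tr, "n_novel": spec.n_novel,
        "n_master": spec.n_master, "noise": spec.noise, "seed": spec.seed,
    }
    (out / "cohort.json").write_text(json.dumps(cfg, indent=1))
    return {"dir": out, "participants": participants, "ground_truth": truths}


def load_subject(subject_dir):
    """Read one subject's events, retrieval outcomes, BOLD data and motion."""
    sdir = Path(subject_dir)
    for fname in ("events.tsv", "bold.nii", "motion.txt"):
        if not (sdir / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {sdir}")
    events = pd.read_csv(sdir / "events.tsv", sep="\t", na_values="NA")
    retrieval = (pd.read_csv(sdir / "retrieval.tsv", sep="\t")
                 if (sdir / "retrieval.tsv").exists() else None)
    img = nib.load(sdir / "bold.nii")
    motion = np.loadtxt(sdir / "motion.txt")
    return {"events": events, "retrieval": retrieval,
            "bold": np.asarray(img.dataobj, dtype=float), "affine": img.affine,
            "motion": motion}


def load_cohort(data_dir):
    """Read the participants table and enumerate subject directories."""
    d = Path(data_dir)
    part = d / "participants.tsv"
    if not part.exists():
        raise FileNotFoundError(f"missing participants.tsv in {d}")
    participants = pd.read_csv(part, sep="\t")
    gt_path = d / "ground_truth.json"
    truth = None
    if gt_path.exists():
        truth = {g: GroundTruth.from_json(v)
                 for g, v in json.loads(gt_path.read_text()).items()}
    return {"dir": d, "participants": participants, "ground_truth": truth,
            "subject_dirs": {row.id: d / row.id for row in participants.itertuples()}}
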