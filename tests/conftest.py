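import numpy as np
import pytest

from cvbms import cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Mixed HC/AD cohort on a small grid, simulated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    spec = cohort.CohortSpec(group_sizes={"HC": 3, "AD": 3},
                             grid_shape=(8, 8, 2), seed=11)
    manifest = cohort.simulate_cohort(spec, out)
    ds = cohort.load_cohort(out)
    subjects = {s: dict(cohort.load_subject(d), tr=spec.tr)
                for s, d in ds["subject_dirs"].items()}
    return {"spec": spec, "manifest": manifest, "dataset": ds,
            "subjects": subjects}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def hc_events():
    """One subject's event schedule and retrieval outcomes (HC-like)."""
    spec = cohort.CohortSpec(group_sizes={"HC": 1}, grid_shape=(4, 4, 1), seed=3)
    retrieval = cohort.simulate_behavior(cohort.DEFAULT_PROFILES["HC"],
                                         spec.n_novel, spec.n_new_foils, seed=2)
    old = retrieval.loc[retrieval["status"] == "old", "response"].to_numpy()
    events = cohort.make_events(spec, old, np.random.default_rng(5))
    return {"spec": spec, "events": events, "retrieval": retrieval}
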