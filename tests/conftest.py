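"""Shared fixtures: one moderately sized synthetic cohort, preprocessed and
fitted once per session, reused by the unit tests that only read it."""

import numpy as np
import pytest

from traj2targets.gbmtm import TrajectoryModelSpec, fit_em
from traj2targets.preprocess import run_preprocess
from traj2targets.synthetic import default_scenario, simulate


@pytest.fixture(scope="session")
def scenario600():
    cfg = default_scenario(600, seed=42)
    vitals, cohort, truth, missing_rec, outlier_rec = simulate(cfg)
    return {
        "config": cfg,
        "vitals": vitals,
        "cohort": cohort,
        "truth": truth,
        "missing": missing_rec,
        "outliers": outlier_rec,
    }


@pytest.fixture(scope="session")
def preprocessed600(scenario600):
    res = run_preprocess(scenario600["vitals"])
    cohort = scenario600["cohort"]
    truth = scenario600["truth"]
    pos = np.searchsorted(cohort["subject_id"].to_numpy(), res.grids.subject_ids)
    return {"result": res, "true_labels": truth.group_label[pos]}


@pytest.fixture(scope="session")
def fit600(preprocessed600):
    spec = TrajectoryModelSpec(K=3, n_starts=2, seed=7)
    return fit_em(preprocessed600["result"].grids, spec)
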