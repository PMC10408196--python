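import warnings

import numpy as np
import pandas as pd
import pytest

import microresist as mr

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def control_study():
    """Small no-intervention cohort with two visits one day apart."""
    cfg = mr.SimulationConfig(n_subjects=30, n_species=60, n_pathways=20, seed=101)
    return mr.simulate_control_cohort(cfg)


@pytest.fixture(scope="session")
def intervention_study():
    """Planted-responder lifestyle cohort (baseline + day-28 sample)."""
    cfg = mr.SimulationConfig(n_subjects=60, n_species=60, n_pathways=20,
                              timepoints=(0, 28), seed=102)
    return mr.simulate_intervention_cohort(cfg)


@pytest.fixture(scope="session")
def fluct_baseline(control_study):
    return mr.estimate_daily_fluctuation(control_study.relative(),
                                         control_study.metadata)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, control_study):
    out = tmp_path_factory.mktemp("study")
    paths = mr.write_study(control_study, out)
    return paths


def two_feature_table(pairs, days=(0, 1)):
    """Build a 2-species relative table whose within-subject Bray-Curtis
    values are exactly the requested |a - b| per subject."""
    cols, vals, meta = [], [], []
    for i, (a, b) in enumerate(pairs):
        subj = f"S{i + 1:02d}"
        for day, x in zip(days, (a, b)):
            sid = f"{subj}_D{day}"
            cols.append(sid)
            vals.append([x, 1.0 - x])
            meta.append({"sample_id": sid, "subject_id": subj, "cohort_id": "C",
                         "cohort_type": "control", "day": day, "phase": "baseline"})
    data = pd.DataFrame(np.array(vals).T, index=["k__B|s__X", "k__B|s__Y"],
                        columns=cols)
    table = mr.AbundanceTable(data, "relative", "species")
    return table, mr.SampleMetadata(pd.DataFrame(meta))
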