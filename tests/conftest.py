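import numpy as np
import pandas as pd
import pytest

from rtmv.specs import ContaminationSpec, DesignSpec, ExGaussianSpec


@pytest.fixture(scope="session")
def menu():
    from rtmv.treatments import standard_table1_menu

    return standard_table1_menu()


@pytest.fixture
def paper_design():
    """The standard study conditions: 30 subjects, 10 obs/condition."""
    return DesignSpec(n_subjects=30, n_obs=10, mu_diff=0.0)


@pytest.fixture
def exg():
    return ExGaussianSpec()  # mu=400, sigma=40, tau=200


@pytest.fixture
def cont10():
    return ContaminationSpec(p=0.1)


def make_table(rts_by_subject_condition):
    """Build a trial table from {(subject, condition): [rts]}."""
    rows = []
    for (subj, cond), rts in rts_by_subject_condition.items():
        for t, rt in enumerate(rts, start=1):
            rows.append(
                {"subject": subj, "condition": cond, "trial": t,
                 "rt": float(rt), "contaminated": False}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_table():
    """A 12-row balanced 2-subject table with one obvious outlier."""
    return make_table(
        {
            (1, 1): [400, 420, 3000],
            (1, 2): [450, 470, 430],
            (2, 1): [380, 410, 390],
            (2, 2): [500, 520, 480],
        }
    )


def random_balanced_table(rng: np.random.Generator, n_subjects=4, n_obs=5):
    """A random balanced table with occasional extreme values."""
    from rtmv.datagen import arrays_to_table, sample_trial_arrays

    rt, flag = sample_trial_arrays(
        DesignSpec(n_subjects, n_obs, 25.0),
        ExGaussianSpec(),
        ContaminationSpec(p=0.15),
        rng,
    )
    return arrays_to_table(rt, flag)
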