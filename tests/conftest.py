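"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from piddm import (
    DDMParameterSet,
    SessionDesign,
    SimOptions,
    apply_rt_cutoffs,
    generate_session,
    simulate_dataset,
)
from piddm.task import GROUP_ESTIMATES


@pytest.fixture(scope="session")
def young_params() -> DDMParameterSet:
    """Parameter set at the young-adult group means, default variabilities."""
    est = GROUP_ESTIMATES["young"]
    return DDMParameterSet(
        v=est["v"], eta=0.10, a=est["a"], sz=0.02, ter=est["ter"], st=0.10
    )


@pytest.fixture(scope="session")
def older_params() -> DDMParameterSet:
    est = GROUP_ESTIMATES["older"]
    return DDMParameterSet(
        v=est["v"], eta=0.10, a=est["a"], sz=0.02, ter=est["ter"], st=0.10
    )


@pytest.fixture(scope="session")
def session_trials():
    """One default 480-trial session."""
    return generate_session(SessionDesign(), seed=101)


@pytest.fixture(scope="session")
def young_dataset(young_params, session_trials) -> pd.DataFrame:
    """One simulated participant at the young group means, cutoffs applied."""
    df = simulate_dataset(young_params, session_trials, SimOptions(seed=202))
    df["participant_id"] = "young_001"
    df["group"] = "young"
    filtered, _ = apply_rt_cutoffs(df)
    return filtered


def make_participant(params, seed, pid="p1", group="g", design=None):
    """Simulate one participant's session and apply the RT cutoffs."""
    design = design or SessionDesign()
    trials = generate_session(design, seed)
    df = simulate_dataset(params, trials, SimOptions(seed=seed + 7919))
    df["participant_id"] = pid
    df["group"] = group
    filtered, _ = apply_rt_cutoffs(df)
    return filtered
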