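import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from corrmem import DesignConfig, simulate_study
from corrmem.config import AgeGroup, Condition, default_params
from corrmem.simulate import ParticipantProfile

# silence the deliberate sparse-cell / convergence warnings during tests
logging.getLogger("corrmem").setLevel(logging.ERROR)
for name in ("corrmem.conditional", "corrmem.mpt.hierarchical",
             "corrmem.mpt.ppc", "corrmem.sdt"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort (both groups, all phases)."""
    trials, profiles, design = simulate_study(
        DesignConfig(n_per_group=24, seed=7))
    return trials, profiles, design


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    return small_cohort[0]


def make_profiles(n, pr, pf, dprime=2.0, criterion=0.0, n_formats=3,
                  remember_dprime=1.4, remember_criterion=0.0):
    """Deterministic profiles with identical latent parameters, for
    closed-form checks of the phase simulators."""
    conds = list(Condition)
    return [
        ParticipantProfile(
            participant_id=f"t{i:05d}", age_group=AgeGroup.YOUNGER,
            format_id=i % n_formats,
            pr_pf={c: (pr, pf) for c in conds},
            detect_dprime={c: dprime for c in conds},
            detect_criterion=criterion,
            remember_dprime={c: remember_dprime for c in conds},
            remember_criterion=remember_criterion,
            retention_hours=48.0)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def default_group_params():
    return default_params()


def counts_frame(count_matrix, condition="CORRECTED_1X", age_group="YOUNGER",
                 prefix="p"):
    d = pd.DataFrame(np.asarray(count_matrix),
                     columns=["n_real", "n_fake", "n_novel"])
    d["participant_id"] = [f"{prefix}{i}" for i in range(len(d))]
    d["age_group"] = age_group
    d["condition"] = condition
    return d


def probit(p):
    return float(norm.ppf(p))
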