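"""Generative simulator: participant sampling and the three phases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from corrmem.config import (
    AgeGroup,
    Condition,
    DesignConfig,
    GroupGenerativeParams,
    default_params,
)
from corrmem.design import make_design
from corrmem.mpt import category_probs
from corrmem.simulate import (
    sample_participants,
    simulate_phase1,
    simulate_phase2,
    simulate_phase3,
    simulate_study,
)
from conftest import make_profiles, probit


def _flat_params(**overrides) -> GroupGenerativeParams:
    base = default_params()[AgeGroup.YOUNGER]
    kwargs = dict(
        mu_probit=base.mu_probit, sigma=base.sigma,
        detect_dprime=base.detect_dprime,
        detect_criterion=base.detect_criterion,
        remember_dprime=base.remember_dprime,
        remember_criterion=base.remember_criterion,
    )
    kwargs.update(overrides)
    return GroupGenerativeParams(**kwargs)


def test_zero_covariance_gives_identical_participants():
    params = _flat_params(sigma=np.zeros((6, 6)))
    profiles = sample_participants(params, 5, seed=1)
    expected = {c: tuple(norm.cdf(v)) for c, v in params.mu_probit.items()}
    for prof in profiles:
        for c in expected:
            assert prof.pr_pf[c] == pytest.approx(expected[c], abs=1e-12)


def test_sampled_probits_centered_on_population_mean():
    params = _flat_params(sigma=np.eye(6))
    profiles = sample_participants(params, 10_000, seed=3)
    theta = np.array([
        [probit(prof.pr_pf[c][j]) for c in params.conditions for j in (0, 1)]
        for prof in profiles])
    assert np.abs(theta.mean(axis=0) - params.mu_vector()).max() < 0.05


def test_participant_sampling_seed_deterministic():
    params = _flat_params()
    a = sample_participants(params, 8, seed=5)
    b = sample_participants(params, 8, seed=5)
    assert a == b
    assert sample_participants(params, 8, seed=6) != a


def test_invalid_hyperparameters_rejected():
    with pytest.raises(ValueError):
        _flat_params(sigma=-np.eye(6))  # not PSD
    with pytest.raises(ValueError):
        _flat_params(rating_thresholds=(0.0, -1.0, 1.0, 2.0, 3.0))
    with pytest.raises(ValueError):
        sample_participants(_flat_params(), 0, seed=1)


@pytest.fixture(scope="module")
def tiny_design():
    return make_design(DesignConfig(seed=11))


def test_phase1_null_repetition_effect(tiny_design):
    params = _flat_params(familiarity_shift_per_exposure=0.0)
    profiles = make_profiles(60, 0.5, 0.5)
    rows = simulate_phase1(profiles, tiny_design,
                           {AgeGroup.YOUNGER: params}, seed=2)
    fam = rows[rows["phase"] == "P1_FAMILIARITY"]
    by_cycle = fam.groupby("presentation_index")["rating"].mean()
    assert abs(by_cycle[1] - by_cycle[2]) < 0.1


def test_phase1_repetition_raises_familiarity(tiny_design):
    params = _flat_params(familiarity_shift_per_exposure=0.4)
    profiles = make_profiles(60, 0.5, 0.5)
    rows = simulate_phase1(profiles, tiny_design,
                           {AgeGroup.YOUNGER: params}, seed=2)
    fam = rows[(rows["phase"] == "P1_FAMILIARITY")
               & (rows["condition"] == Condition.CORRECTED_3X.value)]
    by_cycle = fam.groupby("presentation_index")["rating"].mean()
    assert by_cycle[2] > by_cycle[1]


def test_phase1_real_rated_more_accurate_and_illusory_truth(tiny_design):
    params = _flat_params(real_accuracy_mean=0.4, fake_accuracy_mean=-0.2,
                          illusory_truth_shift=0.3)
    profiles = make_profiles(80, 0.5, 0.5)
    rows = simulate_phase1(profiles, tiny_design,
                           {AgeGroup.YOUNGER: params}, seed=4)
    acc = rows[rows["phase"] == "P1_ACCURACY"]
    means = acc.groupby("condition")["rating"].mean()
    assert means[Condition.AFFIRMED_REAL.value] > means[Condition.CORRECTED_1X.value]
    # repeated fake news rated more accurate than once-seen fake news
    assert means[Condition.CORRECTED_3X.value] > means[Condition.CORRECTED_1X.value]


def test_phase1_saturated_cutpoints_force_categories(tiny_design):
    profiles = make_profiles(3, 0.5, 0.5)
    lo = _flat_params(rating_thresholds=(-1e6, -1e5, -1e4, -1e3, -1e2))
    rows = simulate_phase1(profiles, tiny_design, {AgeGroup.YOUNGER: lo},
                           seed=1)
    assert (rows["rating"] == 6).all()
    hi = _flat_params(rating_thresholds=(1e2, 1e3, 1e4, 1e5, 1e6))
    rows = simulate_phase1(profiles, tiny_design, {AgeGroup.YOUNGER: hi},
                           seed=1)
    assert (rows["rating"] == 1).all()


def test_phase2_zero_sensitivity(tiny_design):
    profiles = make_profiles(100, 0.5, 0.5, dprime=0.0, criterion=0.0)
    rows = simulate_phase2(profiles, tiny_design,
                           {AgeGroup.YOUNGER: _flat_params()}, seed=3)
    rates = rows.groupby("condition")["detect_yes"].mean()
    assert abs(rates[Condition.CORRECTED_1X.value]
               - rates[Condition.AFFIRMED_REAL.value]) < 0.05


def test_phase2_matches_normal_cdf_oracle(tiny_design):
    # d'=2, c=0: hit rate Phi(1), false-alarm rate Phi(-1)
    profiles = make_profiles(700, 0.5, 0.5, dprime=2.0, criterion=0.0)
    rows = simulate_phase2(profiles, tiny_design,
                           {AgeGroup.YOUNGER: _flat_params()}, seed=5)
    rates = rows.groupby("condition")["detect_yes"].mean()
    assert rates[Condition.CORRECTED_1X.value] == pytest.approx(
        norm.cdf(1.0), abs=0.01)
    assert rates[Condition.AFFIRMED_REAL.value] == pytest.approx(
        norm.cdf(-1.0), abs=0.01)


def test_phase2_conservative_extreme(tiny_design):
    profiles = make_profiles(20, 0.5, 0.5, dprime=2.0, criterion=50.0)
    rows = simulate_phase2(profiles, tiny_design,
                           {AgeGroup.YOUNGER: _flat_params()}, seed=5)
    assert (rows["detect_yes"] == 0).all()


def _phase3(profiles, design, params, seed=9):
    group = {AgeGroup.YOUNGER: params}
    p2 = simulate_phase2(profiles, design, group, seed=seed)
    return simulate_phase3(profiles, design, group, p2, seed=seed + 1)


def test_phase3_pure_recollection(tiny_design):
    rows = _phase3(make_profiles(10, 1.0, 0.3), tiny_design, _flat_params())
    corr = rows[rows["condition"].isin(
        [Condition.CORRECTED_1X.value, Condition.CORRECTED_3X.value])]
    assert (corr["p3_choice"] == "REAL").all()


def test_phase3_category_frequencies_converge_to_tree(tiny_design):
    # ~50,000 correction trials at fixed (Pr, Pf): empirical frequencies
    # within 0.01 of the tree probabilities
    pr, pf = 0.4, 0.6
    profiles = make_profiles(1700, pr, pf)
    rows = _phase3(profiles, tiny_design, _flat_params(), seed=13)
    corr = rows[rows["condition"].isin(
        [Condition.CORRECTED_1X.value, Condition.CORRECTED_3X.value])]
    assert len(corr) == 1700 * 30
    freqs = corr["p3_choice"].value_counts(normalize=True)
    expected = dict(zip(["REAL", "FAKE", "NOVEL"], category_probs(Pr=pr, Pf=pf)))
    for k, v in expected.items():
        assert freqs.get(k, 0.0) == pytest.approx(v, abs=0.01)


def test_phase3_pure_guessing_is_equiprobable(tiny_design):
    rows = _phase3(make_profiles(600, 0.0, 0.0), tiny_design, _flat_params())
    corr = rows[rows["condition"] != Condition.AFFIRMED_REAL.value]
    freqs = corr["p3_choice"].value_counts(normalize=True)
    for k in ("REAL", "FAKE", "NOVEL"):
        assert freqs[k] == pytest.approx(1 / 3, abs=0.02)


def test_phase3_gating_exact(small_trials):
    p3 = small_trials[small_trials["phase"] == "P3_TEST"]
    asked = (p3["fake_retrieved"] != "NOT_ASKED").sum()
    remembered = (pd.to_numeric(p3["remember_yes"]) == 1).sum()
    assert asked == remembered


def test_phase3_requires_phase2_rows(tiny_design):
    profiles = make_profiles(4, 0.5, 0.5)
    group = {AgeGroup.YOUNGER: _flat_params()}
    p2 = simulate_phase2(profiles, tiny_design, group, seed=1)
    truncated = p2[p2["participant_id"] != profiles[0].participant_id]
    with pytest.raises(ValueError, match="Phase-2"):
        simulate_phase3(profiles, tiny_design, group, truncated, seed=2)


def test_full_study_deterministic_and_complete():
    cfg = DesignConfig(n_per_group=6, seed=21)
    t1, p1, _ = simulate_study(cfg)
    t2, p2, _ = simulate_study(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert p1 == p2
    assert set(t1["phase"]) == {"P1_FAMILIARITY", "P1_ACCURACY",
                                "P2_DETECTION", "P3_TEST"}
    # every participant is tested on each critical topic at most once
    p3 = t1[t1["phase"] == "P3_TEST"]
    assert not p3.duplicated(["participant_id", "topic_id"]).any()
    assert set(t1["age_group"]) == {"YOUNGER", "OLDER"}
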