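"""Conditional pipelines: toy enumerations, conservation, belief accuracy."""

import numpy as np
import pandas as pd
import pytest

from corrmem.conditional import (
    belief_accuracy,
    classification_table,
    cluster_bootstrap_ci,
    conditional_table,
    conditionalize,
    overall_retrieval,
)


def _trial_row(pid, topic, cond, phase, **kw):
    base = {"participant_id": pid, "age_group": kw.pop("age_group", "YOUNGER"),
            "topic_id": topic, "condition": cond, "phase": phase,
            "presentation_index": 1, "rating": pd.NA, "detect_yes": pd.NA,
            "p3_choice": pd.NA, "p3_accuracy_rating": pd.NA,
            "remember_yes": pd.NA, "fake_retrieved": pd.NA}
    base.update(kw)
    return base


def _toy_table():
    """10 detected correction trials: 6 with fake retrieved (5 real-correct),
    4 without (1 real-correct)."""
    rows = []
    spec = [("CORRECT_FAKE", "REAL")] * 5 + [("CORRECT_FAKE", "NOVEL")] \
        + [("OTHER", "REAL")] + [("OTHER", "NOVEL")] * 3
    for t, (retr, choice) in enumerate(spec):
        rows.append(_trial_row("p0", t, "CORRECTED_1X", "P2_DETECTION",
                               detect_yes=1))
        rows.append(_trial_row("p0", t, "CORRECTED_1X", "P3_TEST",
                               p3_choice=choice, remember_yes=1,
                               fake_retrieved=retr, p3_accuracy_rating=4))
    return pd.DataFrame(rows)


def test_toy_conditionalization_matches_hand_enumeration():
    cells = conditional_table(conditionalize(
        _toy_table(), "real_correct", "fake_retrieval"))
    by = cells.set_index("conditioning_status")
    assert by.loc["FAKE_RETRIEVED", "proportion"] == pytest.approx(5 / 6)
    assert by.loc["FAKE_NOT_RETRIEVED", "proportion"] == pytest.approx(1 / 4)
    assert by.loc["FAKE_RETRIEVED", "weight"] == pytest.approx(0.6)
    assert by.loc["FAKE_NOT_RETRIEVED", "weight"] == pytest.approx(0.4)
    assert by["n_obs"].tolist() == [4, 6] or by["n_obs"].sum() == 10


def test_constant_conditioner_yields_single_full_weight_cell():
    t = _toy_table()
    t.loc[t["phase"] == "P3_TEST", "fake_retrieved"] = "CORRECT_FAKE"
    cells = conditionalize(t, "real_correct", "fake_retrieval")
    assert len(cells) == 1
    assert cells[0].weight == 1.0


def test_sparse_cells_flagged_not_dropped():
    cells = conditional_table(conditionalize(
        _toy_table(), "real_correct", "fake_retrieval", min_n=5))
    assert cells.loc[cells["n_obs"] == 4, "sparse"].all()
    assert not cells.loc[cells["n_obs"] == 6, "sparse"].any()


def _random_conditional_tables(n_cases, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        n = rng.integers(4, 40)
        rows = []
        for t in range(n):
            pid = f"p{rng.integers(0, 4)}"
            rows.append(_trial_row(pid, t, "CORRECTED_1X", "P2_DETECTION",
                                   detect_yes=int(rng.random() < 0.8)))
            remembered = int(rng.random() < 0.6)
            rows.append(_trial_row(
                pid, t, "CORRECTED_1X", "P3_TEST",
                p3_choice=rng.choice(["REAL", "FAKE", "NOVEL"]),
                remember_yes=remembered,
                fake_retrieved=(rng.choice(["CORRECT_FAKE", "OTHER"])
                                if remembered else "NOT_ASKED"),
                p3_accuracy_rating=int(rng.integers(1, 7))))
        yield pd.DataFrame(rows)


def test_law_of_total_probability_exact_on_random_tables():
    # sum_s weight_s * proportion_s reconstructs the marginal exactly
    # (pooled aggregation), on 1,000 randomized tables
    checked = 0
    for table in _random_conditional_tables(1000, seed=17):
        cells = conditionalize(table, "fake_erroneous", "remembering",
                               aggregation="pooled")
        if not cells:
            continue
        gated = table.merge(
            table.loc[table["phase"] == "P2_DETECTION",
                      ["participant_id", "topic_id", "detect_yes"]],
            on=["participant_id", "topic_id"], suffixes=("", "_p2"))
        marg = gated[(gated["phase"] == "P3_TEST")
                     & (gated["detect_yes_p2"] == 1)]
        marginal = (marg["p3_choice"] == "FAKE").mean()
        recon = sum(c.weight * c.proportion for c in cells)
        assert recon == pytest.approx(marginal, abs=1e-12)
        assert sum(c.weight for c in cells) == pytest.approx(1.0, abs=1e-12)
        checked += 1
    assert checked > 900


def test_unknown_measure_names_rejected():
    with pytest.raises(ValueError, match="target"):
        conditionalize(_toy_table(), "nope", "remembering")
    with pytest.raises(ValueError, match="conditioner"):
        conditionalize(_toy_table(), "real_correct", "nope")


def test_classification_table_all_yes():
    rows = [_trial_row("p0", t, c, "P2_DETECTION", detect_yes=1)
            for t in range(5)
            for c in ("CORRECTED_1X", "AFFIRMED_REAL")]
    rows += [_trial_row("p1", t, "CORRECTED_1X", "P2_DETECTION",
                        detect_yes=1) for t in range(5)]
    per, summary = classification_table(pd.DataFrame(rows), n_boot=200)
    assert (per["proportion"] == 1.0).all()
    assert (summary["proportion"] == 1.0).all()


def test_overall_retrieval_structural_bounds(small_trials):
    tab = overall_retrieval(small_trials, aggregation="pooled")
    assert tab["proportion"].between(0, 1).all()
    p3 = small_trials[small_trials["phase"] == "P3_TEST"]
    for (age, cond), grp in p3.groupby(["age_group", "condition"]):
        row = tab[(tab["age_group"] == age) & (tab["condition"] == cond)
                  & (tab["measure"] == "correct_fake_after_remembering")]
        remembered = (pd.to_numeric(grp["remember_yes"]) == 1).mean()
        # the gated measure can never exceed the remembering rate
        assert row["proportion"].iloc[0] <= remembered + 1e-12


def test_overall_retrieval_all_real():
    rows = [_trial_row("p0", t, "CORRECTED_1X", "P3_TEST", p3_choice="REAL",
                       remember_yes=0, fake_retrieved="NOT_ASKED")
            for t in range(6)]
    tab = overall_retrieval(pd.DataFrame(rows))
    by = tab.set_index("measure")["proportion"]
    assert by["correct_real"] == 1.0
    assert by["erroneous_fake"] == 0.0


def test_belief_accuracy_scale_extremes():
    rows = []
    for t in range(6):
        choice = "REAL" if t < 3 else "FAKE"
        rows.append(_trial_row("p0", t, "CORRECTED_1X", "P3_TEST",
                               p3_choice=choice,
                               p3_accuracy_rating=6 if choice == "REAL" else 1,
                               remember_yes=0, fake_retrieved="NOT_ASKED"))
    tab = belief_accuracy(pd.DataFrame(rows))
    assert tab["belief_accuracy"].iloc[0] == pytest.approx(5.0)
    # all ratings equal -> zero difference
    flat = pd.DataFrame(rows)
    flat["p3_accuracy_rating"] = 4
    assert belief_accuracy(flat)["belief_accuracy"].iloc[0] == 0.0


def test_belief_accuracy_higher_when_fake_retrieved():
    # recollection-linked retrieval of the fake detail comes with higher
    # belief in the correctly retrieved real detail (checked on a cohort
    # large enough for the contrast to clear Monte-Carlo error)
    from corrmem import DesignConfig, simulate_study

    trials, _, _ = simulate_study(DesignConfig(n_per_group=150, seed=5))
    tab = belief_accuracy(trials, conditioner="fake_retrieval")
    piv = tab.pivot_table(index=["age_group", "condition"], columns="stratum",
                          values="mean_rating_correct_real")
    assert (piv["FAKE_RETRIEVED"] > piv["FAKE_NOT_RETRIEVED"]).all()
    # erroneous-fake ratings cannot occur in the retrieved stratum: a
    # fake choice removes the fake headline from the gated question
    assert (tab.loc[tab["stratum"] == "FAKE_RETRIEVED",
                    "n_erroneous_fake"] == 0).all()


def test_bootstrap_ci_degenerate_and_deterministic():
    assert cluster_bootstrap_ci([2.0, 2.0, 2.0], B=200, seed=1) == (2.0, 2.0)
    vals = np.random.default_rng(2).normal(size=30)
    a = cluster_bootstrap_ci(vals, B=500, seed=9)
    assert a == cluster_bootstrap_ci(vals, B=500, seed=9)
    assert a != cluster_bootstrap_ci(vals, B=500, seed=10)
    with pytest.raises(ValueError):
        cluster_bootstrap_ci([1.0], B=200, seed=0)
    with pytest.raises(ValueError):
        cluster_bootstrap_ci(vals, B=50, seed=0)


def test_bootstrap_width_shrinks_like_root_n():
    rng = np.random.default_rng(4)
    widths = {}
    for n in (25, 100, 400):
        vals = rng.normal(size=n)
        lo, hi = cluster_bootstrap_ci(vals, B=10_000, seed=3)
        widths[n] = hi - lo
    assert 1.5 < widths[25] / widths[100] < 2.7
    assert 1.5 < widths[100] / widths[400] < 2.7
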