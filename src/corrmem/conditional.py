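"""Descriptive and conditional analyses of the Phase 2/3 responses.

This module produces the paradigm's descriptive chain: yes-rate tables
for detection and remembering, overall retrieval proportions, memory
measures conditionalized on other responses (restricted to trials whose
corrections were detected in Phase 2), belief-accuracy differences, and
cluster (participant-resampling) bootstrap intervals.

Aggregation comes in two flavors everywhere: ``"participant"`` computes
the measure per participant and averages participants (the default,
matching the per-participant signal-detection treatment) and
``"pooled"`` pools trials. Only pooled aggregation satisfies the exact
law-of-total-probability identity
``sum_s weight_s * proportion_s = marginal proportion``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from corrmem.config import CORRECTION_CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "classification_table",
    "overall_retrieval",
    "conditionalize",
    "belief_accuracy",
    "cluster_bootstrap_ci",
]

_CORR = [c.value for c in CORRECTION_CONDITIONS]

# named target measures: boolean per Phase-3 row
_TARGETS = {
    "real_correct": lambda d: d["p3_choice"] == "REAL",
    "fake_erroneous": lambda d: d["p3_choice"] == "FAKE",
}
# named conditioning statuses
_CONDITIONERS = {
    "fake_retrieval": lambda d: np.where(
        d["fake_retrieved"] == "CORRECT_FAKE",
        "FAKE_RETRIEVED", "FAKE_NOT_RETRIEVED"),
    "remembering": lambda d: np.where(
        d["remember_yes"].astype("Int64") == 1,
        "CORRECTION_REMEMBERED", "CORRECTION_NOT_REMEMBERED"),
}


def _yes_column(phase: str) -> str:
    return {"P2_DETECTION": "detect_yes", "P3_TEST": "remember_yes"}[phase]


def classification_table(trials: pd.DataFrame, phase: str = "P2_DETECTION",
                         n_boot: int = 1000, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yes-response proportions per participant x condition, plus summary.

    Returns ``(per_participant, group_summary)``; the summary holds the
    mean proportion per age group x condition with a 95% cluster
    bootstrap CI over participants. Empty cells are absent with a logged
    warning.
    """
    col = _yes_column(phase)
    sub = trials[trials["phase"] == phase].copy()
    sub[col] = pd.to_numeric(sub[col])
    per = (sub.groupby(["participant_id", "age_group", "condition"])[col]
           .agg(proportion="mean", n_trials="count").reset_index())
    if per.empty:
        logger.warning("classification_table: no rows for phase %s", phase)
        return per, per
    rows = []
    for (age, cond), grp in per.groupby(["age_group", "condition"]):
        vals = grp["proportion"].to_numpy()
        if len(vals) < 2:
            logger.warning("classification_table: single participant in "
                           "%s x %s; degenerate CI", age, cond)
            lo = hi = float(vals[0])
        else:
            lo, hi = cluster_bootstrap_ci(vals, B=n_boot, seed=seed)
        rows.append({"age_group": age, "condition": cond,
                     "proportion": float(vals.mean()),
                     "ci_low": lo, "ci_high": hi,
                     "n_participants": len(vals)})
    return per, pd.DataFrame(rows)


def _proportion(frame: pd.DataFrame, flag: pd.Series,
                aggregation: str) -> float:
    if len(frame) == 0:
        return float("nan")
    if aggregation == "pooled":
        return float(flag.mean())
    per = flag.groupby(frame["participant_id"]).mean()
    return float(per.mean())


def overall_retrieval(trials: pd.DataFrame, aggregation: str = "participant"
                      ) -> pd.DataFrame:
    """Overall Phase-3 measures per age group x condition.

    Three measures: correct retrieval of real news, erroneous retrieval
    of fake news, and correct fake retrieval after remembering a
    correction (the gated measure; its numerator requires
    ``remember_yes = 1`` and ``fake_retrieved = CORRECT_FAKE``, its
    denominator is all test trials of the cell).
    """
    p3 = trials[trials["phase"] == "P3_TEST"].copy()
    rows = []
    for (age, cond), grp in p3.groupby(["age_group", "condition"]):
        rem = pd.to_numeric(grp["remember_yes"])
        measures = {
            "correct_real": grp["p3_choice"] == "REAL",
            "erroneous_fake": grp["p3_choice"] == "FAKE",
            "correct_fake_after_remembering":
                (rem == 1) & (grp["fake_retrieved"] == "CORRECT_FAKE"),
        }
        for name, flag in measures.items():
            rows.append({
                "age_group": age, "condition": cond, "measure": name,
                "proportion": _proportion(grp, flag.astype(float),
                                          aggregation),
                "n_obs": len(grp),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionalCell:
    """One conditional proportion with its observation count and weight."""

    age_group: str
    condition: str
    conditioning_status: str
    proportion: float
    n_obs: int
    weight: float
    sparse: bool


def _gated_correction_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Phase-3 correction-condition trials whose correction was detected
    in Phase 2 (the gate for all conditional analyses)."""
    p3 = trials[(trials["phase"] == "P3_TEST")
                & trials["condition"].isin(_CORR)].drop(columns=["detect_yes"])
    p2 = trials[trials["phase"] == "P2_DETECTION"][
        ["participant_id", "topic_id", "detect_yes"]]
    merged = p3.merge(p2, on=["participant_id", "topic_id"], how="left")
    if merged["detect_yes"].isna().any():
        missing = int(merged["detect_yes"].isna().sum())
        raise ValueError(
            f"{missing} correction test trials lack a Phase-2 detection row")
    return merged[pd.to_numeric(merged["detect_yes"]) == 1]


def conditionalize(trials: pd.DataFrame, target: str, conditioner: str,
                   gate: bool = True, min_n: int = 5,
                   aggregation: str = "pooled",
                   restrict_remembered: bool | None = None
                   ) -> list[ConditionalCell]:
    """Conditional proportions of ``target`` within ``conditioner`` strata.

    Parameters
    ----------
    target:
        ``"real_correct"`` or ``"fake_erroneous"``.
    conditioner:
        ``"fake_retrieval"`` (fake retrieved vs not) or ``"remembering"``
        (correction remembered vs not).
    gate:
        Restrict to trials whose correction was detected in Phase 2
        (the standard analysis); required Phase-2 rows must be present.
    min_n:
        Cells with fewer observations are flagged sparse, never dropped.
    aggregation:
        ``"pooled"`` (law-of-total-probability exact) or
        ``"participant"``.
    restrict_remembered:
        Further restrict to remembered-correction trials; defaults to
        True for the ``fake_retrieval`` conditioner (the fake question is
        only asked after a "yes") and False otherwise.

    Weights are the share of each stratum's observations within its age
    group x condition, so ``sum_s weight_s * proportion_s`` (pooled)
    reconstructs the unconditional proportion exactly.
    """
    if target not in _TARGETS:
        raise ValueError(f"unknown target {target!r}; use one of {sorted(_TARGETS)}")
    if conditioner not in _CONDITIONERS:
        raise ValueError(
            f"unknown conditioner {conditioner!r}; use one of {sorted(_CONDITIONERS)}")
    if restrict_remembered is None:
        restrict_remembered = conditioner == "fake_retrieval"

    base = _gated_correction_trials(trials) if gate else (
        trials[(trials["phase"] == "P3_TEST")
               & trials["condition"].isin(_CORR)].copy())
    if restrict_remembered:
        base = base[pd.to_numeric(base["remember_yes"]) == 1]

    base = base.assign(_target=_TARGETS[target](base).astype(float),
                       _status=_CONDITIONERS[conditioner](base))
    cells: list[ConditionalCell] = []
    for (age, cond), grp in base.groupby(["age_group", "condition"]):
        total = len(grp)
        for status, sgrp in grp.groupby("_status"):
            n_obs = len(sgrp)
            prop = _proportion(sgrp, sgrp["_target"], aggregation)
            sparse = n_obs < min_n
            if sparse:
                logger.warning(
                    "sparse conditional cell %s x %s x %s (n=%d)",
                    age, cond, status, n_obs)
            cells.append(ConditionalCell(
                age_group=str(age), condition=str(cond),
                conditioning_status=str(status), proportion=prop,
                n_obs=n_obs, weight=n_obs / total, sparse=sparse))
    return cells


def conditional_table(cells: list[ConditionalCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


@dataclass(frozen=True)
class BeliefAccuracySummary:
    """Belief accuracy: mean rating difference, correct real - erroneous fake."""

    age_group: str
    condition: str
    stratum: str
    mean_rating_correct_real: float
    mean_rating_erroneous_fake: float
    belief_accuracy: float
    n_correct_real: int
    n_erroneous_fake: int


def belief_accuracy(trials: pd.DataFrame, conditioner: str | None = None,
                    gate: bool = False) -> pd.DataFrame:
    """Belief-accuracy summaries per age group x condition (and strata).

    Belief accuracy is the difference between the mean Phase-3 accuracy
    rating given to correctly retrieved real news and the mean rating
    given to erroneously retrieved fake news; larger values mean beliefs
    track veracity better. With ``conditioner`` (``"fake_retrieval"`` or
    ``"remembering"``) the summary is computed within each conditioning
    stratum of detected-correction trials. Empty strata yield NaN with a
    logged warning.
    """
    if conditioner is None:
        base = trials[(trials["phase"] == "P3_TEST")
                      & trials["condition"].isin(_CORR)].copy()
        base["_status"] = "ALL"
    else:
        base = _gated_correction_trials(trials)
        if conditioner == "fake_retrieval":
            base = base[pd.to_numeric(base["remember_yes"]) == 1]
        base = base.assign(_status=_CONDITIONERS[conditioner](base))
    base["p3_accuracy_rating"] = pd.to_numeric(base["p3_accuracy_rating"])

    rows = []
    for (age, cond, status), grp in base.groupby(
            ["age_group", "condition", "_status"]):
        real = grp.loc[grp["p3_choice"] == "REAL", "p3_accuracy_rating"]
        fake = grp.loc[grp["p3_choice"] == "FAKE", "p3_accuracy_rating"]
        if real.empty or fake.empty:
            logger.warning(
                "belief_accuracy: empty stratum %s x %s x %s", age, cond,
                status)
        m_real = float(real.mean()) if len(real) else float("nan")
        m_fake = float(fake.mean()) if len(fake) else float("nan")
        rows.append(BeliefAccuracySummary(
            age_group=str(age), condition=str(cond), stratum=str(status),
            mean_rating_correct_real=m_real,
            mean_rating_erroneous_fake=m_fake,
            belief_accuracy=m_real - m_fake,
            n_correct_real=len(real), n_erroneous_fake=len(fake)).__dict__)
    return pd.DataFrame(rows)


def cluster_bootstrap_ci(stats, B: int = 1000, seed: int = 0,
                         level: float = 0.95) -> tuple[float, float]:
    """Percentile CI of a mean by resampling participants with replacement.

    ``stats`` holds one statistic per participant (the cluster unit).
    Degenerate (constant) statistics yield a zero-width interval with a
    logged warning.
    """
    vals = np.asarray(stats, dtype=float)
    if vals.size < 2:
        raise ValueError("need statistics from at least 2 participants")
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile interval")
    if np.ptp(vals) == 0:
        logger.warning("cluster_bootstrap_ci: degenerate statistics; "
                       "zero-width interval")
        return float(vals[0]), float(vals[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)
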