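"""Equal-variance Gaussian signal detection for correction classifications.

"Yes" responses to real news that corrected fake news are hits; "yes"
responses to affirmed real news (which corrected nothing) are false
alarms. Sensitivity d' = z(H) - z(F) measures the ability to distinguish
corrections from affirmations; criterion c = -(z(H) + z(F)) / 2 measures
response bias, with higher (more conservative) values meaning fewer
reports that a topic was corrected.

The generative convention used throughout the package is
P(yes | signal) = Phi(d'/2 - c) and P(yes | noise) = Phi(-d'/2 - c), of
which the estimator here is the exact inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import norm

from corrmem.config import CORRECTION_CONDITIONS, Condition

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionRule",
    "CountTable",
    "SDTEstimate",
    "corrected_rates",
    "sdt_estimate",
    "sdt_by_cell",
]


class CorrectionRule(str, Enum):
    """Extreme-proportion handling before the probit transform.

    LOGLINEAR (default): (x + 0.5) / (n + 1), applied always so the
    estimator is continuous in the counts. HALF_TRIAL: 1/(2n) and
    1 - 1/(2n) substituted only at proportions of exactly 0 or 1.
    NONE: raw proportions; rates of 0 or 1 raise an error.
    """

    LOGLINEAR = "loglinear"
    HALF_TRIAL = "half_trial"
    NONE = "none"


@dataclass(frozen=True)
class CountTable:
    """Hit/false-alarm counts for one participant x condition cell."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms,
               self.correct_rejections) < 0:
            raise ValueError("all counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTEstimate:
    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    correction_rule: CorrectionRule


def corrected_rates(counts: CountTable,
                    rule: CorrectionRule = CorrectionRule.LOGLINEAR
                    ) -> tuple[float, float]:
    """Hit and false-alarm rates with the chosen extreme-proportion rule."""
    rule = CorrectionRule(rule)
    if counts.n_signal < 1 or counts.n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    if rule is CorrectionRule.LOGLINEAR:
        h = (counts.hits + 0.5) / (counts.n_signal + 1)
        f = (counts.false_alarms + 0.5) / (counts.n_noise + 1)
    else:
        h = counts.hits / counts.n_signal
        f = counts.false_alarms / counts.n_noise
        if rule is CorrectionRule.HALF_TRIAL:
            h = min(max(h, 0.5 / counts.n_signal), 1 - 0.5 / counts.n_signal)
            f = min(max(f, 0.5 / counts.n_noise), 1 - 0.5 / counts.n_noise)
        elif h in (0.0, 1.0) or f in (0.0, 1.0):
            raise ValueError(
                "proportion of 0 or 1 with rule='none'; choose a correction "
                "rule (loglinear or half_trial) to keep rates inside (0, 1)")
    return float(h), float(f)


def sdt_estimate(H: float, F: float,
                 rule: CorrectionRule = CorrectionRule.NONE) -> SDTEstimate:
    """d' and c from hit/false-alarm rates strictly inside (0, 1)."""
    if not (0.0 < H < 1.0 and 0.0 < F < 1.0):
        raise ValueError(f"rates must lie strictly in (0, 1); got H={H}, F={F}")
    zh, zf = norm.ppf(H), norm.ppf(F)
    return SDTEstimate(d_prime=float(zh - zf),
                       criterion_c=float(-(zh + zf) / 2.0),
                       hit_rate=float(H), fa_rate=float(F),
                       correction_rule=CorrectionRule(rule))


_PHASE_RESPONSE = {"P2_DETECTION": "detect_yes", "P3_TEST": "remember_yes"}


def sdt_by_cell(trials: pd.DataFrame, phase: str = "P2_DETECTION",
                rule: CorrectionRule = CorrectionRule.LOGLINEAR
                ) -> pd.DataFrame:
    """Per-participant d'/c for each correction condition.

    "Yes" responses in each correction condition are separate hit rates;
    "yes" responses to affirmed real news are the shared false-alarm
    source. Raw (uncorrected) proportions are emitted alongside the
    corrected rates and estimates. Participants missing a cell are
    excluded with a logged warning.
    """
    if phase not in _PHASE_RESPONSE:
        raise ValueError(f"phase must be one of {sorted(_PHASE_RESPONSE)}")
    col = _PHASE_RESPONSE[phase]
    sub = trials[trials["phase"] == phase].copy()
    if sub.empty:
        raise ValueError(f"no rows for phase {phase}")
    sub[col] = pd.to_numeric(sub[col])
    noise = sub[sub["condition"] == Condition.AFFIRMED_REAL.value]
    if noise.empty:
        raise ValueError(
            "no affirmed-real trials: the false-alarm (noise) distribution "
            "is missing")
    noise_stats = noise.groupby("participant_id")[col].agg(["sum", "count"])

    rows = []
    for cond in CORRECTION_CONDITIONS:
        sig = sub[sub["condition"] == cond.value]
        sig_stats = sig.groupby("participant_id")[col].agg(["sum", "count"])
        for pid, (nyes, ntot) in sig_stats.iterrows():
            if pid not in noise_stats.index:
                logger.warning(
                    "participant %s missing affirmed-real cell; excluded", pid)
                continue
            fyes, ftot = noise_stats.loc[pid]
            counts = CountTable(hits=int(nyes), misses=int(ntot - nyes),
                                false_alarms=int(fyes),
                                correct_rejections=int(ftot - fyes))
            H, F = corrected_rates(counts, rule)
            est = sdt_estimate(H, F, rule)
            age = sig.loc[sig["participant_id"] == pid, "age_group"].iloc[0]
            rows.append({
                "participant_id": pid, "age_group": age,
                "condition": cond.value,
                "raw_hit_rate": nyes / ntot, "raw_fa_rate": fyes / ftot,
                "H": H, "F": F,
                "d_prime": est.d_prime, "c": est.criterion_c,
                "n_signal": int(ntot), "n_noise": int(ftot),
            })
    missing_noise = set(sub["participant_id"]) - set(noise_stats.index)
    if missing_noise:
        logger.warning("%d participants had no noise trials and were excluded",
                       len(missing_noise))
    return pd.DataFrame(rows)
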