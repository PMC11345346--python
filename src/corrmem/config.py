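"""Design and generative-parameter configuration for the paradigm simulator.

The simulator emulates a three-phase misinformation-correction experiment.
Each critical headline topic has a real and a fake version and is assigned
to one of three conditions:

- ``AFFIRMED_REAL``: real news in Phase 1, the same real news repeated
  (affirmed) in Phase 2.
- ``CORRECTED_1X``: fake news once in Phase 1, corrected by real news in
  Phase 2.
- ``CORRECTED_3X``: fake news three times in Phase 1 (twice in Block A,
  once in Block B), corrected by real news in Phase 2.

Topics rotate through conditions across experimental formats so that every
topic serves every condition equally often across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "TestMode",
    "AgeGroup",
    "DesignConfig",
    "GroupGenerativeParams",
    "default_params",
    "CORRECTION_CONDITIONS",
]


class Condition(str, Enum):
    """Headline-type condition (Phase 1 exposure x Phase 2 treatment)."""

    AFFIRMED_REAL = "AFFIRMED_REAL"
    CORRECTED_1X = "CORRECTED_1X"
    CORRECTED_3X = "CORRECTED_3X"


CORRECTION_CONDITIONS = (Condition.CORRECTED_1X, Condition.CORRECTED_3X)


class TestMode(str, Enum):
    """Phase-3 test procedure.

    Both modes emit the same three response categories (real / fake /
    novel); cued recall treats any non-real, non-fake recall (including
    omissions) as NOVEL.
    """

    RECOGNITION_3AFC = "RECOGNITION_3AFC"
    CUED_RECALL = "CUED_RECALL"


class AgeGroup(str, Enum):
    YOUNGER = "YOUNGER"
    OLDER = "OLDER"


class ConfigurationError(ValueError):
    """Raised when a design configuration is internally inconsistent."""


@dataclass(frozen=True)
class DesignConfig:
    """Structural parameters of the three-phase paradigm.

    Defaults reproduce the deployed design: 45 critical topics rotated as
    three sets of 15 through the three conditions, giving three
    counterbalancing formats, plus 15 real-news fillers interleaved with
    the repeated fake news in Phase 1 Block A. ``max_run_length`` bounds
    consecutive same-condition presentations in every phase ordering.
    """

    n_per_group: int = 102
    n_critical_topics: int = 45
    n_fillers: int = 15
    items_per_condition: int = 15
    n_formats: int = 3
    test_mode: TestMode = TestMode.RECOGNITION_3AFC
    max_run_length: int = 3
    retention_hours: float = 52.0  # metadata only; not modeled
    seed: int = 0

    def __post_init__(self) -> None:
        n_conditions = len(Condition)
        if self.n_critical_topics != self.items_per_condition * n_conditions:
            raise ConfigurationError(
                f"n_critical_topics ({self.n_critical_topics}) must equal "
                f"items_per_condition ({self.items_per_condition}) x "
                f"{n_conditions} conditions"
            )
        if self.n_critical_topics % self.n_formats != 0:
            raise ConfigurationError(
                f"n_formats ({self.n_formats}) must divide n_critical_topics "
                f"({self.n_critical_topics}) for a full rotation"
            )
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.max_run_length < 1:
            raise ConfigurationError("max_run_length must be >= 1")


def _as_condition_map(value) -> dict[Condition, float]:
    if isinstance(value, dict):
        return {Condition(k): float(v) for k, v in value.items()}
    return {c: float(value) for c in Condition}


@dataclass
class GroupGenerativeParams:
    """Generative parameters for one age group.

    Latent-process conventions
    --------------------------
    - ``mu_probit[cond]`` is the probit-scale population mean of the
      dual-process parameters ``(Pr, Pf)`` in that condition; participant
      probits are drawn from a multivariate normal with covariance
      ``sigma`` over the stacked ``(condition x parameter)`` vector.
    - Detection (Phase 2) and remembering (Phase 3) follow equal-variance
      Gaussian signal detection: P(yes | correction) = Phi(d'/2 - c),
      P(yes | affirmed real) = Phi(-d'/2 - c). This is the exact inverse of
      the d'/c estimator in :mod:`corrmem.sdt`, by construction.
    - Ordinal 1-6 ratings are a cumulative probit: a latent normal with
      unit residual sd is cut at ``rating_thresholds`` (5 ordered
      cutpoints).

    Repetition enters as additive latent-mean shifts:
    ``familiarity_shift_per_exposure`` per prior presentation for
    familiarity ratings, and ``illusory_truth_shift`` per prior exposure
    for fake-news accuracy ratings (the illusory-truth direction).
    ``belief_shift_recollected`` raises Phase-3 belief ratings on
    recollection-generated choices, and ``remember_boost_recollected``
    shifts the remember-question evidence on those same trials, coupling
    correction memory to recollective retrieval. Conversely,
    ``remember_mask_per_exposure`` lowers the remember evidence on trials
    where the fake detail was erroneously chosen as real, by that amount
    per prior fake exposure: strong fake familiarity both attracts the
    error and masks memory that the detail was corrected, which is what
    concentrates repetition-driven errors in the not-remembered stratum.
    """

    mu_probit: dict[Condition, tuple[float, float]]
    sigma: np.ndarray  # covariance of the stacked participant probit vector
    detect_dprime: dict[Condition, float]
    detect_criterion: float
    remember_dprime: dict[Condition, float]
    remember_criterion: float
    rating_thresholds: tuple[float, ...] = (-1.8, -0.8, 0.0, 0.8, 1.8)
    familiarity_base_mean: float = -0.15
    familiarity_shift_per_exposure: float = 0.15
    real_accuracy_mean: float = 0.20
    fake_accuracy_mean: float = 0.00
    illusory_truth_shift: float = 0.06
    belief_real_mean: float = 0.80
    belief_fake_mean: float = -0.10
    belief_shift_recollected: float = 0.60
    remember_boost_recollected: float = 1.50
    remember_mask_per_exposure: float = 0.20
    fake_id_recollected: float = 0.90
    fake_id_baseline: float = 0.50
    sd_dprime: float = 0.50
    sd_criterion: float = 0.30

    def __post_init__(self) -> None:
        self.mu_probit = {Condition(k): (float(v[0]), float(v[1]))
                          for k, v in self.mu_probit.items()}
        self.detect_dprime = _as_condition_map(self.detect_dprime)
        self.remember_dprime = _as_condition_map(self.remember_dprime)
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = 2 * len(self.mu_probit)
        if self.sigma.shape != (k, k):
            raise ValueError(
                f"sigma must be {k}x{k} for {len(self.mu_probit)} conditions"
            )
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(self.sigma)
        if eigvals.min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")
        thr = np.asarray(self.rating_thresholds, dtype=float)
        if thr.size != 5 or np.any(np.diff(thr) <= 0):
            raise ValueError("rating_thresholds must be 5 strictly increasing cutpoints")

    @property
    def conditions(self) -> list[Condition]:
        return list(self.mu_probit)

    def theta_labels(self) -> list[str]:
        """Labels of the stacked participant probit vector."""
        return [f"{c.value}:{p}" for c in self.mu_probit for p in ("Pr", "Pf")]

    def mu_vector(self) -> np.ndarray:
        return np.array([v for pair in self.mu_probit.values() for v in pair])


def _default_sigma(n_conditions: int, sd: float = 0.6, rho: float = 0.3) -> np.ndarray:
    k = 2 * n_conditions
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    return (sd**2) * corr


def default_params() -> dict[AgeGroup, GroupGenerativeParams]:
    """Default generative parameters for the two age groups.

    Probability-scale dual-process means are typical of recognition
    versions of the paradigm: recollection near 0.47 in both correction
    conditions; familiarity near 0.70 for once-presented fake news in
    younger adults, lower in older adults, and raised by roughly 0.10
    after repeated exposure for older adults. Detection and remembering
    d'/c defaults are probit transforms of realistic yes-rates (hits
    ~ .78-.85 against ~ .17-.18 false alarms in Phase 2; weaker, more
    age-dependent separation in Phase 3). Rating-scale anchors put mean
    ratings in the 2.6-3.8 band with real news rated above fake news.
    """
    from scipy.stats import norm

    def probit_pair(pr: float, pf: float) -> tuple[float, float]:
        return (float(norm.ppf(pr)), float(norm.ppf(pf)))

    younger = GroupGenerativeParams(
        mu_probit={
            Condition.AFFIRMED_REAL: probit_pair(0.75, 0.50),
            Condition.CORRECTED_1X: probit_pair(0.47, 0.70),
            Condition.CORRECTED_3X: probit_pair(0.49, 0.73),
        },
        sigma=_default_sigma(3),
        detect_dprime={
            Condition.AFFIRMED_REAL: 0.0,
            Condition.CORRECTED_1X: 1.9,
            Condition.CORRECTED_3X: 2.0,
        },
        detect_criterion=0.0,
        remember_dprime={
            Condition.AFFIRMED_REAL: 0.0,
            Condition.CORRECTED_1X: 1.35,
            Condition.CORRECTED_3X: 1.55,
        },
        remember_criterion=-0.05,
        familiarity_base_mean=-0.15,
        real_accuracy_mean=0.20,
        fake_accuracy_mean=0.00,
    )
    older = GroupGenerativeParams(
        mu_probit={
            Condition.AFFIRMED_REAL: probit_pair(0.70, 0.50),
            Condition.CORRECTED_1X: probit_pair(0.46, 0.61),
            Condition.CORRECTED_3X: probit_pair(0.44, 0.70),
        },
        sigma=_default_sigma(3),
        detect_dprime={
            Condition.AFFIRMED_REAL: 0.0,
            Condition.CORRECTED_1X: 1.7,
            Condition.CORRECTED_3X: 1.95,
        },
        detect_criterion=0.05,
        remember_dprime={
            Condition.AFFIRMED_REAL: 0.0,
            Condition.CORRECTED_1X: 1.15,
            Condition.CORRECTED_3X: 1.25,
        },
        remember_criterion=-0.30,
        familiarity_base_mean=-0.45,
        real_accuracy_mean=-0.05,
        fake_accuracy_mean=-0.30,
    )
    return {AgeGroup.YOUNGER: younger, AgeGroup.OLDER: older}


def params_with_mu(params: GroupGenerativeParams,
                   mu_probit: dict[Condition, tuple[float, float]]):
    """Copy ``params`` with a replaced dual-process mean structure."""
    k = 2 * len(mu_probit)
    sigma = params.sigma
    if sigma.shape[0] != k:
        sigma = _default_sigma(len(mu_probit),
                               sd=float(np.sqrt(sigma[0, 0])))
    return replace(params, mu_probit=dict(mu_probit), sigma=sigma)
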