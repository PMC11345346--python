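"""Generative simulation of the three-phase correction paradigm.

Each phase is generated from an explicit latent-process model whose
estimators elsewhere in the package are exact inverses:

- Phase 1 ratings are cumulative-probit: a latent normal (unit residual
  sd) whose mean carries repetition effects is cut at the configured
  thresholds to give the 1-6 scale. Familiarity grows with prior
  presentations; fake-news accuracy ratings grow with prior exposures
  (the illusory-truth direction); real news has a higher accuracy mean
  than fake news.
- Phase 2 correction detection is equal-variance Gaussian signal
  detection with participant-level sensitivity and criterion: a single
  decision threshold lambda_i = c_i + mean-correction-d'/2 gives
  P(yes | correction k) = Phi(d'_k - lambda_i) and
  P(yes | affirmed real) = Phi(-lambda_i), i.e. the d'/2 - c convention
  when the two correction sensitivities coincide.
- Phase 3 choices follow the dual-process tree with the participant's
  condition-specific (Pr, Pf); the correction-remembered question uses a
  second signal-detection process whose evidence mean is boosted on
  recollection-generated choices; the gated fake-identification question
  is only asked after a "yes" and succeeds more often on recollection
  branches; belief ratings are cumulative-probit with a recollection
  shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from corrmem.config import (
    AgeGroup,
    Condition,
    CORRECTION_CONDITIONS,
    DesignConfig,
    GroupGenerativeParams,
    default_params,
)
from corrmem.design import FILLER, StudyDesign, make_design
from corrmem.mpt.tree import NovelBranch, _GUESS

__all__ = [
    "ParticipantProfile",
    "sample_participants",
    "simulate_phase1",
    "simulate_phase2",
    "simulate_phase3",
    "simulate_study",
]

TRIAL_COLUMNS = [
    "participant_id", "age_group", "topic_id", "condition", "phase",
    "presentation_index", "rating", "detect_yes", "p3_choice",
    "p3_accuracy_rating", "remember_yes", "fake_retrieved",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent parameters for one simulated participant."""

    participant_id: str
    age_group: AgeGroup
    format_id: int
    pr_pf: dict[Condition, tuple[float, float]]  # probability scale
    detect_dprime: dict[Condition, float]
    detect_criterion: float
    remember_dprime: dict[Condition, float]
    remember_criterion: float
    retention_hours: float


def sample_participants(params: GroupGenerativeParams, n: int, seed: int,
                        age_group: AgeGroup = AgeGroup.YOUNGER,
                        n_formats: int = 3, id_prefix: str = "",
                        retention_hours: float = 52.0,
                        ) -> list[ParticipantProfile]:
    """Draw participant profiles from the group-level hierarchy.

    Dual-process probits are multivariate normal with mean
    ``params.mu_vector()`` and covariance ``params.sigma``; probability-
    scale values are their probit inverses, so they lie strictly in
    (0, 1). Detection/remembering parameters get additive participant
    offsets (a shared sensitivity offset across conditions, plus a
    criterion offset). Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = params.mu_vector()
    # raises LinAlgError-equivalent via config validation; guard anyway
    theta = rng.multivariate_normal(mu, params.sigma, size=n,
                                    method="eigh")
    probs = norm.cdf(theta)
    conds = params.conditions
    d_off = rng.normal(0.0, params.sd_dprime, size=(n, 2))
    c_off = rng.normal(0.0, params.sd_criterion, size=(n, 2))
    profiles = []
    for i in range(n):
        pr_pf = {c: (float(probs[i, 2 * j]), float(probs[i, 2 * j + 1]))
                 for j, c in enumerate(conds)}
        profiles.append(ParticipantProfile(
            participant_id=f"{id_prefix}{age_group.value[0]}{i:04d}",
            age_group=age_group,
            format_id=i % n_formats,
            pr_pf=pr_pf,
            detect_dprime={c: params.detect_dprime[c] + d_off[i, 0]
                           for c in conds},
            detect_criterion=params.detect_criterion + c_off[i, 0],
            remember_dprime={c: params.remember_dprime[c] + d_off[i, 1]
                             for c in conds},
            remember_criterion=params.remember_criterion + c_off[i, 1],
            retention_hours=retention_hours,
        ))
    return profiles


def _ordinal(latent: np.ndarray, thresholds) -> np.ndarray:
    """Cut a latent array at the thresholds, giving integers 1..6."""
    thr = np.asarray(thresholds, dtype=float)
    return 1 + (latent[:, None] > thr[None, :]).sum(axis=1)


def _empty_trial_frame(n: int) -> dict:
    return {c: [pd.NA] * n for c in TRIAL_COLUMNS}


def simulate_phase1(profiles: list[ParticipantProfile], design: StudyDesign,
                    params_by_group: dict[AgeGroup, GroupGenerativeParams],
                    seed: int) -> pd.DataFrame:
    """Phase-1 familiarity (Block A) and accuracy (Block B) rating rows."""
    rng = np.random.default_rng(seed)
    sched = design.schedule
    frames = []
    for prof in profiles:
        params = params_by_group[prof.age_group]
        for phase_key, out_phase in (("P1_BLOCK_A", "P1_FAMILIARITY"),
                                     ("P1_BLOCK_B", "P1_ACCURACY")):
            rows = sched[(sched["format_id"] == prof.format_id)
                         & (sched["phase"] == phase_key)]
            pres = rows["presentation_index"].to_numpy()
            cond = rows["condition"].to_numpy()
            is_fake = np.isin(cond, [c.value for c in CORRECTION_CONDITIONS])
            if out_phase == "P1_FAMILIARITY":
                mean = params.familiarity_base_mean \
                    + params.familiarity_shift_per_exposure * (pres - 1)
            else:
                mean = np.where(
                    is_fake,
                    params.fake_accuracy_mean
                    + params.illusory_truth_shift * (pres - 1),
                    params.real_accuracy_mean)
            latent = mean + rng.standard_normal(len(rows))
            rating = _ordinal(latent, params.rating_thresholds)
            frames.append(pd.DataFrame({
                "participant_id": prof.participant_id,
                "age_group": prof.age_group.value,
                "topic_id": rows["topic_id"].to_numpy(),
                "condition": cond,
                "phase": out_phase,
                "presentation_index": pres,
                "rating": rating,
                "detect_yes": pd.NA, "p3_choice": pd.NA,
                "p3_accuracy_rating": pd.NA, "remember_yes": pd.NA,
                "fake_retrieved": pd.NA,
            }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def _detection_threshold(dprime: dict[Condition, float], criterion: float
                         ) -> float:
    dbar = float(np.mean([dprime[c] for c in CORRECTION_CONDITIONS]))
    return criterion + dbar / 2.0


def simulate_phase2(profiles: list[ParticipantProfile], design: StudyDesign,
                    params_by_group: dict[AgeGroup, GroupGenerativeParams],
                    seed: int) -> pd.DataFrame:
    """Phase-2 correction-detection rows (detect_yes)."""
    rng = np.random.default_rng(seed)
    sched = design.schedule
    frames = []
    for prof in profiles:
        rows = sched[(sched["format_id"] == prof.format_id)
                     & (sched["phase"] == "P2")]
        cond = rows["condition"].to_numpy()
        lam = _detection_threshold(prof.detect_dprime, prof.detect_criterion)
        d = np.array([prof.detect_dprime[Condition(c)]
                      if c != Condition.AFFIRMED_REAL.value else 0.0
                      for c in cond])
        is_signal = cond != Condition.AFFIRMED_REAL.value
        p_yes = np.where(is_signal, norm.cdf(d - lam), norm.cdf(-lam))
        yes = (rng.random(len(rows)) < p_yes).astype(int)
        frames.append(pd.DataFrame({
            "participant_id": prof.participant_id,
            "age_group": prof.age_group.value,
            "topic_id": rows["topic_id"].to_numpy(),
            "condition": cond,
            "phase": "P2_DETECTION",
            "presentation_index": 1,
            "rating": pd.NA,
            "detect_yes": yes,
            "p3_choice": pd.NA, "p3_accuracy_rating": pd.NA,
            "remember_yes": pd.NA, "fake_retrieved": pd.NA,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_phase3(profiles: list[ParticipantProfile], design: StudyDesign,
                    params_by_group: dict[AgeGroup, GroupGenerativeParams],
                    phase2_rows: pd.DataFrame, seed: int,
                    novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS
                    ) -> pd.DataFrame:
    """Phase-3 test rows (choice, belief rating, remember, fake retrieval).

    Requires the Phase-2 rows: every correction-condition test trial must
    have a matching detection trial (the conditional analyses gate on
    them).
    """
    rng = np.random.default_rng(seed)
    sched = design.schedule
    p2_keys = set(zip(phase2_rows["participant_id"], phase2_rows["topic_id"]))
    g = _GUESS[NovelBranch(novel_branch)]
    frames = []
    for prof in profiles:
        params = params_by_group[prof.age_group]
        rows = sched[(sched["format_id"] == prof.format_id)
                     & (sched["phase"] == "P3")]
        cond = rows["condition"].to_numpy()
        topics = rows["topic_id"].to_numpy()
        n = len(rows)
        is_corr = np.isin(cond, [c.value for c in CORRECTION_CONDITIONS])
        missing = [t for t, c in zip(topics, is_corr)
                   if c and (prof.participant_id, t) not in p2_keys]
        if missing:
            raise ValueError(
                f"participant {prof.participant_id}: correction topics "
                f"{missing[:5]} have no Phase-2 detection row")

        pr = np.array([prof.pr_pf[Condition(c)][0] for c in cond])
        pf = np.array([prof.pr_pf[Condition(c)][1] for c in cond])
        u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
        recollected = u1 < pr
        familiar = ~recollected & (u2 < pf)
        # familiarity branch: real vs fake at g_fam = 0.5
        fam_choice = np.where(u3 < 0.5, "REAL", "FAKE")
        # guessing branch
        guess_choice = np.select(
            [u3 < g[0], u3 < g[0] + g[1]], ["REAL", "FAKE"], default="NOVEL")
        choice = np.where(recollected, "REAL",
                          np.where(familiar, fam_choice, guess_choice))

        lam = _detection_threshold(prof.remember_dprime,
                                   prof.remember_criterion)
        d = np.array([prof.remember_dprime[Condition(c)]
                      if c != Condition.AFFIRMED_REAL.value else 0.0
                      for c in cond])
        n_exposures = np.select(
            [cond == Condition.CORRECTED_1X.value,
             cond == Condition.CORRECTED_3X.value], [1.0, 3.0], default=0.0)
        evidence = (np.where(is_corr, d - lam, -lam)
                    + params.remember_boost_recollected
                    * (recollected & is_corr)
                    - params.remember_mask_per_exposure * n_exposures
                    * (choice == "FAKE"))
        remember = (rng.random(n) < norm.cdf(evidence)).astype(int)

        p_correct_fake = np.where(
            recollected, params.fake_id_recollected, params.fake_id_baseline)
        retrieved = np.where(
            rng.random(n) < p_correct_fake, "CORRECT_FAKE", "OTHER")
        retrieved = np.where(is_corr & (choice != "FAKE"), retrieved, "OTHER")
        fake_retrieved = np.where(remember == 1, retrieved, "NOT_ASKED")

        belief_mean = np.where(choice == "REAL", params.belief_real_mean,
                               params.belief_fake_mean) \
            + params.belief_shift_recollected * recollected
        rating = _ordinal(belief_mean + rng.standard_normal(n),
                          params.rating_thresholds)

        frames.append(pd.DataFrame({
            "participant_id": prof.participant_id,
            "age_group": prof.age_group.value,
            "topic_id": topics,
            "condition": cond,
            "phase": "P3_TEST",
            "presentation_index": 1,
            "rating": pd.NA,
            "detect_yes": pd.NA,
            "p3_choice": choice,
            "p3_accuracy_rating": rating,
            "remember_yes": remember,
            "fake_retrieved": fake_retrieved,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_study(config: DesignConfig | None = None,
                   params_by_group: dict[AgeGroup, GroupGenerativeParams]
                   | None = None,
                   seed: int | None = None,
                   ) -> tuple[pd.DataFrame, list[ParticipantProfile],
                              StudyDesign]:
    """Run the full paradigm for both age groups.

    Returns the combined tidy trial table (all phases), the participant
    profiles (the ground truth for recovery tests), and the design. All
    randomness derives from ``seed`` (default: ``config.seed``).
    """
    config = config or DesignConfig()
    params_by_group = params_by_group or default_params()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(5)

    design = make_design(config)
    profiles: list[ParticipantProfile] = []
    for k, (group, params) in enumerate(params_by_group.items()):
        profiles.extend(sample_participants(
            params, config.n_per_group,
            seed=int(child[0].generate_state(1)[0] % (2**31)) + k,
            age_group=group, n_formats=config.n_formats,
            retention_hours=config.retention_hours))

    p1 = simulate_phase1(profiles, design, params_by_group,
                         seed=int(child[1].generate_state(1)[0] % (2**31)))
    p2 = simulate_phase2(profiles, design, params_by_group,
                         seed=int(child[2].generate_state(1)[0] % (2**31)))
    p3 = simulate_phase3(profiles, design, params_by_group, p2,
                         seed=int(child[3].generate_state(1)[0] % (2**31)))
    trials = pd.concat([p1, p2, p3], ignore_index=True)
    return trials, profiles, design
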