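"""Posterior-predictive fit checks for the latent-trait MPT.

Two discrepancy statistics in the tradition of hierarchical-MPT model
checking:

- T1 (means): squared distance between the observed mean category
  frequencies (averaged over participants) and their model expectation
  under the current draw's participant parameters. Detects marginal
  misfit of the tree's category structure.
- T2 (covariances): squared distance between the observed
  across-participant covariance matrix of category frequencies and its
  model expectation (the covariance of the participant-level expected
  frequencies plus average multinomial noise). Detects misfit of the
  individual-difference structure, which the group means cannot.

For each retained posterior draw the same discrepancy is computed for a
replicate dataset simulated from that draw; the posterior-predictive
p-value is the proportion of draws where the replicate discrepancy meets
or exceeds the observed one. Values near 0 or 1 indicate misfit.
"""

from __future__ import annotations

import logging

import numpy as np

from corrmem.mpt.tree import NovelBranch
from corrmem.mpt.hierarchical import CellFit, _tree_probs_from_theta

logger = logging.getLogger(__name__)

__all__ = ["ppc_fit"]


def _cov_entries(freqs: np.ndarray) -> np.ndarray:
    """Unique entries of the 3x3 covariance across participants."""
    c = np.cov(freqs.T, ddof=1)
    iu = np.triu_indices(3)
    return c[iu]


def _expected_cov_entries(probs: np.ndarray, n_trials: np.ndarray) -> np.ndarray:
    """Model-expected covariance of category frequencies across participants."""
    between = np.cov(probs.T, ddof=1)
    # average multinomial sampling covariance of frequencies
    diag = np.einsum("ik,kl->ikl", probs, np.eye(3))
    outer = np.einsum("ik,il->ikl", probs, probs)
    within = ((diag - outer) / n_trials[:, None, None]).mean(axis=0)
    iu = np.triu_indices(3)
    return (between + within)[iu]


def ppc_fit(cell: CellFit, max_draws: int = 200, seed: int = 0
            ) -> tuple[float, float | None]:
    """Posterior-predictive p-values (T1 means, T2 covariances) for a cell.

    Uses the retained participant-level draws stored in the fit
    (subsampled to at most ``max_draws``). T2 is omitted (None, with a
    warning) when there are too few participants or the observed
    frequencies are degenerate.
    """
    counts = cell.counts
    n_trials = counts.sum(axis=1)
    obs_freqs = counts / n_trials[:, None]
    obs_mean = obs_freqs.mean(axis=0)
    n = counts.shape[0]

    theta = cell.theta.reshape(-1, n, 2)  # (draws, participants, 2)
    if theta.shape[0] > max_draws:
        idx = np.linspace(0, theta.shape[0] - 1, max_draws).astype(int)
        theta = theta[idx]
    rng = np.random.default_rng(seed)

    do_t2 = n >= 3 and np.isfinite(_cov_entries(obs_freqs)).all() \
        and _cov_entries(obs_freqs).any()
    if not do_t2:
        logger.warning(
            "ppc_fit cell %s:%s: covariance check omitted "
            "(too few participants or degenerate observed frequencies)",
            cell.age_group, cell.condition)
    obs_cov = _cov_entries(obs_freqs) if do_t2 else None

    t1_ge = t2_ge = 0
    t2_total = 0
    for th in theta:
        probs = _tree_probs_from_theta(th, NovelBranch(cell.novel_branch))
        exp_mean = probs.mean(axis=0)
        rep_counts = np.array(
            [rng.multinomial(int(nt), p) for nt, p in zip(n_trials, probs)])
        rep_freqs = rep_counts / n_trials[:, None]

        t1_obs = float(((obs_mean - exp_mean) ** 2).sum())
        t1_rep = float(((rep_freqs.mean(axis=0) - exp_mean) ** 2).sum())
        t1_ge += t1_rep >= t1_obs

        if do_t2:
            exp_cov = _expected_cov_entries(probs, n_trials)
            t2_obs = float(((obs_cov - exp_cov) ** 2).sum())
            t2_rep = float(((_cov_entries(rep_freqs) - exp_cov) ** 2).sum())
            t2_ge += t2_rep >= t2_obs
            t2_total += 1

    t1 = t1_ge / len(theta)
    t2 = (t2_ge / t2_total) if t2_total else None
    return float(t1), (float(t2) if t2 is not None else None)
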