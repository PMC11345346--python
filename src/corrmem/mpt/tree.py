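"""Category probabilities, likelihood, and closed-form inversion of the tree."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NovelBranch",
    "DualProcessParams",
    "category_probs",
    "moment_estimator",
    "loglik",
]

G_FAM = 0.5  # familiarity-branch guess between real and fake; fixed, never estimated


class NovelBranch(str, Enum):
    """Reading of the no-memory guessing branch.

    ``UNIFORM_THIRDS`` (default): guesses are equiprobable over the three
    response categories. ``SEQUENTIAL_HALVES``: two successive 0.5 splits,
    first real-vs-rest then fake-vs-novel, giving (0.5, 0.25, 0.25).
    """

    UNIFORM_THIRDS = "UNIFORM_THIRDS"
    SEQUENTIAL_HALVES = "SEQUENTIAL_HALVES"


_GUESS = {
    NovelBranch.UNIFORM_THIRDS: (1 / 3, 1 / 3, 1 / 3),
    NovelBranch.SEQUENTIAL_HALVES: (0.5, 0.25, 0.25),
}


@dataclass(frozen=True)
class DualProcessParams:
    """Recollection/familiarity parameters on the probability scale."""

    Pr: float
    Pf: float
    novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS
    boundary_flag: bool = False  # set by moment_estimator when clipping

    @property
    def g_fam(self) -> float:
        return G_FAM


def category_probs(params: DualProcessParams | None = None, *,
                   Pr=None, Pf=None,
                   novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS):
    """Response-category probabilities (p_real, p_fake, p_novel).

    Accepts a :class:`DualProcessParams` or ``Pr``/``Pf`` directly
    (scalars or broadcastable arrays). Probabilities sum to 1 exactly:
    the recollection branch contributes ``Pr`` to real; the familiarity
    branch splits ``(1-Pr)*Pf`` equally between real and fake; the
    guessing branch distributes ``(1-Pr)*(1-Pf)`` per ``novel_branch``.
    """
    if params is not None:
        Pr, Pf, novel_branch = params.Pr, params.Pf, params.novel_branch
    Pr = np.asarray(Pr, dtype=float)
    Pf = np.asarray(Pf, dtype=float)
    if np.any((Pr < 0) | (Pr > 1)) or np.any((Pf < 0) | (Pf > 1)):
        raise ValueError("Pr and Pf must lie in [0, 1]")
    g = _GUESS[NovelBranch(novel_branch)]
    guess_mass = (1.0 - Pr) * (1.0 - Pf)
    fam_mass = (1.0 - Pr) * Pf
    p_real = Pr + fam_mass * G_FAM + guess_mass * g[0]
    p_fake = fam_mass * (1.0 - G_FAM) + guess_mass * g[1]
    p_novel = guess_mass * g[2]
    if p_real.ndim == 0:
        return float(p_real), float(p_fake), float(p_novel)
    return p_real, p_fake, p_novel


def moment_estimator(freqs,
                     novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS
                     ) -> DualProcessParams:
    """Closed-form inverse of :func:`category_probs` from observed proportions.

    Under ``UNIFORM_THIRDS``, the tree gives
    ``(1-Pr)(1-Pf) = 3 * p_novel`` and ``(1-Pr) * Pf = 2 * (p_fake - p_novel)``,
    hence ``1 - Pr = 2 * p_fake + p_novel``. Under ``SEQUENTIAL_HALVES``
    the analogous identities are ``(1-Pr)(1-Pf) = 4 * p_novel`` and
    ``(1-Pr) * Pf = 2 * (p_fake - p_novel)``. Estimates falling outside
    [0, 1] (data outside the model's image, e.g. ``p_fake < p_novel``)
    are clipped and flagged via ``boundary_flag``; ``Pf`` is unidentified
    and flagged when ``Pr = 1``.
    """
    p_real, p_fake, p_novel = (float(x) for x in freqs)
    total = p_real + p_fake + p_novel
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"proportions must sum to 1 (got {total})")
    novel_branch = NovelBranch(novel_branch)
    novel_factor = 1.0 / _GUESS[novel_branch][2]
    guess_mass = novel_factor * p_novel              # (1-Pr)(1-Pf)
    fam_mass = 2.0 * (p_fake - _GUESS[novel_branch][1] * guess_mass)  # (1-Pr)Pf
    one_minus_pr = guess_mass + fam_mass
    flag = False
    if one_minus_pr < 0 or one_minus_pr > 1 or fam_mass < -1e-12:
        flag = True
    pr = float(np.clip(1.0 - one_minus_pr, 0.0, 1.0))
    if one_minus_pr <= 1e-12:
        # pure recollection: familiarity unidentified
        return DualProcessParams(Pr=pr, Pf=np.nan, novel_branch=novel_branch,
                                 boundary_flag=True)
    pf = fam_mass / one_minus_pr
    if pf < 0 or pf > 1:
        flag = True
    pf = float(np.clip(pf, 0.0, 1.0))
    return DualProcessParams(Pr=pr, Pf=pf, novel_branch=novel_branch,
                             boundary_flag=flag)


def loglik(counts, params: DualProcessParams) -> float:
    """Multinomial log-likelihood of (n_real, n_fake, n_novel) under the tree.

    Returns ``-inf`` when a category with zero model probability has a
    nonzero count (an impossible datum under the parameters).
    """
    n = np.asarray(counts, dtype=float)
    if n.shape[-1] != 3 or np.any(n < 0):
        raise ValueError("counts must be three non-negative category counts")
    p = np.asarray(category_probs(params), dtype=float)
    total = n.sum(axis=-1)
    log_coef = gammaln(total + 1) - gammaln(n + 1).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(p), 0.0)
    if np.any((p == 0) & (n > 0)):
        return float("-inf")
    return float(log_coef + terms.sum(axis=-1))
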