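"""Hierarchical Bayesian latent-trait fit of the dual-process tree.

Model (one cell = one age group x condition)
--------------------------------------------
Participant ``i`` contributes category counts
``(n_real_i, n_fake_i, n_novel_i) ~ Multinomial(N_i, category_probs(Pr_i, Pf_i))``
with ``(Pr_i, Pf_i) = (Phi(theta_i1), Phi(theta_i2))`` and probit vector
``theta_i ~ N(mu, Sigma)``. The latent-trait formulation (free covariance
``Sigma``) is used so that the correlation between recollection and
familiarity is itself estimated and checkable.

Priors: ``mu ~ N(0, I)`` on the probit scale (weakly informative: implies
a near-uniform prior on each probability-scale group mean) and
``Sigma ~ Inverse-Wishart(nu0 = 4, Psi0 = I)``, a standard weakly
informative conjugate choice for a 2x2 covariance (prior mean ``I``).

Sampler: Metropolis-within-Gibbs. ``mu`` and ``Sigma`` have exact
conjugate Gibbs updates; the ``theta_i`` are updated jointly by
vectorized random-walk Metropolis with per-participant step sizes
adapted during warm-up toward ~35% acceptance. Chains are independent
and seeded deterministically from the spec seed.

Group-level estimates are reported on the probability scale as
``Phi(mu)`` (the population median of each parameter), matching how
latent-trait MPT group means are conventionally tabulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import invwishart, norm

from corrmem.config import CORRECTION_CONDITIONS
from corrmem.mpt.tree import NovelBranch, _GUESS, G_FAM

logger = logging.getLogger(__name__)

__all__ = [
    "HierarchicalSpec",
    "PosteriorSummary",
    "CellFit",
    "MPTFit",
    "fit_hierarchical",
    "credible_difference",
    "counts_from_trials",
    "simulate_category_counts",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class HierarchicalSpec:
    """MCMC settings for the latent-trait fit.

    Defaults are the desk-scale profile (4 chains x 5,000 retained
    iterations after 1,000 warm-up, no thinning), adequate for the 2x2
    conjugate-plus-Metropolis sampler. :meth:`paper_profile` returns a
    long-run profile for final, publication-grade runs (4 chains x
    100,000 iterations, 20,000 adaptation, 2,000 burn-in, thinning
    factor 5).
    """

    n_chains: int = 4
    n_iter: int = 5_000
    n_adapt: int = 1_000
    n_burn: int = 0
    thin: int = 1
    seed: int = 0
    novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS
    mu_prior_sd: float = 1.0
    iw_df: float = 4.0
    iw_scale: float = 1.0
    target_accept: float = 0.35
    max_theta_draws: int = 500  # retained participant-level draws per chain
    run_ppc: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter, self.n_adapt + 1, self.thin) < 1:
            raise ValueError("MCMC counts must be positive and thin >= 1")

    @classmethod
    def paper_profile(cls, seed: int = 0, **kw) -> "HierarchicalSpec":
        return cls(n_chains=4, n_iter=100_000, n_adapt=20_000, n_burn=2_000,
                   thin=5, seed=seed, **kw)


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary of one scalar posterior (or posterior difference)."""

    label: str
    mean: float
    sd: float
    ci95: tuple[float, float]
    rhat: float | None = None
    ess: float | None = None
    credible: bool | None = None

    def as_dict(self) -> dict:
        return {
            "label": self.label, "mean": self.mean, "sd": self.sd,
            "ci_low": self.ci95[0], "ci_high": self.ci95[1],
            "rhat": self.rhat, "ess": self.ess, "credible": self.credible,
        }


def _summarize(draws: np.ndarray, label: str, diagnostics: bool = True
               ) -> PosteriorSummary:
    """Summarize (chain, draw) array; R-hat/ESS via arviz when 2-D."""
    flat = np.asarray(draws, dtype=float).ravel()
    lo, hi = np.percentile(flat, [2.5, 97.5])
    rhat = ess = None
    if diagnostics and draws.ndim == 2 and draws.shape[0] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(draws[..., None])
            rhat = float(az.rhat(ds)["x"].item())
            ess = float(az.ess(ds)["x"].item())
    return PosteriorSummary(label=label, mean=float(flat.mean()),
                            sd=float(flat.std(ddof=1)), ci95=(float(lo), float(hi)),
                            rhat=rhat, ess=ess)


def _tree_probs_from_theta(theta: np.ndarray, novel_branch: NovelBranch):
    """Category probabilities (n, 3) from probit matrix (n, 2)."""
    pr = norm.cdf(theta[..., 0])
    pf = norm.cdf(theta[..., 1])
    g = _GUESS[novel_branch]
    guess = (1.0 - pr) * (1.0 - pf)
    fam = (1.0 - pr) * pf
    return np.stack(
        [pr + fam * G_FAM + guess * g[0], fam * (1 - G_FAM) + guess * g[1],
         guess * g[2]], axis=-1)


def _cell_loglik(theta: np.ndarray, counts: np.ndarray,
                 novel_branch: NovelBranch) -> np.ndarray:
    """Per-participant multinomial log-likelihood (without the coefficient)."""
    p = _tree_probs_from_theta(theta, novel_branch)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.clip(p, 1e-300, None)), 0.0)
    return ll.sum(axis=-1)


def _run_chain(counts: np.ndarray, spec: HierarchicalSpec, rng: np.random.Generator):
    """One MCMC chain for one cell. Returns dict of retained draws."""
    n = counts.shape[0]
    nb = spec.novel_branch

    # moment-style initialization jittered by the rng
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pr0 = np.clip(1.0 - 2 * freqs[:, 1] - freqs[:, 2], 0.02, 0.98)
    pf0 = np.clip(2 * (freqs[:, 1] - freqs[:, 2]) / np.clip(1 - pr0, 0.05, None),
                  0.02, 0.98)
    theta = norm.ppf(np.column_stack([pr0, pf0])) + 0.1 * rng.standard_normal((n, 2))
    mu = theta.mean(axis=0)
    sigma = np.cov(theta.T) + 0.1 * np.eye(2)

    step = np.full(n, 0.4)
    accepts = np.zeros(n)
    batch = 0

    prior_prec_mu = np.eye(2) / spec.mu_prior_sd**2
    psi0 = spec.iw_scale * np.eye(2)

    total = spec.n_adapt + spec.n_burn + spec.n_iter
    keep_from = spec.n_adapt + spec.n_burn
    n_keep = (spec.n_iter + spec.thin - 1) // spec.thin
    mu_draws = np.empty((n_keep, 2))
    sigma_draws = np.empty((n_keep, 3))  # var_Pr, var_Pf, cov
    theta_stride = max(1, int(np.ceil(n_keep / spec.max_theta_draws)))
    theta_draws = []

    loglik_cur = _cell_loglik(theta, counts, nb)
    kept = 0
    for it in range(total):
        # --- theta update: vectorized random-walk Metropolis
        sigma_inv = np.linalg.inv(sigma)
        prop = theta + step[:, None] * rng.standard_normal((n, 2))
        ll_prop = _cell_loglik(prop, counts, nb)
        d_cur = theta - mu
        d_prop = prop - mu
        lp_cur = -0.5 * np.einsum("ij,jk,ik->i", d_cur, sigma_inv, d_cur)
        lp_prop = -0.5 * np.einsum("ij,jk,ik->i", d_prop, sigma_inv, d_prop)
        log_alpha = (ll_prop + lp_prop) - (loglik_cur + lp_cur)
        accept = np.log(rng.random(n)) < log_alpha
        theta[accept] = prop[accept]
        loglik_cur[accept] = ll_prop[accept]
        accepts += accept

        if it < spec.n_adapt:
            batch += 1
            if batch == 50:
                rate = accepts / batch
                step *= np.exp(np.clip(rate - spec.target_accept, -0.5, 0.5))
                step = np.clip(step, 1e-3, 5.0)
                accepts[:] = 0.0
                batch = 0

        # --- mu update: conjugate normal
        prec = n * sigma_inv + prior_prec_mu
        cov_mu = np.linalg.inv(prec)
        mean_mu = cov_mu @ (sigma_inv @ theta.sum(axis=0))
        mu = mean_mu + np.linalg.cholesky(cov_mu) @ rng.standard_normal(2)

        # --- Sigma update: conjugate inverse-Wishart
        d = theta - mu
        scale = psi0 + d.T @ d
        sigma = invwishart.rvs(df=spec.iw_df + n, scale=scale, random_state=rng)
        sigma = np.asarray(sigma, dtype=float).reshape(2, 2)

        if it >= keep_from and (it - keep_from) % spec.thin == 0:
            mu_draws[kept] = mu
            sigma_draws[kept] = (sigma[0, 0], sigma[1, 1], sigma[0, 1])
            if kept % theta_stride == 0:
                theta_draws.append(theta.copy())
            kept += 1

    return {
        "mu": mu_draws[:kept],
        "sigma": sigma_draws[:kept],
        "theta": np.array(theta_draws),
    }


@dataclass
class CellFit:
    """Posterior draws and summaries for one age group x condition cell."""

    age_group: str
    condition: str
    participant_ids: list
    counts: np.ndarray                      # (n, 3)
    mu_probit: np.ndarray                   # (chain, draw, 2)
    sigma: np.ndarray                       # (chain, draw, 3): varPr, varPf, cov
    theta: np.ndarray                       # (chain, sub_draw, n, 2)
    novel_branch: NovelBranch
    summaries: list[PosteriorSummary] = field(default_factory=list)
    converged: bool = True
    t1_ppp: float | None = None
    t2_ppp: float | None = None

    @property
    def pr_draws(self) -> np.ndarray:
        """Group-level recollection on the probability scale, (chain, draw)."""
        return norm.cdf(self.mu_probit[..., 0])

    @property
    def pf_draws(self) -> np.ndarray:
        """Group-level familiarity on the probability scale, (chain, draw)."""
        return norm.cdf(self.mu_probit[..., 1])

    def summarize(self) -> list[PosteriorSummary]:
        label = f"{self.age_group}:{self.condition}"
        out = [
            _summarize(self.pr_draws, f"{label}:Pr"),
            _summarize(self.pf_draws, f"{label}:Pf"),
            _summarize(self.mu_probit[..., 0], f"{label}:mu_probit_Pr"),
            _summarize(self.mu_probit[..., 1], f"{label}:mu_probit_Pf"),
            _summarize(np.sqrt(self.sigma[..., 0]), f"{label}:sd_probit_Pr"),
            _summarize(np.sqrt(self.sigma[..., 1]), f"{label}:sd_probit_Pf"),
            _summarize(
                self.sigma[..., 2]
                / np.sqrt(self.sigma[..., 0] * self.sigma[..., 1]),
                f"{label}:rho",
            ),
        ]
        self.summaries = out
        self.converged = all(
            s.rhat is None or s.rhat < RHAT_THRESHOLD for s in out
        )
        if not self.converged:
            worst = max(s.rhat for s in out if s.rhat is not None)
            logger.warning(
                "MPT cell %s: possible non-convergence (max R-hat %.3f); "
                "summaries returned but should be treated with caution",
                label, worst,
            )
        return out


@dataclass
class MPTFit:
    """Fit results for all cells, plus convenience accessors."""

    cells: dict[tuple[str, str], CellFit]
    spec: HierarchicalSpec

    def cell(self, age_group: str, condition) -> CellFit:
        key = (str(getattr(age_group, "value", age_group)),
               str(getattr(condition, "value", condition)))
        return self.cells[key]

    @property
    def converged(self) -> bool:
        return all(c.converged for c in self.cells.values())

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells.values():
            for s in cell.summaries:
                rows.append({"age_group": cell.age_group,
                             "condition": cell.condition, **s.as_dict(),
                             "t1_ppp": cell.t1_ppp, "t2_ppp": cell.t2_ppp})
        return pd.DataFrame(rows)

    def draws_table(self) -> pd.DataFrame:
        """Long-format retained draws: one row per chain x iteration x cell."""
        frames = []
        for cell in self.cells.values():
            n_chain, n_draw = cell.pr_draws.shape
            frames.append(pd.DataFrame({
                "age_group": cell.age_group,
                "condition": cell.condition,
                "chain": np.repeat(np.arange(n_chain), n_draw),
                "iteration": np.tile(np.arange(n_draw), n_chain),
                "Pr": cell.pr_draws.ravel(),
                "Pf": cell.pf_draws.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def repetition_effect(self, age_group: str, parameter: str = "Pf",
                          cond_hi: str = "CORRECTED_3X",
                          cond_lo: str = "CORRECTED_1X") -> PosteriorSummary:
        """Credible-difference summary for the fake-news repetition effect."""
        hi = self.cell(age_group, cond_hi)
        lo = self.cell(age_group, cond_lo)
        a = hi.pf_draws if parameter == "Pf" else hi.pr_draws
        b = lo.pf_draws if parameter == "Pf" else lo.pr_draws
        return credible_difference(
            a, b, label=f"{age_group}:{parameter}:repetition")

    def age_effect(self, condition: str, parameter: str = "Pf",
                   group_a: str = "YOUNGER", group_b: str = "OLDER"
                   ) -> PosteriorSummary:
        a_cell = self.cell(group_a, condition)
        b_cell = self.cell(group_b, condition)
        a = a_cell.pf_draws if parameter == "Pf" else a_cell.pr_draws
        b = b_cell.pf_draws if parameter == "Pf" else b_cell.pr_draws
        return credible_difference(
            a, b, label=f"{condition}:{parameter}:age")


def credible_difference(drawsA, drawsB, label: str = "difference"
                        ) -> PosteriorSummary:
    """Summarize drawsA - drawsB; credible iff the 95% CI excludes zero.

    The draws must be aligned samples of equal length (chains are
    flattened; a (chain, draw) layout is preserved for diagnostics).
    """
    a = np.asarray(drawsA, dtype=float)
    b = np.asarray(drawsB, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"draw shapes differ: {a.shape} vs {b.shape}")
    diff = a - b
    s = _summarize(diff if diff.ndim == 2 else diff[None, :], label)
    credible = not (s.ci95[0] <= 0.0 <= s.ci95[1])
    return replace(s, credible=credible)


def counts_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Phase-3 category counts per participant x correction condition.

    Only the conditions that corrected fake news enter the MPT. Returns
    columns (participant_id, age_group, condition, n_real, n_fake,
    n_novel).
    """
    p3 = trials[trials["phase"] == "P3_TEST"]
    corr = {c.value for c in CORRECTION_CONDITIONS}
    p3 = p3[p3["condition"].isin(corr)]
    tab = (
        p3.groupby(["participant_id", "age_group", "condition"])["p3_choice"]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=["REAL", "FAKE", "NOVEL"], fill_value=0)
        .reset_index()
        .rename(columns={"REAL": "n_real", "FAKE": "n_fake", "NOVEL": "n_novel"})
    )
    tab.columns.name = None
    return tab


def simulate_category_counts(mu_probit: tuple[float, float],
                             sigma: np.ndarray, n_participants: int,
                             n_trials: int, seed: int,
                             novel_branch: NovelBranch = NovelBranch.UNIFORM_THIRDS
                             ) -> np.ndarray:
    """Generate (n, 3) category counts from the latent-trait model itself.

    Used for parameter-recovery and calibration studies: participant
    probits are multivariate normal around ``mu_probit`` with covariance
    ``sigma``; counts are multinomial under the tree.
    """
    rng = np.random.default_rng(seed)
    theta = rng.multivariate_normal(np.asarray(mu_probit, float),
                                    np.asarray(sigma, float),
                                    size=n_participants)
    probs = _tree_probs_from_theta(theta, novel_branch)
    return np.array([rng.multinomial(n_trials, p) for p in probs])


def _validate_counts(tab: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "age_group", "condition",
                "n_real", "n_fake", "n_novel"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    counts = tab[["n_real", "n_fake", "n_novel"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("category counts must be non-negative")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("every participant cell needs at least one trial")
    return tab


def fit_hierarchical(counts: pd.DataFrame, spec: HierarchicalSpec | None = None
                     ) -> MPTFit:
    """Fit the latent-trait MPT separately per age group x condition cell.

    Parameters
    ----------
    counts:
        Long table with columns (participant_id, age_group, condition,
        n_real, n_fake, n_novel); correction conditions only.
    spec:
        MCMC settings; defaults to the desk-scale profile.

    Returns
    -------
    MPTFit with per-cell posterior draws (post burn-in, thinned), group
    summaries on the probability scale, R-hat/ESS diagnostics, and
    posterior-predictive p-values (filled in by
    :func:`corrmem.mpt.ppc.ppc_fit`). Deterministic for a fixed spec.
    """
    from corrmem.mpt.ppc import ppc_fit

    if spec is None:
        spec = HierarchicalSpec()
    tab = _validate_counts(counts)
    cells: dict[tuple[str, str], CellFit] = {}
    cell_keys = sorted(
        tab.groupby(["age_group", "condition"]).groups.keys())
    for idx, (age, cond) in enumerate(cell_keys):
        sub = tab[(tab["age_group"] == age) & (tab["condition"] == cond)]
        if len(sub) < 2:
            raise ValueError(
                f"cell {age}x{cond} has {len(sub)} participants; need >= 2")
        cmat = sub[["n_real", "n_fake", "n_novel"]].to_numpy(dtype=float)
        chain_out = []
        for chain in range(spec.n_chains):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, idx, chain]))
            chain_out.append(_run_chain(cmat, spec, rng))
        cell = CellFit(
            age_group=str(age), condition=str(cond),
            participant_ids=list(sub["participant_id"]),
            counts=cmat,
            mu_probit=np.stack([c["mu"] for c in chain_out]),
            sigma=np.stack([c["sigma"] for c in chain_out]),
            theta=np.stack([c["theta"] for c in chain_out]),
            novel_branch=spec.novel_branch,
        )
        cell.summarize()
        if spec.run_ppc:
            cell.t1_ppp, cell.t2_ppp = ppc_fit(cell)
        cells[(str(age), str(cond))] = cell
    return MPTFit(cells=cells, spec=spec)
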