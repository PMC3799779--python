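"""Family disease-burden statistic for sequencing prioritisation.

A family of N members with y_obs affected is scored by the tail
probability P(Y >= y_obs | observed genotypes): how surprising its
disease burden is given the known-locus risk its members carry.
Families with small tail probabilities carry disease that the known
loci cannot explain, and are the best candidates for sequencing.

Given complete genotypes, member disease probabilities come from the
logistic risk model and the affected count Y is Poisson-binomial (a sum
of independent, non-identical Bernoullis), whose tail is evaluated
exactly by dynamic-programming convolution.  Missing genotypes are
integrated out by averaging the exact tail over replicates drawn from
the conditional genotype distribution (inside-outside sampling).  An
optional polygenic residual adds a multivariate-normal liability term
with covariance 2 * kinship * residual_variance shared along the
pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .inside_outside import sample_genotypes
from .pedigree import ObservedGenotypes, Pedigree, kinship
from .risk_model import VariantPanel

__all__ = [
    "PolygenicSpec",
    "BurdenResult",
    "poisson_binomial_tail",
    "poisson_binomial_tail_batch",
    "burden_statistic",
    "rank_families",
]


@dataclass(frozen=True)
class PolygenicSpec:
    """Optional unobserved polygenic liability residual."""

    residual_variance: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_variance < 1.0:
            raise ValueError("residual_variance must lie in [0, 1)")


@dataclass
class BurdenResult:
    """Tail probability P(Y >= y_obs | G_obs) and bookkeeping."""

    p_tail: float
    mc_se: float
    expected_affected: float
    replicates: int
    y_obs: int
    n_members: int
    family_id: str = ""


def poisson_binomial_tail(p: np.ndarray, y: int) -> float:
    """Exact P(sum_j Bernoulli(p_j) >= y) by DP convolution, O(N^2)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D probability vector")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    N = p.size
    if not 0 <= y <= N:
        raise ValueError(f"y={y} outside [0, {N}]")
    return float(poisson_binomial_tail_batch(p[None, :], y)[0])


def poisson_binomial_tail_batch(P: np.ndarray, y: int) -> np.ndarray:
    """Vectorized exact tail for a batch: P is (batch, N), one y for all."""
    P = np.asarray(P, dtype=float)
    B, N = P.shape
    if y <= 0:
        return np.ones(B)
    if y > N:
        raise ValueError(f"y={y} exceeds family size {N}")
    # pmf[:, k] = P(exactly k affected among members processed so far)
    pmf = np.zeros((B, N + 1))
    pmf[:, 0] = 1.0
    for j in range(N):
        pj = P[:, j][:, None]
        shifted = np.zeros_like(pmf)
        shifted[:, 1:] = pmf[:, :-1]
        pmf = pmf * (1.0 - pj) + shifted * pj
    return pmf[:, y:].sum(axis=1)


def burden_statistic(
    ped: Pedigree,
    obs: ObservedGenotypes,
    panel: VariantPanel,
    alpha: float,
    R: int = 10_000,
    seed: int = 0,
    pg: PolygenicSpec | None = None,
) -> BurdenResult:
    """Tail probability of the family's affected count given its genotypes.

    Member disease probabilities are expit(alpha + sum_i b_i g_ij) with
    the panel's log odds ratios.  Fully genotyped families (polygenic
    residual disabled) need no sampling and return a deterministic exact
    Poisson-binomial tail with zero Monte-Carlo error; otherwise the
    tail is averaged over R conditional genotype replicates (and, when
    enabled, per-replicate polygenic liability draws folded in on the
    probit scale via the score-implied threshold equivalent
    T_j = Phi^{-1}(1 - p_j), giving p_j' = 1 - Phi(T_j - r_j)).
    """
    if R < 1:
        raise ValueError("replicate count R must be >= 1")
    pg = pg or PolygenicSpec()
    y_obs = ped.affected_count()
    n = ped.n
    D = obs.matrix(ped)  # (n, L)
    fully_observed = not np.any(np.isnan(D))
    rng = np.random.default_rng(seed)

    if fully_observed and not pg.enabled:
        eta = alpha + D @ panel.effect
        probs = expit(eta)
        p_tail = poisson_binomial_tail(probs, y_obs)
        return BurdenResult(
            p_tail=p_tail,
            mc_se=0.0,
            expected_affected=float(probs.sum()),
            replicates=1,
            y_obs=y_obs,
            n_members=n,
            family_id=ped.family_id,
        )

    if fully_observed:
        G = np.broadcast_to(D[None, :, :], (R, n, D.shape[1]))
    else:
        G = sample_genotypes(ped, obs, panel.freq, R, seed=seed).dosages
    eta = alpha + np.einsum("rnl,l->rn", G.astype(float), panel.effect)
    probs = expit(eta)  # (R, n)

    if pg.enabled and pg.residual_variance > 0.0:
        cov = 2.0 * kinship(ped) * pg.residual_variance
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        resid = rng.standard_normal((R, n)) @ chol.T
        thresh = norm.isf(np.clip(probs, 1e-300, 1 - 1e-16))
        probs = norm.sf(thresh - resid)

    tails = poisson_binomial_tail_batch(probs, y_obs)
    p_tail = float(tails.mean())
    mc_se = float(tails.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0
    return BurdenResult(
        p_tail=p_tail,
        mc_se=mc_se,
        expected_affected=float(probs.sum(axis=1).mean()),
        replicates=R,
        y_obs=y_obs,
        n_members=n,
        family_id=ped.family_id,
    )


def rank_families(results: list[BurdenResult]) -> list[int]:
    """Priority order (indices into ``results``), best sequencing target first.

    Ascending tail probability; ties broken by smaller expected affected
    count (the more surprising family first), then input order.
    """
    if not results:
        raise ValueError("rank_families requires at least one result")
    return sorted(
        range(len(results)),
        key=lambda i: (results[i].p_tail, results[i].expected_affected, i),
    )
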