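"""Simulators: ascertained nuclear families, liability cohorts, pedigrees.

The family simulator follows an infinitesimal liability-threshold
model.  Liability decomposes into a known risk score s ~ Normal(0, V),
a residual genetic component ~ Normal(0, h2 - V) and an environment
component ~ Normal(0, 1 - h2); offspring inherit each heritable
component as the parental midpoint plus a segregation deviate with half
the component variance.  Disease is liability > T(K).  Families are
ascertained by rejection sampling to an exact affected count, the way
multiplex families enter sequencing studies.  Optionally one parent
carries a dominant mutation (transmitted with probability 1/2) that
adds a fixed liability increment to carriers, sized so that the
marginal carrier penetrance P(affected | carrier) is exactly gamma.

The mutation-detection experiment ranks mutation versus non-mutation
families by the burden tail probability computed from member scores
alone, and summarises discrimination as the Mann-Whitney AUC.

The cohort simulators provide large unrelated-individual samples used
as Monte-Carlo oracles for the analytic selection theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .family_burden import poisson_binomial_tail_batch
from .pedigree import AFFECTED, Individual, Pedigree, UNAFFECTED
from .selection_theory import (
    DiseaseDesign,
    TestVariant,
    liability_threshold,
    or_to_liability_shift,
)

__all__ = [
    "FamilyModel",
    "SimulatedFamilies",
    "simulate_families",
    "simulate_family",
    "burden_tail_from_scores",
    "mutation_detection_auc",
    "detection_auc_grid",
    "auc",
    "simulate_cohort",
    "simulate_trait_cohort",
    "random_pedigree",
]


@dataclass(frozen=True)
class FamilyModel:
    """Design of one simulated nuclear-family cell.

    K: disease prevalence; h2: total liability heritability; V:
    liability variance explained by the known risk score (V <= h2);
    n_offspring: children per family; n_affected_required: exact
    affected count for ascertainment; mutation_present: whether one
    parent (the father, heterozygous) carries a dominant mutation of
    carrier penetrance ``penetrance``.
    """

    K: float = 0.01
    h2: float = 0.5
    V: float = 0.125
    n_offspring: int = 2
    n_affected_required: int = 3
    mutation_present: bool = False
    penetrance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError("prevalence K must lie in (0, 1)")
        if not 0.0 <= self.V <= self.h2 < 1.0:
            raise ValueError("need 0 <= V <= h2 < 1")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in (0, 1]")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if not 0 <= self.n_affected_required <= self.n_offspring + 2:
            raise ValueError("n_affected_required must be <= family size")

    @property
    def n_members(self) -> int:
        return self.n_offspring + 2


@dataclass
class SimulatedFamilies:
    """Accepted families; member axis is (father, mother, offspring...)."""

    model: FamilyModel
    score: np.ndarray  # (families, members) known risk score, liability units
    genetic_resid: np.ndarray  # (families, members)
    environment: np.ndarray  # (families, members)
    affected: np.ndarray  # (families, members) bool
    carrier: np.ndarray  # (families, members) bool
    attempts: int  # rejection-sampling attempts consumed

    @property
    def n_families(self) -> int:
        return self.score.shape[0]


_MAX_ATTEMPTS = 10_000_000
_MIN_ACCEPTANCE = 1e-6


def _simulate_batch(model: FamilyModel, B: int, rng: np.random.Generator):
    k = model.n_offspring
    m = model.n_members

    def heritable(var: float) -> np.ndarray:
        comp = np.empty((B, m))
        comp[:, :2] = rng.normal(0.0, np.sqrt(var), (B, 2)) if var > 0 else 0.0
        mid = comp[:, :2].mean(axis=1, keepdims=True)
        seg = rng.normal(0.0, np.sqrt(var / 2.0), (B, k)) if var > 0 else 0.0
        comp[:, 2:] = mid + seg
        return comp

    s = heritable(model.V)
    a = heritable(model.h2 - model.V)
    e = rng.normal(0.0, np.sqrt(1.0 - model.h2), (B, m))
    T = liability_threshold(model.K)
    liab = s + a + e
    carrier = np.zeros((B, m), dtype=bool)
    if model.mutation_present:
        carrier[:, 0] = True  # designated carrier parent (heterozygous)
        carrier[:, 2:] = rng.random((B, k)) < 0.5  # Mendelian transmission
        # liability increment sized so the marginal carrier penetrance,
        # P(affected | carrier), is exactly gamma (infinite at gamma=1)
        shift = T - norm.isf(model.penetrance)
        liab = liab + np.where(carrier, shift, 0.0)
    affected = liab > T
    return s, a, e, affected, carrier


def simulate_families(
    model: FamilyModel, n_families: int, seed: int = 0
) -> SimulatedFamilies:
    """Rejection-sample families with exactly the required affected count."""
    rng = np.random.default_rng(seed)
    keep: list[tuple] = []
    kept = 0
    attempts = 0
    batch = max(2048, min(200_000, 50 * n_families))
    while kept < n_families:
        s, a, e, aff, car = _simulate_batch(model, batch, rng)
        attempts += batch
        ok = aff.sum(axis=1) == model.n_affected_required
        if ok.any():
            keep.append((s[ok], a[ok], e[ok], aff[ok], car[ok]))
            kept += int(ok.sum())
        if attempts >= _MAX_ATTEMPTS and kept < attempts * _MIN_ACCEPTANCE:
            raise RuntimeError(
                "ascertainment acceptance rate below 1e-6; "
                "the requested affected count is practically infeasible"
            )
    s, a, e, aff, car = (np.concatenate(parts)[:n_families] for parts in zip(*keep))
    return SimulatedFamilies(
        model=model,
        score=s,
        genetic_resid=a,
        environment=e,
        affected=aff,
        carrier=car,
        attempts=attempts,
    )


def simulate_family(model: FamilyModel, seed: int = 0) -> SimulatedFamilies:
    """A single accepted family (convenience wrapper)."""
    return simulate_families(model, 1, seed=seed)


def burden_tail_from_scores(
    score: np.ndarray, y_obs: int, K: float, V: float
) -> np.ndarray:
    """Exact burden tails P(Y >= y_obs | member scores) for many families.

    Given a member's known score s, the residual liability is
    Normal(0, 1 - V), so the member's disease probability is
    1 - Phi((T - s) / sqrt(1 - V)); the affected count is
    Poisson-binomial across members (conditionally independent given
    scores).
    """
    T = liability_threshold(K)
    p = norm.sf((T - np.asarray(score, dtype=float)) / np.sqrt(1.0 - V))
    return poisson_binomial_tail_batch(p, y_obs)


def auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC with *smaller* statistics ranked as positive-like.

    Returns P(pos < neg) + 0.5 P(pos = neg): the probability that a
    randomly chosen positive (mutation) family has the more extreme
    (smaller) statistic than a random negative family.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    r = rankdata(np.concatenate([pos, neg]))
    u_greater = r[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(1.0 - u_greater / (pos.size * neg.size))


def mutation_detection_auc(
    K: float = 0.01,
    h2: float = 0.5,
    V: float = 0.125,
    n_offspring: int = 2,
    penetrance: float = 0.5,
    n_families: int = 5000,
    seed: int = 0,
) -> float:
    """AUC for spotting the dominant-mutation families in one design cell.

    Simulates ``n_families`` mutation and ``n_families`` non-mutation
    ascertained families (3 affected by default), scores each by its
    burden tail from member scores, and returns the probability that a
    mutation family looks more surprising than a non-mutation one.
    """
    base = dict(K=K, h2=h2, V=V, n_offspring=n_offspring)
    fam_mut = simulate_families(
        FamilyModel(**base, mutation_present=True, penetrance=penetrance),
        n_families,
        seed=seed,
    )
    fam_null = simulate_families(
        FamilyModel(**base, mutation_present=False, penetrance=penetrance),
        n_families,
        seed=seed + 1,
    )
    y = fam_mut.model.n_affected_required
    t_mut = burden_tail_from_scores(fam_mut.score, y, K, V)
    t_null = burden_tail_from_scores(fam_null.score, y, K, V)
    return auc(t_mut, t_null)


def detection_auc_grid(
    family_sizes: list[int],
    penetrances: list[float],
    K: float = 0.01,
    h2: float = 0.5,
    V: float = 0.125,
    n_families_per_cell: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC over a grid of offspring counts x mutation penetrances."""
    if n_families_per_cell < 100:
        raise ValueError("need at least 100 families per cell")
    rows = []
    for ci, k in enumerate(family_sizes):
        for cj, gamma in enumerate(penetrances):
            cell_seed = seed + 1000 * ci + cj
            a = mutation_detection_auc(
                K=K,
                h2=h2,
                V=V,
                n_offspring=k,
                penetrance=gamma,
                n_families=n_families_per_cell,
                seed=cell_seed,
            )
            rows.append({"n_offspring": k, "penetrance": gamma, "auc": a})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# unrelated-individual cohort simulators (Monte-Carlo oracles)


def simulate_cohort(
    K: float, V: float, variant: TestVariant, n: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Liability-model cohort with one test variant.

    Returns arrays ``score`` (s ~ Normal(0, V)), ``genotype``
    (Binomial(2, f_v)) and ``affected`` (liability = s + residual +
    delta (g - 2 f_v) thresholded at T(K)), with delta calibrated so the
    marginal allele-based odds ratio equals the variant's.
    """
    d = DiseaseDesign(K=K, V=V)
    delta = (
        or_to_liability_shift(variant, d) if variant.odds_ratio is not None else 0.0
    )
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, np.sqrt(V), n) if V > 0 else np.zeros(n)
    g = rng.binomial(2, variant.f_v, n)
    r = rng.normal(0.0, np.sqrt(1.0 - V), n)
    liab = s + r + delta * (g - 2.0 * variant.f_v)
    return {"score": s, "genotype": g, "affected": liab > d.T}


def simulate_trait_cohort(
    beta_v: float, f_v: float, V: float, n: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Standardized quantitative-trait cohort with one test variant.

    ``delta`` is the residual after removing the known score: given g it
    is Normal(beta_v (g - 2 f_v), 1 - V).  ``trait`` = score + delta is
    the raw standardized trait.
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, np.sqrt(V), n) if V > 0 else np.zeros(n)
    g = rng.binomial(2, f_v, n)
    delta = beta_v * (g - 2.0 * f_v) + rng.normal(0.0, np.sqrt(1.0 - V), n)
    return {"score": s, "genotype": g, "delta": delta, "trait": s + delta}


# ----------------------------------------------------------------------
# random tree pedigrees (for property tests and scaling studies)


def random_pedigree(
    n_members: int,
    seed: int = 0,
    max_children: int = 3,
    affected_frac: float = 0.0,
) -> Pedigree:
    """A random loop-free pedigree with exactly ``n_members`` members.

    Grown from a founder couple by repeatedly marrying a new founder
    spouse to a random childless non-founder and giving the couple
    children; every married-in spouse is a founder, so the result is
    always a valid nuclear-unit tree.  Requires ``n_members >= 3``.
    """
    if n_members < 3:
        raise ValueError("a connected pedigree needs at least 3 members (a trio)")
    rng = np.random.default_rng(seed)
    members: list[Individual] = []
    counter = [0]

    def new_person(sex: int, father=None, mother=None) -> str:
        counter[0] += 1
        iid = f"I{counter[0]}"
        members.append(Individual(iid=iid, father=father, mother=mother, sex=sex))
        return iid

    def add_children(father: str, mother: str, k: int) -> list[str]:
        return [
            new_person(int(rng.integers(1, 3)), father=father, mother=mother)
            for _ in range(k)
        ]

    fa = new_person(1)
    mo = new_person(2)
    k = int(rng.integers(1, max_children + 1))
    k = min(k, n_members - 2)
    unmarried = add_children(fa, mo, k)
    couples = [(fa, mo)]

    while len(members) < n_members:
        remaining = n_members - len(members)
        if remaining == 1 or not unmarried:
            fa2, mo2 = couples[int(rng.integers(len(couples)))]
            add_children(fa2, mo2, 1)
            continue
        pick = int(rng.integers(len(unmarried)))
        conn = unmarried.pop(pick)
        conn_sex = next(m for m in members if m.iid == conn).sex
        spouse = new_person(2 if conn_sex == 1 else 1)
        father, mother = (conn, spouse) if conn_sex == 1 else (spouse, conn)
        k = int(rng.integers(1, max_children + 1))
        k = min(k, n_members - len(members))  # >= 1 because remaining >= 2
        unmarried.extend(add_children(father, mother, k))
        couples.append((father, mother))

    if affected_frac > 0:
        for m in members:
            m.affection = (
                AFFECTED if rng.random() < affected_frac else UNAFFECTED
            )
    ped = Pedigree(members=members[:], family_id="SIM")
    return ped
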