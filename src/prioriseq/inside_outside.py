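"""Exact genotype posteriors and conditional sampling on tree pedigrees.

A modified inside-outside algorithm (the tree generalisation of the
HMM forward-backward recursion) over the rooted nuclear-unit tree of a
pedigree.  For each individual and locus the *inside* probability is
the probability of the observed genotype data in that individual's
subtree given their own genotype; the *outside* probability covers the
data in the rest of the pedigree.  Their normalized product is the
exact marginal genotype posterior conditional on all observed data.

Sampling of complete genotype configurations proceeds down the tree
from the root: each married-in spouse is drawn conditional on their
partner's sampled genotype, and each child conditional on both sampled
parents, always weighted by the child's own inside probability — so
every replicate is an exact draw from the joint posterior
P(G_unobs | G_obs, family structure, allele frequency).

Loci are modelled as independent (unlinked, linkage equilibrium) and
genotypes as effect-allele dosages at biallelic loci, so all tables are
3-state.  Observation factors are hard 0/1 indicators: observed
genotypes are conditioned on exactly, with no genotyping-error model.
All computations are vectorized across loci, and per-unit
renormalization (with the constants folded into the log-likelihood
accumulator) guards against underflow on large pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import ObservedGenotypes, Pedigree, UnitTree

__all__ = [
    "MendelianError",
    "transmission",
    "InsideTables",
    "PosteriorTables",
    "SampledGenotypes",
    "inside_pass",
    "outside_pass",
    "sample_genotypes",
]


class MendelianError(ValueError):
    """Observed genotypes are impossible under Mendelian transmission."""


def transmission(f):
    """Founder prior and Mendelian transmission kernel for frequency f.

    Returns ``(prior, M)`` where ``prior`` is the Hardy-Weinberg founder
    genotype distribution ((1-f)^2, 2f(1-f), f^2) and ``M[gm, gf, gc]``
    = P(child dosage gc | mother gm, father gf), the exact Mendelian
    table (each parent transmits the effect allele with probability 0,
    1/2 or 1 according to dosage).  ``f`` may be a scalar or a per-locus
    array; arrays get a leading locus axis.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0.0) or np.any(f_arr >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    L = f_arr.size
    prior = np.stack([(1 - f_arr) ** 2, 2 * f_arr * (1 - f_arr), f_arr**2], axis=1)
    t = np.array([0.0, 0.5, 1.0])  # transmission prob of effect allele by dosage
    a = t[:, None]  # mother
    b = t[None, :]  # father
    M = np.empty((3, 3, 3))
    M[:, :, 0] = (1 - a) * (1 - b)
    M[:, :, 1] = a * (1 - b) + b * (1 - a)
    M[:, :, 2] = a * b
    M = np.broadcast_to(M, (L, 3, 3, 3)).copy()
    if np.isscalar(f) or np.asarray(f).ndim == 0:
        return prior[0], M[0]
    return prior, M


@dataclass
class _Engine:
    """Shared state for the message passing over one pedigree."""

    ped: Pedigree
    tree: UnitTree
    prior: np.ndarray  # (L, 3)
    M: np.ndarray  # (L, 3, 3, 3) [locus, g_mother, g_father, g_child]
    obsfactor: np.ndarray  # (n, L, 3) hard 0/1
    locus_ids: list
    inside: np.ndarray | None = None
    logacc: np.ndarray | None = None
    lik_per_locus: np.ndarray | None = None
    child_msg: dict = field(default_factory=dict)  # iid -> (L,3,3) [gm,gf]
    unit_ms: dict = field(default_factory=dict)  # unit idx -> (L,3) on connector
    conn_units: dict = field(default_factory=dict)  # iid -> [unit idx]


def _locus_name(eng: _Engine, l: int) -> str:
    return str(eng.locus_ids[l]) if eng.locus_ids else f"locus {l}"


def _build_engine(ped: Pedigree, obs: ObservedGenotypes, f) -> _Engine:
    tree = ped.validate()
    D = obs.matrix(ped)  # (n, L)
    L = D.shape[1]
    f_arr = np.broadcast_to(np.atleast_1d(np.asarray(f, dtype=float)), (L,))
    prior, M = transmission(f_arr.copy())
    O = np.ones((ped.n, L, 3))
    observed = ~np.isnan(D)
    gi = np.zeros_like(D, dtype=int)
    gi[observed] = D[observed].astype(int)
    for g in range(3):
        mask = observed & (gi != g)
        O[:, :, g][mask] = 0.0
    eng = _Engine(
        ped=ped,
        tree=tree,
        prior=prior,
        M=M,
        obsfactor=O,
        locus_ids=list(obs.locus_ids),
    )
    for k in tree.order:
        u = tree.units[k]
        eng.conn_units.setdefault(u.connector, []).append(k)
    return eng


def _couple_pair_axes(eng: _Engine, k: int) -> bool:
    """True when the unit's connector is the mother."""
    u = eng.tree.units[k]
    return u.connector == u.mother


def _run_inside(eng: _Engine) -> None:
    ped, tree = eng.ped, eng.tree
    inside = eng.obsfactor.copy()
    L = inside.shape[1]
    logacc = np.zeros(L)

    for k in reversed(tree.order):
        u = tree.units[k]
        conn_is_mother = _couple_pair_axes(eng, k)
        # per-child messages indexed [locus, g_mother, g_father]
        pair = np.ones((L, 3, 3))
        for c in u.children:
            msg = np.einsum("lmfc,lc->lmf", eng.M, inside[ped.index(c)])
            eng.child_msg[c] = msg
            pair = pair * msg
        sp = ped.index(u.spouse)
        spouse_total = eng.prior * inside[sp]  # (L, 3)
        if conn_is_mother:
            ms = np.einsum("lmf,lf->lm", pair, spouse_total)
        else:
            ms = np.einsum("lmf,lm->lf", pair, spouse_total)
        eng.unit_ms[k] = ms
        ci = ped.index(u.connector)
        inside[ci] = inside[ci] * ms
        ssum = inside[ci].sum(axis=1)
        bad = np.flatnonzero(ssum == 0.0)
        if bad.size:
            raise MendelianError(
                f"observed genotypes are Mendelian-impossible at "
                f"{_locus_name(eng, bad[0])}"
            )
        inside[ci] = inside[ci] / ssum[:, None]
        logacc = logacc + np.log(ssum)

    r = ped.index(tree.root_individual)
    lik = np.einsum("lg,lg->l", eng.prior, inside[r])
    bad = np.flatnonzero(lik == 0.0)
    if bad.size:
        raise MendelianError(
            f"observed genotypes are Mendelian-impossible at "
            f"{_locus_name(eng, bad[0])}"
        )
    eng.inside = inside
    eng.logacc = logacc
    eng.lik_per_locus = np.log(lik) + logacc


@dataclass
class InsideTables:
    """Inside probabilities plus the data log-likelihood."""

    inside: np.ndarray  # (n_members, n_loci, 3)
    loglik: float
    loglik_per_locus: np.ndarray
    member_ids: list
    locus_ids: list
    _engine: _Engine | None = None


@dataclass
class PosteriorTables:
    """Inside, outside and marginal genotype posteriors per member/locus."""

    inside: np.ndarray
    outside: np.ndarray
    marginal: np.ndarray
    loglik: float
    member_ids: list
    locus_ids: list


@dataclass
class SampledGenotypes:
    """R complete Mendelian-consistent dosage replicates (R x members x loci)."""

    dosages: np.ndarray
    member_ids: list
    locus_ids: list
    seed: int


def inside_pass(ped: Pedigree, obs: ObservedGenotypes, f) -> InsideTables:
    """Leaf-to-root message passing; returns inside tables and log-likelihood.

    ``f`` is the population effect-allele frequency (scalar, or one per
    locus).  The log-likelihood is that of all observed genotype data
    under Hardy-Weinberg founders and Mendelian transmission.
    """
    eng = _build_engine(ped, obs, f)
    _run_inside(eng)
    return InsideTables(
        inside=eng.inside,
        loglik=float(eng.lik_per_locus.sum()),
        loglik_per_locus=eng.lik_per_locus,
        member_ids=ped.ids,
        locus_ids=eng.locus_ids,
        _engine=eng,
    )


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s == 0.0):
        raise MendelianError("zero posterior mass encountered")
    return x / s


def outside_pass(inside_tables: InsideTables) -> PosteriorTables:
    """Root-to-leaf pass; marginal(i, g) is proportional to inside * outside."""
    eng = inside_tables._engine
    if eng is None:
        raise ValueError("inside_tables must come from inside_pass")
    ped, tree = eng.ped, eng.tree
    inside = eng.inside
    n, L = inside.shape[:2]
    outside = np.zeros_like(inside)
    r = ped.index(tree.root_individual)
    outside[r] = eng.prior

    for k in tree.order:
        u = tree.units[k]
        conn_is_mother = _couple_pair_axes(eng, k)
        ci = ped.index(u.connector)
        sp = ped.index(u.spouse)
        # connector factor excluding this unit's subtree
        conn_excl = outside[ci] * eng.obsfactor[ci]
        for k2 in eng.conn_units.get(u.connector, []):
            if k2 != k:
                conn_excl = conn_excl * eng.unit_ms[k2]
        conn_excl = _normalize_rows(conn_excl)
        spouse_total = eng.prior * inside[sp]

        msgs = [eng.child_msg[c] for c in u.children]
        nc = len(msgs)
        prefix = [np.ones((L, 3, 3))]
        for m in msgs:
            prefix.append(prefix[-1] * m)
        suffix = [np.ones((L, 3, 3)) for _ in range(nc + 1)]
        for i in range(nc - 1, -1, -1):
            suffix[i] = suffix[i + 1] * msgs[i]
        kidprod = prefix[nc]  # (L, 3, 3) [gm, gf]

        # married-in spouse: prior x (connector side + all children of this unit)
        if conn_is_mother:
            out_sp = eng.prior * np.einsum("lmf,lm->lf", kidprod, conn_excl)
        else:
            out_sp = eng.prior * np.einsum("lmf,lf->lm", kidprod, conn_excl)
        outside[sp] = _normalize_rows(out_sp)

        # couple joint over (g_mother, g_father), excluding the children
        if conn_is_mother:
            couple = conn_excl[:, :, None] * spouse_total[:, None, :]
        else:
            couple = spouse_total[:, :, None] * conn_excl[:, None, :]
        for i, c in enumerate(u.children):
            loo = prefix[i] * suffix[i + 1]
            out_c = np.einsum("lmfc,lmf->lc", eng.M, couple * loo)
            outside[ped.index(c)] = _normalize_rows(out_c)

    if not tree.order:  # singleton pedigree
        pass
    marginal = _normalize_rows(inside * outside)
    return PosteriorTables(
        inside=inside,
        outside=outside,
        marginal=marginal,
        loglik=inside_tables.loglik,
        member_ids=ped.ids,
        locus_ids=eng.locus_ids,
    )


def _draw_categorical(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw over the last axis of unnormalized w."""
    cdf = np.cumsum(w, axis=-1)
    tot = cdf[..., -1]
    if np.any(tot <= 0.0):
        raise MendelianError("zero sampling mass encountered")
    u = rng.random(tot.shape) * tot
    return (u[..., None] >= cdf).sum(axis=-1)


_MAX_SAMPLE_CELLS = 2_000_000_000


def sample_genotypes(
    ped: Pedigree, obs: ObservedGenotypes, f, R: int, seed: int
) -> SampledGenotypes:
    """Draw R complete genotype replicates conditional on the observed data.

    Top-down over the rooted unit tree: the root is drawn from its exact
    marginal, each married-in spouse conditional on the partner's
    sampled genotype (weighted by prior, own observation and own
    subtree), and each child conditional on both sampled parents
    (weighted by its inside probability).  Loci are sampled
    independently; observed entries are reproduced exactly.  Traversal
    order is a fixed pre-order, so results are reproducible for a given
    seed.
    """
    if R < 1:
        raise ValueError("replicate count R must be >= 1")
    eng = _build_engine(ped, obs, f)
    _run_inside(eng)
    ped_, tree = eng.ped, eng.tree
    inside = eng.inside
    n, L = inside.shape[:2]
    if R * n * L > _MAX_SAMPLE_CELLS:
        raise ValueError("R x members x loci too large; reduce the replicate count")
    rng = np.random.default_rng(seed)
    samples = np.empty((R, n, L), dtype=np.int8)

    r = ped_.index(tree.root_individual)
    w_root = (eng.prior * inside[r])[None, :, :] * np.ones((R, 1, 1))
    samples[:, r, :] = _draw_categorical(w_root, rng)

    l_idx = np.arange(L)[None, :]
    for k in tree.order:
        u = tree.units[k]
        conn_is_mother = _couple_pair_axes(eng, k)
        ci = ped_.index(u.connector)
        sp = ped_.index(u.spouse)
        g_conn = samples[:, ci, :]  # (R, L)

        kidprod = np.ones((L, 3, 3))
        for c in u.children:
            kidprod = kidprod * eng.child_msg[c]
        # orient to [locus, g_conn, g_spouse]
        kp = kidprod if conn_is_mother else kidprod.transpose(0, 2, 1)
        w_sp = kp[l_idx, g_conn, :] * (eng.prior * inside[sp])[None, :, :]
        g_sp = _draw_categorical(w_sp, rng)
        samples[:, sp, :] = g_sp

        gm, gf = (g_conn, g_sp) if conn_is_mother else (g_sp, g_conn)
        for c in u.children:
            cidx = ped_.index(c)
            w_c = eng.M[l_idx, gm, gf, :] * inside[cidx][None, :, :]
            samples[:, cidx, :] = _draw_categorical(w_c, rng)

    return SampledGenotypes(
        dosages=samples, member_ids=ped_.ids, locus_ids=eng.locus_ids, seed=seed
    )
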