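"""Independent brute-force oracles used across the test suite.

Everything here enumerates exhaustively and is deliberately independent
of the package's message-passing / dynamic-programming code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from prioriseq.inside_outside import transmission


def enumerate_pedigree(ped, obsmat, f):
    """Likelihood, marginals and per-config posterior by 3^N enumeration.

    Returns (likelihood, marginals (n,3), configs, config_posteriors)
    where configs are the complete genotype assignments consistent with
    the observations.
    """
    prior, M = transmission(float(f))
    n = ped.n
    idx = {m.iid: k for k, m in enumerate(ped.members)}
    total = 0.0
    marg = np.zeros((n, 3))
    configs, weights = [], []
    for cfg in itertools.product(range(3), repeat=n):
        ok = True
        p = 1.0
        for k, m in enumerate(ped.members):
            if not np.isnan(obsmat[k, 0]) and int(obsmat[k, 0]) != cfg[k]:
                ok = False
                break
            if m.is_founder:
                p *= prior[cfg[k]]
            else:
                p *= M[cfg[idx[m.mother]], cfg[idx[m.father]], cfg[k]]
        if not ok or p == 0.0:
            continue
        total += p
        marg += p * np.eye(3)[list(cfg)]
        configs.append(cfg)
        weights.append(p)
    if total == 0.0:
        return 0.0, marg, [], np.array([])
    return total, marg / total, configs, np.array(weights) / total


def pairwise_joint(ped, obsmat, f, iid_a, iid_b):
    """Exact joint conditional P(g_a, g_b | obs) by enumeration."""
    _, _, configs, post = enumerate_pedigree(ped, obsmat, f)
    ia, ib = ped.index(iid_a), ped.index(iid_b)
    joint = np.zeros((3, 3))
    for cfg, w in zip(configs, post):
        joint[cfg[ia], cfg[ib]] += w
    return joint


def exhaustive_poisson_binomial_tail(p, y):
    """P(sum Bernoulli(p_j) >= y) by 2^N enumeration."""
    p = np.asarray(p, dtype=float)
    N = p.size
    total = 0.0
    for bits in itertools.product((0, 1), repeat=N):
        w = np.prod(np.where(np.array(bits) == 1, p, 1 - p))
        if sum(bits) >= y:
            total += w
    return total


def enumerate_burden(ped, obsmat, f, effects, alpha, y_obs):
    """Exact E[P(Y >= y_obs | G)] over the conditional genotype law.

    effects: per-locus log odds ratios (single locus supported here);
    member disease probability expit(alpha + b * g).
    """
    from scipy.special import expit

    _, _, configs, post = enumerate_pedigree(ped, obsmat, f)
    total = 0.0
    for cfg, w in zip(configs, post):
        probs = expit(alpha + effects[0] * np.asarray(cfg, dtype=float))
        total += w * exhaustive_poisson_binomial_tail(probs, y_obs)
    return total
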