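"""Risk scoring from known disease loci.

Predicts phenotypes from genotype dosages at a panel of known risk loci,
using a linear model for quantitative traits and a logistic model for
binary (disease) traits, and selects individuals whose observed
phenotype is most poorly explained by their predicted one — the
residual extremes ("super cases" with low predicted risk and "super
controls" with high predicted risk) that are prime sequencing
candidates.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "VariantPanel",
    "GenotypeMatrix",
    "TraitSpec",
    "Prediction",
    "score_quantitative",
    "calibrate_intercept",
    "score_binary",
    "residuals",
    "select_extremes",
]


@dataclass
class VariantPanel:
    """A panel of known risk loci with frequencies and effect sizes.

    Parameters
    ----------
    variant_id
        Unique variant identifiers, one per locus.
    effect_allele, other_allele
        Allele labels; dosages count copies of the effect allele.
    freq
        Effect-allele frequency per locus, each strictly in (0, 1).
    effect
        Per-locus effect size: log odds ratio for binary traits
        (``effect_type="logOR"``), or a standardized beta — trait SD per
        standardized allele — for quantitative traits
        (``effect_type="beta"``).
    """

    variant_id: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    freq: np.ndarray
    effect: np.ndarray
    effect_type: str = "logOR"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        self.variant_id = list(self.variant_id)
        self.effect_allele = list(self.effect_allele)
        self.other_allele = list(self.other_allele)
        n = len(self.variant_id)
        if not (
            len(self.effect_allele) == len(self.other_allele) == n
            and self.freq.shape == (n,)
            and self.effect.shape == (n,)
        ):
            raise ValueError("panel fields must all have the same length")
        if len(set(self.variant_id)) != n:
            raise ValueError("variant_id entries must be unique")
        if np.any(self.freq <= 0.0) or np.any(self.freq >= 1.0):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if not np.all(np.isfinite(self.effect)):
            raise ValueError("effect sizes must be finite")
        if self.effect_type not in ("logOR", "beta"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")

    @property
    def n_loci(self) -> int:
        return len(self.variant_id)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (loci x individuals); entries 0/1/2 or NaN for missing."""

    dosages: np.ndarray
    locus_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (loci x individuals) matrix")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not np.all(valid):
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TraitSpec:
    """Trait description: quantitative (mu, sigma) or binary (prevalence)."""

    kind: str
    mu: float = 0.0
    sigma: float = 1.0
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError("kind must be 'quantitative' or 'binary'")
        if self.kind == "quantitative" and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("binary traits require prevalence in (0, 1)")


@dataclass
class Prediction:
    """Per-individual predicted phenotype, plus residuals when observed."""

    yhat: np.ndarray
    kind: str = "quantitative"
    delta: np.ndarray | None = None


def _check_pairing(panel: VariantPanel, G: GenotypeMatrix) -> None:
    if G.n_loci != panel.n_loci:
        raise ValueError(
            f"genotype matrix has {G.n_loci} loci but panel has {panel.n_loci}"
        )


def _imputed_dosages(panel: VariantPanel, G: GenotypeMatrix) -> np.ndarray:
    """Missing dosages mean-imputed to 2f (unbiased under HWE)."""
    d = G.dosages.copy()
    miss = np.isnan(d)
    if miss.any():
        fill = np.broadcast_to(2.0 * panel.freq[:, None], d.shape)
        d[miss] = fill[miss]
    return d


def score_quantitative(
    panel: VariantPanel, G: GenotypeMatrix, trait: TraitSpec
) -> Prediction:
    """Linear-model prediction of a quantitative trait.

    yhat_j = mu + sigma * sum_i beta_i (g_ij - 2 f_i) / sqrt(2 f_i (1 - f_i))

    Genotypes are centred and standardized so each beta_i is a
    per-standardized-allele effect; on the standardized trait scale the
    score's explained variance is then sum(beta_i^2).
    """
    if trait.kind != "quantitative":
        raise ValueError("score_quantitative requires a quantitative TraitSpec")
    _check_pairing(panel, G)
    d = _imputed_dosages(panel, G)
    z = (d - 2.0 * panel.freq[:, None]) / np.sqrt(
        2.0 * panel.freq[:, None] * (1.0 - panel.freq[:, None])
    )
    yhat = trait.mu + trait.sigma * (panel.effect @ z)
    return Prediction(yhat=yhat, kind="quantitative")


def _score_pmf(panel: VariantPanel, n_bins: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of sum_i b_i g_i over HWE genotypes at independent loci.

    Exact dosage-sum convolution collapsed onto a fixed log-odds grid;
    mass falling between grid points is split linearly between the two
    neighbours, so the discretization error is second order in the bin
    width.
    """
    b = panel.effect
    lo = float(np.sum(np.minimum(0.0, 2.0 * b)))
    hi = float(np.sum(np.maximum(0.0, 2.0 * b)))
    if hi - lo < 1e-12:
        return np.array([lo]), np.array([1.0])
    grid = np.linspace(lo, hi, n_bins)
    h = grid[1] - grid[0]
    pmf = np.zeros(n_bins)
    # point mass at score 0 (all dosages would contribute via shifts below)
    pos = (0.0 - lo) / h
    i0 = int(np.floor(pos))
    fr = pos - i0
    pmf[i0] += 1.0 - fr
    if i0 + 1 < n_bins:
        pmf[i0 + 1] += fr
    for bi, fi in zip(b, panel.freq):
        w = np.array([(1 - fi) ** 2, 2 * fi * (1 - fi), fi**2])
        new = np.zeros(n_bins)
        for dose in range(3):
            if w[dose] == 0.0:
                continue
            shifted = grid + bi * dose
            pos = (shifted - lo) / h
            idx = np.clip(np.floor(pos).astype(int), 0, n_bins - 1)
            fr = pos - idx
            np.add.at(new, idx, pmf * w[dose] * (1.0 - fr))
            hi_idx = np.clip(idx + 1, 0, n_bins - 1)
            np.add.at(new, hi_idx, pmf * w[dose] * fr)
        pmf = new
    return grid, pmf


_MC_DRAWS = 100_000
_MAX_EXACT_LOCI = 25


def calibrate_intercept(panel: VariantPanel, K: float) -> float:
    """Intercept alpha making the population mean predicted risk equal K.

    Solves E_G[expit(alpha + sum_i b_i g_i)] = K over Hardy-Weinberg
    genotypes at independent loci.  Up to 25 loci the genotype-score
    distribution is evaluated by exact convolution on a 4096-bin grid;
    above that, a seeded 100,000-draw Monte-Carlo sample of scores is
    used instead.  Root-finding residual < 1e-10.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence K must lie in (0, 1)")
    if panel.n_loci == 0:
        return float(logit(K))
    if panel.n_loci <= _MAX_EXACT_LOCI:
        scores, weights = _score_pmf(panel)
    else:
        rng = np.random.default_rng(180451813)
        g = rng.binomial(2, panel.freq[:, None], size=(panel.n_loci, _MC_DRAWS))
        scores = panel.effect @ g
        weights = np.full(_MC_DRAWS, 1.0 / _MC_DRAWS)

    def resid(alpha: float) -> float:
        return float(weights @ expit(alpha + scores) - K)

    lo, hi = -50.0, 50.0
    if resid(lo) > 0 or resid(hi) < 0:
        raise ValueError("no intercept in [-50, 50] achieves the target prevalence")
    return float(brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16))


def score_binary(panel: VariantPanel, G: GenotypeMatrix, alpha: float) -> Prediction:
    """Logistic-model disease probabilities expit(alpha + sum_i b_i g_ij)."""
    _check_pairing(panel, G)
    d = _imputed_dosages(panel, G)
    yhat = expit(alpha + panel.effect @ d)
    return Prediction(yhat=yhat, kind="binary")


def residuals(y: np.ndarray, pred: Prediction) -> Prediction:
    """Residuals delta_j = y_j - yhat_j.

    For binary traits y in {0,1}; an affected individual with low
    predicted risk has delta near +1 (a "super case"), an unaffected
    individual with high predicted risk has delta near -1.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != pred.yhat.shape:
        raise ValueError("observed phenotypes and predictions differ in length")
    if pred.kind == "binary" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binary observed phenotypes must be 0/1")
    return Prediction(yhat=pred.yhat, kind=pred.kind, delta=y - pred.yhat)


ExtremeSelection = namedtuple("ExtremeSelection", ["upper", "lower"])


def select_extremes(
    delta: np.ndarray,
    n: int | None = None,
    q: float | None = None,
    tail: str = "upper",
):
    """Indices of the most extreme residuals.

    Exactly one of ``n`` (count per tail) or ``q`` (tail fraction, count
    = round(q*m)) must be given.  Ties are broken by input order
    (stable), so selections are reproducible.  Returns an index array
    for a single tail, or an ``ExtremeSelection(upper, lower)`` pair for
    ``tail="both"``.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("cannot select from an empty residual vector")
    if (n is None) == (q is None):
        raise ValueError("specify exactly one of n or q")
    m = delta.size
    if n is None:
        if not 0.0 < q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        n = int(round(q * m))
    if not 0 <= n <= m:
        raise ValueError(f"cannot select {n} individuals from {m}")
    if tail not in ("upper", "lower", "both"):
        raise ValueError("tail must be 'upper', 'lower' or 'both'")

    def _take(direction: str) -> np.ndarray:
        key = -delta if direction == "upper" else delta
        order = np.argsort(key, kind="stable")
        return order[:n]

    if tail == "both":
        return ExtremeSelection(upper=_take("upper"), lower=_take("lower"))
    return _take(tail)
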