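"""Liability-model theory of risk-score-based sample prioritisation.

Everything here lives on the liability (probit) scale.  Disease arises
when a latent liability l exceeds the threshold T = Phi^{-1}(1 - K) set
by the prevalence K.  Liability decomposes as

    l = s + r + delta * (g - 2 f_v)

with s ~ Normal(0, V) the known risk score (V = liability-scale
variance explained by the score), r ~ Normal(0, 1 - V) the residual,
g ~ Binomial(2, f_v) the genotype of an undiscovered test variant, and
delta the per-allele liability shift calibrated so that the variant's
marginal allele-based odds ratio in unselected individuals equals a
target OR.

Selecting individuals on predicted risk is equivalent to selecting on s
(the link is monotone), so "super cases" are cases in the lowest-q tail
of s among cases, and "super controls" are screened non-cases in the
highest-q tail of s among non-cases.  The module computes the test
variant's allele frequency in those selected groups by numerical
integration, the apparent odds ratio this induces, and the power of an
allelic trend comparison of prioritised versus randomly drawn samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "DiseaseDesign",
    "TestVariant",
    "SelectionDesign",
    "liability_threshold",
    "or_to_liability_shift",
    "genotype_penetrances",
    "unselected_case_control_freqs",
    "selected_case_freq",
    "selected_control_freq",
    "apparent_or",
    "qt_selected_freq",
    "power_trend",
    "power_curve",
    "qt_power_curve",
]

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-10, limit=400)
_S_RANGE = 12.0  # integration / root bracket, in score SD units


@dataclass(frozen=True)
class DiseaseDesign:
    """Disease prevalence K and liability variance V explained by the score."""

    K: float
    V: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError("prevalence K must lie in (0, 1)")
        if not 0.0 <= self.V < 1.0:
            raise ValueError("score variance V must lie in [0, 1)")

    @property
    def T(self) -> float:
        return liability_threshold(self.K)


@dataclass(frozen=True)
class TestVariant:
    """An undiscovered risk variant: frequency plus OR (binary) or beta (QT)."""

    __test__ = False  # not a pytest class, despite the name

    f_v: float
    odds_ratio: float | None = None
    beta_v: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f_v < 1.0:
            raise ValueError("variant frequency must lie in (0, 1)")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class SelectionDesign:
    """Selection fractions, screening flag, sample sizes and alpha."""

    q_case: float = 1.0
    q_control: float = 1.0
    controls_screened: bool = False
    N_case: int = 1000
    N_control: int = 1000
    alpha_sig: float = 5e-8

    def __post_init__(self) -> None:
        for q in (self.q_case, self.q_control):
            if not 0.0 < q <= 1.0:
                raise ValueError("selection fractions must lie in (0, 1]")
        if self.N_case < 1 or self.N_control < 1:
            raise ValueError("sample sizes must be >= 1")


def liability_threshold(K: float) -> float:
    """Threshold T with upper-tail standard-normal probability K."""
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence K must lie in (0, 1)")
    return float(norm.isf(K))


def _hwe(f: float) -> np.ndarray:
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def genotype_penetrances(delta: float, f_v: float, K: float) -> np.ndarray:
    """P(affected | g) for g = 0,1,2 given a per-allele liability shift."""
    T = liability_threshold(K)
    g = np.arange(3)
    # s + r ~ Normal(0, 1) jointly, so penetrance has a closed form
    return norm.cdf(delta * (g - 2 * f_v) - T)


def _allele_or(delta: float, f_v: float, K: float) -> float:
    """Marginal allele-based odds ratio realized by a liability shift."""
    w = _hwe(f_v)
    pen = genotype_penetrances(delta, f_v, K)
    g = np.arange(3)
    p_case = float(w @ pen)
    f_case = float(w @ (g / 2 * pen)) / p_case
    f_ctrl = float(w @ (g / 2 * (1 - pen))) / (1.0 - p_case)
    return (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))


def or_to_liability_shift(v: TestVariant, d: DiseaseDesign) -> float:
    """Per-allele liability shift delta realizing the variant's marginal OR.

    Root-found so that the allele-based odds ratio of the thresholded
    liability matches ``v.odds_ratio`` to 1e-6 or better.
    """
    if v.odds_ratio is None:
        raise ValueError("variant has no odds ratio")
    if v.odds_ratio == 1.0:
        return 0.0

    def resid(delta: float) -> float:
        return _allele_or(delta, v.f_v, d.K) - v.odds_ratio

    lo, hi = -5.0, 5.0
    if resid(lo) * resid(hi) > 0:
        raise ValueError("no liability shift in [-5, 5] matches the odds ratio")
    return float(brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16))


def unselected_case_control_freqs(v: TestVariant, d: DiseaseDesign) -> tuple[float, float]:
    """Test-variant allele frequency in unselected cases and non-cases."""
    delta = or_to_liability_shift(v, d)
    w = _hwe(v.f_v)
    pen = genotype_penetrances(delta, v.f_v, d.K)
    g = np.arange(3)
    p_case = float(w @ pen)
    f_case = float(w @ (g / 2 * pen)) / p_case
    f_ctrl = float(w @ (g / 2 * (1 - pen))) / (1.0 - p_case)
    return f_case, f_ctrl


def _case_mass_given_g(u_hi: float, c_g: float, V: float, T: float) -> float:
    """P(S <= u_hi * sqrt(V), affected | g), integrating over the score.

    With s = sqrt(V) u the integrand is phi(u) * Phi((sqrt(V) u + c_g -
    T) / sqrt(1 - V)); adaptive quadrature to 1e-12 absolute tolerance.
    """
    sV = np.sqrt(V)
    s1V = np.sqrt(1.0 - V)

    def f(u: float) -> float:
        return norm.pdf(u) * norm.cdf((sV * u + c_g - T) / s1V)

    val, _ = quad(f, -_S_RANGE, u_hi, **_QUAD_OPTS)
    return val


def _control_mass_given_g(u_lo: float, c_g: float, V: float, T: float) -> float:
    """P(S >= u_lo * sqrt(V), unaffected | g)."""
    sV = np.sqrt(V)
    s1V = np.sqrt(1.0 - V)

    def f(u: float) -> float:
        return norm.pdf(u) * norm.sf((sV * u + c_g - T) / s1V)

    val, _ = quad(f, u_lo, _S_RANGE, **_QUAD_OPTS)
    return val


def selected_case_freq(v: TestVariant, d: DiseaseDesign, q: float) -> float:
    """Allele frequency among "super cases".

    Cases whose risk score lies in the lowest fraction q of the score
    distribution *among cases*; these achieved disease despite a low
    known-locus burden, so they are enriched for the test variant.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    delta = or_to_liability_shift(v, d)
    w = _hwe(v.f_v)
    g = np.arange(3)
    if d.V == 0.0 or q == 1.0:
        # a flat score (or taking everyone) selects cases at random
        f_case, _ = unselected_case_control_freqs(v, d)
        return f_case
    T = d.T
    c = delta * (g - 2 * v.f_v)
    total = np.array([_case_mass_given_g(_S_RANGE, ci, d.V, T) for ci in c])
    p_case = float(w @ total)

    def tail_mass(u: float) -> np.ndarray:
        return np.array([_case_mass_given_g(u, ci, d.V, T) for ci in c])

    def resid(u: float) -> float:
        return float(w @ tail_mass(u)) - q * p_case

    u_q = brentq(resid, -_S_RANGE, _S_RANGE, xtol=1e-10)
    m = tail_mass(u_q)
    return float(w @ (g / 2 * m)) / float(w @ m)


def selected_control_freq(
    v: TestVariant, d: DiseaseDesign, q: float, screened: bool = True
) -> float:
    """Allele frequency among selected controls.

    ``screened=True``: non-cases whose score lies in the highest
    fraction q among non-cases ("super controls", depleted for the test
    variant).  ``screened=False``: controls drawn from the general
    population, whose allele frequency is the population frequency
    regardless of selection.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    if not screened:
        return v.f_v
    delta = or_to_liability_shift(v, d)
    w = _hwe(v.f_v)
    g = np.arange(3)
    if d.V == 0.0 or q == 1.0:
        _, f_ctrl = unselected_case_control_freqs(v, d)
        return f_ctrl
    T = d.T
    c = delta * (g - 2 * v.f_v)
    total = np.array([_control_mass_given_g(-_S_RANGE, ci, d.V, T) for ci in c])
    p_ctrl = float(w @ total)

    def tail_mass(u: float) -> np.ndarray:
        return np.array([_control_mass_given_g(u, ci, d.V, T) for ci in c])

    def resid(u: float) -> float:
        return float(w @ tail_mass(u)) - q * p_ctrl

    u_q = brentq(resid, -_S_RANGE, _S_RANGE, xtol=1e-10)
    m = tail_mass(u_q)
    return float(w @ (g / 2 * m)) / float(w @ m)


def apparent_or(f_case_sel: float, f_ctrl_sel: float) -> float:
    """Odds ratio implied by the selected case and control frequencies."""
    for f in (f_case_sel, f_ctrl_sel):
        if not 0.0 < f < 1.0:
            raise ValueError("selected frequencies must lie strictly in (0, 1)")
    return (f_case_sel / (1 - f_case_sel)) / (f_ctrl_sel / (1 - f_ctrl_sel))


def qt_selected_freq(
    beta_v: float, f_v: float, V: float, q: float, tail: str = "upper"
) -> float:
    """Allele frequency in a residual tail of a quantitative trait.

    On the standardized trait scale the residual (observed minus
    score-predicted trait) given the test genotype g is Normal(beta_v *
    (g - 2 f_v), 1 - V).  The tail cutoff is solved from the
    genotype-mixture distribution so that a fraction q of individuals is
    selected; the upper tail is enriched for a trait-increasing allele.
    With V = 0 this is selection on the raw trait.
    """
    if not 0.0 <= V < 1.0:
        raise ValueError("V must lie in [0, 1)")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    w = _hwe(f_v)
    g = np.arange(3)
    if beta_v == 0.0 or q == 1.0:
        return f_v
    mu = beta_v * (g - 2 * f_v)
    sd = np.sqrt(1.0 - V)

    def tail_probs(cut: float) -> np.ndarray:
        if tail == "upper":
            return norm.sf((cut - mu) / sd)
        return norm.cdf((cut - mu) / sd)

    def resid(cut: float) -> float:
        return float(w @ tail_probs(cut)) - q

    span = 12.0 * sd + np.max(np.abs(mu)) + 1.0
    lo, hi = (-span, span)
    cut = brentq(resid, lo, hi, xtol=1e-12)
    t = tail_probs(cut)
    return float(w @ (g / 2 * t)) / float(w @ t)


def power_trend(f1: float, f2: float, N1: int, N2: int, alpha_sig: float) -> float:
    """Two-sided asymptotic power of the allelic trend comparison.

    Under an additive model the Cochran-Armitage trend test on 2N1 vs
    2N2 alleles reduces to the two-proportion z-test on allele
    frequencies.  Convention held fixed here: the rejection threshold
    uses the pooled null variance and the alternative uses the unpooled
    variance, so the null power is exactly alpha_sig.
    """
    for f in (f1, f2):
        if not 0.0 < f < 1.0:
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if N1 < 1 or N2 < 1:
        raise ValueError("sample sizes must be >= 1")
    m1, m2 = 2.0 * N1, 2.0 * N2
    pbar = (m1 * f1 + m2 * f2) / (m1 + m2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m2))
    se1 = np.sqrt(f1 * (1 - f1) / m1 + f2 * (1 - f2) / m2)
    z = norm.isf(alpha_sig / 2.0)
    d = abs(f1 - f2)
    power = norm.sf((z * se0 - d) / se1) + norm.sf((z * se0 + d) / se1)
    return float(min(power, 1.0))


def power_curve(
    v: TestVariant,
    d: DiseaseDesign,
    design: SelectionDesign,
    pool_cases: int,
    pool_controls: int,
    N_grid: list[int],
) -> pd.DataFrame:
    """Power of random versus prioritised case-control designs.

    For each sequenced sample size N the random design draws N cases
    and N controls at random from the pools; the prioritised design
    takes the N most extreme on residual risk (q = N/pool per group,
    controls only re-weighted when they are screened non-cases).
    Returns a table with columns N, power_random, power_prioritised and
    the underlying selected allele frequencies.
    """
    f_case_unsel, f_ctrl_unsel = unselected_case_control_freqs(v, d)
    f_ctrl_random = f_ctrl_unsel if design.controls_screened else v.f_v
    rows = []
    for N in N_grid:
        if N > pool_cases or N > pool_controls:
            raise ValueError(f"N={N} exceeds the available pools")
        q_case = N / pool_cases
        q_ctrl = N / pool_controls
        f_case_sel = selected_case_freq(v, d, q_case)
        f_ctrl_sel = selected_control_freq(v, d, q_ctrl, design.controls_screened)
        rows.append(
            {
                "N": N,
                "f_case_random": f_case_unsel,
                "f_control_random": f_ctrl_random,
                "f_case_prioritised": f_case_sel,
                "f_control_prioritised": f_ctrl_sel,
                "power_random": power_trend(
                    f_case_unsel, f_ctrl_random, N, N, design.alpha_sig
                ),
                "power_prioritised": power_trend(
                    f_case_sel, f_ctrl_sel, N, N, design.alpha_sig
                ),
            }
        )
    return pd.DataFrame(rows)


def qt_power_curve(
    beta_v: float,
    f_v: float,
    V: float,
    pool: int,
    N_grid: list[int],
    alpha_sig: float = 5e-8,
) -> pd.DataFrame:
    """Power for extreme-sampling designs on a quantitative trait.

    The prioritised design compares the two tails of the residual after
    removing the score (residual variance 1 - V); the baseline compares
    the two tails of the raw trait (V = 0).  Both tails of size N are
    analysed as a case-control allele comparison.
    """
    rows = []
    for N in N_grid:
        if N > pool:
            raise ValueError(f"N={N} exceeds the pool")
        q = N / pool
        f_hi = qt_selected_freq(beta_v, f_v, V, q, "upper")
        f_lo = qt_selected_freq(beta_v, f_v, V, q, "lower")
        f_hi0 = qt_selected_freq(beta_v, f_v, 0.0, q, "upper")
        f_lo0 = qt_selected_freq(beta_v, f_v, 0.0, q, "lower")
        rows.append(
            {
                "N": N,
                "f_upper_raw": f_hi0,
                "f_lower_raw": f_lo0,
                "f_upper_residual": f_hi,
                "f_lower_residual": f_lo,
                "power_random": power_trend(f_hi0, f_lo0, N, N, alpha_sig),
                "power_prioritised": power_trend(f_hi, f_lo, N, N, alpha_sig),
            }
        )
    return pd.DataFrame(rows)
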