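import numpy as np
import pytest
from scipy.stats import norm

from prioriseq.family_sim import simulate_cohort, simulate_trait_cohort
from prioriseq.selection_theory import (
    DiseaseDesign,
    SelectionDesign,
    TestVariant,
    apparent_or,
    liability_threshold,
    or_to_liability_shift,
    power_curve,
    power_trend,
    qt_power_curve,
    qt_selected_freq,
    selected_case_freq,
    selected_control_freq,
    unselected_case_control_freqs,
)


def empirical_selected_case_freq(coh, q):
    aff = np.flatnonzero(coh["affected"])
    order = np.argsort(coh["score"][aff], kind="stable")
    sel = aff[order[: max(1, int(round(q * aff.size)))]]
    return coh["genotype"][sel].mean() / 2.0, sel.size


def empirical_selected_control_freq(coh, q):
    ctl = np.flatnonzero(~coh["affected"])
    order = np.argsort(coh["score"][ctl], kind="stable")
    sel = ctl[order[-max(1, int(round(q * ctl.size))) :]]
    return coh["genotype"][sel].mean() / 2.0, sel.size


class TestLiabilityThreshold:
    @pytest.mark.parametrize(
        "K,expected", [(0.5, 0.0), (0.01, 2.3263), (0.1, 1.2816)]
    )
    def test_standard_normal_quantiles(self, K, expected):
        assert liability_threshold(K) == pytest.approx(expected, abs=1e-4)

    def test_rejects_degenerate_prevalence(self):
        with pytest.raises(ValueError):
            liability_threshold(0.0)


class TestLiabilityShift:
    def test_null_odds_ratio_maps_to_zero_shift(self):
        d = DiseaseDesign(K=0.05, V=0.2)
        assert or_to_liability_shift(TestVariant(0.1, odds_ratio=1.0), d) == 0.0

    def test_shift_is_increasing_in_odds_ratio(self):
        d = DiseaseDesign(K=0.01, V=0.0)
        shifts = [
            or_to_liability_shift(TestVariant(0.01, odds_ratio=r), d)
            for r in (1.2, 2.0, 4.0)
        ]
        assert shifts == sorted(shifts)
        assert shifts[0] > 0

    def test_realized_odds_ratio_matches_simulation(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        coh = simulate_cohort(0.01, 0.0, v, 4_000_000, seed=2)
        aff, g = coh["affected"], coh["genotype"]
        f_case = g[aff].mean() / 2
        f_ctrl = g[~aff].mean() / 2
        realized = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl))
        n_case_alleles = 2 * aff.sum()
        # binomial SE on the case frequency propagated to the OR scale
        se_or = realized * 3 * np.sqrt(f_case * (1 - f_case) / n_case_alleles) / (
            f_case * (1 - f_case)
        )
        assert abs(realized - 2.0) < se_or


class TestSelectedFrequencies:
    def test_null_variant_unmoved_by_selection(self):
        v = TestVariant(0.05, odds_ratio=1.0)
        d = DiseaseDesign(K=0.05, V=0.3)
        assert selected_case_freq(v, d, 0.2) == pytest.approx(0.05, abs=1e-9)
        assert selected_control_freq(v, d, 0.2, True) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_q_one_reduces_to_unselected(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.25)
        f_case, f_ctrl = unselected_case_control_freqs(v, d)
        assert selected_case_freq(v, d, 1.0) == pytest.approx(f_case)
        assert selected_control_freq(v, d, 1.0, True) == pytest.approx(f_ctrl)

    def test_unscreened_controls_keep_population_frequency(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.25)
        assert selected_control_freq(v, d, 0.1, screened=False) == 0.01

    def test_case_frequency_matches_cohort_simulation(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.25)
        analytic = selected_case_freq(v, d, 0.25)
        coh = simulate_cohort(0.01, 0.25, v, 4_000_000, seed=3)
        emp, n_sel = empirical_selected_case_freq(coh, 0.25)
        se = np.sqrt(emp * (1 - emp) / (2 * n_sel))
        assert abs(analytic - emp) < 3 * se

    def test_control_frequency_matches_cohort_simulation(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.25)
        analytic = selected_control_freq(v, d, 0.25, True)
        coh = simulate_cohort(0.01, 0.25, v, 1_000_000, seed=4)
        emp, n_sel = empirical_selected_control_freq(coh, 0.25)
        se = np.sqrt(analytic * (1 - analytic) / (2 * n_sel))
        assert abs(analytic - emp) < 3 * se


class TestApparentOr:
    def test_equal_frequencies_give_unity(self):
        assert apparent_or(0.03, 0.03) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert apparent_or(0.02, 0.01) == pytest.approx(
            (0.02 / 0.98) / (0.01 / 0.99)
        )

    def test_monotone_in_selection_stringency_and_score_variance(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        ors_by_q = []
        for q in (0.1, 0.5, 1.0):
            d = DiseaseDesign(K=0.01, V=0.25)
            ors_by_q.append(
                apparent_or(
                    selected_case_freq(v, d, q),
                    selected_control_freq(v, d, q, True),
                )
            )
        assert ors_by_q[0] > ors_by_q[1] > ors_by_q[2]
        ors_by_v = [
            apparent_or(
                selected_case_freq(v, DiseaseDesign(K=0.01, V=V), 0.1),
                selected_control_freq(v, DiseaseDesign(K=0.01, V=V), 0.1, True),
            )
            for V in (0.05, 0.25, 0.5)
        ]
        assert ors_by_v[0] < ors_by_v[1] < ors_by_v[2]

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            apparent_or(0.0, 0.01)


class TestQuantitativeSelection:
    def test_null_effect_and_full_selection_return_population_frequency(self):
        assert qt_selected_freq(0.0, 0.01, 0.25, 0.05) == 0.01
        assert qt_selected_freq(0.2, 0.01, 0.25, 1.0) == 0.01

    def test_upper_tail_matches_trait_simulation(self):
        beta, f, V, q = 0.2, 0.01, 0.25, 0.01
        analytic = qt_selected_freq(beta, f, V, q, "upper")
        coh = simulate_trait_cohort(beta, f, V, 10_000_000, seed=5)
        cut = np.quantile(coh["delta"], 1 - q)
        sel = coh["delta"] >= cut
        emp = coh["genotype"][sel].mean() / 2
        se = np.sqrt(emp * (1 - emp) / (2 * sel.sum()))
        assert abs(analytic - emp) < 3 * se

    def test_lower_tail_depleted_for_increasing_allele(self):
        assert qt_selected_freq(0.2, 0.01, 0.25, 0.05, "lower") < 0.01


class TestPowerTrend:
    def test_null_power_equals_alpha(self):
        assert power_trend(0.01, 0.01, 1000, 1000, 0.05) == pytest.approx(0.05)

    def test_power_increases_to_one_with_sample_size(self):
        powers = [
            power_trend(0.02, 0.01, N, N, 5e-8) for N in (2000, 20_000, 200_000)
        ]
        assert powers == sorted(powers)
        assert powers[-1] > 0.999

    def test_matches_binomial_simulation_of_the_test(self):
        f1, f2, N, alpha = 0.02, 0.01, 2000, 5e-8
        analytic = power_trend(f1, f2, N, N, alpha)
        rng = np.random.default_rng(11)
        reps = 100_000
        x1 = rng.binomial(2 * N, f1, reps)
        x2 = rng.binomial(2 * N, f2, reps)
        p1, p2 = x1 / (2 * N), x2 / (2 * N)
        pbar = (x1 + x2) / (4 * N)
        se0 = np.sqrt(pbar * (1 - pbar) * (2 / (2 * N)))
        with np.errstate(invalid="ignore"):
            z = np.abs(p1 - p2) / se0
        reject = z > norm.isf(alpha / 2)
        assert abs(analytic - reject.mean()) < 0.02

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            power_trend(0.0, 0.01, 100, 100, 0.05)


class TestPowerCurves:
    def test_uninformative_score_gives_identical_curves(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.0)
        df = power_curve(
            v, d, SelectionDesign(controls_screened=True), 10_000, 10_000,
            [1000, 5000],
        )
        assert np.allclose(df.power_random, df.power_prioritised)

    def test_prioritised_never_below_random(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        for V in (0.05, 0.25, 0.5):
            d = DiseaseDesign(K=0.01, V=V)
            df = power_curve(
                v, d, SelectionDesign(controls_screened=True), 10_000, 10_000,
                [1000, 2500, 5000],
            )
            assert np.all(
                df.power_prioritised >= df.power_random - 1e-12
            )
            assert np.all(df.power_prioritised.iloc[:-1] > df.power_random.iloc[:-1])

    def test_quantitative_gain_positive_even_for_weak_predictors(self):
        df = qt_power_curve(0.2, 0.01, 0.05, 100_000, [1000, 5000, 20_000])
        assert np.all(df.power_prioritised > df.power_random)

    def test_n_exceeding_pool_rejected(self):
        v = TestVariant(0.01, odds_ratio=2.0)
        d = DiseaseDesign(K=0.01, V=0.1)
        with pytest.raises(ValueError, match="pool"):
            power_curve(v, d, SelectionDesign(), 1000, 1000, [2000])


def test_enrichment_largely_independent_of_allele_frequency():
    d = DiseaseDesign(K=0.01, V=0.25)
    ratios = []
    for f in (0.001, 0.01, 0.1):
        v = TestVariant(f, odds_ratio=2.0)
        a = apparent_or(
            selected_case_freq(v, d, 0.1), selected_control_freq(v, d, 0.1, True)
        )
        ratios.append(a / 2.0)
    spread = (max(ratios) - min(ratios)) / min(ratios)
    assert spread < 0.15
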