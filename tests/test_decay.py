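"""Exponential decay fitting: closed forms, oracle agreement, mixtures."""

import math

import numpy as np
import pytest
from scipy import optimize

from brudecay import simulate_cohort, simulate_experiment, analyze_condition
from brudecay.decay import (
    expressed_gene_filter,
    fit_mixture,
    fit_mixture_junction,
    fit_one_component,
    half_life,
    pst,
    weighted_log_linear,
)

from conftest import make_timecourse


def oracle_beta(times, x):
    """Independent 1-D minimizer of the weighted objective.

    For each candidate beta the optimal intercept has the closed form
    ln x0 = weighted mean of (ln x + beta*tau); the remaining 1-D profile
    objective in beta is minimized by bounded scalar search.
    """
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    tau = times - times[0]
    w = x
    y = np.log(x)

    def profile(beta):
        ln_x0 = np.sum(w * (y + beta * tau)) / np.sum(w)
        return np.sum(w * (y - ln_x0 + beta * tau) ** 2)

    res = optimize.minimize_scalar(
        profile, bounds=(-20.0, 20.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return res.x


class TestOneComponent:
    def test_two_point_closed_form(self):
        tc = make_timecourse([0.5, 2.0], [100.0, 50.0])
        fit = fit_one_component(tc)
        assert fit.beta == pytest.approx(math.log(2) / 1.5, abs=1e-12)
        assert fit.half_life == pytest.approx(1.5)
        assert fit.x0_hat == pytest.approx(100.0)

    def test_constant_expression_zero_rate(self):
        fit = fit_one_component(make_timecourse([0.5, 1.0, 2.0], [80.0] * 3))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_three_point_fit_matches_numeric_minimizer(self):
        tc = make_timecourse([0.5, 1.0, 2.0], [100.0, 80.0, 40.0])
        fit = fit_one_component(tc)
        assert fit.beta == pytest.approx(oracle_beta(tc.times, tc.x), abs=1e-6)

    def test_multipoint_random_fits_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 6)
            times = np.sort(rng.uniform(0.5, 8.0, n))
            times[0] = 0.5
            beta = rng.uniform(-0.5, 3.0)
            x = 100 * np.exp(-beta * (times - 0.5)) * rng.lognormal(0, 0.3, n)
            got = fit_one_component(make_timecourse(times, x)).beta
            assert got == pytest.approx(oracle_beta(times, x), abs=1e-6)

    def test_zero_expression_flagged_not_fit(self):
        fit = fit_one_component(make_timecourse([0.5, 2.0], [100.0, 0.0]))
        assert fit.beta is None and "insufficient_points" in fit.flags

    def test_increasing_expression_negative_rate_flagged(self):
        fit = fit_one_component(make_timecourse([0.5, 2.0], [50.0, 100.0]))
        assert fit.beta < 0 and "negative_rate" in fit.flags

    def test_noiseless_refit_recovers_rate_exactly(self):
        for beta in (0.05, 0.7, 2.5):
            times = np.array([0.5, 2.0])
            x = 120 * np.exp(-beta * (times - 0.5))
            fit = fit_one_component(make_timecourse(times, x))
            assert abs(fit.beta - beta) < 1e-10


class TestMixture:
    def test_forward_simulated_two_point_inversion(self):
        # generated from beta_s=0.2, beta_ir=1.0 at X(0.5)=100, IRI(0.5)=0.2
        tc = make_timecourse(
            [0.5, 2.0], [100.0, 63.7281], iri=[0.2, 0.070025]
        )
        fit = fit_mixture(tc)
        assert fit.beta_s == pytest.approx(0.2, abs=1e-4)
        assert fit.beta_ir == pytest.approx(1.0, abs=1e-4)
        one = fit_one_component(tc)
        assert one.beta == pytest.approx(math.log(100 / 63.7281) / 1.5, abs=1e-9)
        assert fit.beta_s < one.beta < fit.beta_ir

    def test_zero_iri_degenerates_to_one_component(self):
        tc = make_timecourse([0.5, 1.0, 2.0], [100.0, 70.0, 40.0], iri=[0.0] * 3)
        fit = fit_mixture(tc)
        one = fit_one_component(tc)
        assert fit.beta_s == one.beta  # bit-identical
        assert fit.beta_ir is None and "zero_component" in fit.flags

    def test_iri_above_one_excludes_gene(self):
        tc = make_timecourse([0.5, 2.0], [100.0, 60.0], iri=[0.2, 1.2])
        fit = fit_mixture(tc)
        assert fit.beta_s is None and "iri_gt_1" in fit.flags

    def test_components_sum_to_total(self):
        tc = make_timecourse([0.5, 2.0], [100.0, 63.7281], iri=[0.2, 0.070025])
        fit = fit_mixture(tc)
        assert fit.x0_s + fit.x0_ir == pytest.approx(100.0, rel=1e-6)


class TestJunctionVariant:
    def test_halving_ee_counts(self):
        tc = make_timecourse(
            [0.5, 2.0], [1.0, 1.0], x_ee=[40.0, 20.0], x_ei=[20.0, 20.0]
        )
        fit = fit_mixture_junction(tc)
        assert fit.beta_s == pytest.approx(math.log(2) / 1.5, abs=1e-12)
        assert fit.beta_ir == pytest.approx(0.0, abs=1e-12)

    def test_no_ei_reads_gives_spliced_rate_only(self):
        tc = make_timecourse([0.5, 2.0], [1.0, 1.0], x_ee=[40.0, 10.0])
        fit = fit_mixture_junction(tc)
        assert fit.beta_s is not None and fit.beta_ir is None
        assert "zero_component" in fit.flags


class TestDerivedStatistics:
    @pytest.mark.parametrize("iri,expected", [(0.25, 0.75), (0.0, 1.0), (1.0, 0.0)])
    def test_pst_complements_early_iri(self, iri, expected):
        tc = make_timecourse([0.5, 2.0], [10.0, 5.0], iri=[iri, 0.0])
        assert pst(tc) == pytest.approx(expected)

    def test_pst_missing_half_hour_point(self):
        tc = make_timecourse([1.0, 2.0], [10.0, 5.0], iri=[0.1, 0.1])
        assert pst(tc) is None

    @pytest.mark.parametrize(
        "rate,expected", [(0.4621, 1.5), (math.log(2), 1.0), (0.5453, 1.2712)]
    )
    def test_half_life_conversion(self, rate, expected):
        assert half_life(rate) == pytest.approx(expected, abs=5e-4)

    def test_half_life_undefined_for_nonpositive_rate(self):
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_expressed_filter_criteria(self):
        tcs = {
            "ok": make_timecourse([0.5, 2.0], [100.0, 60.0], iri=[0.2, 0.1], gene_id="ok"),
            "iri_high": make_timecourse([0.5, 2.0], [100.0, 60.0], iri=[0.2, 1.2], gene_id="iri_high"),
            "rising": make_timecourse([0.5, 2.0], [60.0, 100.0], iri=[0.2, 0.1], gene_id="rising"),
        }
        fits = {g: fit_mixture(tc) for g, tc in tcs.items()}
        kept = expressed_gene_filter(tcs, fits)
        assert kept == {"ok"}
        # the negative-rate gene is retained in the fit output, only filtered
        assert fits["rising"].beta_s < 0
        assert "negative_rate" in fits["rising"].flags


class TestCohortProperties:
    def test_one_component_rate_between_mixture_rates_noiseless(self):
        # expectation-table (infinite depth) cohort: the single-pool rate of a
        # two-exponential decay must lie between the component rates
        cohort = simulate_cohort(100, seed=5)
        libs, man = simulate_experiment(cohort, depth=1e6, seed=5, exact=True)
        res = analyze_condition(libs, man, "resting")
        checked = 0
        for g, fm in res.fits_mixture.items():
            if cohort.truth.loc[g, "is_housekeeping"]:
                continue
            if fm.beta_s is None or fm.beta_ir is None:
                continue
            fo = res.fits_one[g]
            lo, hi = sorted([fm.beta_s, fm.beta_ir])
            assert lo - 1e-9 <= fo.beta <= hi + 1e-9
            checked += 1
        assert checked > 80

    def test_recovery_on_noisy_cohort(self, fitted500):
        cohort, rest, _ = fitted500
        truth = cohort.truth
        gids = [g for g in rest.expressed if not truth.loc[g, "is_housekeeping"]]
        bs = np.array([rest.fits_mixture[g].beta_s for g in gids])
        rel_s = np.abs(bs - truth.loc[gids, "beta_s_rest"]) / truth.loc[gids, "beta_s_rest"]
        assert np.median(rel_s) < 0.10
        g_ir = [g for g in gids if rest.fits_mixture[g].beta_ir is not None]
        bi = np.array([rest.fits_mixture[g].beta_ir for g in g_ir])
        rel_ir = np.abs(bi - truth.loc[g_ir, "beta_ir_rest"]) / truth.loc[g_ir, "beta_ir_rest"]
        assert np.median(rel_ir) < 0.25
        # spliced pools decay slower than retained pools, as generated
        from brudecay.compare import distribution_test

        assert distribution_test(bs, bi, "less") < 1e-10
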