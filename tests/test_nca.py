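"""Non-compartmental analysis: Cmax/AUC/half-life rules and binding arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bacekit import (
    BindingParams,
    NCAError,
    auc_trapezoid,
    cmax_tmax,
    efflux_ratio,
    gen_pk_profile,
    nca_summary,
    terminal_half_life,
    unbound_auc,
)
from conftest import make_profile

LN2 = math.log(2.0)


class TestCmaxTmax:
    def test_observed_maximum_with_time(self, profile_factory):
        p = profile_factory([1.0, 2.0, 4.0], [1.62, 1.1, 0.6])
        assert cmax_tmax(p) == (1.62, 1.0)

    def test_monotone_decreasing_takes_first_point(self, profile_factory):
        p = profile_factory([0.5, 1, 2, 4], [9.0, 5.0, 2.0, 1.0])
        assert cmax_tmax(p) == (9.0, 0.5)

    def test_matches_brute_force_scan(self, profile_factory):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 48, 200))
        t += np.arange(200) * 1e-6  # ensure strict increase
        c = rng.uniform(0, 10, 200)
        p = profile_factory(t, c)
        cmax, tmax = cmax_tmax(p)
        best = max(zip(c, -t))  # highest conc, earliest time on ties
        assert cmax == best[0] and tmax == -best[1]

    def test_tie_broken_to_earliest_time(self, profile_factory):
        p = profile_factory([1, 2, 3], [5.0, 5.0, 1.0])
        assert cmax_tmax(p) == (5.0, 1.0)

    def test_all_blq_raises(self):
        p = make_profile([1, 2, 3], [np.nan] * 3, blq=[True] * 3, lloq=0.1)
        with pytest.raises(NCAError, match="no quantifiable"):
            cmax_tmax(p)


class TestAucTrapezoid:
    def test_constant_profile_is_rectangle(self, profile_factory):
        p = profile_factory([0, 4, 8, 24], [1.0] * 4)
        assert auc_trapezoid(p, 0, 24) == pytest.approx(24.0)

    def test_matches_fine_grid_integration(self, profile_factory):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 24, 12))
        t[0], t[-1] = 0.0, 24.0
        c = rng.uniform(0.1, 5.0, 12)
        p = profile_factory(t, c)
        fine_t = np.arange(0, 24.0 + 1e-9, 1e-3)
        fine = np.trapezoid(np.interp(fine_t, t, c), fine_t)
        assert auc_trapezoid(p, 0, 24) == pytest.approx(fine, rel=1e-6)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
    def test_additive_over_interior_split(self, concs):
        t = np.unique(np.concatenate([[0.0, 4.0, 24.0],
                                      np.linspace(1, 23, len(concs))]))
        c = [concs[i % len(concs)] for i in range(t.size)]
        p = make_profile(t, c)
        total = auc_trapezoid(p, t[0], t[-1])
        split = auc_trapezoid(p, t[0], 4.0) + auc_trapezoid(p, 4.0, t[-1])
        assert split == pytest.approx(total, rel=1e-12, abs=1e-12)

    def test_window_outside_range_names_gap(self, profile_factory):
        p = profile_factory([0, 4, 8], [1, 1, 1])
        with pytest.raises(NCAError, match="extends beyond"):
            auc_trapezoid(p, 0, 24)

    def test_blq_substitution_rule(self):
        # leading BLQ -> 0, embedded/trailing BLQ -> LLOQ/2
        p = make_profile(
            [0, 1, 2, 3, 4],
            [np.nan, 4.0, np.nan, 2.0, np.nan],
            blq=[True, False, True, False, True],
            lloq=0.2,
        )
        subst = [0.0, 4.0, 0.1, 2.0, 0.1]
        expected = np.trapezoid(subst, [0, 1, 2, 3, 4])
        assert auc_trapezoid(p, 0, 4) == pytest.approx(expected)


class TestTerminalHalfLife:
    def test_closed_form_mono_exponential(self, profile_factory):
        t = np.array([1, 2, 4, 8, 12, 24.0])
        p = profile_factory(t, 10 * np.exp(-0.1 * t))
        fit = terminal_half_life(p)
        assert fit.t_half == pytest.approx(LN2 / 0.1, abs=5e-4)

    @pytest.mark.parametrize("ke", [0.05, 0.3, 1.7])
    def test_noiseless_recovery_any_rate(self, ke, profile_factory):
        t = np.array([0.5, 1, 2, 4, 8, 16.0]) / ke
        p = profile_factory(t, 5 * np.exp(-ke * t))
        assert terminal_half_life(p).lambda_z == pytest.approx(ke, rel=1e-8)

    def test_noisy_recovery_within_15_percent(self, profile_factory):
        rng = np.random.default_rng(0)
        ke = 0.25
        t = np.linspace(1, 24, 10)
        sigma = math.sqrt(math.log(1.01))  # 10 % lognormal CV
        c = 8 * np.exp(-ke * t) * rng.lognormal(-sigma**2 / 2, sigma, t.size)
        fit = terminal_half_life(make_profile(t, c))
        assert fit.lambda_z == pytest.approx(ke, rel=0.15)

    def test_rising_terminal_phase_raises(self, profile_factory):
        p = profile_factory([0, 1, 2, 3, 4], [5.0, 2.0, 2.0, 2.0, 2.5])
        with pytest.raises(NCAError, match="terminal decline"):
            terminal_half_life(p)

    def test_half_life_rate_identity(self, profile_factory):
        t = np.array([1, 2, 4, 8, 16.0])
        fit = terminal_half_life(profile_factory(t, 3 * np.exp(-0.4 * t)))
        assert fit.t_half * fit.lambda_z == pytest.approx(LN2, abs=1e-15)


class TestNcaSummary:
    @staticmethod
    def _pair(cl_l_h=1.0, v=5.0, f=0.6, ka=2.0, dose=2.0):
        ke = cl_l_h / v
        t = np.geomspace(0.01, 8 / ke, 400)
        iv = make_profile(t, dose / v * np.exp(-ke * t), dose=dose, route="iv")
        bate = f * dose / v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        po = make_profile(t, bate, dose=dose, route="po")
        return iv, po

    def test_dense_sampling_recovers_generator_truth(self):
        iv, po = self._pair(cl_l_h=1.2, v=4.0, f=0.55)
        res = nca_summary(iv, po)
        assert res.clearance == pytest.approx(1.2 * 1000 / 60, rel=0.02)
        assert res.vz == pytest.approx(4.0, rel=0.02)
        assert res.f_oral == pytest.approx(0.55, rel=0.02)
        assert res.auc_0_inf >= res.auc_0_t

    def test_bioavailability_identity_and_ratio(self):
        iv, _ = self._pair()
        po_same = iv.with_(route="po")
        assert nca_summary(iv, po_same).f_oral == pytest.approx(1.0, rel=1e-3)
        po_half = iv.with_(route="po", concentrations=iv.concentrations / 2)
        assert nca_summary(iv, po_half).f_oral == pytest.approx(0.5, rel=1e-3)

    def test_rat_preset_closed_loop(self):
        iv, truth = gen_pk_profile("rat", route="iv")
        po, _ = gen_pk_profile("rat", route="po")
        res = nca_summary(iv, po)
        assert res.clearance == pytest.approx(truth.truth["cl_ml_min_kg"], rel=0.02)
        assert res.t_half == pytest.approx(truth.truth["t_half_h"], rel=0.02)


class TestBindingArithmetic:
    @pytest.mark.parametrize(
        "auc,bound,expected",
        [(10.2, 93.8, 0.63), (23.6, 97.7, 0.54)],
    )
    def test_unbound_exposure_printed_values(self, auc, bound, expected):
        assert round(unbound_auc(auc, bound), 2) == expected

    def test_zero_binding_is_identity(self):
        assert unbound_auc(7.7, 0.0) == 7.7

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 90.0), st.floats(0.5, 9.0), st.floats(0.01, 100.0))
    def test_strictly_decreasing_in_bound_percent(self, lo, gap, auc):
        assert unbound_auc(auc, lo) > unbound_auc(auc, lo + gap)

    def test_full_binding_rejected(self):
        with pytest.raises(NCAError):
            unbound_auc(1.0, BindingParams(100.0))

    def test_efflux_ratio(self):
        assert round(efflux_ratio(26.3e-6, 14.1e-6), 1) == 1.9
        assert efflux_ratio(3.0, 3.0) == 1.0
        assert efflux_ratio(2.0, 5.0) == pytest.approx(1 / efflux_ratio(5.0, 2.0))
        with pytest.raises(NCAError):
            efflux_ratio(-1.0, 2.0)
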