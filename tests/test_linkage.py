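"""Two-state O2 binding, GSH release, P50 linkage and threshold/phi fits."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbgsh.linkage import (
    BpgLinkage,
    GshLinkage,
    MwcParams,
    calibrate_KR,
    default_mwc_params,
    equilibrium_free_gsh,
    estimate_threshold,
    fit_phi,
    o2_saturation,
    p50_with_gsh,
    predicted_free_gsh,
    r_state_fraction,
    saturation_to_pO2,
    stoichiometric_release,
    t_state_fraction,
)

pressures = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)
saturations = st.floats(min_value=1e-4, max_value=1 - 1e-4, allow_nan=False)


class TestO2Saturation:
    def test_zero_pressure_gives_zero(self, mwc):
        assert o2_saturation(0.0, mwc) == 0.0

    def test_hill_half_saturation_at_p50(self):
        params = MwcParams(mode="hill", p50=26.0, n_hill=2.7)
        assert o2_saturation(26.0, params) == pytest.approx(0.5, abs=1e-12)

    @given(pressures, st.floats(min_value=0.1, max_value=1e6))
    def test_c_equal_one_collapses_to_noncooperative(self, p, L):
        """With c -> 1 the states are indistinguishable: Y = a/(1+a), any L."""
        params = MwcParams(L=L, c=1 - 1e-15, KR=5.0)
        a = p / 5.0
        assert o2_saturation(p, params) == pytest.approx(a / (1 + a), abs=1e-12)

    @given(pressures, pressures)
    def test_monotone_and_bounded(self, mwc, p1, p2):
        y1, y2 = o2_saturation(p1, mwc), o2_saturation(p2, mwc)
        assert 0.0 <= y1 <= 1.0
        if p1 < p2:
            assert y1 <= y2

    def test_negative_pressure_rejected(self, mwc):
        with pytest.raises(ValueError):
            o2_saturation(-1.0, mwc)


class TestStateFractions:
    def test_zero_ligand_closed_form(self):
        params = MwcParams(L=10.0, c=0.1, KR=1.0)
        assert r_state_fraction(0.0, params) == pytest.approx(1.0 / 11.0, abs=1e-12)

    def test_high_pressure_limit_closed_form(self, mwc):
        # asymptote is 1/(1 + L c^4): nearly all R since c << 1
        limit = 1.0 / (1.0 + mwc.L * mwc.c**4)
        assert r_state_fraction(1e6, mwc) == pytest.approx(limit, abs=1e-4)
        assert limit > 0.99

    def test_direct_arithmetic_example(self):
        # fR = 11^4 / (11^4 + 10 * 2^4) at L=10, c=0.1, KR=1, pO2=10
        params = MwcParams(L=10.0, c=0.1, KR=1.0)
        assert r_state_fraction(10.0, params) == pytest.approx(11**4 / (11**4 + 10 * 2**4), abs=1e-9)

    @given(pressures, pressures)
    def test_fractions_sum_to_one_and_fR_monotone(self, mwc, p1, p2):
        assert r_state_fraction(p1, mwc) + t_state_fraction(p1, mwc) == pytest.approx(1.0, abs=1e-12)
        if p1 < p2:
            assert r_state_fraction(p1, mwc) <= r_state_fraction(p2, mwc) + 1e-15

    def test_hill_mode_unsupported(self):
        with pytest.raises(ValueError):
            r_state_fraction(10.0, MwcParams(mode="hill"))


class TestInversionAndCalibration:
    @given(saturations)
    def test_round_trip_identity(self, mwc, s):
        assert o2_saturation(saturation_to_pO2(s, mwc), mwc) == pytest.approx(s, abs=1e-9)

    def test_hill_mode_p50(self):
        params = MwcParams(mode="hill", p50=26.0, n_hill=2.7)
        assert saturation_to_pO2(0.5, params) == pytest.approx(26.0, abs=1e-9)

    def test_out_of_range_saturation_rejected(self, mwc):
        for s in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                saturation_to_pO2(s, mwc)

    def test_calibrated_defaults_hit_target_p50(self, mwc):
        assert o2_saturation(26.0, mwc) == pytest.approx(0.5, abs=1e-6)

    def test_calibration_against_grid_search_oracle(self):
        """Bisection-based P50 agrees with a brute-force pressure grid."""
        params = calibrate_KR(MwcParams(L=1.7e5, c=0.014), 26.0)
        grid = np.linspace(1.0, 100.0, 200_000)
        y = o2_saturation(grid, params)
        p50_grid = grid[int(np.argmin(np.abs(y - 0.5)))]
        assert saturation_to_pO2(0.5, params) == pytest.approx(p50_grid, abs=1e-3)

    def test_noncooperative_calibration_closed_form(self):
        params = calibrate_KR(MwcParams(c=1 - 1e-15), 26.0)
        assert params.KR == pytest.approx(26.0, rel=1e-9)


class TestRelease:
    def test_full_deoxygenation_releases_capacity(self, mwc):
        link = GshLinkage(phi=1.0)
        released = stoichiometric_release(0.0, 5.23, link, mwc)
        fT0 = t_state_fraction(0.0, mwc)
        assert released == pytest.approx(2 * 5.23 * fT0, rel=1e-12)
        assert released == pytest.approx(10.46, abs=0.01)  # fT(0) ~ 1

    def test_full_oxygenation_releases_nothing(self, mwc, linkage):
        assert stoichiometric_release(1.0, 5.23, linkage, mwc) == 0.0

    def test_occupancy_scales_release(self, mwc):
        link = GshLinkage(phi=0.165)
        # at SO2 -> 0 the T fraction is ~1, so release ~ phi * capacity
        assert stoichiometric_release(0.0, 5.23, link, mwc) == pytest.approx(1.726, abs=0.01)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=6))
    def test_monotone_nonincreasing_in_saturation(self, mwc, linkage, sats):
        sats = sorted(sats)
        rel = [stoichiometric_release(s, 5.23, linkage, mwc) for s in sats]
        assert all(a >= b - 1e-12 for a, b in zip(rel, rel[1:]))

    def test_predicted_curve_baseline_and_monotonicity(self, mwc, linkage):
        base = predicted_free_gsh(0.98, 1.23, 5.23, linkage, mwc)
        assert base == pytest.approx(1.23, abs=0.35)  # near baseline at high SO2
        vals = [predicted_free_gsh(s, 1.23, 5.23, linkage, mwc) for s in (0.2, 0.5, 0.9)]
        assert vals[0] >= vals[1] >= vals[2]

    def test_release_concentrated_at_low_saturation(self, mwc, linkage):
        """The rise is concentrated below ~50-60% SO2 (soft calibration)."""
        hi = stoichiometric_release(0.9, 5.23, linkage, mwc)
        lo = stoichiometric_release(0.2, 5.23, linkage, mwc)
        assert hi < 0.2 * lo

    def test_negative_hb_rejected(self, mwc, linkage):
        with pytest.raises(ValueError):
            stoichiometric_release(0.5, -1.0, linkage, mwc)


class TestEquilibriumFreeGsh:
    def test_no_protein_means_all_free(self, mwc, linkage):
        assert equilibrium_free_gsh(3.0, 0.0, 0.5, linkage, mwc) == 3.0

    def test_quadratic_closed_form(self, mwc):
        """fR=1, n_r=4, Kd=2 uM, Hb=1 uM, total=4 uM: g solves g^2+2g-8=0 (uM)."""
        link = GshLinkage(n_r=4, kd_r_uM=2.0, n_t=2, kd_t_uM=17.0)
        g = equilibrium_free_gsh(0.004, 0.001, 1.0, link, mwc)
        assert g * 1000.0 == pytest.approx(2.0, abs=1e-9)

    def test_weak_binding_limit(self, mwc):
        link = GshLinkage(n_r=4, kd_r_uM=1e9, n_t=2, kd_t_uM=1e9)
        assert equilibrium_free_gsh(3.0, 5.0, 0.5, link, mwc) == pytest.approx(3.0, rel=1e-3)

    @given(
        st.floats(min_value=1e-4, max_value=20.0),
        st.floats(min_value=0.0, max_value=10.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_mass_conservation(self, mwc, linkage, g_total, hb, so2):
        g = equilibrium_free_gsh(g_total, hb, so2, linkage, mwc)
        from hbgsh.linkage import _fT_at_saturation

        fT = _fT_at_saturation(so2, mwc)
        fR = 1 - fT
        kd_r, kd_t = linkage.kd_r_uM / 1000, linkage.kd_t_uM / 1000
        bound = hb * (fR * linkage.n_r * g / (g + kd_r) + fT * linkage.n_t * g / (g + kd_t))
        assert g + bound == pytest.approx(g_total, rel=1e-9, abs=1e-12)


class TestP50Linkage:
    def test_no_ligands_is_baseline(self, mwc, linkage):
        assert p50_with_gsh(0.0, linkage, mwc) == pytest.approx(26.0, abs=1e-6)

    def test_gsh_raises_affinity(self, mwc, linkage):
        assert p50_with_gsh(5.0, linkage, mwc) < 26.0

    def test_bpg_lowers_affinity(self, mwc, linkage):
        assert p50_with_gsh(0.0, linkage, mwc, bpg=BpgLinkage(), bpg_mM=2.0) > 26.0

    def test_monotone_in_each_effector(self, mwc, linkage):
        p50s = [p50_with_gsh(g, linkage, mwc) for g in (0.0, 0.1, 1.0, 5.0)]
        assert all(a > b for a, b in zip(p50s, p50s[1:]))
        p50s_bpg = [p50_with_gsh(0.0, linkage, mwc, bpg_mM=b) for b in (0.0, 0.5, 2.0, 5.0)]
        assert all(a < b for a, b in zip(p50s_bpg, p50s_bpg[1:]))


class TestThresholdEstimation:
    @staticmethod
    def _hinge(s, a, b, k, s_star):
        return a + np.where(s < s_star, b * np.expm1(k * (s_star - s)), 0.0)

    def test_noiseless_recovery_to_grid_resolution(self):
        s = np.linspace(0.98, 0.05, 40)
        g = self._hinge(s, 2.5, 1.0, 5.0, 0.50)
        fit = estimate_threshold(s, g)
        assert fit.threshold == pytest.approx(0.50, abs=0.011)
        assert fit.baseline == pytest.approx(2.5, abs=0.01)

    @pytest.mark.parametrize("s_star", [0.35, 0.50, 0.65])
    def test_noiseless_recovery_across_thresholds(self, s_star):
        s = np.linspace(0.98, 0.05, 60)
        g = self._hinge(s, 2.5, 1.0, 6.0, s_star)
        fit = estimate_threshold(s, g)
        assert fit.threshold == pytest.approx(s_star, abs=0.011)

    def test_constant_data_yields_no_threshold(self):
        s = np.linspace(0.95, 0.05, 20)
        fit = estimate_threshold(s, np.full_like(s, 2.5))
        assert fit.threshold is None
        assert fit.amplitude == 0.0

    def test_pure_noise_rarely_yields_threshold(self):
        rng = np.random.default_rng(5)
        s = np.linspace(0.95, 0.05, 30)
        hits = sum(
            estimate_threshold(s, 2.5 + rng.normal(0, 0.2, s.size)).threshold is not None
            for _ in range(20)
        )
        assert hits <= 3  # nominal 5% level

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_threshold([0.5] * 5, [1.0] * 5)
        with pytest.raises(ValueError):
            estimate_threshold(np.linspace(0, 2, 12), np.ones(12))


class TestPhiFit:
    def test_noiseless_inverse_consistency(self, mwc):
        s = np.linspace(0.98, 0.05, 30)
        gen = GshLinkage(phi=0.17)
        g = np.array([predicted_free_gsh(x, 1.23, 5.23, gen, mwc) for x in s])
        fit = fit_phi(s, g, 5.23, GshLinkage(), mwc)
        assert fit.phi == pytest.approx(0.17, abs=1e-6)
        assert fit.baseline_mM == pytest.approx(1.23, abs=1e-6)

    def test_zero_release_gives_zero_phi(self, mwc):
        s = np.linspace(0.98, 0.05, 20)
        fit = fit_phi(s, np.full_like(s, 1.23), 5.23, GshLinkage(), mwc)
        assert fit.phi == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_saturations_rejected(self, mwc):
        with pytest.raises(ValueError):
            fit_phi(np.full(10, 0.5), np.ones(10), 5.23, GshLinkage(), mwc)

    def test_phi_clipped_to_unit_interval(self, mwc):
        s = np.linspace(0.98, 0.05, 20)
        # absurdly steep rise forces the unconstrained phi above 1
        g = 1.23 + 50.0 * np.array([1 - x for x in s])
        fit = fit_phi(s, g, 5.23, GshLinkage(), mwc)
        assert 0.0 <= fit.phi <= 1.0


class TestParameterValidation:
    def test_invalid_mwc(self):
        for kwargs in ({"L": -1.0}, {"c": 1.5}, {"KR": 0.0}, {"mode": "bogus"}, {"n_hill": 0.5}):
            with pytest.raises(ValueError):
                MwcParams(**kwargs)

    def test_invalid_linkage(self):
        for kwargs in (
            {"n_r": 1, "n_t": 2},
            {"kd_r_uM": 0.0},
            {"phi": 1.5},
        ):
            with pytest.raises(ValueError):
                GshLinkage(**kwargs)
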