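"""Scenario machinery, forcing, analyses, and properties of the full
coupled runs (shared session fixtures)."""

import numpy as np
import pandas as pd
import pytest

from rootflow3d.domain import build_cylinder_domain, uniform_theta_init
from rootflow3d.experiment import (
    compartment_balance,
    delta_psi_pd,
    layer_mean_psi,
    predawn_collar_potential,
    sensitivity_suite,
    transpiration_step_function,
)
from rootflow3d.root_architecture import default_hydraulic_table


class TestTranspirationStepFunction:
    def test_daytime_rate_scales_with_photoperiod(self):
        T, _ = transpiration_step_function([14.0], photoperiod_h=14.0)
        assert T(0.1) == pytest.approx(24.0)       # 14 / (14/24)
        assert T(0.9) == 0.0                       # night

    def test_zero_rate_day(self):
        T, _ = transpiration_step_function([0.0, 5.0])
        assert T(0.3) == 0.0 and T(1.3) > 0.0

    def test_daily_integral_equals_rate(self):
        rates = [3.0, 17.5, 0.0, 22.1]
        T, breaks = transpiration_step_function(rates, photoperiod_h=14.0)
        p = 14.0 / 24.0
        for d, r in enumerate(rates):
            integral = T(d + 0.1) * p          # constant over the light phase
            assert integral == pytest.approx(r, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            transpiration_step_function([-1.0])


class TestLayerMeanPsi:
    def test_uniform_and_hydrostatic_fields(self):
        from rootflow3d.domain import hydrostatic_init

        g = build_cylinder_domain(dx=1.0, dy=1.0, dz=0.5)
        st = uniform_theta_init(g, 0.25)
        vals = layer_mean_psi(st, [-1.5, -6.5, -16.5])
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)
        st2 = hydrostatic_init(g, 0.0)
        v = layer_mean_psi(st2, [-6.25])
        assert v[0] == pytest.approx(-21.5 + 6.25)

    def test_slice_mean_matches_direct_average(self):
        g = build_cylinder_domain(dx=1.0, dy=1.0, dz=0.5)
        st = uniform_theta_init(g, 0.25)
        rng = np.random.default_rng(3)
        st.psi += rng.normal(0, 5.0, size=st.psi.shape)
        k = g.slice_index(7.5)
        ref = st.psi[:, :, k][g.is_soil[:, :, k]].mean()
        assert layer_mean_psi(st, [-7.5])[0] == pytest.approx(ref)

    def test_depth_inside_layer_slab_rejected(self):
        g = build_cylinder_domain(dx=1.0, dy=1.0, dz=0.5,
                                  layer_depths=(5.0,))
        st = uniform_theta_init(g, [0.25, 0.25])
        with pytest.raises(ValueError, match="slab"):
            layer_mean_psi(st, [-5.25])


@pytest.fixture(scope="module")
def profiles():
    from rootflow3d.synthetic import GeneratorParams, generate_architecture

    rs = generate_architecture(GeneratorParams(seed=9), duration=16.0)
    return rs, sensitivity_suite(rs, default_hydraulic_table(), 16.0)


class TestSensitivitySuite:
    def test_each_mode_profile_sums_to_one(self, profiles):
        _, prof = profiles
        for col in ("reference", "1", "2", "3"):
            assert prof[col].sum() == pytest.approx(1.0, abs=1e-8)

    def test_depth_bins_quarter_centimeter(self, profiles):
        _, prof = profiles
        d = np.diff(prof.index.to_numpy())
        np.testing.assert_allclose(d, -0.25)

    def test_uniform_conductivity_scaling_leaves_profile_unchanged(
            self, profiles):
        import dataclasses

        rs, prof = profiles
        tab = default_hydraulic_table()
        scaled = dataclasses.replace(
            tab,
            kx_bands={k: [(a, 5.0 * v) for a, v in b]
                      for k, b in tab.kx_bands.items()},
            kr_constant=5.0 * tab.kr_constant,
            kr_bands={k: [(a, 5.0 * v) for a, v in b]
                      for k, b in tab.kr_bands.items()})
        prof2 = sensitivity_suite(rs, scaled, 16.0)
        pd.testing.assert_frame_equal(prof, prof2, rtol=1e-9)

    def test_age_dependent_radial_mode_is_flatter_over_depth(
            self, profiles):
        """Age-dependent radial conductivity shifts uptake toward young
        (deep) segments, making the depth profile more uniform than the
        constant-radial reference."""
        _, prof = profiles
        depths = -prof.index.to_numpy()

        def center_of_mass(p):
            return float((depths * p).sum())

        # deeper mean uptake depth = flatter (less top-concentrated)
        assert center_of_mass(prof["2"]) > center_of_mass(prof["1"])
        assert center_of_mass(prof["3"]) > center_of_mass(prof["reference"])


class TestReducedRuns:
    """Properties of the three desk-scale coupled scenario runs."""

    def test_mass_closure_within_half_percent(self, reduced_runs):
        """Cumulative transpiration and cumulative storage loss agree to
        0.5 % in every scenario (closed domain)."""
        for kind in ("CD", "NC", "SC"):
            r = reduced_runs[kind]
            total_depl = r.summary_table().loc["total", "depletion"]
            err = abs(r.cumulative_transpiration - total_depl)
            assert err <= 0.005 * r.cumulative_transpiration, kind

    def test_total_rwu_equals_total_transpiration(self, reduced_runs):
        for kind in ("CD", "NC", "SC"):
            r = reduced_runs[kind]
            total_rwu = r.summary_table().loc["total", "RWU"]
            assert total_rwu == pytest.approx(
                r.cumulative_transpiration, rel=1e-6), kind

    def test_sealed_compartments_rwu_equals_storage_change(
            self, reduced_runs):
        """With non-conductive layers every compartment is sealed:
        uptake equals depletion compartment by compartment."""
        r = reduced_runs["NC"]
        tbl = r.summary_table()
        for c in range(4):
            bal = compartment_balance(r, c)
            np.testing.assert_allclose(bal["cum_inflow"], 0.0, atol=1e-3)
            assert tbl.loc[c, "RWU"] == pytest.approx(
                tbl.loc[c, "depletion"], abs=0.05)

    def test_compartment_ledgers_close(self, reduced_runs):
        """RWU = storage loss + net inflow at every output time, in every
        compartment, for the leaky scenario."""
        r = reduced_runs["SC"]
        for c in range(4):
            bal = compartment_balance(r, c)
            scale = max(1.0, bal["cum_rwu"].abs().max())
            assert bal["closure"].abs().max() <= 2e-3 * scale + 0.05

    def test_compartment_sum_reproduces_domain_balance(self, reduced_runs):
        r = reduced_runs["SC"]
        tbl = r.summary_table()
        assert tbl.loc["total", "RWU"] == pytest.approx(
            sum(tbl.loc[c, "RWU"] for c in range(4)))
        # interior plane fluxes cancel in the sum
        total_inflow = sum(
            compartment_balance(r, c)["cum_inflow"].iloc[-1]
            for c in range(4))
        assert abs(total_inflow) <= 0.02

    def test_nc_decline_is_sequential_and_tied_to_root_arrival(
            self, reduced_runs):
        """Sealed compartments dry top-down, and a compartment's
        tensiometer only starts falling after roots arrive in it."""
        r = reduced_runs["NC"]
        ve = reduced_runs["bundle"]
        tens = r.tensiometer
        drop = tens.iloc[0] - tens.iloc[-1]
        d0, d1, d2, d3 = [drop[d] for d in ve.tensiometer_depths]
        # top compartment dries hard; compartment II (roots arrive only
        # around day 7) has just begun; III and IV are untouched
        assert d0 > 50.0
        assert d0 > 10.0 * d1 > 0.0
        assert abs(d2) < 0.5 and abs(d3) < 0.5

        # compartment II potential is exactly flat until roots arrive
        arch = ve.architecture
        below = arch.pos[:, 2] < -5.0
        t_arrive = float(arch.t_s[below].min())
        t2 = tens[ve.tensiometer_depths[1]]
        moved = t2[(t2.iloc[0] - t2) > 0.5]
        assert len(moved) > 0
        assert moved.index[0] >= t_arrive - 0.5

    def test_sc_slows_upper_and_accelerates_lower_drying_vs_nc(
            self, reduced_runs):
        """Leaky layers resupply the rooted top compartment from below:
        the upper tensiometer falls more slowly and the one below the
        first layer falls earlier/faster than with sealed layers."""
        ve = reduced_runs["bundle"]
        nc = reduced_runs["NC"].tensiometer
        sc = reduced_runs["SC"].tensiometer
        top = ve.tensiometer_depths[0]
        second = ve.tensiometer_depths[1]
        # end-of-run: SC upper compartment is wetter than NC's
        assert sc[top].iloc[-1] > nc[top].iloc[-1] + 10.0
        # and SC has drawn the sub-layer compartment down further
        assert sc[second].iloc[-1] < nc[second].iloc[-1] - 1.0

    def test_predawn_split_penalty_nonnegative(self, reduced_runs):
        """|psi_pd| under leaky layers is at least that of the continuous
        domain on every day, and grows as drying proceeds."""
        d = delta_psi_pd(reduced_runs["SC"], reduced_runs["CD"])
        assert (d >= -1e-6).all()
        assert d.iloc[-1] > 10.0
        nc_pen = delta_psi_pd(reduced_runs["NC"], reduced_runs["CD"])
        assert nc_pen.iloc[-1] >= d.iloc[-1] - 1e-6

    def test_diurnal_amplitude_damped_with_depth(self, reduced_runs):
        """Day-night tensiometer cycling is strongest in the rooted top
        compartment and damped below the layers."""
        ve = reduced_runs["bundle"]
        for kind in ("NC", "SC"):
            tens = reduced_runs[kind].tensiometer
            last2 = tens[tens.index >= tens.index[-1] - 2.0]
            amp = {d: float(np.ptp(np.diff(last2[d])))
                   for d in ve.tensiometer_depths}
            depths = list(ve.tensiometer_depths)
            assert amp[depths[0]] > amp[depths[2]]
            assert amp[depths[0]] > amp[depths[3]]

    def test_predawn_equals_suf_weighted_interface_potential(
            self, reduced_runs):
        """The recorded predawn collar potential is the SUF-weighted
        effective soil potential (zero-flow identity), re-derived
        independently from the final state snapshot."""
        from rootflow3d.coupling import SegmentSoilMap
        from rootflow3d.doussan import compute_suf, solve_xylem

        r = reduced_runs["CD"]
        ve = reduced_runs["bundle"]
        day = int(r.predawn["day"].iloc[-1])
        st = r.final_state
        arch = ve.architecture
        active = arch.active_subset(float(day))
        table = ve.hydraulic_table
        kr, kx = table.segment_conductivities(active, float(day))
        smap = SegmentSoilMap(st.grid, arch)
        W, _ = smap.restrict(active)
        psi_int = W @ st.psi.ravel()
        suf = compute_suf(active, kr, kx)
        psi_eff = float(suf[1:] @ psi_int[1:])
        pd_val = predawn_collar_potential(r, day)
        sol = solve_xylem(active, kr, kx, psi_int, ("flux", 0.0))
        assert sol.psi_collar == pytest.approx(pd_val, abs=1e-6)
        # gravity keeps psi_collar within ~column height of the
        # SUF-weighted mean; without gravity they coincide
        sol0 = solve_xylem(active, kr, kx, psi_int, ("flux", 0.0),
                           gravity=False)
        assert sol0.psi_collar == pytest.approx(psi_eff, abs=0.5)
        assert pd_val == pytest.approx(psi_eff, abs=25.0)
        lo, hi = psi_int[1:].min(), psi_int[1:].max()
        assert lo - 22.0 <= pd_val <= hi + 22.0

    def test_delta_psi_pd_antisymmetric_and_zero_on_self(self, reduced_runs):
        a, b = reduced_runs["SC"], reduced_runs["CD"]
        d_ab = delta_psi_pd(a, b)
        d_ba = delta_psi_pd(b, a)
        np.testing.assert_allclose(d_ab, -d_ba, atol=1e-12)
        np.testing.assert_allclose(delta_psi_pd(a, a), 0.0, atol=1e-12)

    def test_tensiometer_depletion_misattributes_rwu_in_continuous_soil(
            self, reduced_runs):
        """The experimental reduction (uniform-potential depletion from a
        single tensiometer per compartment) misplaces uptake when soil
        redistribution is free: per-compartment depletion disagrees
        strongly with true uptake, while the domain total still matches
        cumulative transpiration."""
        from rootflow3d.measurement import depletion_from_tensiometer
        from rootflow3d.soil_hydraulics import default_materials

        r = reduced_runs["CD"]
        ve = reduced_runs["bundle"]
        soil = default_materials()["soil"]
        grid = r.final_state.grid
        tbl = r.summary_table()
        comp_vol = np.array([grid.compartment_mask(c).sum()
                             for c in range(4)]) * grid.cell_volume
        est = []
        for c, d in enumerate(ve.tensiometer_depths):
            series = r.tensiometer[d]
            depl = depletion_from_tensiometer(series, comp_vol[c], soil)
            est.append(depl.iloc[-1])
        true_rwu = tbl.loc[range(4), "RWU"].to_numpy()
        est = np.asarray(est)
        # totals agree (sealed domain) ...
        assert est.sum() == pytest.approx(r.cumulative_transpiration,
                                          rel=0.25)
        # ... but the attribution to compartments does not: the rooted
        # top compartment's uptake is strongly underestimated
        assert est[0] < 0.5 * true_rwu[0]
        assert np.abs(est - true_rwu).max() > 0.3 * true_rwu.max()
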