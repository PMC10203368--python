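"""Synthetic generator: kinetics, model anchors, determinism and recovery."""

import numpy as np
import pytest

from hydrodr.diffspec import subtract_solute
from hydrodr.models import eval_model, gamma1_effective_limits, static_permittivity
from hydrodr.nmr import pathway_correlation, pathway_profiles
from hydrodr.pipeline import analyze_timelapse, recovered_spectrum
from hydrodr.synthetic import (
    HydrationState,
    NmrConfig,
    TemperatureProfile,
    ThzTdsConfig,
    TimelapseConfig,
    evolve_hydration,
    simulate_nmr_table,
    simulate_thz_tds,
    simulate_timelapse,
    solution_model,
    water_debye_params,
)


class TestWaterParams:
    def test_room_temperature_static_value(self):
        eps_s, _, tau = water_debye_params(25.0)
        assert 78.0 <= eps_s <= 79.0
        assert tau == pytest.approx(8.27e-12, rel=1e-6)

    def test_monotone_in_temperature(self):
        assert water_debye_params(30.0)[0] < water_debye_params(20.0)[0]
        assert water_debye_params(30.0)[2] < water_debye_params(20.0)[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            water_debye_params(75.0)


class TestSolutionModel:
    def test_pure_water_has_no_solute_components(self):
        m = solution_model(0.0, 25.0)
        assert {c.label for c in m.components} == {"gamma1", "gamma2"}

    @pytest.mark.parametrize(
        "conc,limits", [(9.1, (68.59, 5.28)), (2.9, (76.55, 5.49))]
    )
    def test_printed_anchor_limits(self, conc, limits):
        m = solution_model(conc, 24.0)
        s, inf = gamma1_effective_limits(m)
        assert s == pytest.approx(limits[0], abs=1e-9)
        assert inf == pytest.approx(limits[1], abs=1e-9)

    def test_hydration_transfer_conserves_static_permittivity(self):
        m0 = solution_model(9.1, 24.0, HydrationState(f_transfer=0.0))
        m5 = solution_model(9.1, 24.0, HydrationState(f_transfer=0.5))
        assert static_permittivity(m5) == pytest.approx(static_permittivity(m0), rel=1e-12)
        # and the transfer moves strength from gamma2 into delta2
        assert m5.component("gamma2").strength < m0.component("gamma2").strength
        assert m5.component("delta2").strength > m0.component("delta2").strength

    def test_generated_spectra_passive(self, grid):
        for conc in (0.0, 2.9, 9.1, 28.6):
            spec = eval_model(solution_model(conc, 28.0), grid)
            assert np.all(spec.eps_imag >= 0)


class TestHydrationKinetics:
    def test_unit_multiplier_matches_control(self):
        s = HydrationState(kappa_thz=1.0)
        a = evolve_hydration(s, "THz", 10.0, during_irradiation=True)
        b = evolve_hydration(s, "GC", 10.0)
        assert a.f_transfer == pytest.approx(b.f_transfer)

    def test_long_time_reaches_equilibrium(self):
        s = evolve_hydration(HydrationState(), "GC", 1e7)
        assert s.f_transfer == pytest.approx(1.0)

    def test_ten_minute_exposure_beats_four_hours_unperturbed(self):
        # with the default rates a 10-min irradiation advances the transfer
        # further than 240 min of unperturbed equilibration
        s0 = HydrationState()
        irr = evolve_hydration(s0, "THz", 10.0, during_irradiation=True)
        slow = evolve_hydration(s0, "GC", 240.0)
        assert 1.0 - irr.f_transfer < 1.0 - slow.f_transfer


class TestTemperatureProfiles:
    def test_profile_shapes(self):
        for cond, peak in (("GC", 24.0), ("THz", 28.0), ("HTC", 30.0), ("LTC", 20.0)):
            p = TemperatureProfile.standard(cond)
            assert p.at(0.0) == 24.0
            assert p.at(28.0) == pytest.approx(peak)
            assert p.at(50.0) == 24.0  # recovered ~20 min after the perturbation


class TestSimulateTimelapse:
    def test_same_seed_bit_identical(self):
        cfg = TimelapseConfig(conditions=("GC",), n_replicates=2)
        a = simulate_timelapse(cfg, 42)
        b = simulate_timelapse(cfg, 42)
        for key in a.records:
            assert np.array_equal(a.records[key].s11, b.records[key].s11)

    def test_no_noise_constant_conditions_static_in_time(self):
        cfg = TimelapseConfig(
            conditions=("GC",),
            n_replicates=1,
            noise_sigma=0.0,
            hydration=HydrationState(k=0.0),
        )
        ds = simulate_timelapse(cfg, 0)
        ref = ds.records[("GC", 0, 18.0)].s11
        for t in cfg.times_min[1:]:
            assert np.allclose(ds.records[("GC", 0, t)].s11, ref)

    def test_reference_time_recovery_is_exact(self):
        # the same-sample Standard makes the first time point reproduce the
        # assigned single-Debye spectrum identically
        cfg = TimelapseConfig(conditions=("GC",), n_replicates=1)
        ds = simulate_timelapse(cfg, 7)
        spec = recovered_spectrum(ds, "GC", 0, 18.0)
        info = ds.truth[("GC", 18.0)]
        from hydrodr.models import single_debye

        expected = single_debye(
            info["eps_gamma1_s"], info["eps_gamma1_inf"], info["tau_gamma1"], ds.grid
        )
        assert np.allclose(spec.values, expected.values, rtol=1e-9)

    def test_planted_intercepts_recovered_within_one_percent(self):
        ds = simulate_timelapse(TimelapseConfig(conditions=("GC",)), 11)
        df = analyze_timelapse(ds)
        means = df.groupby("time_min")[["eps_gamma1_s", "eps_gamma1_inf"]].mean()
        for t in ds.config.times_min:
            tr = ds.truth[("GC", t)]
            assert means.loc[t, "eps_gamma1_s"] == pytest.approx(
                tr["eps_gamma1_s"], rel=0.01
            )
            assert means.loc[t, "eps_gamma1_inf"] == pytest.approx(
                tr["eps_gamma1_inf"], rel=0.01
            )


class TestSimulateNmr:
    def test_zero_effect_zero_noise_exercises_degenerate_path(self):
        cfg = NmrConfig(
            a=0.0, b=0.0, sigma_d=0.0, sigma_uncorr=0.0, noise=0.0, conc_sigma=0.0
        )
        t = simulate_nmr_table(cfg, 1)
        profs = pathway_profiles(t)
        with pytest.raises(ValueError):
            pathway_correlation(profs[("THz", "3h")], profs[("GC", "24h")])

    def test_noise_free_collinearity(self):
        cfg = NmrConfig(noise=0.0, sigma_uncorr=0.0)
        t = simulate_nmr_table(cfg, 1)
        profs = pathway_profiles(t)
        r_pos = pathway_correlation(profs[("THz", "3h")], profs[("GC", "24h")])
        r_neg = pathway_correlation(profs[("THz", "3h")], profs[("HTC", "3h")])
        assert r_pos == pytest.approx(1.0, abs=1e-9)
        assert r_neg == pytest.approx(-1.0, abs=1e-9)

    def test_table_has_57_analyzed_methyls_per_sample(self):
        t = simulate_nmr_table(NmrConfig(), 3)
        counts = t.peaks.groupby(["condition", "timepoint"]).size()
        assert (counts == 57).all()
        assert len(counts) == 6

    def test_same_seed_reproducible(self):
        a = simulate_nmr_table(NmrConfig(), 5)
        b = simulate_nmr_table(NmrConfig(), 5)
        assert a.peaks["intensity"].equals(b.peaks["intensity"])


class TestSimulateThzTds:
    def test_solute_subtraction_recovers_water_exactly_without_noise(self):
        cfg = ThzTdsConfig(noise=0.0, n_replicates=1)
        s = simulate_thz_tds(cfg, 1)
        mix = s.mean_spectrum("control")
        water = subtract_solute(mix, s.solute_ref, cfg.water_fraction)
        assert np.allclose(water.eps_imag, s.truth["water_imag_clean"], atol=1e-12)

    def test_gamma2_difference_peaks_at_expected_frequency(self):
        cfg = ThzTdsConfig(noise=0.0, n_replicates=1)
        s = simulate_thz_tds(cfg, 1)
        diff = s.mean_spectrum("control").eps_imag - s.mean_spectrum("irradiated").eps_imag
        f_peak = s.grid.frequencies[np.argmax(diff)]
        assert f_peak == pytest.approx(0.6005e12, rel=2e-2)

    def test_same_seed_reproducible(self):
        a = simulate_thz_tds(ThzTdsConfig(), 9)
        b = simulate_thz_tds(ThzTdsConfig(), 9)
        assert np.array_equal(a.water_reps[0], b.water_reps[0])
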