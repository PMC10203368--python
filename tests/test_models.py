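"""Multi-Debye model evaluation, limits and loss curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrodr.models import (
    ComplexPermittivitySpectrum,
    DebyeComponent,
    FrequencyGrid,
    RelaxationSpectrumModel,
    eval_debye_component,
    eval_model,
    gamma1_effective_limits,
    gamma2_imag_mode,
    single_debye,
    static_permittivity,
)


def comp(label="gamma1", strength=10.0, tau=1e-11):
    return DebyeComponent(label, strength, tau)


class TestDebyeComponent:
    def test_half_height_at_relaxation_frequency(self):
        c = comp(strength=10.0, tau=1e-10)
        g = FrequencyGrid(np.array([c.f_relax]))
        s = eval_debye_component(c, g)
        assert s.eps_real[0] == pytest.approx(5.0)
        assert s.eps_imag[0] == pytest.approx(5.0)

    def test_static_limit(self):
        c = comp(strength=10.0, tau=1e-10)
        g = FrequencyGrid(np.array([1e-3]))
        s = eval_debye_component(c, g)
        assert s.eps_real[0] == pytest.approx(10.0, abs=1e-9)
        assert s.eps_imag[0] == pytest.approx(0.0, abs=1e-9)

    def test_loss_closed_form_at_methods_parameters(self):
        # d_eps = 68.59 - 5.28, tau = 58.8 ps: at f = 1/(2 pi tau) the loss
        # is exactly d_eps/2 = 31.655.
        c = comp(strength=63.31, tau=5.88e-11)
        g = FrequencyGrid(np.array([2.7067e9]))
        s = eval_debye_component(c, g)
        assert s.eps_imag[0] == pytest.approx(31.655, rel=1e-4)

    @pytest.mark.parametrize("bad", [dict(strength=-1.0), dict(tau=0.0), dict(label="zeta")])
    def test_invariant_violations_rejected(self, bad):
        kw = dict(label="gamma1", strength=1.0, tau=1e-12)
        kw.update(bad)
        with pytest.raises(ValueError):
            DebyeComponent(**kw)


class TestEvalModel:
    def test_empty_model_is_constant(self, grid):
        m = RelaxationSpectrumModel((), 5.0)
        s = eval_model(m, grid)
        assert np.allclose(s.eps_real, 5.0)
        assert np.allclose(s.eps_imag, 0.0)

    def test_single_gamma1_closed_form(self):
        m = RelaxationSpectrumModel((comp(strength=63.31, tau=5.88e-11),), 5.28)
        g = FrequencyGrid(np.array([2.7067e9]))
        s = eval_model(m, g)
        assert s.eps_real[0] == pytest.approx(36.935, rel=1e-4)
        assert s.eps_imag[0] == pytest.approx(31.655, rel=1e-4)

    def test_static_limit_equals_sum_rule(self):
        comps = tuple(
            DebyeComponent(lbl, s, t)
            for lbl, s, t in [
                ("beta", 10.0, 16e-9),
                ("delta1", 2.0, 1.6e-9),
                ("delta2", 3.0, 4e-11),
                ("gamma1", 55.0, 8.3e-12),
                ("gamma2", 1.5, 2.65e-13),
            ]
        )
        m = RelaxationSpectrumModel(comps, 4.0)
        assert static_permittivity(m) == pytest.approx(75.5)
        g = FrequencyGrid(np.array([1e-6]))
        assert eval_model(m, g).eps_real[0] == pytest.approx(75.5, rel=1e-9)

    def test_vibrational_sum_rule_enforced(self):
        RelaxationSpectrumModel((), 5.0, vib_strengths=(1.0, 1.5), eps_inf=2.5)
        with pytest.raises(ValueError):
            RelaxationSpectrumModel((), 5.0, vib_strengths=(1.0,), eps_inf=2.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        strengths=st.lists(st.floats(0.1, 80.0), min_size=1, max_size=5),
        taus=st.lists(st.floats(1e-13, 1e-8), min_size=5, max_size=5),
        eps_inf_relax=st.floats(1.0, 10.0),
    )
    def test_loss_nonnegative_for_any_valid_model(self, strengths, taus, eps_inf_relax):
        labels = ("beta", "delta1", "delta2", "gamma1", "gamma2")
        comps = tuple(
            DebyeComponent(lbl, s, t) for lbl, s, t in zip(labels, strengths, taus)
        )
        m = RelaxationSpectrumModel(comps, eps_inf_relax)
        g = FrequencyGrid.log_spaced(1e6, 1e13, 60)
        assert np.all(eval_model(m, g).eps_imag >= 0)

    def test_component_locus_lies_on_debye_circle(self):
        # one Debye term plus offset traces the circle centred at
        # ((eps_s + eps_inf)/2, 0) with radius (eps_s - eps_inf)/2
        eps_inf, d = 5.0, 70.0
        m = RelaxationSpectrumModel((comp(strength=d, tau=1e-11),), eps_inf)
        g = FrequencyGrid.log_spaced(1e8, 1e12, 200)
        s = eval_model(m, g)
        center, radius = eps_inf + d / 2.0, d / 2.0
        dist = np.hypot(s.eps_real - center, s.eps_imag)
        assert np.max(np.abs(dist - radius)) < 1e-12 * radius


class TestGammaLimits:
    def test_effective_limits_hand_sum(self):
        m = RelaxationSpectrumModel(
            (comp("gamma1", 62.0, 1e-11), comp("gamma2", 1.5, 2.65e-13)), 5.0
        )
        s, inf = gamma1_effective_limits(m)
        assert s == pytest.approx(68.5)
        assert inf == pytest.approx(6.5)
        assert s - inf == pytest.approx(m.component("gamma1").strength)

    def test_missing_component_raises(self):
        m = RelaxationSpectrumModel((comp("gamma1", 62.0, 1e-11),), 5.0)
        with pytest.raises(KeyError):
            gamma1_effective_limits(m)


class TestGamma2Mode:
    def test_peak_frequency_and_height(self):
        g = FrequencyGrid.linear(0.1e12, 2.5e12, 4001)
        y = gamma2_imag_mode(3.0, 0.265e-12, g)
        f_peak = g.frequencies[np.argmax(y)]
        assert f_peak == pytest.approx(0.6005e12, rel=2e-3)
        assert np.max(y) == pytest.approx(1.5, rel=1e-3)

    def test_zero_strength_is_zero(self, grid):
        assert np.all(gamma2_imag_mode(0.0, 1e-12, grid) == 0.0)


class TestSerialization:
    def test_config_round_trip(self):
        m = RelaxationSpectrumModel(
            (comp("gamma1", 63.31, 5.88e-11), comp("gamma2", 1.5, 2.65e-13)), 3.78
        )
        m2 = RelaxationSpectrumModel.from_config(m.to_config())
        assert m2.eps_inf_relax == m.eps_inf_relax
        assert m2.components == m.components


class TestSpectrumContainer:
    def test_from_complex_sign_convention(self, grid):
        s = single_debye(76.55, 5.49, 5.88e-11, grid)
        # loss stored positive, complex values carry eps' - j eps''
        assert np.all(s.eps_imag >= 0)
        assert np.allclose(s.values.imag, -s.eps_imag)

    def test_length_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            ComplexPermittivitySpectrum(grid, np.ones(3), np.ones(3))

    @pytest.mark.parametrize(
        "freqs", [np.array([1.0, 1.0]), np.array([2.0, 1.0]), np.array([-1.0, 1.0])]
    )
    def test_grid_must_increase_and_be_positive(self, freqs):
        with pytest.raises(ValueError):
            FrequencyGrid(freqs)
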