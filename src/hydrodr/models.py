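"""Parametric multi-Debye complex-permittivity models.

An aqueous protein solution shows several superposed dipolar relaxations:
a protein-derived dispersion near 10 MHz (beta), two hydration-water
dispersions near 0.1 and 4 GHz (delta1, delta2), and slow/fast bulk-water
dispersions near 20 GHz and in the sub-THz range (gamma1, gamma2).  Each is
modelled as a pure Debye term ``d_eps / (1 + j w tau)`` and the spectrum is
their sum plus an apparent high-frequency limit ``eps(inf)_relax`` that lumps
all vibrational strengths above the measured band.

Sign convention throughout the package: ``eps* = eps' - j eps''`` with the
loss ``eps''`` stored positive, so a Nyquist plot (eps'' against eps') shows
the loss semicircle above the real axis.  Frequencies are stored in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "COMPONENT_LABELS",
    "DebyeComponent",
    "RelaxationSpectrumModel",
    "FrequencyGrid",
    "ComplexPermittivitySpectrum",
    "eval_debye_component",
    "eval_model",
    "static_permittivity",
    "gamma1_effective_limits",
    "gamma2_imag_mode",
    "single_debye",
]

#: Recognised dispersion labels, slow to fast.
COMPONENT_LABELS = ("beta", "delta1", "delta2", "gamma1", "gamma2")


@dataclass(frozen=True)
class DebyeComponent:
    """One Debye dispersion: relaxation strength ``strength`` (dimensionless
    permittivity units) and relaxation time ``tau`` in seconds."""

    label: str
    strength: float
    tau: float

    def __post_init__(self) -> None:
        if self.label not in COMPONENT_LABELS:
            raise ValueError(
                f"unknown component label {self.label!r}; expected one of {COMPONENT_LABELS}"
            )
        if not self.strength > 0:
            raise ValueError(f"relaxation strength must be > 0, got {self.strength}")
        if not self.tau > 0:
            raise ValueError(f"relaxation time must be > 0, got {self.tau}")

    @property
    def f_relax(self) -> float:
        """Relaxation (loss-peak) frequency 1/(2 pi tau) in Hz."""
        return 1.0 / (2.0 * np.pi * self.tau)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(f > 0):
            raise ValueError("all frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n: int) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n))

    @classmethod
    def linear(cls, f_min: float, f_max: float, n: int) -> "FrequencyGrid":
        return cls(np.linspace(f_min, f_max, n))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies 2 pi f."""
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.frequencies.shape == other.frequencies.shape and np.array_equal(
            self.frequencies, other.frequencies
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.frequencies.shape, float(self.frequencies[0]), float(self.frequencies[-1])))


@dataclass
class ComplexPermittivitySpectrum:
    """Frequency-indexed complex permittivity, optionally with per-point
    standard deviations.  The central data currency of the pipeline."""

    grid: FrequencyGrid
    eps_real: np.ndarray
    eps_imag: np.ndarray
    sigma_real: np.ndarray | None = None
    sigma_imag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.grid)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        for name in ("eps_real", "eps_imag"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have the same length as the grid")
        for name in ("sigma_real", "sigma_imag"):
            s = getattr(self, name)
            if s is not None:
                s = np.asarray(s, dtype=float)
                if s.shape != (n,):
                    raise ValueError(f"{name} must have the same length as the grid")
                setattr(self, name, s)

    @classmethod
    def from_complex(
        cls,
        grid: FrequencyGrid,
        values: np.ndarray,
        sigma_real: np.ndarray | None = None,
        sigma_imag: np.ndarray | None = None,
    ) -> "ComplexPermittivitySpectrum":
        """Build from ``eps* = eps' - j eps''`` complex values; the stored
        imaginary part is the positive loss ``-Im(eps*)``."""
        values = np.asarray(values, dtype=complex)
        return cls(grid, values.real, -values.imag, sigma_real, sigma_imag)

    @property
    def values(self) -> np.ndarray:
        """Complex permittivity ``eps' - j eps''``."""
        return self.eps_real - 1j * self.eps_imag


def eval_debye_component(c: DebyeComponent, grid: FrequencyGrid) -> ComplexPermittivitySpectrum:
    """Evaluate a single Debye term ``d_eps / (1 + j w tau)`` on a grid.

    At the relaxation frequency (w tau = 1) the term contributes d_eps/2 to
    both the real part and the loss.
    """
    wt = grid.omega * c.tau
    z = c.strength / (1.0 + 1j * wt)
    return ComplexPermittivitySpectrum.from_complex(grid, z)


def eval_model(m: "RelaxationSpectrumModel", grid: FrequencyGrid) -> ComplexPermittivitySpectrum:
    """Evaluate the full multi-Debye model: sum of all component terms plus
    the apparent high-frequency limit in the real part."""
    z = np.full(len(grid), complex(m.eps_inf_relax))
    for c in m.components:
        wt = grid.omega * c.tau
        z = z + c.strength / (1.0 + 1j * wt)
    return ComplexPermittivitySpectrum.from_complex(grid, z)


@dataclass(frozen=True)
class RelaxationSpectrumModel:
    """Multi-Debye relaxation model.

    Parameters
    ----------
    components:
        The Debye dispersions, typically a subset of
        (beta, delta1, delta2, gamma1, gamma2).
    eps_inf_relax:
        Apparent high-frequency limit of the Debye-type part; it lumps the
        summed vibrational strengths of everything above the measured band
        together with the true high-frequency limit.
    vib_strengths, eps_inf:
        Optional decomposition of ``eps_inf_relax``; when both are given the
        sum rule ``eps_inf_relax = sum(vib_strengths) + eps_inf`` must hold.
    """

    components: tuple[DebyeComponent, ...]
    eps_inf_relax: float
    vib_strengths: tuple[float, ...] | None = None
    eps_inf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.eps_inf_relax < 1.0:
            raise ValueError("eps_inf_relax must be >= 1 (vacuum lower bound)")
        if self.vib_strengths is not None:
            object.__setattr__(self, "vib_strengths", tuple(float(v) for v in self.vib_strengths))
            if self.eps_inf is None:
                raise ValueError("eps_inf required when vib_strengths are given")
            total = sum(self.vib_strengths) + self.eps_inf
            if not np.isclose(total, self.eps_inf_relax, rtol=1e-9, atol=1e-9):
                raise ValueError(
                    "eps_inf_relax must equal sum(vib_strengths) + eps_inf "
                    f"({total} != {self.eps_inf_relax})"
                )

    def component(self, label: str) -> DebyeComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"model has no {label!r} component")

    def has(self, label: str) -> bool:
        return any(c.label == label for c in self.components)

    # -- plain-text serialization ------------------------------------------

    def to_config(self) -> str:
        """Serialize to a flat plain-text config (one component per line)."""
        lines = [f"eps_inf_relax = {self.eps_inf_relax!r}"]
        for c in self.components:
            lines.append(f"component = {c.label} {c.strength!r} {c.tau!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "RelaxationSpectrumModel":
        eps_inf_relax = None
        comps: list[DebyeComponent] = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "eps_inf_relax":
                eps_inf_relax = float(value)
            elif key == "component":
                label, strength, tau = value.split()
                comps.append(DebyeComponent(label, float(strength), float(tau)))
            else:
                raise ValueError(f"unknown model config key {key!r}")
        if eps_inf_relax is None:
            raise ValueError("model config missing eps_inf_relax")
        return cls(tuple(comps), eps_inf_relax)


def static_permittivity(m: RelaxationSpectrumModel) -> float:
    """Static (zero-frequency) permittivity: sum of all relaxation strengths
    plus the apparent high-frequency limit."""
    return float(sum(c.strength for c in m.components) + m.eps_inf_relax)


def gamma1_effective_limits(m: RelaxationSpectrumModel) -> tuple[float, float]:
    """Approximate frequency limits of the slow bulk-water (gamma1) dispersion.

    Because gamma1 is well separated in frequency from the slower beta/delta
    dispersions and from the faster gamma2 one, its static and high-frequency
    limits are, to a good approximation::

        eps_g1(s)   = d_eps_g1 + d_eps_g2 + eps_inf_relax
        eps_g1(inf) =            d_eps_g2 + eps_inf_relax

    Their difference is exactly the gamma1 strength.

    Raises
    ------
    KeyError
        If the model lacks a gamma1 or gamma2 component.
    """
    g1 = m.component("gamma1")
    g2 = m.component("gamma2")
    eps_inf = g2.strength + m.eps_inf_relax
    return (g1.strength + eps_inf, eps_inf)


def gamma2_imag_mode(strength: float, tau: float, grid: FrequencyGrid) -> np.ndarray:
    """Debye loss curve ``d_eps * w tau / (1 + w^2 tau^2)`` of the fast-water
    (gamma2) mode; peaks at f = 1/(2 pi tau) with height d_eps/2."""
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if not tau > 0:
        raise ValueError("tau must be > 0")
    wt = grid.omega * tau
    return strength * wt / (1.0 + wt**2)


def single_debye(
    eps_s: float, eps_inf: float, tau: float, grid: FrequencyGrid
) -> ComplexPermittivitySpectrum:
    """Single-Debye spectrum with static limit ``eps_s``, high-frequency
    limit ``eps_inf`` and relaxation time ``tau`` — the reference shape of
    the slow-water dispersion used for calibration standards."""
    if not eps_s > eps_inf:
        raise ValueError("eps_s must exceed eps_inf")
    wt = grid.omega * tau
    z = eps_inf + (eps_s - eps_inf) / (1.0 + 1j * wt)
    return ComplexPermittivitySpectrum.from_complex(grid, z)
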