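"""File formats and run configuration.

Formats handled:

* Touchstone v1 ``.s1p`` (RI and MA dialects) for reflection records,
* CSV spectra with columns ``frequency_hz, eps_real, eps_imag`` and optional
  ``sigma_real, sigma_imag``,
* CSV reflection records with columns ``frequency_hz, s11_real, s11_imag``,
* flat sectioned plain-text run configuration (INI syntax).

Frequencies are always serialized in Hz; files are UTF-8 with header rows;
decimal parsing is locale-independent (always ``.``).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hydrodr.calibration import ReflectionRecord
from hydrodr.models import ComplexPermittivitySpectrum, FrequencyGrid

__all__ = [
    "read_touchstone",
    "write_touchstone",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_reflection_csv",
    "write_reflection_csv",
    "RunConfig",
]

_TS_UNIT = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


class TouchstoneFormatError(ValueError):
    """Malformed Touchstone file."""


def read_touchstone(path: str | Path) -> ReflectionRecord:
    """Read a one-port Touchstone v1 file (RI or MA data dialects).

    The option line ``# <unit> S <format> R <z0>`` is parsed
    case-insensitively with the standard defaults (GHz, MA, 50 ohm).
    Frequencies are normalized to Hz and must be strictly increasing.
    """
    unit, fmt = 1e9, "MA"
    freqs: list[float] = []
    vals: list[complex] = []
    text = Path(path).read_text(encoding="utf-8")
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line[1:].upper().split()
            i = 0
            while i < len(tokens):
                tok = tokens[i]
                if tok in _TS_UNIT:
                    unit = _TS_UNIT[tok]
                elif tok in ("RI", "MA", "DB"):
                    fmt = tok
                elif tok == "R" and i + 1 < len(tokens):
                    i += 1  # reference impedance, unused here
                elif tok == "S":
                    pass
                else:
                    raise TouchstoneFormatError(f"unknown option token {tok!r}")
                i += 1
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TouchstoneFormatError(
                f"expected 3 columns for a 1-port record, got {len(parts)}: {line!r}"
            )
        f, a, b = (float(p) for p in parts)
        freqs.append(f * unit)
        if fmt == "RI":
            vals.append(complex(a, b))
        elif fmt == "MA":
            vals.append(a * np.exp(1j * np.deg2rad(b)))
        else:  # DB
            mag = 10.0 ** (a / 20.0)
            vals.append(mag * np.exp(1j * np.deg2rad(b)))
    if not freqs:
        raise TouchstoneFormatError(f"no data lines in {path}")
    if not np.all(np.diff(freqs) > 0):
        raise TouchstoneFormatError("frequencies must be strictly increasing")
    return ReflectionRecord(FrequencyGrid(np.array(freqs)), np.array(vals), validate_passive=False)


def write_touchstone(rec: ReflectionRecord, path: str | Path, fmt: str = "RI") -> None:
    """Write a one-port Touchstone v1 file in the RI or MA dialect, Hz."""
    fmt = fmt.upper()
    if fmt not in ("RI", "MA"):
        raise ValueError("fmt must be 'RI' or 'MA'")
    lines = [f"# HZ S {fmt} R 50"]
    for f, s in zip(rec.grid.frequencies, rec.s11):
        if fmt == "RI":
            lines.append(f"{f:.10e} {s.real:.12e} {s.imag:.12e}")
        else:
            lines.append(f"{f:.10e} {abs(s):.12e} {np.angle(s, deg=True):.12e}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum_csv(path: str | Path) -> ComplexPermittivitySpectrum:
    """Read a permittivity CSV (frequency_hz, eps_real, eps_imag
    [, sigma_real, sigma_imag])."""
    df = pd.read_csv(path)
    for col in ("frequency_hz", "eps_real", "eps_imag"):
        if col not in df.columns:
            raise ValueError(f"spectrum CSV missing column {col!r}")
    return ComplexPermittivitySpectrum(
        FrequencyGrid(df["frequency_hz"].to_numpy(float)),
        df["eps_real"].to_numpy(float),
        df["eps_imag"].to_numpy(float),
        sigma_real=df["sigma_real"].to_numpy(float) if "sigma_real" in df else None,
        sigma_imag=df["sigma_imag"].to_numpy(float) if "sigma_imag" in df else None,
    )


def write_spectrum_csv(spec: ComplexPermittivitySpectrum, path: str | Path) -> None:
    data = {
        "frequency_hz": spec.grid.frequencies,
        "eps_real": spec.eps_real,
        "eps_imag": spec.eps_imag,
    }
    if spec.sigma_real is not None:
        data["sigma_real"] = spec.sigma_real
    if spec.sigma_imag is not None:
        data["sigma_imag"] = spec.sigma_imag
    pd.DataFrame(data).to_csv(path, index=False)


def read_reflection_csv(path: str | Path) -> ReflectionRecord:
    """Read a reflection CSV (frequency_hz, s11_real, s11_imag)."""
    df = pd.read_csv(path)
    for col in ("frequency_hz", "s11_real", "s11_imag"):
        if col not in df.columns:
            raise ValueError(f"reflection CSV missing column {col!r}")
    s11 = df["s11_real"].to_numpy(float) + 1j * df["s11_imag"].to_numpy(float)
    return ReflectionRecord(
        FrequencyGrid(df["frequency_hz"].to_numpy(float)), s11, validate_passive=False
    )


def write_reflection_csv(rec: ReflectionRecord, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": rec.grid.frequencies,
            "s11_real": rec.s11.real,
            "s11_imag": rec.s11.imag,
        }
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated run configuration for the CLI.

    Sections (INI syntax): ``[simulate]`` (seed, concentration_wt,
    noise_sigma, n_replicates), ``[analysis]`` (fit/peak bands in Hz),
    ``[dose]`` (surface power density and medium parameters).  Every band
    must be a nonempty interval inside the simulated data range.
    """

    seed: int = 0
    concentration_wt: float = 9.1
    noise_sigma: float = 1e-3
    n_replicates: int = 5
    fit_band: tuple[float, float] = (0.1e9, 14e9)
    peak_band: tuple[float, float] = (6e9, 10e9)
    p_s: float = 160.0
    eps_real_100ghz: float = 7.7
    alpha: float = 83.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path, encoding="utf-8") as fh:
            cp.read_file(fh)
        kw: dict = {}
        if cp.has_section("simulate"):
            s = cp["simulate"]
            for key, cast in (
                ("seed", int),
                ("concentration_wt", float),
                ("noise_sigma", float),
                ("n_replicates", int),
            ):
                if key in s:
                    kw[key] = cast(s[key])
        if cp.has_section("analysis"):
            a = cp["analysis"]
            for key in ("fit_band", "peak_band"):
                if key in a:
                    lo, hi = (float(v) for v in a[key].split())
                    kw[key] = (lo, hi)
        if cp.has_section("dose"):
            d = cp["dose"]
            for key in ("p_s", "eps_real_100ghz", "alpha"):
                if key in d:
                    kw[key] = float(d[key])
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("fit_band", "peak_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be a nonempty positive interval")
        if self.noise_sigma < 0 or self.n_replicates < 1:
            raise ValueError("noise_sigma must be >= 0 and n_replicates >= 1")
        for name in ("p_s", "eps_real_100ghz", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
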