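"""Time-lapse difference spectra and band statistics.

Subtracting the permittivity spectrum at a reference time from a later one
isolates the slow spectral changes.  Three frequency bands summarize a
difference spectrum:

* L (0.3-3 GHz): the hydration-water (delta) dispersion region,
* H (3-6.5 GHz): the intermediate region,
* P: the standing-wave excursion peak near 7 GHz (real part) or 8 GHz
  (imaginary part), measured against the 4-5 GHz background mean.

Uncertainties propagate in quadrature: the difference of two spectra with
per-point standard deviations sigma_A, sigma_B carries
``sqrt(sigma_A^2 + sigma_B^2)``.  The same module handles the THz-TDS
solute subtraction (remove the dehydrated-protein vibrational spectrum,
then normalize by the water fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from hydrodr.models import ComplexPermittivitySpectrum, FrequencyGrid

__all__ = [
    "BandConfig",
    "DifferenceSpectrum",
    "BandStatistics",
    "difference",
    "band_statistics",
    "correlate",
    "subtract_solute",
    "moving_average",
]


@dataclass(frozen=True)
class BandConfig:
    """Frequency windows (Hz) for the band statistics."""

    low: tuple[float, float] = (0.3e9, 3e9)
    high: tuple[float, float] = (3e9, 6.5e9)
    background: tuple[float, float] = (4e9, 5e9)
    peak_real: tuple[float, float] = (6.5e9, 7.5e9)
    peak_imag: tuple[float, float] = (7.5e9, 8.5e9)


@dataclass
class DifferenceSpectrum:
    """Difference of two complex-permittivity spectra with propagated
    per-point uncertainties (None when the inputs carry none)."""

    grid: FrequencyGrid
    d_real: np.ndarray
    d_imag: np.ndarray
    sigma_real: np.ndarray | None = None
    sigma_imag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.grid)
        self.d_real = np.asarray(self.d_real, dtype=float)
        self.d_imag = np.asarray(self.d_imag, dtype=float)
        for name in ("d_real", "d_imag"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must match the grid length")


@dataclass(frozen=True)
class BandStatistics:
    """Band means and background-subtracted peak height of one part
    (real or imaginary) of a difference spectrum."""

    l_mean: float
    h_mean: float
    p_height: float
    p_mean: float  # frequency-averaged background-subtracted signal over the peak window
    part: str


def _combine_sigma(a: np.ndarray | None, b: np.ndarray | None) -> np.ndarray | None:
    if a is None or b is None:
        return None
    return np.sqrt(np.asarray(a) ** 2 + np.asarray(b) ** 2)


def difference(
    a: ComplexPermittivitySpectrum, b: ComplexPermittivitySpectrum
) -> DifferenceSpectrum:
    """Pointwise difference ``a - b`` with quadrature-propagated sigma."""
    if a.grid != b.grid:
        raise ValueError("spectra must share a common frequency grid")
    return DifferenceSpectrum(
        grid=a.grid,
        d_real=a.eps_real - b.eps_real,
        d_imag=a.eps_imag - b.eps_imag,
        sigma_real=_combine_sigma(a.sigma_real, b.sigma_real),
        sigma_imag=_combine_sigma(a.sigma_imag, b.sigma_imag),
    )


def _window_mask(grid: FrequencyGrid, band: tuple[float, float]) -> np.ndarray:
    m = (grid.frequencies >= band[0]) & (grid.frequencies <= band[1])
    if not np.any(m):
        raise ValueError(f"grid has no points in band {band}")
    return m


def band_statistics(
    d: DifferenceSpectrum, part: str, bands: BandConfig = BandConfig()
) -> BandStatistics:
    """L/H band means and background-subtracted peak statistics.

    ``part`` selects the real or imaginary difference.  The peak height is
    the maximum inside the part-specific peak window minus the mean over the
    background window; ``p_mean`` is the window-averaged background-
    subtracted signal (the frequency-averaged P used for correlations).
    """
    if part == "real":
        y = d.d_real
        peak_band = bands.peak_real
    elif part in ("imag", "imaginary"):
        y = d.d_imag
        peak_band = bands.peak_imag
    else:
        raise ValueError("part must be 'real' or 'imaginary'")

    l_mean = float(np.mean(y[_window_mask(d.grid, bands.low)]))
    h_mean = float(np.mean(y[_window_mask(d.grid, bands.high)]))
    bg = float(np.mean(y[_window_mask(d.grid, bands.background)]))
    w = y[_window_mask(d.grid, peak_band)]
    return BandStatistics(
        l_mean=l_mean,
        h_mean=h_mean,
        p_height=float(np.max(w) - bg),
        p_mean=float(np.mean(w) - bg),
        part="real" if part == "real" else "imaginary",
    )


def correlate(points: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation and least-squares line for (response, predictor)
    pairs, e.g. frequency-averaged P against the L band mean.

    Parameters
    ----------
    points:
        Array-like of shape (n, 2): column 0 the response (P-bar), column 1
        the predictor.  Requires n >= 3 and non-degenerate variance.

    Returns
    -------
    (R, slope, intercept) of the response regressed on the predictor.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (response, predictor)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    y, x = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlate input")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def subtract_solute(
    raw: ComplexPermittivitySpectrum,
    solute_ref: ComplexPermittivitySpectrum,
    water_fraction: float,
) -> ComplexPermittivitySpectrum:
    """Remove the solute's reference spectrum and rescale to the water part:
    ``(raw - solute_ref) / water_fraction`` with sigma scaled by
    ``1/water_fraction`` (the reference is treated as exact)."""
    if not 0 < water_fraction <= 1:
        raise ValueError("water_fraction must be in (0, 1]")
    if raw.grid != solute_ref.grid:
        raise ValueError("spectra must share a common frequency grid")
    scale = 1.0 / water_fraction
    return ComplexPermittivitySpectrum(
        grid=raw.grid,
        eps_real=(raw.eps_real - solute_ref.eps_real) * scale,
        eps_imag=(raw.eps_imag - solute_ref.eps_imag) * scale,
        sigma_real=None if raw.sigma_real is None else raw.sigma_real * scale,
        sigma_imag=None if raw.sigma_imag is None else raw.sigma_imag * scale,
    )


def moving_average(series: np.ndarray, window: int = 11) -> np.ndarray:
    """Centred moving average with edge truncation (the window shrinks near
    the edges instead of padding).  ``window`` must be odd and >= 1."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    y = np.asarray(series, dtype=float)
    if window == 1:
        return y.copy()
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts
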