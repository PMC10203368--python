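"""Open/Short/Standard (OSM) coaxial-probe calibration.

An open-ended coaxial probe maps the permittivity ``eps`` of the liquid at
its aperture to a measured reflection coefficient ``S11`` through a bilinear
(Moebius) transformation.  Three reference measurements pin the map down:

* Open  — probe in air, ``eps = 1``,
* Short — ideally reflecting termination, the ``eps -> inf`` limit,
* Standard — a load of known permittivity ``eps_a*``.

Any measured ``S_m`` is then converted per frequency with the cross-ratio
formula::

    eps_m* = [eps_a* (S_m - S_o)(S_s - S_a) + (S_m - S_a)(S_o - S_s)]
             / [(S_m - S_s)(S_o - S_a)]

which inverts *any* bilinear probe map exactly — no probe model is assumed.
``forward_reflection`` provides the exact inverse map (fixed by the same
three anchors) used for synthesis and round-trip testing.

In time-lapse mode the Standard is the same specimen measured at a reference
time with its permittivity assigned from a known relaxation model, so that
later measurements of the same sample are expressed relative to it; this
cancels slowly varying systematics of the probe and cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hydrodr.models import ComplexPermittivitySpectrum, FrequencyGrid

__all__ = [
    "ReflectionRecord",
    "CalibrationSet",
    "CalibrationDegeneracyError",
    "calibrate_osm",
    "forward_reflection",
]

#: Anchor pairs closer than this (absolute, in the S plane) are degenerate.
DEGENERACY_TOL = 1e-9

#: Passivity headroom on |S11|.
PASSIVITY_TOL = 1e-6


class CalibrationDegeneracyError(ValueError):
    """Raised when two calibration anchors coincide at some frequency."""


@dataclass
class ReflectionRecord:
    """Complex reflection coefficient S11 per frequency.

    ``validate_passive=True`` enforces |S11| <= 1 + 1e-6 (passive load);
    synthetic or transformed records may disable the check.
    """

    grid: FrequencyGrid
    s11: np.ndarray
    validate_passive: bool = True
    timestamp_min: float | None = None  # time-lapse metadata, minutes

    def __post_init__(self) -> None:
        self.s11 = np.asarray(self.s11, dtype=complex)
        if self.s11.shape != (len(self.grid),):
            raise ValueError("s11 must have the same length as the grid")
        if self.validate_passive and np.any(np.abs(self.s11) > 1.0 + PASSIVITY_TOL):
            worst = float(np.max(np.abs(self.s11)))
            raise ValueError(f"|S11| exceeds passivity bound: max |S11| = {worst:.6g}")


@dataclass
class CalibrationSet:
    """The three anchor records plus the Standard's known permittivity.

    All records must share one frequency grid and the three anchor values
    must be pairwise separated by more than ``DEGENERACY_TOL`` at every
    frequency.
    """

    open_rec: ReflectionRecord
    short_rec: ReflectionRecord
    standard_rec: ReflectionRecord
    standard_eps: ComplexPermittivitySpectrum

    def __post_init__(self) -> None:
        g = self.open_rec.grid
        for rec in (self.short_rec, self.standard_rec):
            if rec.grid != g:
                raise ValueError("calibration records must share a common frequency grid")
        if self.standard_eps.grid != g:
            raise ValueError("standard permittivity must be on the calibration grid")
        so, ss, sa = self.open_rec.s11, self.short_rec.s11, self.standard_rec.s11
        for name, d in (
            ("open/short", so - ss),
            ("open/standard", so - sa),
            ("short/standard", ss - sa),
        ):
            bad = np.abs(d) <= DEGENERACY_TOL
            if np.any(bad):
                f = g.frequencies[np.argmax(bad)]
                raise CalibrationDegeneracyError(
                    f"degenerate {name} anchors at {f:.6g} Hz"
                )

    @property
    def grid(self) -> FrequencyGrid:
        return self.open_rec.grid


def calibrate_osm(
    cal: CalibrationSet, measured: ReflectionRecord
) -> ComplexPermittivitySpectrum:
    """Convert a measured reflection record to complex permittivity.

    Points where ``S_m`` falls within the degeneracy tolerance of the Short
    anchor (the ``eps -> inf`` pole of the map) are returned as NaN rather
    than as divergent values.
    """
    if measured.grid != cal.grid:
        raise ValueError("measured record must be on the calibration grid")
    so, ss, sa = cal.open_rec.s11, cal.short_rec.s11, cal.standard_rec.s11
    sm = measured.s11
    ea = cal.standard_eps.values

    num = ea * (sm - so) * (ss - sa) + (sm - sa) * (so - ss)
    den = (sm - ss) * (so - sa)
    invalid = np.abs(sm - ss) <= DEGENERACY_TOL
    eps = np.empty_like(num)
    eps[~invalid] = num[~invalid] / den[~invalid]
    eps[invalid] = np.nan + 1j * np.nan
    return ComplexPermittivitySpectrum.from_complex(cal.grid, eps)


def forward_reflection(
    eps: ComplexPermittivitySpectrum, cal: CalibrationSet
) -> ReflectionRecord:
    """Exact inverse of :func:`calibrate_osm`: the Moebius map fixed by the
    anchors ``eps=1 -> S_o``, ``eps->inf -> S_s``, ``eps=eps_a -> S_a``.

    Solving the calibration formula for ``S_m`` gives a closed form linear
    in ``S_m``; the round trip ``calibrate_osm(forward_reflection(e)) == e``
    holds to machine precision for non-degenerate anchors.
    """
    if eps.grid != cal.grid:
        raise ValueError("permittivity must be on the calibration grid")
    so, ss, sa = cal.open_rec.s11, cal.short_rec.s11, cal.standard_rec.s11
    ea = cal.standard_eps.values
    e = eps.values

    # e*(Sm-Ss)(So-Sa) = ea*(Sm-So)(Ss-Sa) + (Sm-Sa)(So-Ss)
    # => Sm * [e(So-Sa) - ea(Ss-Sa) - (So-Ss)]
    #      = e*Ss*(So-Sa) - ea*So*(Ss-Sa) - Sa*(So-Ss)
    coef = e * (so - sa) - ea * (ss - sa) - (so - ss)
    rhs = e * ss * (so - sa) - ea * so * (ss - sa) - sa * (so - ss)
    sm = rhs / coef
    return ReflectionRecord(cal.grid, sm, validate_passive=False)
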