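# hydrodr

Time-lapse dielectric relaxation analysis of protein hydration, with a
synthetic measurement generator that emulates the full experiment.

## The problem

When a dehydrated globular protein such as hen lysozyme is dissolved in
water, its hydration shell keeps reorganizing for hours: water population
slowly shifts between the fast, weakly bonded component and the slower,
more hydrogen-bonded hydration-water component.  Intense 0.1 THz
irradiation can accelerate this reorganization nonthermally.  Detecting the
effect requires resolving permittivity changes well below 0.1 in a sample
that is simultaneously being heated by the radiation — a combination of
time-lapse microwave dielectric relaxation (DR) spectroscopy, THz
time-domain spectroscopy (THz-TDS) and methyl-resolved NMR.

`hydrodr` implements the complete analysis chain for such experiments, and
a generator of synthetic datasets with the same statistical structure so
that every stage can be validated end-to-end.

## The model

The complex permittivity of an aqueous protein solution is a sum of Debye
dispersions plus an apparent high-frequency limit:

    eps*(w) = eps(inf)_relax + sum_x  d_eps_x / (1 + j w tau_x),
    x in {beta, delta1, delta2, gamma1, gamma2}

with the protein tumbling term (beta, ~10 MHz), two hydration-water terms
(delta1, delta2; ~0.1 and ~4 GHz), and slow/fast bulk-water terms (gamma1,
gamma2).  Rather than fitting all five dispersions, the analysis isolates
the dominant slow-water term gamma1, whose Nyquist locus (eps'' against
eps') is a semicircle centred on the real axis:

    center = (eps_g1(s) + eps_g1(inf)) / 2,   radius r = (eps_g1(s) - eps_g1(inf)) / 2

A closed-form least-squares circle fit (Kåsa form, centre constrained to
the real axis) yields the effective limits eps_g1(s), eps_g1(inf) and,
through the inscribed-angle identity w·tau = eps''/(eps' - eps_g1(inf)),
the relaxation frequency f_c.

Two further statistics carry the time-lapse information:

* **Delta r** — the radial deviation of each measured point from the fitted
  semicircle (positive inward).  A thin sample cell supports a quarter-wave
  standing wave (lambda proportional to 1/sqrt(eps)); small permittivity
  decreases detune it and produce a sharp localized Delta-r excursion,
  whose baseline-subtracted peak height **P_dr** resolves permittivity
  changes far below the per-point noise.
* **Difference-spectrum band statistics** — means of the spectral
  difference over the 0.3–3 GHz (L) and 3–6.5 GHz (H) bands plus the peak
  height near 7–8 GHz against a 4–5 GHz background, with uncertainties
  propagated in quadrature.

Raw reflection coefficients are converted to permittivity with the
Open/Short/Standard calibration, which inverts any bilinear probe map
exactly per frequency:

    eps_m* = [eps_a* (S_m - S_o)(S_s - S_a) + (S_m - S_a)(S_o - S_s)]
             / [(S_m - S_s)(S_o - S_a)]

In time-lapse mode the Standard is the same specimen at the reference time
with its permittivity assigned from the fitted single-Debye model, which
cancels slowly varying systematics of the probe and cell.

The NMR side enumerates the 61 AILMTV methyl reporters of lysozyme,
normalizes peak intensities by the 1H-1D integral, correlates pathway
profiles (intensity ratios against the reference condition) and flags
residues whose ratio deviates from 1 by more than one standard deviation.

## Worked example

```python
from hydrodr.models import FrequencyGrid, single_debye
from hydrodr.nyquist import fit_semicircle, relaxation_frequency

grid = FrequencyGrid.log_spaced(0.1e9, 14e9, 201)
spec = single_debye(68.59, 5.28, 5.88e-11, grid)   # 9.1 wt% lysozyme standard
fit = fit_semicircle(spec)
print(f"eps_g1(s) = {fit.eps_gamma1_s:.2f}, eps_g1(inf) = {fit.eps_gamma1_inf:.2f}")
print(f"f_c_gamma1 = {relaxation_frequency(spec, fit) / 1e9:.3f} GHz")
```

    eps_g1(s) = 68.59, eps_g1(inf) = 5.28
    f_c_gamma1 = 2.707 GHz

The circle fit recovers the static and high-frequency limits of the
slow-water dispersion exactly, and the relaxation frequency 2.707 GHz is
1/(2 pi tau) for tau = 58.8 ps.  A full synthetic experiment — four
temperature/irradiation conditions, five replicates, five time points —
runs through the same pipeline:

```python
from hydrodr.synthetic import TimelapseConfig, simulate_timelapse
from hydrodr.pipeline import peak_timecourse, difference_statistics

ds = simulate_timelapse(TimelapseConfig(conditions=("GC", "THz", "HTC")), seed=1)
print(peak_timecourse(ds).pivot(index="time_min", columns="condition", values="height").round(3))
for cond in ("GC", "THz", "HTC"):
    st = difference_statistics(ds, cond, t_late=60.0, part="imaginary")
    print(f"{cond}: d_eps''(0.3-3 GHz) = {st.l_mean:+.4f}")
```

    condition     GC    HTC    THz
    time_min
    18.0       0.000  0.000  0.000
    28.0       0.008  0.232  0.182
    40.0       0.010  0.087  0.068
    50.0       0.011  0.013  0.012
    60.0       0.009  0.006 -0.005

    GC: d_eps''(0.3-3 GHz) = +0.0042
    THz: d_eps''(0.3-3 GHz) = +0.0191
    HTC: d_eps''(0.3-3 GHz) = +0.0062

P_dr spikes during the perturbation (t = 28 min) in proportion to the
temperature excursion and relaxes afterwards; the post-exposure change
(t = 60 minus t = 28) is less negative for the irradiated condition
(-0.187) than for the heated control (-0.226), reflecting the accelerated
hydration shift that irradiation leaves behind.  The same shift appears as
a positive imaginary-part gain in the 0.3–3 GHz band of the THz
difference spectrum, three times the control level.

A command-line interface exposes the pipeline stages
(`hydrodr simulate | calibrate | analyze-relaxation | analyze-deltar |
diffspec | thz-subtract | nmr | dosimetry`); `hydrodr dosimetry` prints the
irradiation field strength (0.15 kV/m), energy density (1.48 uJ/m^3) and
penetration depth (120.5 um) for the default 160 W/m^2 exposure.

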