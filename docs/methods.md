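# Methods

This note documents the models, numerical choices and known limitations of
`hydrodr`, in the order the data flow through the pipeline.

## Relaxation models

Spectra are sums of pure Debye terms `d_eps / (1 + j w tau)` over the five
dispersions of an aqueous protein solution (beta, delta1, delta2, gamma1,
gamma2) plus an apparent high-frequency limit `eps(inf)_relax` that lumps
all vibrational strengths above the measured band with the true
high-frequency limit.  No stretched-exponent (Cole-Cole/Cole-Davidson)
shapes are supported: the analysis below deliberately avoids multi-
dispersion fitting, and pure Debye terms are all it requires.  The sign
convention is `eps* = eps' - j eps''` with the loss stored positive.
Frequencies are stored in Hz everywhere; CSV and Touchstone serializations
are Hz-normalized to avoid unit drift between modules.

The fast-water loss curve is implemented as the standard real Debye loss
`d_eps * w tau / (1 + w^2 tau^2)`; this is the only form that is a real,
non-negative loss curve.

## Probe calibration

The Open/Short/Standard conversion treats the probe as an unknown bilinear
(Moebius) map from permittivity to reflection coefficient and inverts it
per frequency through the cross-ratio formula.  This is exact for *any*
bilinear map — the round-trip property `calibrate(forward(eps)) = eps` holds
to 1e-10 relative over random anchor sets, and the result is invariant
under a common Moebius transformation of all four S-parameters.  Anchor
pairs closer than 1e-9 (absolute, S-plane) are rejected as degenerate;
measured points within that tolerance of the Short anchor (the pole of the
map) are returned as NaN rather than as divergent permittivities.  No
smoothing across frequency is applied at this stage.

Time-lapse mode uses the same specimen at the reference time as the
Standard, with its permittivity assigned from the fitted single-Debye
slow-water model.  This makes the recovered spectrum at the reference time
exactly the assigned model and expresses later spectra relative to it,
cancelling probe and cell systematics that vary on timescales longer than
the experiment.

## Semicircle analysis

The slow-water circle fit minimizes the algebraic (Kåsa) residual with the
centre ordinate constrained to zero: writing `x^2 + y^2 = 2 a x + c`, the
problem is linear in `(a, c)` and solved in closed form; `r = sqrt(c + a^2)`.
The fit is deterministic, exact on noiseless Debye data, and needs no
iterative refinement.  At least 3 in-band points with positive loss are
required; degenerate loci raise.  The default fit band is the measured
0.1–14 GHz range, configurable up to 40 GHz.

The relaxation frequency uses the inscribed-angle identity of the Debye
circle, `w tau = eps'' / (eps' - eps_g1(inf))` per point, with `tau`
estimated by through-origin least squares of those per-point values against
`w` over all usable points (rather than from a single point or the vertex);
this estimator is unbiased under zero-mean vertical noise, which the test
suite verifies by Monte-Carlo.

`Delta r` is the radial deviation `r - |(eps', eps'') - (center, 0)|`,
positive for points displaced inward, so a permittivity decrease raises the
peak.  The peak statistic `P_dr` is the argmax of Delta r inside the search
band (default 6–10 GHz; ties broken toward lower frequency), minus a
baseline defined as the mean of Delta r over 1-GHz flanking windows on both
sides with the peak's half-height support excluded — exclusion keeps the
height stable when the peak has wide shoulders.  The temporal peak course
is read from the moving-averaged (11-point) Delta-r of the replicate-mean
spectrum, mirroring the five-measurement averaging of the protocol.

## Cell model and dosimetry

The 1-D slab model computes the input reflection of the
probe | sample | backing stack,

    G_in = (G1 + G2 e^{-2 gamma l}) / (1 + G1 G2 e^{-2 gamma l}),
    gamma = j 2 pi f sqrt(eps*) / c,

with interface reflections from wave-impedance mismatches, converts it to
the permittivity of the equivalent homogeneous half-space, and maps that
through the probe's forward Moebius map.  It reduces exactly to the plain
forward map for a matched backing and satisfies `|G_in| <= 1` for passive
media.  The PDMS backing is treated as lossless and non-dispersive
(eps = 2.68, a typical literature value).

The slab model alone, however, cannot produce a sharp in-band anomaly: at
1 mm thickness the quarter-wave condition of an aqueous sample falls near
17 GHz and water loss limits any 1-D interference to Q < 1.  The observed
sharp excursion arises from the confined probe-aperture field, which the
normal-incidence stack does not capture.  The cell model therefore carries
a single weakly coupled resonant mode with centre frequency

    f_r = c / (4 n l_path),   n = Re sqrt(eps*(f_ref)),

a complex Lorentzian lineshape (Q = 10), fractional amplitude 0.1 scaled by
the sample/backing reflection magnitude (so it vanishes for a matched
backing), and effective path l_path = 2.34 mm — longer than the 1.0 mm
geometric layer because the fringing field travels obliquely, and chosen to
place the anomaly at 7–8 GHz for an aqueous lysozyme solution at room
temperature.  Because f_r is tied to `1/sqrt(eps)`, a uniform permittivity
decrease shifts the excursion to higher frequency, which the tests verify
through the full calibrate-fit-Delta-r chain.

Dosimetry closed forms: field strength `E = sqrt(P_s / (c eps0 sqrt(eps')))`,
energy density `U = P_s sqrt(eps') / c`, penetration depth `1/alpha`.
Defaults are the irradiation conditions: 160 W/m^2 (from 16 mW/cm^2),
eps' = 7.7 at 0.1 THz, alpha = 83 1/cm, 0.8 us pulses at 10 kHz.  The duty
cycle is exposed but unused: dosimetry works with average power.
Constants: c = 299 792 458 m/s, eps0 = 8.8541878128e-12 F/m.

## Difference spectra

Differences propagate per-point uncertainties in quadrature.  Band means
are unweighted over grid points inside closed intervals L = [0.3, 3] GHz,
H = [3, 6.5] GHz, background = [4, 5] GHz.  Peak heights take the maximum
inside 6.5–7.5 GHz (real part) or 7.5–8.5 GHz (imaginary part) minus the
background mean; the frequency-averaged P used in correlations is the
window mean of the background-subtracted signal.  The THz-TDS solute
subtraction computes `(raw - solute_ref) / water_fraction` (default
fraction 0.714 for the 28.6 wt% scenario) with the reference treated as
exact.  The moving average is centred with edge truncation, default window
11 points.

## NMR methyl analysis

Methyl multiplicities are A=1, I=2, L=2, M=1, T=1, V=2; the bundled mature
hen-lysozyme sequence (129 aa) yields 61 reporters, of which 4 are marked
overlap-excluded in the synthetic fixture (the excluded identities are
configuration — real datasets specify their own), leaving 57 analysed.
Intensities are normalized per sample by the 1H-1D integral, which removes
concentration differences exactly.  Pathway correlations are Pearson
coefficients of `(ratio - 1)` vectors over the common methyl set —
numerically identical to correlating raw ratios, chosen for readability.
Responsive residues satisfy `|ratio - 1| > SD`, with SD the sample standard
deviation (n-1 denominator) of the analysed ratios, computed per pathway.
Flag sets are invariant to global intensity rescaling.

## Synthetic data generator

The generator produces every input the pipeline consumes, under the study
conditions: four conditions (GC constant 24 °C; THz +4 °C during a 10-min
irradiation; HTC +6 °C; LTC −4 °C, all recovering to 24 °C twenty minutes
after the perturbation), five replicates, measurements at 18, 28, 40, 50
and 60 min on 201 log-spaced points over 0.1–14 GHz.

*Water*: single-Debye with the Malmberg–Maryott static permittivity
(78.3 at 25 °C, about −0.36/K) and an Arrhenius relaxation time anchored at
8.27 ps / 25 °C with 18 kJ/mol activation energy.

*Solutions*: the gamma1 term is anchored to the printed semicircle limits
(68.59/5.28 at 9.1 wt%, 76.55/5.49 at 2.9 wt%, tau = 58.8 ps at 24 °C),
linearly inter-/extrapolated in concentration, with strength and time
scaled with temperature like pure water's.  The beta/delta strengths are
not published in the main text; the defaults — beta (4, 16 ns), delta1
(3, 1.6 ns), delta2 (2, 40 ps), gamma2 (1.5, 0.265 ps) at 9.1 wt%, solute
terms scaling linearly with concentration — are synthetic choices
consistent with the quoted relaxation-frequency ranges, and configurable.

*Hydration kinetics*: a fraction `f` of a transferable strength pool moves
from the fast-water gamma2 band into the hydration delta2 band, conserving
the static permittivity.  `f` relaxes first-order toward equilibrium at
k = 0.002/min (natural equilibration over many hours), multiplied by
kappa = 30 during irradiation, so a 10-min exposure advances hydration
further than four hours of unperturbed equilibration.  The pool default is
0.2 permittivity units at 9.1 wt%, which puts the imaginary-part gain of
the post-irradiation difference spectra in the 0.3–3 GHz band at the
few-0.01 level — clearly above the five-replicate noise, as in the
reported difference spectra.  With these defaults the post-exposure P_dr
change is strictly less negative for the irradiated condition than for the
heated control; the generator does not reproduce a literal post-exposure
*rise* of P_dr, which would require a hydration effect on the standing wave
larger than the thermal one.

*Measurement*: the probe is a capacitive bilinear map
`S = (1 - j w Z0 C0 eps) / (1 + j w Z0 C0 eps)` with C0 = 0.05 pF (chosen
to balance conversion sensitivity across the band); Open is the probe in
air, Short is the exact `eps -> inf` limit, and the Standard is the
replicate's own first time point.  Additive circular complex Gaussian noise
(sigma = 1e-3 per quadrature) models the VNA floor; anchors are noiseless,
as calibration references are heavily averaged in practice.  A single seed
expands into fixed per-condition/per-replicate substreams
(`default_rng([seed, condition_index, replicate_index])`), making datasets
bit-reproducible.

*NMR tables*: a latent per-methyl displacement `d` moves the GC pathway
between 3 h and 24 h; irradiation advances `a·d` (a = 0.8) within 3 h and
heating moves `-b·d` (b = 0.5), planting the positive THz-3h/GC-24h and
negative THz-3h/HTC-3h correlations; independent components decorrelate
the 24-h THz and HTC samples.  Lognormal measurement noise and
concentration spreads are folded into the raw intensities and 1H-1D
integrals.

*THz-TDS*: imaginary-part spectra on 0.3–2.5 THz from the gamma1+gamma2
water tail plus a smooth synthetic stand-in for the dehydrated-protein
vibrational spectrum; the irradiated mixture carries a reduced gamma2
strength so the control-minus-irradiated difference is a gamma2-shaped
loss peaking at 0.60 THz.  Four replicates with additive noise provide the
SD estimates.

## What the synthetic data do and do not show

Passing tests demonstrate that the analysis is exact on its model class
(bilinear probes, Debye dispersions, the planted cavity artifact) and
statistically well-behaved at the study's noise level and replication.
They do not validate the 1-D cell model against the real three-dimensional
probe-cell electromagnetics, the single-mode artifact against the true
multimode standing-wave structure, temperature gradients inside the
sample, or any real NMR lineshape effects — the generator's methyl
displacements are a geometric encoding of pathway correlations, not a
physical model of side-chain dynamics.

## Problem sizes

The default test and acceptance runs use 201-point spectra, five
replicates, 100-seed repetitions for the statistical properties, and
500-repeat Monte-Carlo checks for estimator bias; the full suite completes
in well under a minute on one CPU.
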