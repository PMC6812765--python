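# Methods

This note records the models, parameter choices and numerical
conventions behind `evnanoarray`, and what the synthetic benchmarks do
and do not establish about real scans.

## Adsorption geometry

A vesicle of suspension diameter D tethered with aspect ratio
AR ∈ (0, 1] is modelled as an oblate ellipsoid with footprint diameter
d and apex height h:

    d = D · AR^(−1/3),   h = D · AR^(2/3),   so   D³ = d²h   exactly.

The volume π d²h / 6 of the full ellipsoid equals the sphere volume
π D³ / 6 (no volume change on adsorption). Only this full-ellipsoid
volume convention makes the deformability law AR = D³ · d⁻³ hold, which
is what the through-origin least-squares fit of AR on x = d⁻³ assumes;
the rendered topography is nonetheless the upper dome
z(r) = h·√(1 − (2r/d)²), since the lower half is against the substrate.
The inverse estimator D = (d²h)^(1/3) is the algebraic round trip of the
generator and is tested to 1e-9 relative.

The model ignores membrane mechanics entirely: no bending energy, no
contact-angle physics, no tether deformation. It is a bookkeeping ansatz
connecting the three measurable lengths, not a simulation.

## Synthetic scenes

The generator emulates the study conditions of a nanopatterned
tethering chip:

- **Lattice.** Square lattice of brush spots, default spot diameter
  200 nm, default pitch 1414.2 nm — the value that reproduces the
  chip-level density of 5.0 × 10⁵ spots/mm² via density = (10⁶/pitch)².
  Pitch is a free parameter; dense test scenes use 400 nm so a few
  hundred spots fit in a small rendered field. Per-spot brush height is
  drawn uniformly from [2, 3] nm (per spot, not per pixel).
- **Vesicles.** One EV per occupied spot by default (individual
  immobilization is the platform's premise; multi-occupancy is a config
  option). D and AR are drawn independently. Cell-line presets:
  Sk-Br-3 D ~ N(27.7, 4.7) nm, AR ~ N(0.20, 0.04); HEK293
  D ~ N(25.0, 2.6) nm, AR ~ N(0.18, 0.04); AR truncated to (0, 1].
  The AR spread 0.04 is an assumption — only group means and the
  0.15–0.30 range are known for the real populations.
- **Lipoprotein-like particles.** Footprints 10–18 nm, AR uniform in
  [0.3, 0.6], placed uniformly on an annulus at spot radius ± 20 nm
  (the rim placement is qualitative; the exact radial law is unknown).
- **Scan artifacts.** Background plane tilt (nm/nm), one Gaussian offset
  per scan row, i.i.d. Gaussian pixel noise (default σ = 0.3 nm), and
  optional tip broadening: grayscale dilation of the physical surface by
  a spherical-cap structuring element of the tip radius. Dilation is
  applied to the surface *before* tilt/offsets/noise are added (the
  physically meaningful order; at the tiny tilts used the difference
  from dilating afterwards is negligible). Pixel default 5 nm.

What the scenes do **not** emulate: tip–sample elastic deformation,
feedback artifacts (parachuting, overshoot), thermal drift, coupled
D–AR statistics, vesicle shapes other than the ellipsoidal dome, and
spot-diameter dispersion. Passing recovery tests therefore shows the
measurement chain is unbiased for ideal dome-shaped particles under
realistic noise — not that every instrument artifact is handled.

## Leveling

Plane leveling fits a polynomial background (order 1 by default, 2 for
bow) by least squares on background pixels only, excluding pixels more
than 3 robust σ (MAD × 1.4826) above the current fit, two refit passes;
the background median is re-zeroed. If the mask falls below 10% of
pixels the fit falls back to all pixels with a warning. Scan-row
leveling subtracts each row's background median. Heights are then
referenced to the bare substrate (z = 0), with brush tops at their
physical 2–3 nm. Leveling preserves particle heights: on noise-free
scenes the apex-minus-background of a rendered dome moves by < 0.05 nm.

## Detection and measurement

The detection operator (the instrument software's operator being
unknown, this one is the package's own, chosen to be testable against
the generator):

1. Light Gaussian smoothing, σ = 0.5 px.
2. Background estimate: grey opening with a flat disk of radius
   60 nm — above the largest vesicle footprint radius (~43 nm), below
   the brush-spot radius — computed on a more strongly smoothed copy
   (σ = 2 px) to suppress the opening's noise-minimum bias, then
   dilated by a small disk so the eroded/blurred brush-disc rims are
   pushed back past the true edge. The top-hat (map − background,
   clipped at 0) contains the domes measured from their local base and
   essentially nothing else.
3. Seeds: regional maxima of the top-hat with prominence ≥ the seed
   threshold (h-maxima transform). The threshold defaults to
   max(1.0 nm, 3σ_noise); at σ = 0.3 nm this yields ≤ 1 false seed per
   256² pixels of pure noise.
4. Footprints: connected region above the fractional contour f·h_seed
   (f = 0.1) around each seed; pixels contested between seeds go to the
   nearest seed; regions under 4 px are dropped.

Measurement happens on the smoothed *leveled* map, never on the
top-hat: the local baseline is the median on a 2-px annulus around the
footprint (on a spot this is the brush top, so h excludes the 2–3 nm
brush — consistent with the 7-nm EV floor being a membrane-only height;
a `baseline="substrate"` switch references z = 0 instead). h is the
footprint maximum above baseline; major/minor axes come from the
footprint mask's second central moments, corrected by 1/√(1 − f²)
(≈ 0.5%, exact for the ellipsoidal dome at contour f); d is their mean.
Regions whose annulus would leave the map are flagged border-touching
and excluded from population statistics. No tip deconvolution is
attempted; tip broadening exists only as a generator option, and
measured d is monotone in tip radius while h is unchanged.

Recovery under the defaults (200 domes, d 35–85 nm, AR 0.15–0.30,
σ = 0.3 nm, 5-nm pixels): population-mean d, h and D within 5% of
truth, every per-particle footprint within 2 px.

## Classification and its censoring effect

EV: d > 30 nm and h > 7 nm, both strict. Lipoprotein-like: d < 20 nm
and AR ∈ [0.3, 0.6] (inclusive; the published "about 0.3–0.6" is
resolved to its endpoints, configurable). Rules are evaluated in that
order; everything else is unclassified. The classes partition the
detections, and growing d and h never demotes an EV.

One consequence worth knowing: at the tethered-population size presets
(D ≈ 25–28 nm) the EV height floor sits inside the h distribution
(h = D·AR^(2/3) ≈ 8 nm at the HEK293 means), so the class filter
censors the low-AR tail and attenuates between-population AR
differences. The end-to-end discrimination test and the comparison
example therefore draw D comfortably above the floor (≈ 28–42 nm) so
the AR populations pass uncensored; with the presets themselves the
0.02 AR gap shrinks to ≈ 0.01 and needs several hundred vesicles per
group for reliable significance. Real analyses hitting this regime
should treat mean-AR comparisons as size-conditional.

## Population statistics

Summaries are arithmetic means with sample (n−1) standard deviations
over EV-class, non-border particles. The t-test is the pooled-variance
two-sample Student's t, df = n_a + n_b − 2, two-sided p from the t
distribution, α = 0.05; degenerate zero-variance inputs return t = 0,
p = 1 (equal means) or p = 0 with a warning (unequal). The capture
model is dimensionless — captured iff c_drag·v·D² ≤ F_resist, critical
diameter D\* = √(F/(c·v)) — and only its scaling laws (drag ∝ D²,
D\* ∝ v^(−1/2), truncation of the captured population from above) are
contractual.

Reports serialize with sorted keys and 4-significant-digit floats, so
regeneration from identical inputs is byte-identical; absent sections
are null, never missing.

## Numerical conventions and degenerate inputs

All lengths in nm; row-major grids, origin top-left,
x = column·pixel size. Randomness flows from a single integer seed
through `numpy.random.default_rng`; truth tables and pre-noise fields
are bit-identical across runs with equal seeds. Distribution truncation
uses rejection sampling with a bounded retry budget (error on
persistent rejection). Empty detection lists are results, not errors;
empty populations, zero-spot layouts and sub-2 samples raise
`ValueError`. ASCII map I/O is lossless at ≥ 6 significant digits;
float-TIFF at float32 precision with a JSON sidecar carrying the pixel
size.

Test problem sizes — scenes of 200–450 spots at pitch 400 nm,
1200–2300² px, two seeds for the end-to-end comparison — were chosen so
the whole suite completes in about a minute while keeping ≥ 150
vesicles per compared population.
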