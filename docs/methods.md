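# Methods

This note records the models implemented by `slicepasef`, their
assumptions, the defaults that matter, and the numerical choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The precursor ion cloud and its synthetic generator

A *cloud* is a set of precursor ions, each with m/z, charge z, reduced ion
mobility 1/K0 (V·s/cm²), abundance, and a Gaussian LC elution profile
(apex, FWHM). The generator emulates the structure of a tryptic
whole-proteome digest on a timsTOF-class instrument:

- **Charges** are drawn from `charge_probs` (default 1+: 0.15, 2+: 0.55,
  3+: 0.25, 4+: 0.05).
- **Masses** are per-charge log-normal (median neutral masses 900, 1300,
  2100, 2800 Da for z = 1–4), converted to m/z with a proton mass of
  1.00728 Da and rejection-sampled into `mz_range` (default 400–1000).
- **Mobility** follows a per-charge linear trend 1/K0 = a_z + b_z · m/z
  plus Gaussian scatter (`im_scatter_sd`, default 0.026), clipped to
  `im_range` (default 0.6–1.45). Defaults:
  z=1: (0.650, 9.5e-4), z=2: (0.400, 8.5e-4), z=3: (0.332, 8.5e-4),
  z=4: (0.300, 7.8e-4). The charge-1 band sits at higher 1/K0 than the
  multiply charged bands at every m/z, so envelope-based designs over
  z ≥ 2 exclude singly charged ions by geometry rather than by a code
  path.
- **Intensities** are log-normal (median 10⁴, σ = 1.2 in log units);
  **apexes** are uniform over the gradient (default 300 s, i.e. a
  5-minute separation) with a common FWHM (default 2 s, typical of fast
  analytical-flow chromatography).
- **Fragments**: each precursor gets 3–10 fragment ions at uniform m/z
  within the MS2 scan range (default 200–1700) with flat-Dirichlet
  relative intensities (summing to 1). The matching engine needs
  positions and intensities, not fragmentation chemistry.

The trend coefficients and scatter are a generator choice; they were fixed
once so that the defining geometric statistic of such ion maps holds: among
charge 2–3 ions within 0.01-wide 1/K0 bins spanning 0.85–1.15, the mean
interquartile m/z range is ≈ 70 Th. At equal mobility the 2+ and 3+ bands
sit ~80 Th apart (equal slopes, offset intercepts) and each contributes
~30 Th of within-band spread (0.026 / 8.5e-4), which the tests confirm
combines to the target. A fixed seed reproduces a cloud bit for bit.

What the generator does **not** emulate: peptide sequences and in-silico
digestion, CCS physics, isotope envelopes, correlated fragment patterns,
intensity-dependent mobility, retention-time structure beyond uniform
apexes. Passing tests therefore demonstrate the correctness of the scheme
arithmetic, geometry and matching logic under realistic *global* structure,
not identification performance on real spectra.

## Scheme model

`Subcycle → Frame → SliceStep`: a slice step pairs a 1/K0 interval with a
Q1 window; an MS2 frame is an ordered set of steps with pairwise-disjoint
mobility intervals plus a fill time and a repeat count; subcycles
optionally open with an MS1 survey frame. All intervals are **half-open**
[lo, hi) in both axes so abutting steps never double-isolate a point and
point-in-scheme queries are deterministic.

Method tables are plain-text CSV, one row per step, header
`#MS Type,Cycle Id,Start IM,End IM,Start Mass,End Mass,CE` with `MS Type ∈
{MS1, PASEF}`, MS1 rows carrying the full ranges with cycle id 0, PASEF
frames numbered from 1 in acquisition order, CE blank when unset, floats at
4 decimals. The 7-column row table cannot express per-frame fill times,
repeat counts or subcycle membership, so the writer prefixes optional
`##`-metadata lines carrying them; a file without metadata still parses
(fill 100 ms, repeats 1, subcycles split at MS1 rows). Parsing is separate
from validation: geometrically invalid rows parse, and `validate_scheme`
reports them (inverted intervals, overlapping mobility intervals, steps
outside bounds, windows below the 2 Th instrument minimum).

## Designer

**1F**: the targeted 1/K0 range is split into `n_im_steps` (default 20)
equal contiguous slices. Each slice's Q1 window spans the empirical
[q_lo, q_hi] m/z quantiles of charge ≥ 2 ions in the slice, padded by
`pad_mz` (5 Th) per side and widened symmetrically to at least
`min_width_mz` (50 Th). Defaults q_lo = 0.005, q_hi = 0.995 were chosen so
that a default design isolates ≥ 99% of the multiply charged intensity in
the targeted region — with Gaussian-like per-slice tails, 1%-quantiles plus
a 5 Th pad fall just short of that coverage contract, 0.5%-quantiles meet
it with margin. Empty slices inherit linearly interpolated windows from
their nearest populated neighbours (quasi-continuous slicing must not leave
holes). Quantiles are lower-interpolation order statistics (value at
ceil(q·n), 1-based): simple and exactly checkable against a sort.

**2F/4F**: each step's 1F window is cut into 2 or 4 contiguous segments;
frame j takes segment j across all steps, so the per-step union of the
frames equals the 1F window exactly. Boundaries sit at equal-width
midpoints or, in `balanced` mode, at per-step intensity-weighted quantiles
of the isolated ions (balancing signal between frames). With
`shift_subcycles`, a second subcycle offsets every interior boundary by
half a segment (clamped to the window edges) and the cycle alternates the
two variants — the simplest overlapping-window schedule; richer schedules
would extend the same mechanism.

**dia-PASEF reference**: n_frames × windows_per_frame fixed-width windows
tile the m/z range (an exact-tiling precondition; violations report the
width that would tile). Window rank i (ascending m/z) occupies mobility
stratum i of equally many, and frame j collects ranks ≡ j (mod n_frames).
Any consistent diagonal interleave gives the same evaluator figures; this
round-robin one keeps each frame's strata maximally separated.

**CE ramp**: piecewise-linear in 1/K0, clamped outside the anchors;
defaults 20 eV at 1/K0 = 0.60 rising to 59 eV at 1.60, applied at each
step's mobility midpoint.

**Frame repeats**: the largest r ≥ 1 with
fwhm / ((ms1 + r·ms2) · frame_time) ≥ min_points (default 3 points per
peak at FWHM), falling back to 1 with a warning when even a single
acquisition breaks the floor.

## Evaluator

Per-precursor MS/MS duty cycle = (Σ fill·repeats over MS2 frames isolating
the point) / (Σ fill·repeats over all MS2 frames in the cycle). **MS1
frames are excluded from both numerator and denominator**: this is what
makes the 1F figure exactly 100% and the 8-frame reference exactly 12.5%
whether or not survey scans are present. Cycle time, by contrast, counts
every frame including MS1 and repeats. Scheme-level duty and coverage are
intensity-weighted over charge ≥ 2 ions (ion-count-weighted values are
reported alongside); points per peak = peak FWHM / cycle time. Frame
overhead defaults to 0 ms — instrument overhead (visible in published
cycle-time estimates for many-window methods) is deliberately not modelled.

## Acquisition simulator

Cycles tile the RT window (whole cycles only). In each MS2 frame every
isolated precursor contributes one peak per fragment with

intensity = precursor intensity × run factor × g(t) × rel_intensity ×
(fill / 100 ms),

annotated with the isolating step's Q1 boundaries. g(t) is the Gaussian
elution factor at the frame's midpoint; the 100 ms reference encodes
accumulation-time proportionality, the premise of the duty-cycle
arithmetic. Elution factors below 1e-12 emit no peak.

Noise model:

- `intensity_cv` is a **per-precursor, per-run** multiplicative log-normal
  factor (mean 1), i.e. run-level technical variation. Independent
  per-peak intensity noise would average out across the dozens of cycles
  summed into a quantity, so a per-peak interpretation could never
  reproduce an injected replicate CV; the run-level reading propagates 1:1
  into quantities and is what replicate benchmarks measure.
- m/z jitter is Gaussian in ppm (default 3), mobility jitter Gaussian
  (default 0.005) — both well inside the default matching tolerances.
- `noise_peaks_per_frame` junk peaks get a random step's boundaries and a
  low log-normal intensity.
- The optional quadrupole-switch loss model (off by default) attenuates
  the first 10% of each step that follows a *discontinuous* Q1 jump
  (windows that do not touch) by 50%. Sliced frames shift the window
  continuously and are unaffected; classical dia-PASEF frames take the
  hit. The magnitude of the real effect is qualitative in the literature;
  these defaults are placeholders and documented as such.

Peaks are ideal centroids; no TOF resolution, saturation or profile shapes.

## Matcher and quantification

A frame is a *candidate* for a precursor iff it contains ≥ 1 peak whose Q1
boundaries contain the precursor m/z and whose 1/K0 is within `im_tol` of
the precursor's; only boundary-matching peaks are considered downstream.
Defaults: 15 ppm m/z tolerance at both MS levels, `im_tol` 0.05 (the m/z
value follows fixed-mass-accuracy practice for this data type; the mobility
tolerance is a package choice, config-exposed).

Fragment intensity per subcycle = the maximum intensity among matching
peaks over the subcycle's frames; ties go to the lowest frame index so
reprocessing is deterministic. Repeat merging combines peaks with identical
boundaries and m/z / mobility within tolerance — intensity **summed**
(repeats accumulate ions; summing is what raises signal-to-noise under
additive noise), coordinates intensity-weighted — conserving total
intensity exactly; clustering is greedy along sorted m/z within
identical-boundary groups.

The XIC is the per-cycle sum over fragments (and over subcycles within a
cycle) of these best-peak intensities. The default quantity is the **summed
per-cycle signal** of the trace — total collected ion signal. A
time-integrated area (trapezoid over the contiguous region above half the
apex) is also computed, but it normalises away sampling density: two
schemes acquiring the same peak at 100 ms and 800 ms cycles have equal
areas, while the signal a mass spectrometer actually accumulates — and the
quantity whose between-scheme ratio equals the duty-cycle ratio — scales
with the number of cycles. The summed quantity keeps the
duty-ratio-vs-simulation oracle exact; the area variant remains available
via `quantify(xic, method="area_fwhm")`. Measured points-per-peak is the
count of cycles at or above half the apex.

CV = standard deviation (n−1 denominator) of untransformed quantities
divided by their mean, reported only for n ≥ 3 by default (smaller n is
computed but flagged suppressed); a zero mean yields NaN with a flag.

Out of scope by design: FDR machinery, spectral-library scoring, 2D peak
picking (merging operates on already-centroided simulated peaks), RT
alignment, match-between-runs, and multiplexed channels.

## Problem sizes and numerical choices

The default cloud is 50,000 ions; simulation-backed tests use an
8,000-ion cloud from which ~40 jointly covered precursors are carried
through 16–24 s RT windows — large enough for stable medians, small enough
that the whole suite runs in well under a minute. Determinism: every
stochastic stage takes a single integer seed (`numpy.random.default_rng`);
the CLI derives stage seeds from one master seed. Method tables round-trip
at 4-decimal precision (5e-5 worst-case rounding error per field). Interval
membership is half-open everywhere; degenerate inputs (empty clouds, empty
bins, all-zero traces, unattainable points-per-peak floors) return flagged
values or warnings rather than raising, except where a contract is violated
(MS1 frames queried for isolation, mismatched merge positions, RT windows
shorter than one cycle).

## Known limitations

- The generator's trend coefficients are plausible but not fitted to any
  real ion-map export; real clouds also show charge-dependent scatter and
  curvature the linear model omits.
- The simulator's linear fill-time scaling ignores trap capacity and
  space-charge effects, so duty-cycle gains translate to signal gains
  without saturation.
- The switch-loss magnitude is arbitrary (documented above).
- Real method-editor dialects differ between instrument-control versions;
  the method-table format here is frozen by this repository's tests, and
  interchange with a specific editor would need reconciliation against its
  exported files.
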