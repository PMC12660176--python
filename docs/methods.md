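# Methods

This note documents the models, estimators, defaults and numerical choices
behind `quantalmap`, and what the synthetic-data tests do and do not show
about real recordings.

## Coordinate and unit conventions

Positions are physical (µm) from the field origin; x runs along columns,
y along rows. Pixel `(i, j)` spans `[j, j+1) × [i, i+1)` pixels with its
center at `(j+0.5, i+0.5)` px; detectors and renderers share this
convention, so centroids agree to sub-pixel accuracy. The default pixel
size is 0.133 µm/px (a typical 60×/EMCCD configuration) and is configurable
everywhere. All distance thresholds are compared in µm. Stimulus times map
to frames as `floor(t_stim × frame_rate)`; at 8 Hz imaging with 1 Hz
stimulation no ties can occur.

Randomness: every public simulation call takes one integer seed, expanded
through `numpy.random.SeedSequence` children in a documented order
(geometry, Pr, spontaneous rates, miscellaneous; movies additionally spawn
one child per AZ). Identical inputs and seed give bit-identical output.

## The synthetic NMJ

`make_geometry` places boutons as disks chained along the terminal axis
(bouton 0 = terminal) and AZs inside each bouton by dart-throwing with a
1.0 µm spacing floor, matching the micron-scale nearest-neighbour distances
of larval NMJ AZs. Each AZ is opposed by a PSD jittered by σ = 0.05 µm;
an optional orphan fraction adds unopposed PSDs. Per-AZ parameters:

- **Pr** from a named distribution — `constant`, `uniform`, `beta`, or
  `age_linear` (Pr = intercept + slope·age + noise, clipped to [0, 1]), the
  last modelling maturation.
- **Spontaneous rate** (events/min ≥ 0) from a named distribution.
- **Age** (days, 0–6, the span of larval development) with per-bouton means
  encoding the growth mode: `stretching` (new boutons intercalate, terminal
  bouton oldest) or `budding` (new boutons bud from the end, terminal
  youngest).
- **Cac occupancy**: a configurable fraction of AZs (default 10%, the
  observed share of spontaneous-only sites) lacks Ca²⁺ channels; these are
  forced to Pr = 0 but keep a positive spontaneous rate (floor 0.1/min),
  modelling immature sites that support spontaneous fusion only.

Puncta stacks render each synapse as a 2D Gaussian (PSF σ = 0.2 µm,
diffraction-limited confocal) at an integer focal plane with a Gaussian
axial profile (σ = 1 plane), over a uniform background (10) with additive
Gaussian noise (SD 5 against default spot peaks of ~100). Spot peak
amplitude is proportional to a per-synapse value (age for the old-receptor
channel, Cac occupancy for the Cac channel, unity otherwise), so
background-subtracted integrated intensities are linear in the requested
quantity.

Quantal movies: at each stimulus frame every AZ flashes independently with
probability Pr (Bernoulli); spontaneous flashes are per-AZ Poisson counts
at `rate × duration` placed uniformly on non-stimulus frames. A flash is an
additive 2D Gaussian (σ = 0.3 µm — broader than the PSF because the
reporter fills the postsynaptic membrane) with single-frame rise and
geometric decay (ratio 0.4 over 3 frames). Defaults — flash amplitude 60,
noise SD 10, background 100 — were chosen once so that detection is
non-trivially hard (peak ≈ 6 noise SD before smoothing) but solvable; the
true event log is returned alongside the movie.

Photoconversion series: at t = 0 the entire green pool converts to red
(red(0) = pre-conversion green; green restarts at 0), red decays as
`2^(−t/T½)`, green accumulates linearly at `delivery_rate` units/day.
Per-synapse abundances are lognormal (σ = 0.3). The series is longitudinal:
the same geometry, abundances and focal planes are imaged at every
timepoint, as in repeated imaging of one NMJ.

### What the generator does not emulate

No photobleaching beyond turnover decay, no muscle-contraction motion (such
sessions are discarded in practice), no z-drift, no 3D PSF, no detector
shot-noise statistics (noise is Gaussian, not Poisson-Gaussian). Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to motion or bleaching artefacts.

## Event detection and Pr mapping

Per-pixel ΔF is the movie minus a causal rolling 20th-percentile baseline
(window 16 frames; the first window is reused for the initial frames),
computed in column slabs to bound memory. Because a low-percentile baseline
sits below the noise median, ΔF is re-centered on its global median before
thresholding. Frames are smoothed with a Gaussian (σ = 1 px); the noise
scale is the robust MAD-based SD of smoothed ΔF and the detection threshold
is 4 × that. Per-frame local maxima above threshold (minimum peak distance
0.4 µm, image borders excluded because incomplete smoothing support
inflates noise there) become candidate events, with two temporal rules:

- **persistence** — the peak pixel must stay above half threshold in the
  next frame. GCaMP transients outlast one frame at 8 Hz; single-frame
  spikes are noise. Without this rule a 4σ threshold yields hundreds of
  false events per 5-minute movie, swamping spontaneous-rate estimates.
- **refractory** — peaks within 0.5 µm of an event in the previous 2 frames
  are the decay of that event, not a new one.

Events are assigned to the nearest ROI center within 0.8 µm (exact ties to
the lower ROI id; a KD-tree is used, and tests verify exact agreement with
an all-pairs scan). ROIs are equal-sized circles (default radius 0.5 µm),
taken from detected AZ puncta or a user CSV.

Classification uses the coincidence rule: frames with ≥ 3 simultaneous
events across the NMJ are evoked (nerve stimulation fires many AZs at
once); all their events are evoked, everything else is spontaneous, except
that events in the frame immediately after an evoked frame within 0.5 µm of
an evoked event are attributed to decay and excluded from both tallies.
Note the rule needs a large AZ population: with only ~10 ROIs in view, most
stimulus frames contain fewer than 3 events and evoked release is
under-called. Per ROI, `Pr = evoked count / stimulations` (capped at 1 with
a flag if the count exceeds the stimulation count, which indicates double
counting) and `spontaneous rate = count / minutes`; unassigned and
decay-attributed events are reported in a summary, never silently dropped.

## Puncta analysis

Stacks are max-projected; puncta are 8-connected components above a
threshold, filtered at 4 px minimum area. The default threshold is the
plane median + 3 robust (MAD-based) SDs: with puncta sparse, median and MAD
are dominated by background, giving a reproducible analogue of an
operator-set level. (A background sample restricted to the dimmest pixel
quartile was rejected: truncation biases both its mean and SD low, placing
the threshold ~1.5 noise SDs above background and promoting noise clumps to
puncta.) Centroids are intensity-weighted; areas are in µm².

Colocalization deficits report the percentage of channel-A puncta with no
channel-B punctum within a cutoff (and the reverse); an empty query set
yields NaN, never 0%. AZ–PSD opposition uses greedy mutual-nearest pairing
within 0.8 µm (shortest distance first, ties to the smaller id), keeping
unpaired entries; for well-separated synapses this equals optimal matching,
which the tests verify by exhaustive assignment. Densities are counts per
10 µm² of NMJ area (e.g. from a loose membrane-channel mask).

## Age classification and turnover

PSD masks are detected on the summed red+green projection so both channels
are measured over identical masks, with per-channel background (median
outside masks) subtracted. A PSD is *old* iff its red sum exceeds a
threshold — by default a per-PSD integrated detection floor of 3 × red
noise SD × √area, an operational version of "any detectable old-receptor
signal". Red sums are normalized per NMJ (brightest PSD = 1.0) before
pooling, making the age score invariant to channel gain. Classification is
monotone in the threshold by construction.

Turnover measurements integrate puncta signal on the plane-sum projection
(linear, hence unbiased for ratios) over masks detected on the max
projection and dilated by 2 px to capture sub-threshold Gaussian tails. For
a longitudinal series the t₀ masks are reused at t₁ so the captured flux
fraction is identical at both timepoints and the remaining fraction
`100 × S₁/S₀` is unbiased. Half-life models:

- `exponential` (default): `T½ = dt·ln2 / ln(S₀/S₁)` — first-order decay.
- `rate`: `T½ = dt·ln2 / (fraction lost per dt)` — the convention behind
  commonly reported single-interval pulse-chase half-lives (e.g. 27.1% loss
  per day ⇒ 2.56 d); it approximates the exponential form for small losses.
- `linear`: straight-line extrapolation to 50%.

Remaining must lie strictly between 0 and 100%; anything else is an error
("no decay"), not a number. Ca²⁺-influx comparisons report the percent
increase of mean per-AZ sums, test vs control; the acceptance script uses a
paired design (same geometry and abundances, uniformly scaled) mirroring
within-animal comparisons.

## Problem sizes and test design

The simulation-based checks use 50-AZ NMJs (5 boutons × 10 AZs) with
5-minute movies at 8 Hz — the scale at which the coincidence rule is
reliable — and 72-synapse NMJs in cohorts of three for pulse-chase
recovery, where the remaining-fraction estimator has ≈1% noise and
half-life recovery lands within 10% even at a 4-day half-life (sensitivity
to the measured ratio grows sharply as the remaining fraction approaches
100%). Property tests (assignment vs exhaustive scan, colocalization vs
all-pairs, max projection vs loops) are seeded or derandomized.

## Known limitations

- The coincidence rule conflates stimulus timing with event multiplicity;
  at low AZ counts or very low Pr it under-calls evoked release. Stimulus
  timestamps, where available, would be strictly more powerful; the rule is
  retained because it matches the established acquisition workflow.
- Spontaneous rates are mildly inflated by residual false positives near
  threshold; evoked Pr is essentially immune since false positives rarely
  coincide with evoked frames at an assigned ROI.
- Detection assumes a stationary field; there is no motion or drift
  correction. Positional stability should be verified upstream (sessions
  with drift > 1 px discarded rather than corrected).
- Two-timepoint half-life estimation cannot distinguish first-order decay
  from other monotone decay laws; the model choice is explicit.
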