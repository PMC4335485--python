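# Methods

This note documents the model, the estimation choices, and the synthetic
ground-truth generator implemented in `prfmap`, together with their
numerical details and limitations.

## Stimulus model

All stimuli are represented as binary aperture masks on a square pixel
grid covering the circular display (`CarrierConfig`: maximum
eccentricity, pixels per degree; x increases rightward, y upward, origin
at fixation).  The underlying carrier is a counterphase-flickering
pattern

```
I(x, y) = sqrt(x^2 + y^2) * cos{ 2*pi*(sin(d)*pi*x/180 + cos(d)*pi*y/180)^4 + theta }
```

with `d(theta) = sin(theta)/4 + 1/2`, rectified to a binary texture,
bounded by the display disc with a linear-contrast fringe
(`edge_band_px` pixels wide).  `theta` steps from 0 to 4*pi in 72 steps
of 32 ms, giving a pattern cycle of 1.15 s.  The model never sees the
carrier: only the aperture masks enter the forward model, so the carrier
exists for completeness of the stimulus description.

Conditions (TR = 2.55 s):

- **Bars** (`bar_sequence`): one run = two trials of a 24-volume sweep
  along the given direction, a 24-volume sweep along the orthogonal
  direction, and 24 blank volumes (144 volumes, 48 blank).  The second
  trial reverses the sweep sign.  *Size-invariant* bars are 2.70 degrees
  wide at the 16-degree display.  *Eccentricity-scaled* ("log") bars
  follow `width(c) = max(e_min, |c| * kappa)` with
  `kappa = ln(max_ecc / e_min) / 24`, one logarithmic step per volume
  from the foveal minimum `e_min` to the display edge.
- **Wedge and ring** (`wedge_ring_sequence`): simultaneous 18-degree
  rotating wedge (20 volumes per revolution, 6 cycles) and
  expanding/contracting ring stepping through 15 log-spaced annuli per
  cycle with 50% overlap in the log domain (8 cycles), 120 stimulation
  volumes plus 24 terminal blanks.  The paired run reverses both
  directions.
- **Photic bursts** (`photic_sequence`): ten trials of one full-field
  volume followed by eleven blanks (120 volumes), used for HRF
  estimation.
- **Session** (`session_schedule`): 4 invariant-bar runs, 4 log-bar
  runs, 2 wedge-ring runs; 1440 volumes.

Display scaling: all geometry is stated at the 16-degree display and
multiplied by `max_ecc / 16`, including the foveal log minimum
(0.06 degrees at 16), so a 9-degree display is an exact 9/16 similarity
of the 16-degree one at matched pixel counts.

## Forward model

A vertex's population receptive field is an isotropic 2D Gaussian
`(x0, y0, sigma, beta)` with unit peak.  The neural response per volume
is the sum of Gaussian weights inside the binary aperture; the BOLD
prediction is that series convolved (causally, truncated to the run
length, never across run borders) with a double-gamma HRF and scaled by
`beta`.  The HRF kernel is

```
h(t) = g(t; response_delay) - g(t; undershoot_delay) / ratio
```

where `g(.; d)` is a unit-scale gamma density with shape `d + 1`, so
each component's mode sits exactly at its named delay; the kernel is
normalized to unit peak.  Defaults: response delay 6 s, undershoot delay
16 s, ratio 6, sampled at TR.

A difference-of-Gaussians variant (`neural_prediction_dog`,
`make_dog_truth`) subtracts `surround_amp` times a broader surround
Gaussian (`surround_ratio` times the center sigma) from the neural
response.  It is used only as a ground-truth generator to probe bias of
the plain-Gaussian fit; `surround_amp * surround_ratio^2 < 1` is
enforced so the surround weakens rather than inverts responses.

## HRF estimation

The photic-burst run is reduced to one averaged epoch: the top decile of
vertices by spectral power at the trial frequency is pooled, the pooled
series is cut into 12-volume epochs, and per time-point values more than
1.5 SD from the across-trial mean are rejected before averaging.  A
four-parameter least-squares fit (two delays, ratio, nuisance amplitude)
by Nelder-Mead recovers the double-gamma parameters.  Noiseless
recovery is exact from distant starts; at realistic noise the response
delay is well determined while the undershoot delay is weakly
identified (the objective changes by ~0.1% of the epoch peak per second
of undershoot delay), so its estimate should be treated as descriptive.

## pRF fitting

Two stages:

1. **Coarse** (`coarse_fit`): exhaustive Pearson-correlation search over
   HRF-convolved predictions for a lattice of candidate centers
   (2.4-degree steps within the stimulated field) crossed with 34
   exponentially spaced sigma levels from 0.32 to 32 degrees.
   Candidates are ordered by (sigma, center radius) ascending so an
   argmax tie resolves to the smallest, most foveal candidate.  The
   coarse stage sees data smoothed 8.3 mm FWHM along the cortical sheet
   (geodesic Gaussian weights, per-vertex normalized).  Vertices with
   non-positive best correlation or squared correlation at or below
   0.05 are excluded.
2. **Fine** (`fine_fit`): Nelder-Mead over `(x0, y0, sigma, beta)` on
   the unsmoothed series, started from the coarse winner with beta
   initialized by least-squares projection; `sigma <= 0` is repelled
   with an infinite objective; tolerances 1e-4, at most 1600
   evaluations.  Goodness of fit is `1 - SS_res / SS_tot`; downstream
   analyses threshold at 0.1.

## Phase-encoded analysis

Wedge-ring runs are analyzed by the traveling-wave method: after
removing the terminal blanks and a linear trend, the DFT coefficient at
6 cycles/run (wedge) and 8 cycles/run (ring) is extracted per vertex.
Hemodynamic lag cancels by negating the reversed-direction phases and
circularly averaging the two runs.  Phase decodes linearly to polar
angle (clockwise from the positive x-axis in the reference run) and
log-linearly to eccentricity, `e = e_min * (max_ecc / e_min)^u` with `u`
the cycle fraction.

## Cross-validation and summaries

pRF tables trained on one condition predict held-out series through the
known apertures of another; per-vertex Pearson correlations are Fisher
z-transformed, averaged within ROIs, and compared between training
conditions by paired t-tests over the pairing unit.  Further summaries:
sigma-vs-eccentricity curves in 1-degree bins (SEM across subjects when
available), OLS slopes and their paired comparison, the mean-luminance
truncation control (`truncate_blanks`, dropping earlier blank segments
first), and a normalized-eccentricity comparison of model-based against
phase-encoded estimates.

## Synthetic ground truth

`make_sheet` builds a flattened cortical patch: vertices split across
ROIs (defaults V1/V2/V3 with `sigma = 0.5 + 0.25*ecc`, `0.7 + 0.35*ecc`,
`0.9 + 0.45*ecc`), eccentricity log-spaced along one sheet axis
(emulating cortical magnification) and polar angle uniform along the
other, with a small seeded jitter so pRF centers are not grid-aligned.
ROI blocks are stitched edge-to-edge into one connected graph of edge
lengths in millimetres.  `simulate_bold` convolves every ground-truth
neural response with the HRF per run and adds AR(1) Gaussian noise whose
standard deviation is the per-vertex peak prediction divided by the
contrast-to-noise ratio (defaults CNR 3, lag-1 correlation 0.2);
`cnr = inf` disables noise.

The generator emulates the large-scale retinotopic organization the
estimation stages rely on.  It does **not** model cortical folding,
draining veins, physiological noise spectra, eye movements, attention,
or receptive-field shapes beyond the isotropic Gaussian /
difference-of-Gaussians families.

## Numerical choices

- Grid predictions are built in chunks (~2e7 elements) as
  (candidates x pixels) @ (pixels x volumes) products; convolution uses
  FFT along the time axis with causal truncation per run segment.
- Surface smoothing uses Dijkstra shortest paths truncated at 3 SD.
- Correlations in the coarse stage are computed as standardized inner
  products; zero-variance rows are flagged and excluded rather than
  propagated as NaN.
- Phase combination uses resultant-vector (circular) means; Fisher z
  clips |r| at 1 - 1e-7 and flags clipped vertices.

## Limitations

- Aperture masks sample bar edges at pixel resolution; at 2 pixels per
  degree the narrowest foveal steps of eccentricity-scaled bars fall
  below one pixel, so analyses of that regime should use a finer grid.
- The undershoot delay of the HRF is weakly identified from a single
  10-trial photic run (see above).
- The coarse stage's correlation objective is scale-free; amplitude
  (beta) is only estimated in the fine stage.
- Simulated noise is stationary AR(1); real fMRI noise is not.
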