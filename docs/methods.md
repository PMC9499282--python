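# Methods

## Stimuli

Dynamic random-dot stereograms follow the study design they emulate:
9-arcmin square dots, bright 27.0 and dark 0 cd/m² on a 13.5 cd/m²
background, equal numbers of each polarity covering 25% of each region's
area, repositioned independently on every frame at 60 Hz. Two
configurations are provided: a disc target of radius 2.3° inside a
zero-disparity annulus (outer radius 3.4°), and a horizontal depth edge
between a 3.40° × 2.33° target rectangle above the midline and an
identical reference below. Stimuli are placed at eccentricities of
0–12.7° along the horizontal (rightward) or vertical (downward)
meridian. Disparity is signed with crossed (near) positive and applied
symmetrically, ±d/2 per eye, keeping the cyclopean position fixed; the
split is configurable. Anticorrelation flips the polarity of every
target dot in one eye (right by default).

Choices the design leaves open, fixed here: the 25% coverage is enforced
per region; the dot count is `round(coverage·area/dot_size²)` lowered to
the nearest even number so polarities balance exactly (worst-case
coverage error 1.5 dot-areas; ~0.2% for the actual regions); dots may
overlap, later dots overwriting earlier ones in generation order
(reference first, then target); dots displaced out of their region are
still drawn and no gap-filling dots are added. Rasterisation snaps
continuous dot centres to the nearest pixel at 1.9 arcmin/pixel
(configurable) and draws un-antialiased axis-aligned squares. Durations
map to frames by rounding duration × 60 Hz (80 ms → 5, 700 ms → 42).
The full canvas is fixation-centred and sized to the stimulus at its
eccentricity plus one stimulus diameter; model analyses render only a
window around the filters, which is equivalent and much cheaper.

## First-order energy model

Receptive fields are isotropic Gaussians (SD σ) times a carrier at
frequency f; the default σ is half a carrier period, the carrier is
vertical, and quadrature pairs use phases 0 and π/2. Preferred disparity
is realised as pure position disparity, split ±d_pref/2 across the eyes.
Images are converted to Weber contrast about the background before
filtering, so a blank display gives zero response and energy is
quadratic in contrast.

Tuning curves average the energy over freshly generated frames per probe
disparity. Two evaluation paths exist and are cross-checked:

* `rerender` re-rasterises the stimulus at every probe disparity with
  per-dot pixel snapping — the display's own semantics.
* `filter_shift` (default) renders one base frame and realises the probe
  disparity as an exactly equivalent subpixel translation of the
  receptive fields (⟨w(x), I(x−δ)⟩ = ⟨w(x+δ), I(x)⟩). It requires the
  filter support to lie inside the target region (checked: at most 2% of
  receptive-field weight may fall outside) and evaluates all probes from
  one rasterisation per frame, two orders of magnitude faster.

All probe disparities and both correlations share each frame's dot
field (common random numbers). This leaves means unbiased while making
the curve *shape* far more stable, and it makes the inversion identity
exact at the frame level: anticorrelation negates the binocular
cross-term only, so per frame E_corr + E_anti = 2·(monocular terms).

## Second-order energy model

Stage one filters each eye at a fine scale (defaults 4, 8 or 16
cyc/deg, σ half a period), squares and sums quadrature outputs — a
polarity-discarding rectification. Stage two is an ordinary binocular
energy unit at a quarter of the first-stage frequency (σ again half a
period) applied to the two energy maps. The maps are mean-subtracted
within the analysis window first; energy maps are non-negative and
without demeaning their DC level swamps the disparity signal. There is
no square root or gain control between stages. Both stages are vertical,
which keeps every filter separable (Gaussian along y, carrier along x);
stage one runs as two 1-D passes and stage two as a y-collapse followed
by 1-D inner products.

Scale-averaged tuning shares every frame across scales, so the averaged
curve equals the mean of the per-scale curves exactly. Second-order
analyses default to 0.95 arcmin/pixel rendering: at the display's
1.9 arcmin pixels the 16 cyc/deg channel sits above the Nyquist
frequency (15.8 cyc/deg) and cannot be sampled faithfully.

## Decoding

A bank of position-disparity units spans −40…40 arcmin in 4-arcmin
steps, each preferred disparity represented at several carrier scales
(4/8/16 cyc/deg first-order; 8 cyc/deg first stage second-order) whose
responses are averaged. Three readouts map a population profile to a
near/far judgment:

* `template_sign` (default): Pearson-correlate the profile with the
  expected correlated-stimulus profiles at ±28 arcmin (the filters'
  scale-averaged cross-correlation, an analytic Gabor in preferred
  disparity) and take the sign of the difference. This is a
  matched-filter two-alternative readout that assumes a binocularly
  matched world — precisely why first-order ACRDS populations, whose
  profile is the *negative* of the expected one, decode reversed.
* `centroid_sign`: response-weighted mean preferred disparity, weights
  taken above the population floor. Kept for comparison; because energy
  tuning is band-pass (near-zero-mass modulation with strong side lobes
  on a large pedestal), its sign is unreliable — measured CRDS decoding
  at +28 arcmin is near chance under this rule, which is why it is not
  the default.
* `argmax_sign`: sign of the peak unit's preferred disparity. Robust
  for CRDS; ambiguous for ACRDS, whose inverted profile peaks on both
  flanks of the stimulus disparity.

Confidence is a threshold on |decision variable|: 0.5 on the
(dimensionless) template correlation difference, half the 28-arcmin
stimulus disparity for the arcmin-valued rules. The experiment records
confidence but implies no mechanism; this is an explicit modelling
choice. Ties, including all-zero populations, resolve by a fair coin
and are marked unconfident.

## Synthetic observer

The generative model for each non-zero-disparity trial is
P(natural) = Φ(β₀ + β₁·e) with eccentricity e in **arc minutes** — the
study's printed slopes (≈ −0.002) are only dimensionally plausible on
that scale given the 0–762 arcmin range; degrees are available by
option. Zero-disparity trials are near/far coin flips and carry no
natural/reversed code. Default (β₀, β₁) per condition are the printed
per-condition regression coefficients of the two experiments, so the
simulator doubles as a parameter-recovery harness. Confidence is drawn
with probability 0.8 after a natural-direction response and 0.3
otherwise — purely a fixture choice. Participant-level random intercepts
are off by default (the original mixed-effects structure is unstated)
but available as Gaussian jitter. The simulator reproduces the block
bookkeeping exactly: 40 repeats × 3 disparities per block, one block per
eccentricity × correlation, 10 blocks per condition.

What the generator does not emulate: response times, learning, lapses,
eye movements, and any within-block sequential structure. Passing tests
therefore validate the analysis pipeline's correctness and calibration
on probit-world data, not the behaviour of human observers.

## Analysis pipeline

Natural/reversed recoding keeps only the ±28 arcmin trials. Pooling is
probit averaging, Φ(mean Φ⁻¹(p_i)); proportions of exactly 0 or 1 are
first pulled to 1/(2n) or 1−1/(2n). Confidence limits are percentile
intervals from a parametric bootstrap (default 10000 resamples)
redrawing each participant's count from Binomial(n_i, p̂_i) — the
closest literal reading of the described procedure, resampling at the
participant level only. The probit regression is a fixed-effects GLM fit
from first principles by Fisher-scoring IRLS (convergence when the score
falls below 1e−8, at most 100 iterations; SEs from the inverse Fisher
information; separation flagged as non-converged). The original analysis
was a mixed-effects model over three participants; its random-effects
structure is unstated and is deliberately not modelled, so printed
t(13) degrees of freedom are not reproduced (the fit reports df = n−2).
No multiple-testing correction is applied. Figure-style outputs plot
proportion natural and proportion confident against eccentricity with
bootstrap limits, per condition.

## Problem sizes and numerical checks

Default tuning grids span −30…+30 arcmin in 1-arcmin steps. Library
defaults are 1000 frames per probe disparity for first-order curves and
500 for second-order; the shipped analyses and tests use 300–500 frames,
which common random numbers make ample for locating peaks to one grid
step. Statistical validation uses 20000 trials per eccentricity for
parameter recovery, 500 simulated datasets (2000 bootstrap resamples
each) for interval coverage, and 200 replicates for the zero-slope
calibration. Filter responses are validated against per-pixel
double-loop oracles on 16×16 frames at 1e−10 relative tolerance, the
IRLS fit against an independent coarse-to-fine grid maximiser of the
likelihood (1e−4) and against an external GLM implementation, and the
probit-average against a 20-digit symbolic reference. The side-lobe
scaling test uses 2-arcmin dots so the curve's periodicity reflects the
filters rather than the 9-arcmin dot profile.

## Known limitations

The package predicts pathway tendencies, not human proportions: no
contrast normalisation, orientation pooling, cue combination between
pathways, or fitting of the readout to behavioural data. The first-order
reversal under the template readout is stronger than human reversed
depth for circular stimuli, as expected for an early-stage signal that
later processing attenuates. The filter-shift tuning path treats the
reference region as outside the filter support; units whose support
genuinely straddles a region boundary must use the rerender path (the
decoder's trial evaluation always renders the true stimulus). Tuning
examples encode disparity as pure position disparity; the anticorrelated
first-order curve then has flanking maxima equidistant from the stimulus
disparity, so no single "anti-preferred disparity" is asserted.
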