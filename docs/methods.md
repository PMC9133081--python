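# Methods

This note documents the models, algorithms and design choices behind
`muecho`, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open choices were made.

## Simulated muscle and motor-unit population

The muscle cross-section is an ellipse of 598 mm² under a 1 mm skin and
2.5 mm subcutaneous layer, imaged over a 40 × 40 mm field of view at
128 × 128 px (0.3125 mm/px). The medio-lateral semi-axis defaults to 18 mm;
the depth semi-axis follows from the area. Territories are circular discs
with areas drawn from an exponential distribution (scale 10 mm²) truncated
to 5–44 mm², reproducing the strongly skewed size distribution of real MU
pools (many small, few large). Centres are sampled uniformly over the
ellipse and redrawn until the whole disc fits inside (the shrunken-ellipse
containment test is exact here because territory radii are far below the
boundary's minimal radius of curvature). Territory overlap is allowed.
Fibre counts are area × 135 fibres/mm², clipped to 150–1500; note the
nominal fibre-count range and the territory-area range are mutually
inconsistent at constant density, so the territory area (which drives the
mechanics) is taken as primary and fibre counts are clipped.

Recruitment is strictly size-ordered: a contraction level activates the `n`
smallest units, with `n` ∈ {32, 50, 74, 106, 138} for the five levels
(3/5/7/10/20 % MVC). Active sets are therefore nested across levels. Mean
discharge rates are assigned linearly in population size rank from 15 pps
(smallest, first-recruited) to 8 pps (largest), i.e. an onion-skin profile.
Inter-spike intervals are Gaussian with a 15 % coefficient of variation,
truncated below at half the mean interval; the first spike gets a uniform
random phase. With these defaults a 10 s train carries 80–150 spikes and
its empirical ISI CoV converges to 0.15 ± 0.01.

Firing-pattern quality control mirrors decomposition practice: units with
fewer than 20 firings in the analysis window or an ISI CoV above 30 % are
excluded before identification.

## Twitch model and velocity movie

Each discharge produces an axial-velocity twitch: a positive (contraction)
half-sine of 50 ms followed by a negative (relaxation) half-sine with twice
the duration and half the amplitude, so the continuous-time velocity
integrates to zero and tissue returns to rest. The lobe durations are
quantized to the frame grid (the positive lobe spans `round(0.05·fps)`
samples — 51 at 1024 fps) and the profile is normalized to peak 1; the
discrete sample sum is then zero only to O(1/fps), which is the tolerance
the tests use. The relative lobe shape is a modeling choice — only the
contraction-phase duration is well constrained (it matches the 50 ms
matching waveform); the 2:1 duration and 1:0.5 amplitude ratios follow from
the zero-displacement constraint and the observation that relaxation is
slower and weaker than contraction.

A unit's spatial gain is `(area/44 mm²)²` (quadratic area scaling,
normalized to the largest simulated territory) inside the disc, decaying
outside as `exp(−(d − r)/r)` with distance `d` from the centre — 37 % of
the centre velocity at `d = 2r`. The movie is the exactly linear
superposition of every active unit's (gain map) × (spike train ∗ twitch),
scaled so the largest unit's centre peaks at 5 mm/s; the analysis is
correlation- and centroid-based, hence scale-free. No tissue inertia,
propagation delay or out-of-plane motion is modelled, and no measurement
noise is added — passing simulation tests therefore demonstrates the
machinery under idealized interference, not robustness to experimental
noise sources (speckle decorrelation, probe motion, physiological tremor).

## Velocity estimation from RF (experimental path)

For experimental use, axial velocity is estimated from beamformed RF frames
with the 2-D autocorrelation method: the phase of the lag-one temporal
autocorrelation of the analytic signal gives the inter-frame displacement,
corrected by the running echo centre frequency estimated from the lag-one
axial autocorrelation phase. Both autocorrelations are averaged over a
10 ms sliding ensemble and a one-wavelength axial window (the axial window
length is a free parameter; one wavelength is the shortest that stabilizes
the phase). Centre-frequency estimates outside ±50 % of the nominal
carrier (envelope nulls) fall back to the carrier. Estimates beyond the
1 mm inter-frame displacement bound, or with autocorrelation phase within
5 % of ±π (aliasing), are flagged and clipped. Axial resampling onto the
0.3 mm analysis grid uses block averaging (anti-aliased), not decimation.
The simulation path bypasses this stage: movies are simulated directly at
the analysis grid.

Conditioning (both paths): per-frame 2-D median filter with a 1 × 1 mm
kernel (3 × 3 px, forced odd), then a per-pixel 5 Hz high-pass implemented
as a second-order Butterworth run forward-backward — zero phase (twitch
timing is preserved; the cross-correlation peak between input and output of
a band-limited probe sits at lag 0) with a fourth-order magnitude response.

## Sliding-ROI SVD + spatio-temporal ICA

ROIs of 38 px (12 mm) slide in 5 px (1.6 mm) steps; on a 128 px axis the
origins tile exactly 19 positions ending flush with the image edge, and on
other sizes a final origin is clamped to the edge. Each ROI movie
(1444 pixels × T frames) is centred per pixel and reduced with a randomized
truncated SVD to 50 components; singular values below 10⁻³ of the leading
one are discarded (whitening would otherwise amplify numerically null
directions into unstable ICA components — all-zero ROIs are flagged
degenerate, reduced-rank ROIs return fewer components).

The retained subspace is rotated by a single orthogonal matrix `W` found by
a symmetric fixed-point iteration (tanh contrast, symmetric decorrelation,
tolerance 1e-4, at most 200 iterations, seeded random orthogonal
initialization). The contrast gradient is the α-weighted sum of the updates
computed on the whitened temporal principal components and on the whitened
spatial basis — α = 0.5 by default weighs temporal and spatial
independence equally; α = 1 reduces exactly to temporal FastICA (verified
against scikit-learn's implementation on synthetic mixtures). Temporal
components are zero-mean, unit-variance and exactly uncorrelated; each is
paired with the spatial image that reconstructs the ROI movie, and signs
are arbitrary until matching aligns them. The iteration cap is a
pragmatic choice: convergence is typically reached in well under 100
iterations and the downstream correlation matching is insensitive to late
fine rotation; non-converged ROIs are flagged.

## Matching, segmentation, centroid, profile

The displacement train (spike indicator ∗ 50 ms positive half-sine) is
correlated with every temporal component of every ROI at lags within
±20 ms; each ROI keeps its best component/lag, with the stored peak
sign-aligned to be non-negative and the flip recorded. The 19 × 19 map is
thresholded at cc > 0.5 (absolute correlation units — strict inequality),
8-connected components are labelled, and the cluster is chosen by size with
mean correlation as tie-break (the alternative mean-first ordering is a
one-line change in `segment_map`). An empty cluster is a valid "unit not
matched" outcome.

The cluster's sign-aligned best spatial components are overlap-added on a
full-image canvas and the sum is divided by the per-pixel count of covering
cluster ROIs. Without this coverage normalization, interior pixels receive
up to 8× the weight of pixels near the cluster margin purely because of the
38 px/5 px tiling, which biases centroids toward the cluster interior by
1 px or more; the normalization removes the tiling artifact while leaving
the per-ROI component scale untouched. The unit's centroid is the
|value|-weighted mean pixel position in millimetres.

The unit's velocity profile is the spike-triggered average (window −25 to
+175 ms, covering the twitch; spikes whose window exceeds the record are
dropped, and at least 20 usable spikes are required) of the cluster-mean
sign-aligned temporal component, reported as mean ± SD per lag.

## Evaluation metrics

Localization error is the Euclidean distance between the identified
centroid and the true territory centre, in mm.

Profile fidelity deserves care. At 8–15 pps the ~150 ms twitch overlaps
neighbouring discharges, so a unit's velocity time course is never a train
of isolated twitches, and the spike-triggered average of even a *perfectly*
recovered time course contains the train's own periodic structure (the
conditional-intensity oscillation convolved with the twitch) plus the 5 Hz
high-pass response. The primary metric therefore correlates the identified
STA profile with the **reference profile**: the unit's simulated noise-free
velocity time course passed through the same high-pass and the same
spike-triggered averaging (`reference_sta_profile`). This measures what the
decomposition could at best recover; it equals 1 exactly in the clean
single-unit case. The literal zero-lag correlation against the bare twitch
is also reported per unit (`profile_cc_twitch`); it is structurally bounded
near 0.5 for fast-firing units regardless of algorithm quality.

The medio-lateral EMG↔US association uses ordinary least squares of the
identified centroid's x on the EMG amplitude-distribution centroid's x over
matched units, plus the four-coefficient multiple regression
`Y = β₁ + β₂x₁ + β₃x₂ + β₄x₁x₂` (x₁ EMG centroid, x₂ identification depth)
with 95 % confidence intervals per coefficient. The surrogate EMG model
(fibre count × exp(−3-D distance/λ), λ = 8 mm, electrodes on the skin
plane) replaces a full anisotropic volume-conductor simulation: downstream
analysis consumes only the amplitude centroid, and the surrogate preserves
the one property that matters — deeper units produce flatter surface
distributions whose centroids shrink toward the grid centre, which is what
the interaction term detects. λ is configurable; monopolar vs differential
derivations are collapsed into it.

Study summaries report per-level min/median/max and pooled medians over
*matched* units (unmatched counts reported separately), seeded
percentile-bootstrap CIs for medians, and a one-way ANOVA across levels as
a convenience.

## Study problem sizes

The packaged study configuration runs the five levels at 5 s and 512 fps on
the 128 × 128 grid (the full-scale design is 10 s at 1024 fps; the scaled
variant halves both time axes and is the size used by the test suite and
the acceptance script). Single-unit demonstrations use 2.5 s at 256 fps,
ample for a noise-free rank-one movie. At the scaled size a full five-level
run takes about five minutes on one CPU, dominated by the 5 × 361 ROI
decompositions.

## Known limitations

- Unmatched units: at the two highest contraction levels roughly half the
  active units produce no ROI cluster above cc 0.5; medians and regressions
  are over matched units.
- The scaled-down study shows a significant error increase at the 20 % MVC
  level (one-way ANOVA), i.e. interference grows faster than at full scale
  where the level effect can be absent.
- Centroids of superficial units are biased ~0.5–1 mm deeper: the
  exponential velocity tail is truncated at the image top, displacing the
  |value|-weighted centroid of even the *true* field. This is inherent to
  the centroid definition under the unmasked decay model, not an
  identification error.
- The simulator omits measurement noise, out-of-plane motion and nonlinear
  twitch summation; conclusions about real recordings require the RF path
  plus experimental validation.
- The recruitment model enforces the per-level active counts only; no
  excitation-based rate coding or force model is included.
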