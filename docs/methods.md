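# Methods

`optocorr` implements a complete analysis chain for inferring shared
synaptic input to pairs of simultaneously voltage-clamped neurons from
optogenetic activation of a presynaptic population, together with a
synthetic-data generator that supplies ground-truth test beds, and SWC
morphology analytics for the complementary anatomical overlap analysis.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not establish.

## Synaptic model

Under voltage clamp, capacitive currents vanish and voltage-gated currents
are stationary, so a recorded trace is modelled as the linear superposition
of unitary synaptic currents plus recording noise. The unitary conductance
evoked by a presynaptic spike at `tspike` is the alpha-like kernel

    g(t) = gmax * (t - tspike)/tau * exp(-(t - tspike - tau)/tau)

which peaks at exactly `gmax` one `tau` after the spike, and the clamp
current is ohmic, `i = g * (v - e)`. Defaults are `gmax = 1 µS`,
`tau = 1 ms`, `v = -70 mV`, `e = 0 mV`, giving a -70 nA unitary EPSC. These
printed parameter values imply unphysiologically large unitary currents;
because every downstream statistic is normalized (Pearson-type correlation
coefficients, amplitude-relative noise), the absolute scale is
inconsequential and the defaults are kept, with `gmax` freely configurable.
The kernel is truncated at 13 tau, where it has decayed below 1e-4 of its
peak, to bound convolution cost. Traces are sampled at 20 kHz
(`dt = 0.05 ms`). An IPSC preset flips the driving force so events are
outward, for the reverse-direction (inhibitory input) experiments.

## Synthetic circuits and stimuli

**Convergence design.** Two recorded cells each receive exactly
`inputs_per_post = 8` presynaptic partners drawn from a pool of 16; the
size of the intersection (`n_shared`, 0-8) is the ground truth the
analyses must recover. Connection weights default to 1 with optional
log-normal heterogeneity.

**Ramp stimulus and spiking.** The widefield stimulus is an 8 s linear
ramp of relative intensity 0 to 1, repeated 5 times. Each presynaptic cell
has an intensity threshold drawn log-normally (median 0.4, sigma 0.5,
folded into (0, 1]) so recruitment staggers along the ramp, and a
saturating peak rate drawn uniformly from 15-25 Hz. Above threshold the
cell fires an inhomogeneous Poisson train with rate

    r(t) = r_peak * u(t) / (u(t) + u50),   u(t) = (I(t) - theta) / (1 - theta)

with `u50 = 0.25` and an absolute refractory period of 3 ms; a per-trial
log-normal threshold jitter (sd 0.05) adds trial-to-trial latency
variability beyond the Poisson randomness. These rate parameters are
package choices (the quantity of interest — correlation structure — is
insensitive to them within a broad range) and are all exposed in
`RampNoiseParams` and the network generator.

**Focal stimulus and spiking.** The focal protocol scans a 10 x 7 grid of
sites spaced 20 µm (scanning area 180 µm x 120 µm) with 1 ms pulses at 5
sites/s, each repeat visiting every site once in a fresh pseudorandom
order, 10 repeats per intensity. A pulse can activate a presynaptic cell
when the soma lies within a hard-disc footprint (default radius 20 µm) and
the intensity clears the distance-scaled threshold `theta * (1 + d/r)`;
the activating-site count is therefore non-decreasing in intensity. An
effective pulse triggers at most one spike, with probability 0.9, at
latency `2 ms + Gamma(shape 2, mean 8 ms)`. The gamma latency shape
matters: the shift-predictor correction assumes trial-to-trial latency
variability well above the 4 ms coincidence bin, and a distribution piled
against a hard minimum would defeat it. The footprint default keeps
activation sparse — typically at most one input of a recorded cell per
pulse — matching the regime in which template matching can resolve events
and in which evoked counts land in the hundreds over a full protocol.

**What the generator does not emulate.** Opsin kinetics, light scattering,
dendritic filtering, series-resistance artifacts, synaptic depression, and
correlated (non-white) recording noise are all absent. Passing tests
therefore establish that the analysis chain recovers ground truth under
its own stated assumptions, not that those assumptions hold in any
particular recording.

## Widefield (ramp) analysis

Traces are band-pass filtered at 10-120 Hz with a second-order Butterworth
applied forward and backward (`sosfiltfilt`), so the filter contributes no
phase shift and DC is removed. Filtered traces are then FIR-decimated to
1 kHz: the pass band ends at 120 Hz, far below the decimated Nyquist of
500 Hz, so the correlation analysis is unaffected while its cost drops by
400x. Each 250 ms window (stepped by 10 ms) of both traces is
mean-subtracted and scaled to unit variance, and the Pearson-type
correlation coefficient is evaluated at lags within ±25 ms; the per-window
peak and its lag are retained, the lag refined below the sampling step by
three-point parabolic interpolation (so lag variance is not quantized to
the 1 ms analysis step). Windows with zero variance get coefficient 0 and
a flag.

Pair metrics follow as:

* `CC_peak_mean` — per-window peak coefficients averaged over the five
  trials, smoothed by a centered moving average over 5 windows (50 ms),
  maximized over the photo-stimulation interval (stimulus duration plus a
  100 ms margin);
* `CC_lag_var` — the across-trial population standard deviation of the
  peak lag per window, smoothed the same way, minimized over the interval
  and squared (ms²).

The ±25 ms lag search, the 5-window smoother and the 100 ms margin are
package choices where the procedure leaves latitude; the test suite
exercises the chain's qualitative conclusions (overlap monotonicity, null
calibration) rather than any particular choice, and all three are
configurable in `RampAnalysisConfig`.

**Null and classification.** Thresholds come from synthetic pairs
assembled from cells recorded in different sessions (1000 pairs by
default): the peak threshold is the 95th percentile of the shuffled
`CC_peak_mean` and the lag-variance threshold the 5th percentile of the
shuffled `CC_lag_var` — upper and lower tails respectively, matching the
direction of each criterion. A pair is "coordinated" iff its peak exceeds
the peak threshold and its lag variance falls below the lag-variance
threshold. A two-cluster k-means on standardized metrics (50 restarts,
fixed seed; the cluster with the higher mean peak labelled coordinated)
serves as a scale-free corroboration. Literature threshold presets are
provided for both recording directions, including both published variants
of the reverse-direction lag-variance bound (0.1 and 0.2 ms²), neither
hard-coded.

Condition comparisons (e.g. pharmacological blockade emulated by scaling
shared-connection weights) report per-pair changes in `CC_peak_mean` with
missing pairs flagged as absent, never as zero change. Distance dependence
is an ordinary least-squares line of metric on inter-soma distance with
adjusted R² and the F-test p-value, via statsmodels.

## Focal analysis

**Event detection.** Sliding optimally scaled template fit: at each offset
the template `w` is fitted to the trace segment as `scale*w + offset` and
the detection statistic is `scale / SE(scale)`; candidate events are local
maxima of the statistic above the signal-to-noise threshold 2.5 with a
2 ms minimum separation. Candidates are then confirmed in descending order
of the statistic, each accepted event's fitted template being subtracted
before the remaining candidates are re-fitted; this resolves genuinely
overlapping events while rejecting the secondary maxima that a large
event's decay otherwise seeds. The default template is a double
exponential (0.5 ms rise, 3 ms decay, 15 ms long); any waveform array can
be supplied, and the simulation pipeline passes its own unitary kernel —
the analogue of defining the template from recorded events. An optional
amplitude floor (the pipeline uses 3x a robust MAD-based noise SD)
discards the small noise-matched fluctuations that the criterion alone
admits at threshold 2.5; without it, white-noise false positives
(~10 Hz) dominate the evoked-count bookkeeping.

**Evoked events and response maps.** Detections whose latency from the
preceding pulse falls within 2-30 ms are attributed to that pulse's site;
the remainder estimate the background (spontaneous/noise) rate from the
inter-pulse epochs. A response map sums evoked amplitudes per site. The
intensity used for pair analysis is chosen by the operating-range rule:
among measured levels, prefer those whose total evoked count lies in
335-908, breaking ties toward 7x the threshold intensity (the lowest
level with any response); out-of-range data are flagged.

**Correlation probability.** Within each site, event-time differences
between the two cells' matched trials are histogrammed in 4 ms bins with
the central bin spanning 0 ± 2 ms, and correlograms are summed over sites.
The shift predictor repeats this with one cell's trial index circularly
shifted by one within each site, estimating stimulus-locked but non-shared
coincidences. Then

    Pc = (central bin - shifted central bin) / N_evoked

with `N_evoked` the smaller of the two cells' background-corrected evoked
counts, so that perfect sharing yields Pc near 1 (the summed counts are
selectable to `sum` instead). Zero evoked events make Pc undefined and it
is reported as missing with a diagnostic, never as 0. Map correlation is
the Pearson coefficient over the 70 sites, ranked against 100 within-map
permutations of both maps.

## Morphology

SWC trees are parsed with strict validation (single root, parents before
children, finite coordinates), with configurable type-code mapping.
Coordinates are µm with axis 1 dorsoventral, axis 2 mediolateral, axis 3
cortical depth; layers are parallel planes perpendicular to the depth
axis. Per-layer lengths and 5 µm voxel length densities both use exact
geometric clipping — segments are split at each plane or grid crossing and
each piece credited where its midpoint lies — so partitions conserve total
length to floating precision (the conservation tests require 1e-6 µm).
Segments lying exactly in a boundary plane belong to the layer the plane
opens.

The axo-dendritic overlap of a presynaptic axon grid and a postsynaptic
dendrite grid is the voxel-wise product of length densities summed over
voxels, normalized by its value with the somata co-located (grids must
therefore be built in soma-centred frames; translations are rounded to
whole voxels). The triplet measure for one presynaptic and two
postsynaptic cells combines the two normalized pairwise overlaps by their
geometric mean — symmetric, equal to the pairwise value when the two
agree, and 1 in the co-somatic configuration — and is set to 0 whenever
either pairwise overlap is non-positive; a zero co-somatic normalizer
makes it undefined (NaN). The geometric-mean combination is an
interpretive choice (only the zero rule is dictated by the procedure being
reproduced) and the arithmetic mean is selectable.

The synthetic tree generator grows persistent random-walk branches from a
soma with positive step lengths and soft confinement to a depth band,
returning its internally summed length for round-trip checks. It produces
plausible laminar arbors for testing the analytics; it does not model
branching statistics of real neuron classes.

## Problem sizes and runtimes

The reference checks use: 100 simulations per overlap level (five levels)
of full 8 s, 20 kHz, five-trial pair recordings for the monotonicity
curve; a 1000-pair shuffled null assembled from 20 independent simulated
recordings; a 100-pair labelled cohort and a separate 100-pair independent
cohort for classification and calibration; 20 seeds per condition for the
focal correlation-probability suite (10-repeat, 70-site protocols with
full event detection at 20 kHz); and 20 random trees for morphology
conservation. The complete reproduction script runs in roughly ten
minutes on one CPU.

## Known limitations

* The generator's spiking laws are phenomenological; rate parameters are
  stated conditions, not fits to recordings.
* The focal footprint is a hard disc with deterministic
  intensity-threshold geometry; real photoactivation falls off smoothly
  and can activate axons of passage.
* Pc is ill-conditioned when evoked counts are small relative to the
  detector's background rate; the operating-range selection rule exists
  precisely to avoid that regime, and analyses outside it should treat Pc
  with caution.
* Overlap ratios quantize placements to the 5 µm voxel grid.
* The distance-dependence fit is deliberately linear; it will not capture
  non-monotonic spatial profiles.
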