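# optocorr

Inference of **shared synaptic input** to pairs of simultaneously
voltage-clamped neurons from optogenetic activation of a presynaptic
population.

When two downstream neurons (for example parvalbumin-positive
interneurons in layer 2 of the medial entorhinal cortex) receive input
from overlapping sets of channelrhodopsin-expressing presynaptic cells
(stellate cells), asynchronous activation of the presynaptic population
produces temporally correlated synaptic currents in the pair. `optocorr`
implements the two complementary analysis chains built on this idea,
plus the simulation and anatomy tooling around them:

1. **Widefield ramp analysis.** An 8 s light ramp recruits presynaptic
   cells asynchronously, in order of their intensity thresholds. Each
   pair's band-pass-filtered (10–120 Hz) currents are cross-correlated
   in 250 ms windows stepped by 10 ms, yielding

   * `CC_peak_mean` — the maximum over windows of the smoothed,
     trial-averaged peak correlation coefficient, and
   * `CC_lag_var` — the square of the minimum over windows of the
     smoothed across-trial SD of the peak lag (ms²).

   Pairs with common input show high `CC_peak_mean` and low
   `CC_lag_var`. Thresholds come from a null of ~1000 synthetic pairs
   assembled across different recordings; a k-means grouping corroborates
   the threshold classification, and distance-dependence is summarized by
   OLS fits.

2. **Focal grid mapping.** A 1 ms laser pulse scans a 7×10 grid of sites
   spaced 20 µm (120 × 180 µm scanning area). Synaptic events are
   detected by optimally scaled template matching (signal-to-noise
   criterion 2.5, overlapping events resolved by subtractive
   confirmation) and the **correlation probability**

   `Pc = (central − shifted central) / N_evoked`

   counts coincidences of the two cells' evoked events within ±2 ms,
   corrects them with a trial-shifted predictor, and normalizes by the
   evoked event count. Per-site response maps are compared by Pearson
   correlation against within-map shuffles.

3. **Synthetic data.** Ground-truth bipartite networks with a controlled
   shared-input fraction, ramp- and grid-evoked spike trains, the alpha
   conductance kernel `g(t) = gmax·(t/τ)·e^{−(t−τ)/τ}` with ohmic clamp
   current `i = g·(v − e)` (defaults gmax = 1 µS, τ = 1 ms, v = −70 mV,
   e = 0 mV, 20 kHz sampling), and synthetic SWC morphologies — so every
   stage is testable without downloading recordings.

4. **Morphology analytics.** SWC parsing/writing, per-layer neurite
   lengths, maximal axis extents, 5 µm voxel length densities with exact
   conservation, and the co-somatically normalized axo-dendritic overlap
   ratio for one presynaptic and two postsynaptic cells.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Simulate a pair with fully shared input and a pair with disjoint input
under identical ramp conditions, and compare their metrics; then run the
focal pipeline on a fully shared pair:

```python
from optocorr import pipelines as pl, focal as fc

m8 = pl.ramp_pair_metrics(n_shared=8, seed=1)   # identical input sets
m0 = pl.ramp_pair_metrics(n_shared=0, seed=1)   # disjoint input sets
print(f"shared pair:      CC_peak_mean = {m8.cc_peak_mean:.3f}   "
      f"CC_lag_var = {m8.cc_lag_var:.4f} ms^2")
print(f"independent pair: CC_peak_mean = {m0.cc_peak_mean:.3f}   "
      f"CC_lag_var = {m0.cc_lag_var:.4f} ms^2")

ev_a, ev_b, grid, net = pl.focal_pair_events(n_shared=8, seed=1)
res = fc.correlation_probability(ev_a, ev_b, grid)
print(f"focal shared pair: Pc = {res.pc:.2f}  (central {res.central_count:.0f}, "
      f"shifted {res.shifted_central_count:.0f}, evoked {res.normalizer:.0f})")
```

prints

```
shared pair:      CC_peak_mean = 1.000   CC_lag_var = 0.0000 ms^2
independent pair: CC_peak_mean = 0.421   CC_lag_var = 31.8587 ms^2
focal shared pair: Pc = 0.76  (central 228, shifted 56, evoked 227)
```

The fully shared pair's currents are near-identical after filtering
(peak coefficient 1, lag variance 0), while the independent pair's window
peaks are low with lags jumping across the ±25 ms search range. In the
focal experiment, 228 coincidences within ±2 ms against 56 expected from
the shift predictor give a correlation probability of 0.76 — most of this
pair's evoked input is shared.

A thin CLI exposes the same chains over files
(`optocorr simulate ramp|focal|morph`, `optocorr ramp-analyze`,
`optocorr focal-analyze`, `optocorr morph lengths|extent|density|overlap`);
run `optocorr --help`.

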