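"""End-to-end experiment drivers: simulate a ground-truth circuit under a
stimulation protocol and run the matching analysis chain.

These functions define the package's reference study conditions: the
convergence design fixes eight presynaptic inputs per postsynaptic cell
while the shared-input count varies, traces run for the full 8 s ramp at
20 kHz, and five trials per pair are analysed. They are used by the CLI,
the test-suite oracles and the reproduction script alike.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import focal as fc
from . import rampcorr as rc
from .kernels import SynapticKernelParams, sampled_kernel
from .network import GroundTruthNetwork, generate_network
from .protocols import FocalGridProtocol, RampProtocol
from .spikes import (RampNoiseParams, SpikeTrainSet, generate_focal_spikes,
                     generate_ramp_spikes)
from .traces import TraceSet, simulate_postsynaptic_trace

__all__ = [
    "simulate_ramp_pair", "ramp_pair_metrics", "monotonicity_curve",
    "independent_sessions", "classification_cohort", "focal_pair_events",
    "focal_pc", "ramp_condition_pair",
]

#: presynaptic pool for the convergence design: supports any overlap of
#: two cells with eight inputs each
DEFAULT_N_PRE = 16
DEFAULT_INPUTS = 8


def _child_seed(seed: int, *tags: int) -> int:
    """Derive an independent 31-bit seed from a master seed and tags."""
    ss = np.random.SeedSequence([int(seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# widefield (ramp) experiments
# --------------------------------------------------------------------------

def simulate_ramp_pair(n_shared: int,
                       seed: int,
                       inputs_per_post: int = DEFAULT_INPUTS,
                       n_pre: int = DEFAULT_N_PRE,
                       ramp: RampProtocol = RampProtocol(),
                       params: SynapticKernelParams = SynapticKernelParams(),
                       noise_sd_na: Optional[float] = None,
                       noise_params: Optional[RampNoiseParams] = None,
                       ) -> Tuple[TraceSet, GroundTruthNetwork]:
    """Simulate one recorded pair under the ramp protocol.

    Two postsynaptic cells receive ``inputs_per_post`` presynaptic inputs
    each, ``n_shared`` of them common, from a fixed-size presynaptic pool;
    spike trains are ramp-evoked and convolved into voltage-clamp traces.
    """
    net = generate_network(n_pre=n_pre, n_post=2,
                           inputs_per_post=inputs_per_post,
                           n_shared=n_shared, seed=_child_seed(seed, 1))
    spikes = generate_ramp_spikes(net, ramp, noise_params,
                                  seed=_child_seed(seed, 2))
    traces = simulate_postsynaptic_trace(spikes, net, params=params,
                                         noise_sd_na=noise_sd_na,
                                         duration_ms=ramp.duration_ms,
                                         seed=_child_seed(seed, 3))
    return traces, net


def ramp_pair_metrics(n_shared: int, seed: int,
                      config: rc.RampAnalysisConfig = rc.RampAnalysisConfig(),
                      ramp: RampProtocol = RampProtocol(),
                      pair_id: Optional[str] = None,
                      **sim_kwargs) -> rc.PairMetrics:
    """Simulate one pair and return its (cc_peak_mean, cc_lag_var)."""
    traces, net = simulate_ramp_pair(n_shared, seed, ramp=ramp, **sim_kwargs)
    ta = traces.traces_for("post00")
    tb = traces.traces_for("post01")
    return rc.pair_metrics(
        ta, tb, config=config,
        pair_id=pair_id or f"shared{n_shared}_seed{seed}",
        stim_duration_ms=ramp.duration_ms,
        distance_um=net.pair_distance_um("post00", "post01"))


def monotonicity_curve(levels: Sequence[int] = (0, 2, 4, 6, 8),
                       n_sims: int = 100,
                       seed: int = 0,
                       config: rc.RampAnalysisConfig = rc.RampAnalysisConfig(),
                       ramp: RampProtocol = RampProtocol(),
                       ) -> pd.DataFrame:
    """Mean pair metrics as a function of the shared-input count.

    Runs ``n_sims`` seeded simulations per overlap level of the
    eight-input convergence design and averages the pair metrics; the
    diagnostic of the method is that the mean peak coefficient rises and
    the mean lag variance falls as the overlap grows.
    """
    rows = []
    for level in levels:
        peaks, lvars = [], []
        for k in range(n_sims):
            m = ramp_pair_metrics(level, _child_seed(seed, level, k),
                                  config=config, ramp=ramp)
            peaks.append(m.cc_peak_mean)
            lvars.append(m.cc_lag_var)
        rows.append({
            "n_shared": level,
            "cc_peak_mean": float(np.mean(peaks)),
            "cc_peak_sd": float(np.std(peaks)),
            "cc_lag_var": float(np.mean(lvars)),
            "cc_lag_var_sd": float(np.std(lvars)),
            "n_sims": n_sims,
        })
    return pd.DataFrame(rows)


def independent_sessions(n_recordings: int,
                         seed: int,
                         config: rc.RampAnalysisConfig = rc.RampAnalysisConfig(),
                         ramp: RampProtocol = RampProtocol(),
                         ) -> List[rc.RecordingSession]:
    """Simulate independent recordings for the shuffled-pair null.

    Each recording holds two cells with disjoint presynaptic input sets
    (an unshared pair recorded simultaneously); traces are preprocessed
    once so sessions can be recombined cheaply into shuffled pairs.
    """
    sessions = []
    for r in range(n_recordings):
        traces, _ = simulate_ramp_pair(0, _child_seed(seed, 100, r), ramp=ramp)
        pre = {cell: [rc.preprocess_trace(t, config)
                      for t in traces.traces_for(cell)]
               for cell in traces.cell_ids()}
        sessions.append(rc.RecordingSession(f"rec{r:03d}", pre))
    return sessions


def classification_cohort(n_seeds: int = 10,
                          shared_per_seed: int = 5,
                          independent_per_seed: int = 5,
                          seed: int = 0,
                          n_shared: int = DEFAULT_INPUTS,
                          config: rc.RampAnalysisConfig = rc.RampAnalysisConfig(),
                          ramp: RampProtocol = RampProtocol(),
                          ) -> pd.DataFrame:
    """Cohort of simulated pairs with known ground truth.

    Returns a metrics frame with a ``ground_truth`` column ('shared' for
    pairs with fully overlapping input, 'independent' for disjoint input).
    """
    rows = []
    for s in range(n_seeds):
        for k in range(shared_per_seed):
            m = ramp_pair_metrics(n_shared, _child_seed(seed, 200, s, k),
                                  config=config, ramp=ramp,
                                  pair_id=f"shared_s{s}_{k}")
            d = m.as_dict()
            d["ground_truth"] = "shared"
            rows.append(d)
        for k in range(independent_per_seed):
            m = ramp_pair_metrics(0, _child_seed(seed, 300, s, k),
                                  config=config, ramp=ramp,
                                  pair_id=f"indep_s{s}_{k}")
            d = m.as_dict()
            d["ground_truth"] = "independent"
            rows.append(d)
    return pd.DataFrame(rows)


def ramp_condition_pair(seed: int,
                        n_shared: int = DEFAULT_INPUTS,
                        shared_weight_factor: float = 0.5,
                        config: rc.RampAnalysisConfig = rc.RampAnalysisConfig(),
                        ramp: RampProtocol = RampProtocol(),
                        ) -> Tuple[rc.PairMetrics, rc.PairMetrics]:
    """Metrics for one pair under control and a manipulated condition.

    The manipulation scales the weights of the shared connections by
    ``shared_weight_factor`` while keeping the same presynaptic spike
    trains, emulating a treatment that selectively weakens the common
    drive (the way blocking an indirect pathway would).
    """
    net = generate_network(n_pre=DEFAULT_N_PRE, n_post=2,
                           inputs_per_post=DEFAULT_INPUTS, n_shared=n_shared,
                           seed=_child_seed(seed, 1))
    spikes = generate_ramp_spikes(net, ramp, seed=_child_seed(seed, 2))

    shared_ids = (net.presynaptic_ids("post00")
                  & net.presynaptic_ids("post01"))
    adj_treat = net.adjacency.copy()
    mask = adj_treat["pre_id"].isin(shared_ids)
    adj_treat.loc[mask, "weight"] *= shared_weight_factor
    net_treat = GroundTruthNetwork(net.pre.copy(), net.post.copy(), adj_treat)

    out = []
    for label, network in (("control", net), ("treatment", net_treat)):
        traces = simulate_postsynaptic_trace(
            spikes, network, duration_ms=ramp.duration_ms,
            seed=_child_seed(seed, 3))
        m = rc.pair_metrics(traces.traces_for("post00"),
                            traces.traces_for("post01"),
                            config=config, pair_id=f"pair_seed{seed}",
                            stim_duration_ms=ramp.duration_ms,
                            condition=label)
        out.append(m)
    return out[0], out[1]


# --------------------------------------------------------------------------
# focal experiments
# --------------------------------------------------------------------------

def _focal_network(n_shared: int, seed: int,
                   inputs_per_post: int = DEFAULT_INPUTS,
                   disjoint_sites: bool = False,
                   span_um: Tuple[float, float] = (180.0, 120.0),
                   ) -> GroundTruthNetwork:
    """Ground-truth network with presynaptic somata inside the scanning
    area. In ``disjoint_sites`` mode the two cells' input pools occupy
    opposite mediolateral halves of the grid, so their activating site
    sets cannot overlap."""
    rng = np.random.default_rng(seed)
    need = 2 * inputs_per_post - n_shared
    if disjoint_sites and n_shared > 0:
        raise ValueError("disjoint-site mode requires n_shared = 0")
    dv = rng.uniform(-span_um[0] / 2, span_um[0] / 2, size=need)
    if disjoint_sites:
        ml = np.concatenate([
            rng.uniform(-span_um[1] / 2, -span_um[1] / 6, size=inputs_per_post),
            rng.uniform(span_um[1] / 6, span_um[1] / 2, size=inputs_per_post)])
    else:
        ml = rng.uniform(-span_um[1] / 2, span_um[1] / 2, size=need)
    thresholds = rng.uniform(0.3, 0.7, size=need)
    pre = pd.DataFrame({
        "cell_id": [f"pre{i:03d}" for i in range(need)],
        "pos_dv_um": dv, "pos_ml_um": ml,
        "threshold": thresholds,
        "peak_rate_hz": np.full(need, 20.0),
    })
    post = pd.DataFrame({
        "cell_id": ["post00", "post01"],
        "pos_dv_um": [-50.0, 50.0], "pos_ml_um": [0.0, 0.0],
        "cell_class": ["recorded", "recorded"],
    })
    ids = pre["cell_id"].tolist()
    set_a = ids[:inputs_per_post]
    set_b = ids[:n_shared] + ids[inputs_per_post:need]
    rows = [(p, "post00", 1.0) for p in set_a] + \
           [(p, "post01", 1.0) for p in set_b]
    adjacency = pd.DataFrame(rows, columns=["pre_id", "post_id", "weight"])
    return GroundTruthNetwork(pre, post, adjacency)


def focal_pair_events(n_shared: int,
                      seed: int,
                      grid: FocalGridProtocol = FocalGridProtocol(),
                      intensity: float = 1.0,
                      activation_radius_um: float = 20.0,
                      latency_jitter_ms: float = 8.0,
                      disjoint_sites: bool = False,
                      params: SynapticKernelParams = SynapticKernelParams(),
                      weight_to_pa: float = 1000.0,
                      snr_threshold: float = 2.5,
                      ) -> Tuple[fc.EventTable, fc.EventTable,
                                 FocalGridProtocol, GroundTruthNetwork]:
    """Full focal pipeline for one simulated pair.

    Simulates grid-evoked spikes, convolves them into per-repeat traces,
    detects events by template matching at the configured signal-to-noise
    threshold, and attributes evoked events to their stimulation sites.
    """
    net = _focal_network(n_shared, _child_seed(seed, 11),
                         disjoint_sites=disjoint_sites)
    protocol_seed = _child_seed(seed, 12)
    spikes = generate_focal_spikes(net, grid, intensity=intensity,
                                   activation_radius_um=activation_radius_um,
                                   latency_jitter_ms=latency_jitter_ms,
                                   seed=protocol_seed)
    traces = simulate_postsynaptic_trace(
        spikes, net, params=params, duration_ms=grid.repeat_duration_ms,
        seed=_child_seed(seed, 13))
    # template taken from the simulation's own unitary event waveform,
    # the analogue of defining the template from recorded events
    template = np.abs(sampled_kernel(params, traces[("post00", 0)].dt_ms))
    lo, hi = fc.DEFAULT_EVOKED_WINDOW_MS
    nonevoked_s = (grid.repeats
                   * (grid.repeat_duration_ms - grid.n_sites * (hi - lo))
                   / 1000.0)
    tables = []
    for cell in ("post00", "post01"):
        frames = []
        n_detected = 0
        for trial in traces.trials(cell):
            tr = traces[(cell, trial)]
            det = fc.detect_events(tr, template,
                                   snr_threshold=snr_threshold,
                                   min_amplitude=3.0 * fc.estimate_noise_sd(tr))
            n_detected += len(det)
            frames.append(fc.assign_events_to_sites(
                det, grid, trial, protocol_seed, cell_id=cell,
                amplitude_scale=weight_to_pa))
        table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=fc.EVENT_COLUMNS))
        # detections outside the evoked windows estimate the background
        # (spontaneous/noise) rate used to correct the Pc normalizer
        spont_rate = max(n_detected - len(table), 0) / max(nonevoked_s, 1e-9)
        tables.append(fc.EventTable(table, (grid.rows, grid.cols),
                                    spontaneous_rate_hz=spont_rate))
    return tables[0], tables[1], grid, net


def focal_pc(n_shared: int, seed: int, intensity: float = 1.0,
             disjoint_sites: bool = False,
             **kwargs) -> fc.CorrelationProbabilityResult:
    """Correlation probability of one simulated focal pair."""
    ev_a, ev_b, grid, _ = focal_pair_events(
        n_shared, seed, intensity=intensity,
        disjoint_sites=disjoint_sites, **kwargs)
    return fc.correlation_probability(ev_a, ev_b, grid)
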