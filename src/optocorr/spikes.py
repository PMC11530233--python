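"""Presynaptic spike-train synthesis for widefield ramp and focal grid stimuli.

Ramp trains: each channelrhodopsin-expressing cell is silent until the ramp
first exceeds its intensity threshold and then fires an inhomogeneous
Poisson train whose rate saturates with suprathreshold drive, with a 3 ms
absolute refractory period. Per-trial lognormal jitter of the effective
threshold reproduces trial-to-trial first-spike latency variability.

Focal trains: a 1 ms pulse at a grid site can trigger at most one spike in
cells whose soma lies within a hard-disc activation footprint of the site,
provided the stimulus intensity clears the cell's distance-scaled
threshold; spike latency after the pulse is jittered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .network import GroundTruthNetwork
from .protocols import FocalGridProtocol, RampProtocol

__all__ = ["SpikeTrainSet", "RampNoiseParams", "generate_ramp_spikes",
           "generate_focal_spikes"]

SPIKE_COLUMNS = ["cell_id", "trial_id", "site_row", "site_col", "time_ms"]

REFRACTORY_MS = 3.0


@dataclass
class SpikeTrainSet:
    """Tidy table of spike times, one row per spike.

    Columns: ``cell_id, trial_id, site_row, site_col, time_ms``. Site
    columns are NaN for widefield (ramp) stimulation. Times are ms from
    stimulus onset (ramp) or from the start of the repeat (focal).
    """

    table: pd.DataFrame
    duration_ms: float

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table, columns=SPIKE_COLUMNS)
        t = self.table["time_ms"]
        if len(t) and ((t < 0).any() or (t > self.duration_ms).any()):
            raise ValueError("spike times outside [0, duration]")
        for (_, _), grp in self.table.groupby(["cell_id", "trial_id"], sort=False):
            tt = grp["time_ms"].to_numpy()
            if len(tt) > 1 and not (np.diff(tt) > 0).all():
                raise ValueError("spike times must be strictly increasing "
                                 "within a cell-trial")

    def times(self, cell_id, trial_id) -> np.ndarray:
        m = (self.table["cell_id"] == cell_id) & (self.table["trial_id"] == trial_id)
        return self.table.loc[m, "time_ms"].to_numpy()

    @property
    def cell_ids(self):
        return list(pd.unique(self.table["cell_id"]))

    @property
    def trial_ids(self):
        return sorted(pd.unique(self.table["trial_id"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration_ms: float) -> "SpikeTrainSet":
        return cls(pd.read_csv(path), duration_ms)


@dataclass(frozen=True)
class RampNoiseParams:
    """Variability knobs for ramp-evoked spiking.

    ``threshold_jitter_sd``: sd of the per-trial lognormal multiplier on a
    cell's threshold (relative units). ``rate_half_drive``: normalized
    suprathreshold drive at which the firing rate reaches half its
    saturating value.
    """

    threshold_jitter_sd: float = 0.05
    rate_half_drive: float = 0.25


def _cell_stream(seed: int, cell_index: int, trial: int) -> np.random.Generator:
    # Independent, reproducible stream per (seed, cell, trial).
    return np.random.default_rng(np.random.SeedSequence([seed, cell_index, trial]))


def ramp_rate_hz(t_ms: np.ndarray, ramp: RampProtocol, threshold: float,
                 peak_rate_hz: float, half_drive: float) -> np.ndarray:
    """Saturating rate law: r = r_peak * u / (u + u50).

    ``u`` is the suprathreshold drive (intensity - threshold) normalized by
    the cell's dynamic range (final intensity - threshold); zero below
    threshold.
    """
    intensity = ramp.intensity(t_ms)
    span = max(ramp.final_intensity - threshold, 1e-12)
    u = np.clip((intensity - threshold) / span, 0.0, None)
    return peak_rate_hz * u / (u + half_drive)


def _thin_poisson(rng: np.random.Generator, t_grid: np.ndarray,
                  rate_hz: np.ndarray, duration_ms: float) -> np.ndarray:
    """Inhomogeneous Poisson by thinning a homogeneous bound, then an
    absolute refractory period applied forward in time."""
    rmax = float(rate_hz.max(initial=0.0))
    if rmax <= 0:
        return np.empty(0)
    n_exp = rmax / 1000.0 * duration_ms
    n = rng.poisson(n_exp)
    cand = np.sort(rng.uniform(0.0, duration_ms, size=n))
    keep = rng.uniform(0.0, rmax, size=n) < np.interp(cand, t_grid, rate_hz)
    cand = cand[keep]
    out = []
    last = -np.inf
    for t in cand:
        if t - last >= REFRACTORY_MS:
            out.append(t)
            last = t
    return np.asarray(out)


def generate_ramp_spikes(
    network: GroundTruthNetwork,
    ramp: RampProtocol,
    noise_params: Optional[RampNoiseParams] = None,
    seed: int = 0,
) -> SpikeTrainSet:
    """Ramp-evoked asynchronous spike trains for every presynaptic cell.

    Cells whose (jittered) threshold exceeds the final ramp intensity stay
    silent on that trial. Above threshold, spiking is an inhomogeneous
    Poisson process with the saturating rate law of :func:`ramp_rate_hz`
    and a 3 ms refractory period. Fully determined by ``seed``.
    """
    noise = noise_params or RampNoiseParams()
    duration = ramp.duration_ms
    t_grid = np.arange(0.0, duration + 1.0, 1.0)
    rows = []
    for idx, cell in network.pre.reset_index(drop=True).iterrows():
        if cell["threshold"] >= ramp.final_intensity:
            continue  # never recruited, even with trial jitter
        for trial in range(ramp.repeats):
            rng = _cell_stream(seed, idx, trial)
            jitter = rng.lognormal(0.0, noise.threshold_jitter_sd) \
                if noise.threshold_jitter_sd > 0 else 1.0
            thr = cell["threshold"] * jitter
            if thr >= ramp.final_intensity:
                continue
            rate = ramp_rate_hz(t_grid, ramp, thr, cell["peak_rate_hz"],
                                noise.rate_half_drive)
            tt = _thin_poisson(rng, t_grid, rate, duration)
            rows += [(cell["cell_id"], trial, np.nan, np.nan, t) for t in tt]
    table = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    return SpikeTrainSet(table, duration)


def generate_focal_spikes(
    network: GroundTruthNetwork,
    grid: FocalGridProtocol,
    intensity: Optional[float] = None,
    activation_radius_um: float = 20.0,
    latency_jitter_ms: float = 8.0,
    base_latency_ms: float = 2.0,
    spike_probability: float = 0.9,
    seed: int = 0,
) -> SpikeTrainSet:
    """Focal-grid-evoked spike trains with site labels.

    A pulse at a site can activate a presynaptic cell only if the soma lies
    within ``activation_radius_um`` of the site (hard-disc footprint) and
    the pulse intensity reaches the cell's distance-scaled threshold
    ``threshold * (1 + d/r)``, so the activating-site count grows with
    intensity. Each effective pulse triggers at most one spike, emitted
    with probability ``spike_probability`` at latency
    ``base_latency_ms`` plus truncated-Gaussian jitter.

    Trial ids enumerate repeats; spike times are ms from repeat onset.
    """
    if activation_radius_um <= 0:
        raise ValueError("activation radius must be positive")
    level = grid.intensity if intensity is None else intensity
    if level <= 0:
        raise ValueError("intensity must be positive")

    sites = grid.site_positions()
    pre = network.pre.reset_index(drop=True)
    soma = pre[["pos_dv_um", "pos_ml_um"]].to_numpy()
    # (n_cells, n_sites) effective thresholds; inf outside the footprint
    d = np.linalg.norm(soma[:, None, :] - sites[None, :, :], axis=2)
    eff = pre["threshold"].to_numpy()[:, None] * (1.0 + d / activation_radius_um)
    eff[d > activation_radius_um] = np.inf

    rows = []
    for rep in range(grid.repeats):
        order = grid.site_order(rep, seed)
        pulse_t = np.arange(grid.n_sites) * grid.inter_pulse_ms
        for idx in range(len(pre)):
            rng = _cell_stream(seed, idx, rep)
            active = level >= eff[idx, order]
            fires = active & (rng.uniform(size=grid.n_sites) < spike_probability)
            # gamma latencies: right-skewed with mean base + jitter and sd
            # jitter/sqrt(2), the broad trial-to-trial variability seen at
            # threshold photostimulation
            lat = base_latency_ms + rng.gamma(2.0, latency_jitter_ms / 2.0,
                                              size=grid.n_sites)
            for k in np.flatnonzero(fires):
                site = order[k]
                rows.append((pre.loc[idx, "cell_id"], rep,
                             site // grid.cols, site % grid.cols,
                             pulse_t[k] + grid.pulse_ms + lat[k]))
    table = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    table = table.sort_values(["cell_id", "trial_id", "time_ms"],
                              kind="stable").reset_index(drop=True)
    return SpikeTrainSet(table, grid.repeat_duration_ms)


def activating_site_count(network: GroundTruthNetwork, grid: FocalGridProtocol,
                          intensity: float, activation_radius_um: float = 30.0,
                          ) -> pd.Series:
    """Number of grid sites able to activate each presynaptic cell at the
    given intensity (deterministic footprint geometry)."""
    sites = grid.site_positions()
    pre = network.pre.reset_index(drop=True)
    soma = pre[["pos_dv_um", "pos_ml_um"]].to_numpy()
    d = np.linalg.norm(soma[:, None, :] - sites[None, :, :], axis=2)
    eff = pre["threshold"].to_numpy()[:, None] * (1.0 + d / activation_radius_um)
    eff[d > activation_radius_um] = np.inf
    counts = (intensity >= eff).sum(axis=1)
    return pd.Series(counts, index=pre["cell_id"], name="n_activating_sites")
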