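"""Simulation of voltage-clamp current traces from spike trains and a
ground-truth network, plus trace containers and HDF5/CSV I/O.

Because the postsynaptic cell is voltage clamped, capacitive currents are
zero and voltage-gated currents stationary, so the recorded trace is the
linear superposition of unitary synaptic currents (one kernel per
presynaptic spike, scaled by the connection weight) plus recording noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .kernels import SynapticKernelParams, sampled_kernel
from .network import GroundTruthNetwork
from .spikes import SpikeTrainSet

__all__ = ["CurrentTrace", "TraceSet", "simulate_postsynaptic_trace"]

DEFAULT_DT_MS = 0.05  # 20 kHz digitization


@dataclass
class CurrentTrace:
    """Uniformly sampled membrane current at fixed holding potential.

    ``samples`` are in nA; ``dt_ms`` defaults to 0.05 ms (20 kHz);
    ``t0_ms`` is the time of the first sample.
    """

    samples: np.ndarray
    dt_ms: float = DEFAULT_DT_MS
    t0_ms: float = 0.0
    holding_mv: float = -70.0
    cell_id: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.samples)) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * self.dt_ms

    def copy_with(self, samples: np.ndarray, dt_ms: Optional[float] = None
                  ) -> "CurrentTrace":
        return CurrentTrace(samples, dt_ms if dt_ms is not None else self.dt_ms,
                            self.t0_ms, self.holding_mv, self.cell_id,
                            self.trial_id)


class TraceSet(dict):
    """Mapping from (cell_id, trial_id) to :class:`CurrentTrace`.

    Keys are tuples; helper accessors keep call sites readable and the
    HDF5 layout is one group per cell with one dataset per trial.
    """

    def cell_ids(self):
        return sorted({c for c, _ in self.keys()})

    def trials(self, cell_id):
        return sorted(t for c, t in self.keys() if c == cell_id)

    def traces_for(self, cell_id):
        return [self[(cell_id, t)] for t in self.trials(cell_id)]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for (cell, trial), tr in self.items():
                ds = fh.create_dataset(f"{cell}/trial{trial:03d}",
                                       data=tr.samples)
                ds.attrs["dt_ms"] = tr.dt_ms
                ds.attrs["t0_ms"] = tr.t0_ms
                ds.attrs["holding_mv"] = tr.holding_mv
                ds.attrs["units"] = "nA"

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        out = cls()
        with h5py.File(path, "r") as fh:
            for cell in fh:
                for name in fh[cell]:
                    ds = fh[cell][name]
                    trial = int(name.replace("trial", ""))
                    out[(cell, trial)] = CurrentTrace(
                        ds[()], float(ds.attrs["dt_ms"]),
                        float(ds.attrs["t0_ms"]),
                        float(ds.attrs["holding_mv"]), cell, trial)
        return out

    def to_csv(self, path) -> None:
        frames = []
        for (cell, trial), tr in sorted(self.items()):
            frames.append(pd.DataFrame({
                "cell_id": cell, "trial_id": trial,
                "time_ms": tr.times_ms, "current_na": tr.samples}))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def simulate_postsynaptic_trace(
    spikes: SpikeTrainSet,
    network: GroundTruthNetwork,
    params: Optional[SynapticKernelParams] = None,
    noise_sd_na: Optional[float] = None,
    duration_ms: Optional[float] = None,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int = 0,
    post_ids: Optional[list] = None,
) -> TraceSet:
    """Convolve presynaptic spike trains into postsynaptic current traces.

    For every postsynaptic cell and trial the trace is the sum over its
    presynaptic partners of the unitary current kernel placed at each
    spike time and scaled by the connection weight, plus additive Gaussian
    white noise. With ``noise_sd_na = 0`` superposition holds exactly.

    ``noise_sd_na`` defaults to 5% of the unitary event peak. Raises if
    the spike table contains cell ids missing from the network or spikes
    beyond ``duration_ms``.
    """
    params = params or SynapticKernelParams()
    if noise_sd_na is None:
        noise_sd_na = 0.05 * abs(params.unitary_peak_na)
    duration = spikes.duration_ms if duration_ms is None else duration_ms
    if len(spikes.table) and (spikes.table["time_ms"] >= duration).any():
        raise ValueError("spike times must fall before the trace end")
    known = set(network.pre["cell_id"])
    stray = set(spikes.table["cell_id"]) - known
    if stray:
        raise ValueError(f"spike table references unknown cells: {sorted(stray)}")

    kernel = sampled_kernel(params, dt_ms)
    n = int(round(duration / dt_ms))
    posts = post_ids if post_ids is not None else list(network.post["cell_id"])
    trials = spikes.trial_ids or [0]

    adj = network.adjacency
    out = TraceSet()
    for post in posts:
        partners = adj.loc[adj["post_id"] == post, ["pre_id", "weight"]]
        wmap = dict(zip(partners["pre_id"], partners["weight"]))
        sub = spikes.table[spikes.table["cell_id"].isin(wmap.keys())]
        for trial in trials:
            post_tag = zlib.crc32(str(post).encode())  # stable across runs
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, post_tag, trial]))
            st = sub[sub["trial_id"] == trial]
            if len(st):
                drive = np.zeros(n)
                idx = np.round(st["time_ms"].to_numpy() / dt_ms).astype(int)
                w = st["cell_id"].map(wmap).to_numpy(dtype=float)
                np.add.at(drive, np.clip(idx, 0, n - 1), w)
                trace = fftconvolve(drive, kernel)[:n]
            else:
                trace = np.zeros(n)
            if noise_sd_na > 0:
                trace = trace + rng.normal(0.0, noise_sd_na, size=n)
            out[(post, trial)] = CurrentTrace(trace, dt_ms, 0.0, params.v_mv,
                                              post, trial)
    return out
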