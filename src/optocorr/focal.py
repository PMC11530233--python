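"""Focal-stimulation analysis: synaptic event detection by optimally scaled
template matching, shift-corrected correlation probability (Pc), per-site
response maps, and spatial map correlation against a within-map shuffle null.

Event detection follows the sliding template-fit approach: at every offset
the template is optimally scaled and offset onto the trace, and the
detection statistic is the fitted scale divided by its standard error;
local maxima of the statistic above the signal-to-noise threshold are
events, so partially overlapping events are resolved down to the minimum
separation.

The correlation probability cross-correlates detected event times of two
simultaneously recorded cells within matched trials at each stimulation
site (4 ms bins, central bin 0±2 ms), sums correlograms over sites,
subtracts the central bin of a shift predictor (trials circularly shifted
by one within each site) and normalizes by the evoked event count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocols import FocalGridProtocol
from .traces import CurrentTrace

__all__ = [
    "EventTemplate", "EventTable", "CorrelationProbabilityResult",
    "ResponseMap", "MapCorrelationResult", "SelectedIntensity",
    "detect_events", "assign_events_to_sites", "correlation_probability",
    "build_response_map", "map_correlation", "select_intensity",
]

EVENT_COLUMNS = ["cell_id", "trial_id", "site_row", "site_col", "time_ms",
                 "amplitude_pa"]

#: events this long after a pulse count as evoked (ms)
DEFAULT_EVOKED_WINDOW_MS = (2.0, 30.0)


@dataclass(frozen=True)
class EventTemplate:
    """Double-exponential synaptic event template, peak normalized to 1."""

    rise_ms: float = 0.5
    decay_ms: float = 3.0
    length_ms: float = 15.0

    def waveform(self, dt_ms: float) -> np.ndarray:
        if self.rise_ms <= 0 or self.decay_ms <= self.rise_ms:
            raise ValueError("need 0 < rise < decay")
        t = np.arange(0.0, self.length_ms, dt_ms)
        w = (1 - np.exp(-t / self.rise_ms)) * np.exp(-t / self.decay_ms)
        return w / w.max()

    def peak_offset_ms(self, dt_ms: float) -> float:
        return float(np.argmax(self.waveform(dt_ms))) * dt_ms


@dataclass
class EventTable:
    """Detected synaptic events, one row per event.

    ``time_ms`` is relative to the triggering pulse; amplitudes are
    magnitudes in pA; site indices address the stimulation grid.
    """

    table: pd.DataFrame
    grid_shape: Tuple[int, int] = (0, 0)
    #: background (non-evoked) detection rate, estimated from inter-pulse
    #: epochs; used to correct the evoked-count normalizer of Pc
    spontaneous_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table, columns=EVENT_COLUMNS)
        if len(self.table):
            if (self.table["amplitude_pa"] <= 0).any():
                raise ValueError("event amplitudes must be positive magnitudes")
            if not np.isfinite(self.table["time_ms"]).all():
                raise ValueError("event times must be finite")
            rows, cols = self.grid_shape
            if rows and cols:
                r = self.table["site_row"]
                c = self.table["site_col"]
                if ((r < 0) | (r >= rows) | (c < 0) | (c >= cols)).any():
                    raise ValueError("event site outside stimulation grid")

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_shape=(0, 0)) -> "EventTable":
        return cls(pd.read_csv(path), grid_shape)


def _fit_at(x: np.ndarray, w: np.ndarray, i: int, sw: float, sww: float,
            denom: float) -> Tuple[float, float]:
    """Optimal (scale, criterion) of the template at offset ``i``."""
    n = len(w)
    y = x[i:i + n]
    sy = y.sum()
    swy = float(np.dot(w, y))
    scale = (swy - sw * sy / n) / denom
    offset = (sy - scale * sw) / n
    sse = (float(np.dot(y, y)) + scale ** 2 * sww + n * offset ** 2
           - 2.0 * (scale * swy + offset * sy - scale * offset * sw))
    sse = max(sse, 0.0)
    se = np.sqrt(sse / (n - 1) / denom)
    if se > 0:
        return scale, scale / se
    # an exact fit: infinitely significant if it has positive amplitude
    return scale, (np.inf if scale > 0 else 0.0)


def estimate_noise_sd(trace: CurrentTrace) -> float:
    """Robust baseline noise SD via the median absolute deviation of
    first differences (insensitive to sparse synaptic events)."""
    d = np.diff(np.asarray(trace.samples, dtype=float))
    return float(np.median(np.abs(d - np.median(d))) / 0.6744898 / np.sqrt(2.0))


def detect_events(trace: CurrentTrace,
                  template=EventTemplate(),
                  snr_threshold: float = 2.5,
                  min_separation_ms: float = 2.0,
                  polarity: int = -1,
                  subtract: bool = True,
                  min_amplitude: Optional[float] = None) -> pd.DataFrame:
    """Template-matching event detection on a single trace.

    At every offset the template ``w`` is fitted to the trace segment ``y``
    as ``scale * w + offset`` in the least-squares sense; the detection
    statistic is ``scale / SE(scale)``. Candidate events are local maxima
    of the statistic above ``snr_threshold`` separated by at least
    ``min_separation_ms``. With ``subtract=True`` candidates are then
    confirmed in descending order of the statistic, each accepted event's
    fitted template being subtracted from the trace before the remaining
    candidates are re-fitted; this resolves genuinely overlapping events
    while rejecting the spurious secondary maxima that a large event's
    decay would otherwise seed.

    ``template`` is an :class:`EventTemplate` or a waveform array sampled
    at the trace's dt (peak-normalized). ``polarity=-1`` detects inward
    (negative) events, the voltage-clamp EPSC convention at -70 mV.
    ``min_amplitude`` optionally discards events whose fitted peak falls
    below an absolute floor (trace units), the usual companion of the
    signal-to-noise criterion.

    Returns a DataFrame with ``time_ms`` (event onset within the trace)
    and ``amplitude`` (fitted peak magnitude, trace units).
    """
    x = polarity * np.asarray(trace.samples, dtype=float)
    if isinstance(template, EventTemplate):
        w = template.waveform(trace.dt_ms)
    else:
        w = np.asarray(template, dtype=float)
        if w.max() > 0:
            w = w / w.max()
    n = len(w)
    if n >= len(x):
        raise ValueError("template must be shorter than the trace")

    sw = w.sum()
    sww = float(np.dot(w, w))
    ones = np.ones(n)
    sy = np.convolve(x, ones, mode="valid")
    syy = np.convolve(x * x, ones, mode="valid")
    swy = sps.fftconvolve(x, w[::-1], mode="valid")

    denom = sww - sw * sw / n
    scale = (swy - sw * sy / n) / denom
    offset = (sy - scale * sw) / n
    sse = (syy + scale ** 2 * sww + n * offset ** 2
           - 2.0 * (scale * swy + offset * sy - scale * offset * sw))
    sse = np.clip(sse, 0.0, None)
    se = np.sqrt(sse / (n - 1) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(se > 0, scale / se,
                        np.where(scale > 0, np.inf, 0.0))

    dist = max(int(round(min_separation_ms / trace.dt_ms)), 1)
    peaks, _ = sps.find_peaks(crit, height=snr_threshold, distance=dist)
    floor = 0.0 if min_amplitude is None else float(min_amplitude)

    if not subtract or not len(peaks):
        keep = np.abs(scale[peaks]) >= floor
        return pd.DataFrame({
            "time_ms": trace.t0_ms + peaks[keep] * trace.dt_ms,
            "amplitude": np.abs(scale[peaks][keep]),
        })

    residual = x.copy()
    accepted = []
    for i in peaks[np.argsort(crit[peaks])[::-1]]:
        sc, cr = _fit_at(residual, w, i, sw, sww, denom)
        if cr >= snr_threshold and sc >= max(floor, 1e-300):
            accepted.append((i, sc))
            residual[i:i + n] -= sc * w
    accepted.sort()
    idx = np.array([i for i, _ in accepted], dtype=int)
    amp = np.array([s for _, s in accepted])
    return pd.DataFrame({
        "time_ms": trace.t0_ms + idx * trace.dt_ms,
        "amplitude": np.abs(amp),
    })


def assign_events_to_sites(events: pd.DataFrame,
                           protocol: FocalGridProtocol,
                           repeat: int,
                           protocol_seed: int,
                           cell_id: str = "",
                           evoked_window_ms: Tuple[float, float]
                           = DEFAULT_EVOKED_WINDOW_MS,
                           amplitude_scale: float = 1.0) -> pd.DataFrame:
    """Attribute detected events of one repeat to stimulation sites.

    Events whose latency from the preceding pulse onset falls inside
    ``evoked_window_ms`` become evoked events of that site; the rest are
    treated as spontaneous and dropped from the table (they inform the
    spontaneous-rate estimate). ``amplitude_scale`` converts trace units
    to pA (e.g. 1000 for traces in nA).
    """
    rows = []
    order = protocol.site_order(repeat, protocol_seed)
    lo, hi = evoked_window_ms
    for _, ev in events.iterrows():
        t = ev["time_ms"]
        k = int(t // protocol.inter_pulse_ms)
        if not (0 <= k < protocol.n_sites):
            continue
        rel = t - k * protocol.inter_pulse_ms
        if lo <= rel <= hi:
            site = order[k]
            rows.append((cell_id, repeat, site // protocol.cols,
                         site % protocol.cols, rel,
                         ev["amplitude"] * amplitude_scale))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass
class CorrelationProbabilityResult:
    """Shift-corrected correlation probability for one pair of cells."""

    pc: float
    central_count: float
    shifted_central_count: float
    n_evoked_a: float
    n_evoked_b: float
    normalizer: float
    correlogram: Optional[np.ndarray] = None
    shifted_correlogram: Optional[np.ndarray] = None
    bin_edges_ms: Optional[np.ndarray] = None
    missing: bool = False
    note: str = ""


def _site_trial_times(table: pd.DataFrame) -> Dict[tuple, np.ndarray]:
    out = {}
    for (r, c, tr), grp in table.groupby(["site_row", "site_col", "trial_id"]):
        out[(int(r), int(c), int(tr))] = grp["time_ms"].to_numpy()
    return out


def correlation_probability(events_a: EventTable,
                            events_b: EventTable,
                            protocol: FocalGridProtocol,
                            bin_ms: float = 4.0,
                            max_lag_ms: float = 20.0,
                            trial_shift: int = 1,
                            normalizer: str = "min",
                            spontaneous_rate_hz: Optional[float] = None,
                            evoked_window_ms: Tuple[float, float]
                            = DEFAULT_EVOKED_WINDOW_MS,
                            ) -> CorrelationProbabilityResult:
    """Correlation probability Pc between two cells' evoked events.

    Within each stimulation site, event-time differences (B - A) from
    matched trials are histogrammed into ``bin_ms`` bins with the central
    bin spanning 0 ± bin/2; correlograms are summed over sites. The shift
    predictor repeats this with B's trial index circularly shifted by
    ``trial_shift`` within the site. Pc = (central - shifted central) /
    evoked-count normalizer, where the normalizer is the smaller
    (``'min'``) or the sum (``'sum'``) of the two cells' evoked counts,
    each optionally corrected for expected spontaneous events.

    Returns a result flagged ``missing`` when there are no evoked events.
    """
    if normalizer not in ("min", "sum"):
        raise ValueError("normalizer must be 'min' or 'sum'")
    nbins_half = int(np.ceil(max_lag_ms / bin_ms))
    edges = bin_ms * (np.arange(-nbins_half, nbins_half + 2) - 0.5)
    central = nbins_half

    ta = _site_trial_times(events_a.table)
    tb = _site_trial_times(events_b.table)
    hist = np.zeros(len(edges) - 1)
    shifted = np.zeros(len(edges) - 1)
    n_rep = protocol.repeats
    for r in range(protocol.rows):
        for c in range(protocol.cols):
            for tr in range(n_rep):
                a = ta.get((r, c, tr))
                if a is None or not len(a):
                    continue
                b = tb.get((r, c, tr))
                if b is not None and len(b):
                    d = (b[None, :] - a[:, None]).ravel()
                    hist += np.histogram(d, bins=edges)[0]
                bs = tb.get((r, c, (tr + trial_shift) % n_rep))
                if bs is not None and len(bs):
                    d = (bs[None, :] - a[:, None]).ravel()
                    shifted += np.histogram(d, bins=edges)[0]

    lo, hi = evoked_window_ms
    window_s = (hi - lo) / 1000.0
    n_pulses = protocol.n_sites * protocol.repeats
    rate_a = (events_a.spontaneous_rate_hz if spontaneous_rate_hz is None
              else spontaneous_rate_hz)
    rate_b = (events_b.spontaneous_rate_hz if spontaneous_rate_hz is None
              else spontaneous_rate_hz)
    n_a = max(len(events_a) - rate_a * window_s * n_pulses, 0.0)
    n_b = max(len(events_b) - rate_b * window_s * n_pulses, 0.0)
    norm = min(n_a, n_b) if normalizer == "min" else n_a + n_b

    if norm <= 0:
        return CorrelationProbabilityResult(
            pc=np.nan, central_count=float(hist[central]),
            shifted_central_count=float(shifted[central]),
            n_evoked_a=n_a, n_evoked_b=n_b, normalizer=norm,
            correlogram=hist, shifted_correlogram=shifted,
            bin_edges_ms=edges, missing=True,
            note="no evoked events; Pc undefined")
    pc = (hist[central] - shifted[central]) / norm
    return CorrelationProbabilityResult(
        pc=float(pc), central_count=float(hist[central]),
        shifted_central_count=float(shifted[central]),
        n_evoked_a=n_a, n_evoked_b=n_b, normalizer=norm,
        correlogram=hist, shifted_correlogram=shifted, bin_edges_ms=edges)


@dataclass
class ResponseMap:
    """Summed evoked event amplitude per stimulation site (pA)."""

    data: np.ndarray
    cell_id: str = ""
    intensity: float = np.nan

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if (self.data < 0).any():
            raise ValueError("response map entries must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.data).to_csv(path, index=False, header=False)

    def plot(self, ax=None):
        """Render the map as a heat map (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.data, origin="lower", cmap="viridis")
        ax.set_xlabel("grid column")
        ax.set_ylabel("grid row")
        ax.figure.colorbar(im, ax=ax, label="summed amplitude (pA)")
        return ax


def build_response_map(events: EventTable, protocol: FocalGridProtocol,
                       intensity: float = np.nan,
                       cell_id: str = "") -> ResponseMap:
    """Sum event amplitudes per site across repeats into a grid map."""
    grid = np.zeros((protocol.rows, protocol.cols))
    t = events.table
    if len(t):
        r = t["site_row"].to_numpy(dtype=int)
        c = t["site_col"].to_numpy(dtype=int)
        np.add.at(grid, (r, c), t["amplitude_pa"].to_numpy(dtype=float))
    if not cell_id and len(t):
        cell_id = str(t["cell_id"].iloc[0])
    return ResponseMap(grid, cell_id=cell_id, intensity=intensity)


@dataclass
class MapCorrelationResult:
    """Pearson correlation of two response maps with its shuffle percentile."""

    r: float
    percentile: float
    null_r: Optional[np.ndarray] = None
    missing: bool = False
    note: str = ""


def map_correlation(map_a: ResponseMap, map_b: ResponseMap,
                    n_shuffles: int = 100, seed: int = 0
                    ) -> MapCorrelationResult:
    """Pearson R over sites, against a null of within-map permutations.

    Each shuffle permutes the site values of both maps independently and
    recomputes R; the reported percentile is the fraction of shuffles
    strictly below the observed R (x100). Maps must share shape. A map
    with zero variance yields a result flagged ``missing``.
    """
    a = map_a.data.ravel()
    b = map_b.data.ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    if a.std() == 0 or b.std() == 0:
        return MapCorrelationResult(np.nan, np.nan, missing=True,
                                    note="zero-variance map; R undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = np.corrcoef(rng.permutation(a), rng.permutation(b))[0, 1]
    pct = 100.0 * float(np.mean(null < r_obs))
    return MapCorrelationResult(r_obs, pct, null_r=null)


@dataclass(frozen=True)
class SelectedIntensity:
    """Outcome of the analysis-intensity selection rule."""

    intensity: float
    count: int
    in_range: bool
    threshold_intensity: float
    preferred_intensity: float


def select_intensity(counts: Mapping[float, int],
                     target_range: Tuple[int, int] = (335, 908),
                     threshold_multiple: float = 7.0) -> SelectedIntensity:
    """Choose the stimulus intensity used for the pair analysis.

    The threshold intensity is the lowest level with any evoked events;
    the preferred level is ``threshold * threshold_multiple``. Among
    levels whose total evoked count falls in ``target_range`` the one
    closest to the preferred level wins; if none is in range, the level
    with the count nearest the range is returned with ``in_range=False``.
    """
    if len(counts) < 2:
        raise ValueError("need at least two measured intensity levels")
    items = sorted(counts.items())
    responsive = [i for i, n in items if n > 0]
    if not responsive:
        raise ValueError("no intensity evoked any events")
    threshold = responsive[0]
    preferred = threshold * threshold_multiple
    lo, hi = target_range
    in_range = [(i, n) for i, n in items if lo <= n <= hi]
    if in_range:
        best = min(in_range, key=lambda kv: abs(kv[0] - preferred))
        return SelectedIntensity(best[0], best[1], True, threshold, preferred)
    best = min(items, key=lambda kv: min(abs(kv[1] - lo), abs(kv[1] - hi)))
    return SelectedIntensity(best[0], best[1], False, threshold, preferred)
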