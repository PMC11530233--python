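"""Widefield (ramp) analysis: band-pass filtering, sliding-window
cross-correlation, pair summary metrics, shuffled-pair null thresholds,
classification, condition comparison and distance-dependence fits.

The chain mirrors the paired voltage-clamp analysis: currents are band-pass
filtered (10-120 Hz), cross-correlated in 250 ms windows stepped by 10 ms,
and each pair is summarized by

* ``cc_peak_mean`` - maximum over windows of the smoothed, trial-averaged
  peak correlation coefficient, and
* ``cc_lag_var``   - square of the minimum over windows of the smoothed,
  across-trial standard deviation of the peak lag (ms^2).

Pairs receiving coordinated input show high ``cc_peak_mean`` and low
``cc_lag_var``; thresholds are derived from a null of synthetic pairs
assembled across different recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len, irfft, rfft
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm

from .traces import CurrentTrace

__all__ = [
    "RampAnalysisConfig", "WindowedCC", "PairMetrics", "NullThresholds",
    "RecordingSession", "bandpass_filter", "decimate_trace",
    "preprocess_trace", "windowed_crosscorr", "summarize_pair",
    "pair_metrics", "shuffle_null", "thresholds_from_metrics",
    "classify_pairs",
    "classify_pairs_kmeans", "condition_delta", "fit_distance_dependence",
    "PV_INPUT_PRESET", "SC_PAIR_PRESET", "SC_PAIR_LENIENT_PRESET",
]


@dataclass(frozen=True)
class RampAnalysisConfig:
    """Tunable parameters of the widefield analysis chain."""

    low_hz: float = 10.0
    high_hz: float = 120.0
    filter_order: int = 2
    window_ms: float = 250.0
    step_ms: float = 10.0
    max_lag_ms: float = 25.0
    smooth_windows: int = 5
    #: traces are decimated to this rate before windowed correlation;
    #: far above the 120 Hz band limit, so no information is lost
    analysis_rate_hz: float = 1000.0
    #: windows considered for the extrema: stimulus interval plus margin
    photo_margin_ms: float = 100.0


@dataclass
class WindowedCC:
    """Per-window peak correlation and its lag for one trial of one pair.

    ``table`` columns: window_start_ms, peak_coeff, peak_lag_ms,
    zero_variance (True where either window had no variance and the
    coefficient was defined as 0).
    """

    table: pd.DataFrame
    window_ms: float
    step_ms: float
    max_lag_ms: float

    @property
    def n_windows(self) -> int:
        return len(self.table)


@dataclass
class PairMetrics:
    """Summary metrics for one simultaneously recorded pair."""

    pair_id: str
    cc_peak_mean: float
    cc_lag_var: float
    distance_um: float = np.nan
    axis: str = ""
    condition: str = ""
    classification: str = ""

    def as_dict(self) -> dict:
        return {
            "pair_id": self.pair_id, "cc_peak_mean": self.cc_peak_mean,
            "cc_lag_var": self.cc_lag_var, "distance_um": self.distance_um,
            "axis": self.axis, "condition": self.condition,
            "classification": self.classification,
        }


def metrics_frame(metrics: Sequence[PairMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in metrics])


@dataclass(frozen=True)
class NullThresholds:
    """Coordination thresholds from a shuffled-pair null distribution.

    ``peak_threshold`` is the upper-tail percentile of the shuffled
    ``cc_peak_mean`` and ``lag_var_threshold`` the matching lower-tail
    percentile of the shuffled ``cc_lag_var`` (the criterion is an upper
    bound on peak and a lower bound on lag variance).
    """

    peak_threshold: float
    lag_var_threshold: float
    n_pairs: int = 0
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.peak_threshold)
                and np.isfinite(self.lag_var_threshold)):
            raise ValueError("thresholds must be finite")

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"peak_threshold": self.peak_threshold,
                       "lag_var_threshold": self.lag_var_threshold,
                       "n_pairs": self.n_pairs,
                       "percentile": self.percentile}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NullThresholds":
        import json
        with open(path) as fh:
            return cls(**json.load(fh))


#: thresholds reported for stellate-cell input to parvalbumin interneuron
#: pairs (95th percentile of 1000 shuffled pairs)
PV_INPUT_PRESET = NullThresholds(0.27, 0.22, n_pairs=1000)
#: reverse direction (interneuron input to stellate-cell pairs), strict
SC_PAIR_PRESET = NullThresholds(0.35, 0.1, n_pairs=0)
#: reverse direction, lenient lag-variance bound
SC_PAIR_LENIENT_PRESET = NullThresholds(0.35, 0.2, n_pairs=0)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def _design_sos(low_hz: float, high_hz: float, fs_hz: float, order: int):
    nyq = fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz invalid for "
                         f"sampling rate {fs_hz} Hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs_hz, output="sos")


def bandpass_filter(trace: CurrentTrace, low_hz: float = 10.0,
                    high_hz: float = 120.0, order: int = 2) -> CurrentTrace:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    Forward-backward application cancels the filter's phase response, so
    cross-correlation lags are not biased, and the pass-band attenuation
    is the squared magnitude of the one-pass filter. DC is removed by the
    high-pass edge.
    """
    fs = 1000.0 / trace.dt_ms
    sos = _design_sos(low_hz, high_hz, fs, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(trace) <= padlen:
        raise ValueError(f"trace of {len(trace)} samples is shorter than the "
                         f"filter warm-up ({padlen} samples)")
    return trace.copy_with(signal.sosfiltfilt(sos, trace.samples))


def decimate_trace(trace: CurrentTrace, target_rate_hz: float) -> CurrentTrace:
    """FIR decimation (zero phase) to approximately ``target_rate_hz``."""
    fs = 1000.0 / trace.dt_ms
    factor = int(round(fs / target_rate_hz))
    if factor <= 1:
        return trace
    out = signal.decimate(trace.samples, factor, ftype="fir", zero_phase=True)
    return trace.copy_with(out, dt_ms=trace.dt_ms * factor)


def preprocess_trace(trace: CurrentTrace,
                     config: RampAnalysisConfig = RampAnalysisConfig()
                     ) -> CurrentTrace:
    """Band-pass at the acquisition rate, then decimate for correlation."""
    filtered = bandpass_filter(trace, config.low_hz, config.high_hz,
                               config.filter_order)
    return decimate_trace(filtered, config.analysis_rate_hz)


# --------------------------------------------------------------------------
# windowed cross-correlation
# --------------------------------------------------------------------------

def _standardized_windows(x: np.ndarray, wlen: int, step: int):
    win = np.lib.stride_tricks.sliding_window_view(x, wlen)[::step]
    mu = win.mean(axis=1, keepdims=True)
    sd = win.std(axis=1, keepdims=True)
    flat = sd[:, 0] <= 0
    sd = np.where(sd > 0, sd, 1.0)
    return ((win - mu) / sd).astype(np.float32), flat


def windowed_crosscorr(trace_a: CurrentTrace, trace_b: CurrentTrace,
                       window_ms: float = 250.0, step_ms: float = 10.0,
                       max_lag_ms: float = 25.0) -> WindowedCC:
    """Sliding-window normalized cross-correlation between two traces.

    Each 250 ms window (default) of both traces is mean-subtracted and
    scaled to unit variance; the Pearson-type correlation coefficient is
    evaluated at lags within ±``max_lag_ms`` and the (signed) maximum and
    its lag are returned per window. The peak lag is refined below the
    sampling step by 3-point parabolic interpolation. Positive lag means
    trace B follows trace A.

    Windows in which either trace has zero variance get coefficient 0 and
    are flagged ``zero_variance``.
    """
    if abs(trace_a.dt_ms - trace_b.dt_ms) > 1e-12:
        raise ValueError("traces must share the sampling interval")
    if len(trace_a) != len(trace_b):
        raise ValueError("traces must have the same length")
    dt = trace_a.dt_ms
    wlen = int(round(window_ms / dt))
    step = max(int(round(step_ms / dt)), 1)
    lag = int(round(max_lag_ms / dt))
    if wlen > len(trace_a):
        raise ValueError("window longer than trace")
    if lag >= wlen:
        raise ValueError("max lag must be smaller than the window")

    aw, flat_a = _standardized_windows(trace_a.samples, wlen, step)
    bw, flat_b = _standardized_windows(trace_b.samples, wlen, step)
    flat = flat_a | flat_b
    nfft = next_fast_len(wlen + 2 * lag + 1)
    fa = rfft(aw, n=nfft, axis=1)
    fb = rfft(bw, n=nfft, axis=1)
    cc = irfft(np.conj(fa) * fb, n=nfft, axis=1) / wlen
    # lags -lag..+lag: negative lags wrap to the end of the FFT buffer
    cc = np.concatenate([cc[:, nfft - lag:], cc[:, :lag + 1]], axis=1)

    k = np.argmax(cc, axis=1)
    rows = np.arange(cc.shape[0])
    peak = cc[rows, k].astype(float)
    lag_samples = (k - lag).astype(float)
    # parabolic refinement where the peak is interior
    interior = (k > 0) & (k < cc.shape[1] - 1)
    if interior.any():
        km, kp = k[interior] - 1, k[interior] + 1
        r = rows[interior]
        y0, y1, y2 = cc[r, km], cc[r, k[interior]], cc[r, kp]
        denom = y0 - 2 * y1 + y2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        lag_samples[interior] = k[interior] - lag + delta
        peak[interior] = y1 - 0.25 * (y0 - y2) * delta
    peak = np.clip(peak, -1.0, 1.0)
    peak[flat] = 0.0
    lag_samples[flat] = 0.0

    starts = trace_a.t0_ms + np.arange(cc.shape[0]) * step * dt
    table = pd.DataFrame({
        "window_start_ms": starts,
        "peak_coeff": peak,
        "peak_lag_ms": lag_samples * dt,
        "zero_variance": flat,
    })
    return WindowedCC(table, window_ms, step_ms, max_lag_ms)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; shrinks symmetrically at the edges so a
    constant series is preserved exactly."""
    if width <= 1:
        return x.astype(float)
    return (pd.Series(x).rolling(width, center=True, min_periods=1)
            .mean().to_numpy())


def summarize_pair(trial_wccs: Sequence[WindowedCC],
                   pair_id: str = "",
                   smooth_windows: int = 5,
                   photo_window_ms: Optional[Tuple[float, float]] = None,
                   distance_um: float = np.nan,
                   axis: str = "",
                   condition: str = "") -> PairMetrics:
    """Collapse per-trial windowed cross-correlations into pair metrics.

    ``cc_peak_mean``: trial-mean peak coefficient per window, smoothed by a
    centered moving average over ``smooth_windows`` windows, maximized over
    the photo-stimulation interval. ``cc_lag_var``: across-trial standard
    deviation of the peak lag per window (population sd), smoothed the same
    way, minimized over the interval, then squared (ms^2).
    """
    if len(trial_wccs) < 2:
        raise ValueError("need at least two trials")
    counts = {w.n_windows for w in trial_wccs}
    if len(counts) != 1:
        raise ValueError(f"trials disagree on window count: {sorted(counts)}")

    peaks = np.vstack([w.table["peak_coeff"].to_numpy() for w in trial_wccs])
    lags = np.vstack([w.table["peak_lag_ms"].to_numpy() for w in trial_wccs])
    starts = trial_wccs[0].table["window_start_ms"].to_numpy()

    mean_peak = _smooth(peaks.mean(axis=0), smooth_windows)
    lag_sd = _smooth(lags.std(axis=0, ddof=0), smooth_windows)

    if photo_window_ms is not None:
        lo, hi = photo_window_ms
        mask = (starts >= lo) & (starts <= hi)
        if not mask.any():
            raise ValueError("photo-stimulation window excludes all windows")
    else:
        mask = np.ones_like(starts, dtype=bool)

    return PairMetrics(
        pair_id=pair_id,
        cc_peak_mean=float(mean_peak[mask].max()),
        cc_lag_var=float(lag_sd[mask].min() ** 2),
        distance_um=distance_um, axis=axis, condition=condition,
    )


def pair_metrics(traces_a: Sequence[CurrentTrace],
                 traces_b: Sequence[CurrentTrace],
                 config: RampAnalysisConfig = RampAnalysisConfig(),
                 pair_id: str = "",
                 preprocessed: bool = False,
                 stim_duration_ms: Optional[float] = None,
                 **summary_kwargs) -> PairMetrics:
    """Full chain for one pair: preprocess, window-correlate each trial,
    summarize. ``traces_a[i]`` and ``traces_b[i]`` must be simultaneous.
    """
    if len(traces_a) != len(traces_b):
        raise ValueError("need matched trial lists")
    if not preprocessed:
        traces_a = [preprocess_trace(t, config) for t in traces_a]
        traces_b = [preprocess_trace(t, config) for t in traces_b]
    wccs = [windowed_crosscorr(a, b, config.window_ms, config.step_ms,
                               config.max_lag_ms)
            for a, b in zip(traces_a, traces_b)]
    photo = None
    if stim_duration_ms is not None:
        photo = (0.0, stim_duration_ms + config.photo_margin_ms)
    return summarize_pair(wccs, pair_id=pair_id,
                          smooth_windows=config.smooth_windows,
                          photo_window_ms=photo, **summary_kwargs)


# --------------------------------------------------------------------------
# shuffled-pair null and classification
# --------------------------------------------------------------------------

@dataclass
class RecordingSession:
    """Traces from one recording: cell id -> per-trial preprocessed traces.

    Used to assemble the shuffled-pair null; traces should already have
    been through :func:`preprocess_trace`.
    """

    recording_id: str
    traces: Dict[str, List[CurrentTrace]]

    def cells(self) -> List[str]:
        return sorted(self.traces)


def shuffle_null(sessions: Sequence[RecordingSession],
                 n_pairs: int = 1000,
                 percentile: float = 95.0,
                 seed: int = 0,
                 config: RampAnalysisConfig = RampAnalysisConfig(),
                 stim_duration_ms: Optional[float] = None,
                 return_metrics: bool = False):
    """Null thresholds from synthetic pairs assembled across recordings.

    Each shuffled pair takes one cell from one recording and one cell from
    a different recording, so stimulus-locked structure survives but any
    genuinely shared input is destroyed. The peak threshold is the upper
    ``percentile`` of the shuffled ``cc_peak_mean``; the lag-variance
    threshold is the matching lower percentile (100 - ``percentile``) of
    the shuffled ``cc_lag_var``.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two recordings for a shuffled null")
    rng = np.random.default_rng(seed)
    metrics = _shuffled_metrics(sessions, n_pairs, rng, config,
                                stim_duration_ms)
    peaks = np.array([m.cc_peak_mean for m in metrics])
    lvars = np.array([m.cc_lag_var for m in metrics])
    thresholds = thresholds_from_metrics(peaks, lvars, percentile)
    if return_metrics:
        return thresholds, metrics_frame(metrics)
    return thresholds


def thresholds_from_metrics(peaks: np.ndarray, lag_vars: np.ndarray,
                            percentile: float = 95.0) -> NullThresholds:
    """Percentile thresholds from shuffled-pair metric samples: upper tail
    for the peak coefficient, matching lower tail for the lag variance."""
    return NullThresholds(
        peak_threshold=float(np.percentile(peaks, percentile)),
        lag_var_threshold=float(np.percentile(lag_vars, 100.0 - percentile)),
        n_pairs=len(np.asarray(peaks)), percentile=percentile)


def _shuffled_metrics(sessions, n_pairs, rng, config, stim_duration_ms):
    metrics = []
    n_sessions = len(sessions)
    for k in range(n_pairs):
        i, j = rng.choice(n_sessions, size=2, replace=False)
        sa, sb = sessions[i], sessions[j]
        ca = sa.cells()[rng.integers(len(sa.cells()))]
        cb = sb.cells()[rng.integers(len(sb.cells()))]
        ta, tb = sa.traces[ca], sb.traces[cb]
        n_tr = min(len(ta), len(tb))
        m = pair_metrics(ta[:n_tr], tb[:n_tr], config=config,
                         pair_id=f"shuf{k:04d}", preprocessed=True,
                         stim_duration_ms=stim_duration_ms)
        m.condition = f"{sa.recording_id}|{sb.recording_id}"
        metrics.append(m)
    return metrics


def classify_pairs(metrics: pd.DataFrame, thresholds: NullThresholds
                   ) -> pd.Series:
    """Label each pair 'coordinated' iff cc_peak_mean exceeds the peak
    threshold AND cc_lag_var falls below the lag-variance threshold."""
    coord = ((metrics["cc_peak_mean"] > thresholds.peak_threshold)
             & (metrics["cc_lag_var"] < thresholds.lag_var_threshold))
    return pd.Series(np.where(coord, "coordinated", "uncoordinated"),
                     index=metrics.index, name="classification")


def classify_pairs_kmeans(metrics: pd.DataFrame, k: int = 2, seed: int = 0,
                          n_init: int = 50) -> Tuple[pd.Series, bool]:
    """k-means corroboration of the threshold classification.

    Clusters standardized (cc_peak_mean, cc_lag_var); the cluster with the
    higher mean cc_peak_mean is labelled 'coordinated'. Returns
    ``(labels, degenerate)`` where ``degenerate`` is True when the points
    cannot support k distinct clusters (e.g. all identical).
    """
    if len(metrics) < k:
        raise ValueError(f"need at least {k} pairs")
    X = metrics[["cc_peak_mean", "cc_lag_var"]].to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        labels = pd.Series("uncoordinated", index=metrics.index,
                           name="classification")
        return labels, True
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xs)
    assign = km.labels_
    degenerate = len(np.unique(assign)) < k
    means = [X[assign == c, 0].mean() if (assign == c).any() else -np.inf
             for c in range(k)]
    coord_cluster = int(np.argmax(means))
    labels = pd.Series(np.where(assign == coord_cluster, "coordinated",
                                "uncoordinated"),
                       index=metrics.index, name="classification")
    return labels, degenerate


def condition_delta(metrics_control: pd.DataFrame,
                    metrics_treatment: pd.DataFrame) -> pd.DataFrame:
    """Per-pair change in cc_peak_mean between two conditions.

    Returns one row per pair present in either condition with columns
    ``delta_cc_peak_mean`` (treatment - control), the per-condition values
    and classifications, distance, and ``status`` ('paired', or which
    condition is missing). Missing pairs keep NaN deltas rather than 0.
    """
    cols = ["pair_id", "cc_peak_mean", "cc_lag_var", "distance_um",
            "classification"]
    c = metrics_control[[x for x in cols if x in metrics_control]].copy()
    t = metrics_treatment[[x for x in cols if x in metrics_treatment]].copy()
    merged = c.merge(t, on="pair_id", how="outer",
                     suffixes=("_control", "_treatment"))
    merged["delta_cc_peak_mean"] = (merged["cc_peak_mean_treatment"]
                                    - merged["cc_peak_mean_control"])
    status = np.where(merged["cc_peak_mean_control"].isna(),
                      "missing_in_control",
                      np.where(merged["cc_peak_mean_treatment"].isna(),
                               "missing_in_treatment", "paired"))
    merged["status"] = status
    if "distance_um_control" in merged:
        merged["distance_um"] = merged["distance_um_control"].fillna(
            merged.get("distance_um_treatment"))
    return merged


@dataclass(frozen=True)
class DistanceFit:
    """OLS fit of a pair metric against inter-soma distance."""

    slope: float
    intercept: float
    r2_adj: float
    p_value: float
    n: int


def fit_distance_dependence(metrics: pd.DataFrame,
                            metric: str = "cc_peak_mean",
                            distance: str = "distance_um") -> DistanceFit:
    """Ordinary least-squares line of ``metric`` on ``distance`` with
    adjusted R^2 and the F-test p-value (identical to the slope t-test for
    a single regressor)."""
    sub = metrics[[distance, metric]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three pairs with distances")
    y = sub[metric].to_numpy(dtype=float)
    x = sub[distance].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return DistanceFit(0.0, float(y[0]), 0.0, 1.0, len(y))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return DistanceFit(slope=float(res.params[1]),
                       intercept=float(res.params[0]),
                       r2_adj=float(res.rsquared_adj),
                       p_value=float(res.f_pvalue),
                       n=int(res.nobs))
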