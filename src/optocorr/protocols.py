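"""Stimulation protocols for widefield (ramp) and focal (grid) optogenetic mapping.

Two protocols are modelled. The widefield protocol is a slow ramp of light
intensity that recruits channelrhodopsin-expressing presynaptic cells
asynchronously, in order of their intensity thresholds. The focal protocol
scans a brief laser pulse over a rectangular grid of sites, one site at a
time, in a fresh pseudorandom order on every repeat.

All times are milliseconds from stimulus onset; positions are micrometres.
Axis 1 is dorsoventral, axis 2 mediolateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["RampProtocol", "FocalGridProtocol"]


@dataclass(frozen=True)
class RampProtocol:
    """Ramp-modulated widefield light stimulus.

    Parameters
    ----------
    duration_s : float
        Stimulus duration in seconds (default 8).
    final_intensity : float
        Intensity reached at the end of the ramp, in relative units
        (default 1.0). Cell thresholds are expressed on the same scale.
    repeats : int
        Number of trials (default 5).
    profile : callable, optional
        Monotone non-decreasing map from normalized time in [0, 1] to
        normalized intensity in [0, 1] with profile(0) = 0. Defaults to a
        linear ramp.
    """

    duration_s: float = 8.0
    final_intensity: float = 1.0
    repeats: int = 5
    profile: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("ramp duration must be positive")
        if self.final_intensity <= 0:
            raise ValueError("final intensity must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        i = self.intensity(np.array([0.0]))
        if abs(float(i[0])) > 1e-12:
            raise ValueError("intensity profile must start at 0")

    @property
    def duration_ms(self) -> float:
        return self.duration_s * 1000.0

    def intensity(self, t_ms) -> np.ndarray:
        """Light intensity at time(s) ``t_ms`` (0 outside the stimulus)."""
        t = np.asarray(t_ms, dtype=float)
        u = np.clip(t / self.duration_ms, 0.0, 1.0)
        shape = self.profile(u) if self.profile is not None else u
        out = np.where((t >= 0) & (t <= self.duration_ms),
                       self.final_intensity * shape, 0.0)
        return out

    def threshold_crossing_ms(self, threshold: float) -> float:
        """First time the ramp exceeds ``threshold`` (inf if never).

        Solved on a 1 ms grid followed by local bisection, so arbitrary
        monotone profiles are supported.
        """
        if threshold >= self.final_intensity:
            i_end = self.intensity(np.array([self.duration_ms]))[0]
            return self.duration_ms if i_end >= threshold else np.inf
        t = np.arange(0.0, self.duration_ms + 1.0, 1.0)
        above = self.intensity(t) >= threshold
        if not above.any():
            return np.inf
        k = int(np.argmax(above))
        if k == 0:
            return 0.0
        lo, hi = t[k - 1], t[k]
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if self.intensity(np.array([mid]))[0] >= threshold:
                hi = mid
            else:
                lo = mid
        return hi


@dataclass(frozen=True)
class FocalGridProtocol:
    """Serial focal laser scanning over a rows x columns grid.

    Sites are spaced ``spacing_um`` apart along rows and columns. Each
    repeat visits every site exactly once in a pseudorandom order; the
    pulse train runs at ``sites_per_second``.
    """

    rows: int = 10
    cols: int = 7
    spacing_um: float = 20.0
    pulse_ms: float = 1.0
    sites_per_second: float = 5.0
    repeats: int = 10
    intensity: float = 1.0
    center_um: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.spacing_um <= 0:
            raise ValueError("site spacing must be positive")
        if self.sites_per_second <= 0:
            raise ValueError("sites_per_second must be positive")

    @property
    def n_sites(self) -> int:
        return self.rows * self.cols

    @property
    def span_um(self) -> tuple:
        """(dorsoventral span, mediolateral span) of the scanning area.

        Rows advance along axis 1 (dorsoventral), columns along axis 2,
        so the default 10 x 7 grid at 20 µm spacing scans 180 µm x 120 µm.
        """
        return ((self.rows - 1) * self.spacing_um,
                (self.cols - 1) * self.spacing_um)

    @property
    def inter_pulse_ms(self) -> float:
        return 1000.0 / self.sites_per_second

    @property
    def repeat_duration_ms(self) -> float:
        return self.n_sites * self.inter_pulse_ms

    def site_positions(self) -> np.ndarray:
        """(rows*cols, 2) array of site centres in µm, grid centred on
        ``center_um``; ordering is row-major."""
        r = np.arange(self.rows) * self.spacing_um
        c = np.arange(self.cols) * self.spacing_um
        r = r - r.mean() + self.center_um[0]
        c = c - c.mean() + self.center_um[1]
        rr, cc = np.meshgrid(r, c, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def site_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"site ({row}, {col}) outside grid")
        return row * self.cols + col

    def site_order(self, repeat: int, seed: int) -> np.ndarray:
        """Pseudorandom visiting order of site indices for one repeat.

        Deterministic in (seed, repeat); every site appears exactly once.
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, repeat]))
        return rng.permutation(self.n_sites)

    def pulse_schedule(self, seed: int):
        """Yield (repeat, pulse_time_ms, site_row, site_col) for all pulses.

        Pulse times are relative to the start of each repeat.
        """
        for rep in range(self.repeats):
            order = self.site_order(rep, seed)
            for k, site in enumerate(order):
                yield rep, k * self.inter_pulse_ms, site // self.cols, site % self.cols
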