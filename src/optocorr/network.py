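"""Ground-truth bipartite connectivity between a presynaptic population and
recorded postsynaptic cells.

The central design is the "convergence with controlled overlap" experiment:
two postsynaptic cells each receive a fixed number of presynaptic inputs
while the number of inputs they share is varied. The shared-input count is
the ground truth that the correlation analyses attempt to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GroundTruthNetwork", "generate_network"]

PRE_COLUMNS = ["cell_id", "pos_dv_um", "pos_ml_um", "threshold", "peak_rate_hz"]
POST_COLUMNS = ["cell_id", "pos_dv_um", "pos_ml_um", "cell_class"]
ADJ_COLUMNS = ["pre_id", "post_id", "weight"]


@dataclass
class GroundTruthNetwork:
    """Bipartite pre -> post network with per-connection weights.

    Attributes
    ----------
    pre : DataFrame
        Columns ``cell_id, pos_dv_um, pos_ml_um, threshold, peak_rate_hz``.
        ``threshold`` is the light intensity (relative units) above which
        the cell can fire; ``peak_rate_hz`` its saturating firing rate.
    post : DataFrame
        Columns ``cell_id, pos_dv_um, pos_ml_um, cell_class``.
    adjacency : DataFrame
        Columns ``pre_id, post_id, weight`` with ``weight > 0``.
    """

    pre: pd.DataFrame
    post: pd.DataFrame
    adjacency: pd.DataFrame

    def __post_init__(self) -> None:
        self.pre = pd.DataFrame(self.pre, columns=PRE_COLUMNS)
        self.post = pd.DataFrame(self.post, columns=POST_COLUMNS)
        self.adjacency = pd.DataFrame(self.adjacency, columns=ADJ_COLUMNS)
        self.validate()

    def validate(self) -> None:
        if self.pre["cell_id"].duplicated().any():
            raise ValueError("duplicate presynaptic cell ids")
        if self.post["cell_id"].duplicated().any():
            raise ValueError("duplicate postsynaptic cell ids")
        pre_ids = set(self.pre["cell_id"])
        post_ids = set(self.post["cell_id"])
        bad_pre = set(self.adjacency["pre_id"]) - pre_ids
        bad_post = set(self.adjacency["post_id"]) - post_ids
        if bad_pre or bad_post:
            raise ValueError(
                f"adjacency references unknown cells: pre={sorted(bad_pre)}, "
                f"post={sorted(bad_post)}")
        if (self.adjacency["weight"] <= 0).any():
            raise ValueError("connection weights must be positive")

    def presynaptic_ids(self, post_id) -> set:
        sel = self.adjacency.loc[self.adjacency["post_id"] == post_id, "pre_id"]
        return set(sel)

    def shared_input_count(self, post_a, post_b) -> int:
        """Number of presynaptic cells projecting to both ``post_a`` and
        ``post_b``, recomputed from the adjacency table."""
        return len(self.presynaptic_ids(post_a) & self.presynaptic_ids(post_b))

    def pair_distance_um(self, post_a, post_b, axis: str = "euclidean") -> float:
        p = self.post.set_index("cell_id")
        a, b = p.loc[post_a], p.loc[post_b]
        d_dv = b["pos_dv_um"] - a["pos_dv_um"]
        d_ml = b["pos_ml_um"] - a["pos_ml_um"]
        if axis == "dorsoventral":
            return abs(float(d_dv))
        if axis == "mediolateral":
            return abs(float(d_ml))
        return float(np.hypot(d_dv, d_ml))

    # ---- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "pre": self.pre.to_dict(orient="records"),
            "post": self.post.to_dict(orient="records"),
            "adjacency": self.adjacency.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["pre"]),
                   pd.DataFrame(payload["post"]),
                   pd.DataFrame(payload["adjacency"]))


def _draw_thresholds(rng: np.random.Generator, n: int, final_intensity: float,
                     median: float, sigma: float) -> np.ndarray:
    """Log-normal thresholds folded into (0, final_intensity].

    A log-normal gives staggered recruitment along the ramp; values above
    the final intensity are redrawn uniformly in the upper half so every
    generated cell is recruitable by default.
    """
    th = rng.lognormal(mean=np.log(median * final_intensity), sigma=sigma, size=n)
    high = th > final_intensity
    th[high] = rng.uniform(0.5 * final_intensity, final_intensity, high.sum())
    return np.clip(th, 1e-6, final_intensity)


def generate_network(
    n_pre: int,
    n_post: int = 2,
    inputs_per_post: int = 8,
    n_shared: int = 0,
    spatial_layout: Optional[dict] = None,
    seed: int = 0,
    weight: float = 1.0,
    weight_cv: float = 0.0,
    threshold_median: float = 0.4,
    threshold_sigma: float = 0.5,
    peak_rate_hz: tuple = (15.0, 25.0),
) -> GroundTruthNetwork:
    """Generate a seeded ground-truth network with a designated pair.

    The first two postsynaptic cells are the designated pair: each receives
    exactly ``inputs_per_post`` presynaptic partners and their presynaptic
    sets intersect in exactly ``n_shared`` cells. Additional postsynaptic
    cells receive ``inputs_per_post`` partners drawn at random.

    Parameters
    ----------
    spatial_layout : dict, optional
        ``{"pre_extent_um": (dv, ml), "post_positions_um": [(dv, ml), ...]}``.
        Presynaptic somata are scattered uniformly over the extent centred
        on the origin; postsynaptic positions default to 100 µm spacing
        along the dorsoventral axis.
    weight, weight_cv : float
        Mean connection weight and optional log-normal coefficient of
        variation (0 = identical weights).

    Raises
    ------
    ValueError
        If the overlap design is infeasible for the given ``n_pre``.
    """
    if not (0 <= n_shared <= inputs_per_post):
        raise ValueError("need 0 <= n_shared <= inputs_per_post")
    if inputs_per_post > n_pre:
        raise ValueError("inputs_per_post exceeds number of presynaptic cells")
    need = 2 * inputs_per_post - n_shared
    if n_post >= 2 and need > n_pre:
        raise ValueError(
            f"infeasible overlap design: 2*{inputs_per_post} - {n_shared} = "
            f"{need} distinct presynaptic cells required but n_pre={n_pre}")
    if n_post < 1:
        raise ValueError("need at least one postsynaptic cell")

    rng = np.random.default_rng(seed)
    layout = spatial_layout or {}
    extent = layout.get("pre_extent_um", (300.0, 300.0))
    pre_pos = rng.uniform(-0.5, 0.5, size=(n_pre, 2)) * np.asarray(extent)
    thresholds = _draw_thresholds(rng, n_pre, 1.0, threshold_median, threshold_sigma)
    rates = rng.uniform(peak_rate_hz[0], peak_rate_hz[1], size=n_pre)
    pre = pd.DataFrame({
        "cell_id": [f"pre{i:03d}" for i in range(n_pre)],
        "pos_dv_um": pre_pos[:, 0],
        "pos_ml_um": pre_pos[:, 1],
        "threshold": thresholds,
        "peak_rate_hz": rates,
    })

    default_post = [(100.0 * i, 0.0) for i in range(n_post)]
    post_pos = layout.get("post_positions_um", default_post)
    if len(post_pos) != n_post:
        raise ValueError("post_positions_um length must equal n_post")
    post = pd.DataFrame({
        "cell_id": [f"post{i:02d}" for i in range(n_post)],
        "pos_dv_um": [p[0] for p in post_pos],
        "pos_ml_um": [p[1] for p in post_pos],
        "cell_class": ["recorded"] * n_post,
    })

    pre_ids = pre["cell_id"].to_numpy()
    rows = []

    def _weights(k: int) -> np.ndarray:
        if weight_cv <= 0:
            return np.full(k, weight)
        sigma = np.sqrt(np.log(1.0 + weight_cv ** 2))
        return weight * rng.lognormal(-0.5 * sigma ** 2, sigma, size=k)

    if n_post >= 2:
        picks = rng.choice(n_pre, size=need, replace=False)
        shared = picks[:n_shared]
        own_a = picks[n_shared:inputs_per_post]
        own_b = picks[inputs_per_post:]
        set_a = np.concatenate([shared, own_a]).astype(int)
        set_b = np.concatenate([shared, own_b]).astype(int)
        for post_id, chosen in (("post00", set_a), ("post01", set_b)):
            w = _weights(len(chosen))
            rows += [(pre_ids[j], post_id, w[k]) for k, j in enumerate(chosen)]
        others = range(2, n_post)
    else:
        chosen = rng.choice(n_pre, size=inputs_per_post, replace=False)
        w = _weights(len(chosen))
        rows += [(pre_ids[j], "post00", w[k]) for k, j in enumerate(chosen)]
        others = range(1, 1)

    for i in others:
        chosen = rng.choice(n_pre, size=inputs_per_post, replace=False)
        w = _weights(len(chosen))
        rows += [(pre_ids[j], f"post{i:02d}", w[k]) for k, j in enumerate(chosen)]

    adjacency = pd.DataFrame(rows, columns=ADJ_COLUMNS)
    net = GroundTruthNetwork(pre, post, adjacency)
    if n_post >= 2:
        assert net.shared_input_count("post00", "post01") == n_shared
    return net
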