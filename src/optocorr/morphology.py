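"""SWC morphology analytics: per-layer neurite lengths, maximal axis
extents, voxel length-density grids, the normalized axo-dendritic overlap
ratio, and a seeded generator of synthetic neurite trees.

Conventions: axis 1 (x) is dorsoventral, axis 2 (y) mediolateral, axis 3
(z) the cortical-depth axis along which layer boundaries are defined as
parallel planes. All positions and lengths are micrometres. Segment-voxel
and segment-layer apportioning use exact geometric clipping, so summed
densities and layer lengths conserve total neurite length to floating
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Morphology", "DensityGrid", "MorphologyParams", "read_swc", "write_swc",
    "layer_lengths", "max_extent", "voxel_density", "overlap_integral",
    "overlap_ratio", "generate_synthetic_morphology",
]

NODE_COLUMNS = ["id", "type_code", "x", "y", "z", "radius", "parent"]

DEFAULT_TYPE_MAP = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}

AXIS_INDEX = {"dorsoventral": 0, "x": 0, "mediolateral": 1, "y": 1,
              "depth": 2, "z": 2}


@dataclass
class Morphology:
    """Validated SWC-style neurite tree.

    ``nodes`` columns: id, type_code, x, y, z, radius, parent (-1 for the
    root). ``compartment`` is derived from ``type_code`` via ``type_map``.
    Metadata may carry the slice plane and layer boundary positions.
    """

    nodes: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    type_map: Dict[int, str] = field(default_factory=lambda: dict(DEFAULT_TYPE_MAP))

    def __post_init__(self) -> None:
        self.nodes = pd.DataFrame(self.nodes, columns=NODE_COLUMNS)
        self.validate()
        self.nodes["compartment"] = [
            self.type_map.get(int(t), "other")
            for t in self.nodes["type_code"]]

    def validate(self) -> None:
        n = self.nodes
        if not np.isfinite(n[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite node coordinates")
        ids = n["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        roots = (n["parent"] == -1).sum()
        if roots != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        seen = set()
        for _, row in n.iterrows():
            pid = int(row["parent"])
            nid = int(row["id"])
            if pid != -1 and pid not in seen:
                raise ValueError(
                    f"node {nid}: parent {pid} missing or appears later "
                    "(parent must precede child)")
            seen.add(nid)

    # ---- geometry ------------------------------------------------------
    def segments(self, compartment: Optional[str] = None) -> np.ndarray:
        """(n_segments, 2, 3) array of (parent xyz, child xyz); the child
        node's compartment labels the segment."""
        n = self.nodes
        child = n[n["parent"] != -1]
        if compartment is not None:
            child = child[child["compartment"] == compartment]
        if not len(child):
            return np.zeros((0, 2, 3))
        pos = n.set_index("id")[["x", "y", "z"]]
        p0 = pos.loc[child["parent"]].to_numpy(dtype=float)
        p1 = child[["x", "y", "z"]].to_numpy(dtype=float)
        return np.stack([p0, p1], axis=1)

    def total_length(self, compartment: Optional[str] = None) -> float:
        seg = self.segments(compartment)
        if not len(seg):
            return 0.0
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())

    @property
    def soma_position(self) -> np.ndarray:
        root = self.nodes[self.nodes["parent"] == -1].iloc[0]
        return root[["x", "y", "z"]].to_numpy(dtype=float)

    def translated(self, offset_um: Sequence[float]) -> "Morphology":
        out = self.nodes.copy()
        out[["x", "y", "z"]] = out[["x", "y", "z"]].to_numpy() \
            + np.asarray(offset_um, dtype=float)
        return Morphology(out[NODE_COLUMNS], dict(self.metadata),
                          dict(self.type_map))


def read_swc(path, type_map: Optional[Dict[int, str]] = None) -> Morphology:
    """Parse an SWC file into a validated :class:`Morphology`.

    Raises ``ValueError`` naming the offending node for cyclic, orphaned
    or out-of-order parents.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 SWC fields, "
                                 f"got {len(parts)}")
            rows.append([int(parts[0]), int(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5]),
                         int(parts[6])])
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return Morphology(nodes, metadata={"source": str(path)},
                      type_map=type_map or dict(DEFAULT_TYPE_MAP))


def write_swc(morph: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for _, r in morph.nodes.iterrows():
            fh.write(f"{int(r['id'])} {int(r['type_code'])} "
                     f"{r['x']:.17g} {r['y']:.17g} {r['z']:.17g} "
                     f"{r['radius']:.6g} {int(r['parent'])}\n")


# --------------------------------------------------------------------------
# layer lengths and extents
# --------------------------------------------------------------------------

def layer_lengths(morph: Morphology, boundaries: Sequence[float],
                  compartment: str, depth_axis: str = "z") -> np.ndarray:
    """Neurite length per layer, clipping segments at boundary planes.

    ``boundaries`` are strictly increasing positions along the depth axis;
    the returned vector has ``len(boundaries) + 1`` entries covering
    (-inf, b0), [b0, b1), ..., [b_last, inf). Lengths sum to the total
    compartment length by construction.
    """
    b = np.asarray(boundaries, dtype=float)
    if len(b) and not (np.diff(b) > 0).all():
        raise ValueError("layer boundaries must be strictly increasing")
    ax = AXIS_INDEX[depth_axis]
    out = np.zeros(len(b) + 1)
    seg = morph.segments(compartment)
    if not len(seg):
        return out
    lengths = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
    z0 = seg[:, 0, ax]
    z1 = seg[:, 1, ax]
    zmin, zmax = np.minimum(z0, z1), np.maximum(z0, z1)
    edges = np.concatenate([[-np.inf], b, [np.inf]])
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        span = zmax - zmin
        flat = span <= 0
        frac = np.zeros(len(seg))
        with np.errstate(invalid="ignore", divide="ignore"):
            ov = np.clip(np.minimum(zmax, hi) - np.maximum(zmin, lo), 0, None)
            frac[~flat] = ov[~flat] / span[~flat]
        # segments parallel to the boundary planes fall wholly in one layer
        frac[flat] = ((zmin[flat] >= lo) & (zmin[flat] < hi)).astype(float)
        out[i] += float((frac * lengths).sum())
    return out


def max_extent(morph: Morphology, axis: str, compartment: str,
               layer_bounds: Optional[Tuple[float, float]] = None,
               depth_axis: str = "z") -> float:
    """Max minus min coordinate along ``axis`` over a compartment's
    segment endpoints, optionally restricted to points whose depth lies in
    ``layer_bounds``. Falls back to bare nodes for a segment-free
    compartment (e.g. an isolated soma)."""
    seg = morph.segments(compartment)
    if len(seg):
        coords = seg.reshape(-1, 3)
    else:
        n = morph.nodes[morph.nodes["compartment"] == compartment]
        if not len(n):
            raise ValueError(f"no nodes of compartment {compartment!r}")
        coords = n[["x", "y", "z"]].to_numpy(dtype=float)
    if layer_bounds is not None:
        lo, hi = layer_bounds
        depth = coords[:, AXIS_INDEX[depth_axis]]
        coords = coords[(depth >= lo) & (depth < hi)]
        if not len(coords):
            return 0.0
    v = coords[:, AXIS_INDEX[axis]]
    return float(v.max() - v.min())


# --------------------------------------------------------------------------
# voxel densities and overlap
# --------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Per-voxel neurite length (µm) on a cubic grid.

    ``origin`` is the position of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_um: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        if (self.data < -1e-9).any():
            raise ValueError("densities must be non-negative")

    @property
    def total_length(self) -> float:
        return float(self.data.sum())


def voxel_density(morph: Morphology, compartment: str,
                  voxel_um: float = 5.0,
                  origin: Optional[Sequence[float]] = None) -> DensityGrid:
    """Exact per-voxel neurite length for one compartment.

    Every segment is split at each grid-plane crossing and each piece is
    credited to the voxel containing its midpoint, so the grid sum equals
    the total compartment length to floating tolerance.
    """
    seg = morph.segments(compartment)
    if not len(seg):
        raise ValueError(f"morphology has no {compartment!r} segments")
    pts = seg.reshape(-1, 3)
    if origin is None:
        origin = np.floor(pts.min(axis=0) / voxel_um) * voxel_um
    origin = np.asarray(origin, dtype=float)
    shape = np.maximum(
        np.ceil((pts.max(axis=0) - origin) / voxel_um).astype(int) + 1, 1)
    grid = np.zeros(tuple(shape))

    for p0, p1 in seg:
        d = p1 - p0
        length = float(np.linalg.norm(d))
        if length == 0.0:
            continue
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            lo = min(p0[ax], p1[ax])
            hi = max(p0[ax], p1[ax])
            k0 = math.ceil((lo - origin[ax]) / voxel_um)
            k1 = math.floor((hi - origin[ax]) / voxel_um)
            for k in range(k0, k1 + 1):
                t = (origin[ax] + k * voxel_um - p0[ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts = np.unique(np.asarray(ts))
        mids = p0 + np.outer(0.5 * (ts[:-1] + ts[1:]), d)
        idx = np.floor((mids - origin) / voxel_um).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        pieces = np.diff(ts) * length
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), pieces)
    return DensityGrid(grid, voxel_um, origin)


def overlap_integral(grid_a: DensityGrid, grid_b: DensityGrid,
                     offset_um: Sequence[float] = (0.0, 0.0, 0.0)) -> float:
    """Sum over voxels of the product of two densities, with grid B
    translated by ``offset_um`` (rounded to whole voxels)."""
    if abs(grid_a.voxel_um - grid_b.voxel_um) > 1e-9:
        raise ValueError("grids must share the voxel size")
    v = grid_a.voxel_um
    shift = (grid_b.origin + np.asarray(offset_um, dtype=float)
             - grid_a.origin) / v
    shift_int = np.round(shift).astype(int)
    a, b = grid_a.data, grid_b.data
    total = 0.0
    # overlap of index ranges: voxel ib in B aligns with ia = ib + shift
    lo_a = np.maximum(shift_int, 0)
    hi_a = np.minimum(np.array(a.shape), np.array(b.shape) + shift_int)
    if (hi_a <= lo_a).any():
        return 0.0
    sl_a = tuple(slice(lo, hi) for lo, hi in zip(lo_a, hi_a))
    sl_b = tuple(slice(lo - s, hi - s)
                 for lo, hi, s in zip(lo_a, hi_a, shift_int))
    return float((a[sl_a] * b[sl_b]).sum())


def overlap_ratio(pre_axon: DensityGrid,
                  post_a_dendrite: DensityGrid,
                  post_b_dendrite: DensityGrid,
                  offset_a_um: Sequence[float] = (0.0, 0.0, 0.0),
                  offset_b_um: Sequence[float] = (0.0, 0.0, 0.0),
                  combine: str = "geometric") -> float:
    """Normalized triplet axo-dendritic overlap.

    Each pairwise overlap (presynaptic axon density x postsynaptic
    dendrite density, summed over voxels) is normalized by its co-somatic
    value, i.e. the overlap at zero offset; the grids must therefore be
    built in soma-centred frames so that zero offset co-locates the somata.
    The two normalized overlaps are combined by their geometric mean
    (``combine='mean'`` selects the arithmetic mean). Whenever either
    pairwise overlap is non-positive the ratio is 0. A zero co-somatic
    normalizer makes the ratio undefined and NaN is returned.
    """
    o0_a = overlap_integral(pre_axon, post_a_dendrite)
    o0_b = overlap_integral(pre_axon, post_b_dendrite)
    if o0_a <= 0 or o0_b <= 0:
        return float("nan")
    o_a = overlap_integral(pre_axon, post_a_dendrite, offset_a_um)
    o_b = overlap_integral(pre_axon, post_b_dendrite, offset_b_um)
    if o_a <= 0 or o_b <= 0:
        return 0.0
    ra, rb = o_a / o0_a, o_b / o0_b
    if combine == "geometric":
        return float(np.sqrt(ra * rb))
    if combine == "mean":
        return float(0.5 * (ra + rb))
    raise ValueError("combine must be 'geometric' or 'mean'")


# --------------------------------------------------------------------------
# synthetic morphology generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyParams:
    """Parameters of the synthetic neurite-tree generator.

    Branches are persistent random walks from the soma; ``depth_band``
    softly confines growth along the depth axis, emulating the laminar
    restriction of real arbors.
    """

    soma_position: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_axon_branches: int = 3
    n_dendrite_branches: int = 4
    segments_per_branch: int = 30
    segment_length_um: float = 8.0
    segment_length_sd_um: float = 2.0
    direction_persistence: float = 0.8
    depth_band_um: Tuple[float, float] = (-50.0, 50.0)
    soma_radius_um: float = 6.0

    def __post_init__(self) -> None:
        if self.segment_length_um <= 0:
            raise ValueError("segment length must be positive")
        if self.segment_length_sd_um < 0:
            raise ValueError("segment length sd must be non-negative")
        if self.segments_per_branch < 1:
            raise ValueError("need at least one segment per branch")
        if self.n_axon_branches < 0 or self.n_dendrite_branches < 0:
            raise ValueError("branch counts must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def generate_synthetic_morphology(params: MorphologyParams = MorphologyParams(),
                                  seed: int = 0
                                  ) -> Tuple[Morphology, float]:
    """Seeded synthetic SWC tree; returns (morphology, total length).

    The returned total length is the generator's internal sum of drawn
    segment lengths, against which SWC round-trips can be checked.
    """
    rng = np.random.default_rng(seed)
    soma = np.asarray(params.soma_position, dtype=float)
    rows = [[1, 1, soma[0], soma[1], soma[2], params.soma_radius_um, -1]]
    next_id = 2
    total = 0.0
    plan = ([2] * params.n_axon_branches) + ([3] * params.n_dendrite_branches)
    lo, hi = params.depth_band_um
    for type_code in plan:
        direction = _unit(rng.normal(size=3))
        parent = 1
        pos = soma.copy()
        for _ in range(params.segments_per_branch):
            step = params.segment_length_um
            if params.segment_length_sd_um > 0:
                step = abs(rng.normal(params.segment_length_um,
                                      params.segment_length_sd_um))
                step = max(step, 1e-3)
            wobble = rng.normal(size=3) * (1.0 - params.direction_persistence)
            direction = _unit(params.direction_persistence * direction + wobble)
            # soft confinement to the depth band
            depth = pos[2] - soma[2]
            if depth > hi:
                direction[2] -= 0.5
            elif depth < lo:
                direction[2] += 0.5
            direction = _unit(direction)
            pos = pos + step * direction
            total += step
            rows.append([next_id, type_code, pos[0], pos[1], pos[2],
                         0.5, parent])
            parent = next_id
            next_id += 1
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    morph = Morphology(nodes, metadata={"generator_seed": seed})
    return morph, total
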