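"""Trabecular descriptors computed on a spatial graph.

Eight descriptors characterize the stereom's beam network: chord length
(straight node-to-node distance), curved length (path length along the
centerline), tortuosity (their ratio; 1 for a straight beam), mean radius,
slenderness ratio (length over radius of gyration, g_r = d/4 for a circular
section), inter-trabecular angle (ITA, the angle between the direction
vectors of two segments sharing a node), node configuration (valence), and
the orientation angles theta (against the z-axis, folded to [0°, 90°]) and
phi (azimuth in the horizontal plane, [0°, 360°)).

Summary tables report median ± MAD (unscaled median absolute deviation),
min, max and N, mirroring the conventions of trabecular morphometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Segment, SpatialGraph

#: chords shorter than this (µm) are treated as zero: tortuosity, theta and
#: phi are undefined for them (closed loops survive skeleton cleaning).
CHORD_TOL = 1e-6


# ---------------------------------------------------------------------------
# per-segment scalar descriptors
# ---------------------------------------------------------------------------

def chord_length(segment: Segment) -> float:
    """Straight-line distance between the segment's two endpoints (µm)."""
    return float(np.linalg.norm(segment.points[-1] - segment.points[0]))


def curved_length(segment: Segment) -> float:
    """Path length along the polyline centerline (µm)."""
    d = np.diff(segment.points, axis=0)
    return float(np.sum(np.linalg.norm(d, axis=1)))


def tortuosity(segment: Segment, chord_tol: float = CHORD_TOL) -> float | None:
    """Curved length over chord length; ``None`` for (near-)zero chords."""
    lc = chord_length(segment)
    if lc < chord_tol:
        return None
    return curved_length(segment) / lc


def segment_mean_radius(segment: Segment) -> float:
    """Arithmetic mean of all point radii along the segment (µm)."""
    if segment.radii is None:
        raise ValueError("segment carries no point radii")
    return float(np.mean(segment.radii))


def radius_of_gyration(d_t: float) -> float:
    """g_r = d_t / 4 for a circular cross-section of diameter ``d_t``."""
    return d_t / 4.0


def slenderness_ratio(length: float, g_r: float) -> float:
    """R_S = L / g_r.  ``length`` is the physical beam (curved) length."""
    if g_r <= 0:
        raise ValueError("radius of gyration must be > 0")
    return length / g_r


# ---------------------------------------------------------------------------
# directions and angles
# ---------------------------------------------------------------------------

def segment_direction_at_node(segment: Segment, node_id: int,
                              mode: str = "chord") -> np.ndarray | None:
    """Unit direction of a segment as seen from one of its nodes.

    ``chord`` mode (default) points from the queried node straight to the
    segment's other endpoint; ``tangent`` mode uses the first polyline step
    away from the node.  Returns ``None`` when the direction is undefined
    (zero chord / coincident points).
    """
    if node_id == segment.start:
        a, b = segment.points[0], segment.points[-1]
        step = segment.points[1]
    elif node_id == segment.end:
        a, b = segment.points[-1], segment.points[0]
        step = segment.points[-2]
    else:
        raise ValueError(f"node {node_id} is not an endpoint of segment {segment.id}")
    v = (step - a) if mode == "tangent" else (b - a)
    norm = np.linalg.norm(v)
    if norm < CHORD_TOL:
        return None
    return v / norm


def pairwise_angles(directions: list[np.ndarray]) -> list[float]:
    """Angles (degrees) between every unordered pair of unit vectors."""
    out = []
    for i in range(len(directions)):
        for j in range(i + 1, len(directions)):
            c = float(np.clip(np.dot(directions[i], directions[j]), -1.0, 1.0))
            out.append(math.degrees(math.acos(c)))
    return out


def inter_trabecular_angles(node_id: int, graph: SpatialGraph,
                            mode: str = "chord") -> list[float]:
    """All pairwise ITAs at a node, via the normalized dot product.

    A node of valence n yields n(n-1)/2 angles.  Self-loops contribute both
    of their (identical chord) directions.  Pairs involving an undefined
    direction are omitted.
    """
    dirs: list[np.ndarray] = []
    for s in graph.incident_segments(node_id):
        ends = [e for e in (s.start, s.end) if e == node_id]
        for _ in ends:  # self-loops twice
            d = segment_direction_at_node(s, node_id, mode=mode)
            if d is not None:
                dirs.append(d)
    return pairwise_angles(dirs)


def theta(segment: Segment) -> float | None:
    """Angle between the segment chord and the z-axis, folded to [0°, 90°].

    0° is a trabecula perpendicular to the plate's surface (along z); 90° is
    one lying in the horizontal x-y plane.  ``None`` for zero chords.
    """
    v = segment.points[-1] - segment.points[0]
    norm = np.linalg.norm(v)
    if norm < CHORD_TOL:
        return None
    return math.degrees(math.acos(min(1.0, abs(v[2]) / norm)))


def _oriented_chord(segment: Segment) -> np.ndarray | None:
    v = segment.points[-1] - segment.points[0]
    if np.linalg.norm(v) < CHORD_TOL:
        return None
    # orient to non-negative z; for horizontal chords fall back to +x then +y
    if v[2] < 0 or (v[2] == 0 and (v[0] < 0 or (v[0] == 0 and v[1] < 0))):
        v = -v
    return v


def phi(segment: Segment) -> float | None:
    """Azimuth of the chord's horizontal projection, degrees in [0°, 360°).

    Measured counterclockwise from +x, after orienting the chord to
    non-negative z.  ``None`` for zero chords and purely vertical chords
    (undefined azimuth).
    """
    v = _oriented_chord(segment)
    if v is None or math.hypot(v[0], v[1]) < CHORD_TOL:
        return None
    a = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return a if a < 360.0 else 0.0


def direction_from_angles(theta_deg: float, phi_deg: float | None) -> np.ndarray:
    """Unit chord direction from (theta, phi); inverse of the two angles.

    For theta = 0 (vertical chord) phi may be ``None``.
    """
    t = math.radians(theta_deg)
    if phi_deg is None:
        return np.array([0.0, 0.0, 1.0])
    p = math.radians(phi_deg)
    return np.array([math.sin(t) * math.cos(p),
                     math.sin(t) * math.sin(p),
                     math.cos(t)])


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def segment_table(graph: SpatialGraph, slenderness_length: str = "curved",
                  direction_mode: str = "chord") -> pd.DataFrame:
    """Per-segment descriptor records.

    ``slenderness_length`` selects the length entering R_S = L / g_r
    ("curved", the physical beam length, or "chord").  Zero-chord segments
    carry NaN tortuosity/theta/phi but keep their lengths and radii.
    """
    rows = []
    for s in sorted(graph.segments, key=lambda s: s.id):
        lc = chord_length(s)
        lt = curved_length(s)
        tau = tortuosity(s)
        r = segment_mean_radius(s) if s.radii is not None else np.nan
        d_t = 2.0 * r
        g_r = radius_of_gyration(d_t)
        L = lt if slenderness_length == "curved" else lc
        rs = L / g_r if g_r > 0 else np.nan
        rows.append({
            "segment_id": s.id, "start_node": s.start, "end_node": s.end,
            "chord_length": lc, "curved_length": lt,
            "tortuosity": np.nan if tau is None else tau,
            "mean_radius": r, "diameter": d_t, "radius_of_gyration": g_r,
            "slenderness": rs,
            "theta": np.nan if (t := theta(s)) is None else t,
            "phi": np.nan if (p := phi(s)) is None else p,
            "n_points": s.points.shape[0],
        })
    cols = ["segment_id", "start_node", "end_node", "chord_length",
            "curved_length", "tortuosity", "mean_radius", "diameter",
            "radius_of_gyration", "slenderness", "theta", "phi", "n_points"]
    return pd.DataFrame(rows, columns=cols)


def node_table(graph: SpatialGraph, direction_mode: str = "chord") -> pd.DataFrame:
    """Per-node records: valence, node radius, pairwise-ITA summary."""
    rows = []
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        val = graph.valence(nid)
        itas = inter_trabecular_angles(nid, graph, mode=direction_mode) if val >= 2 else []
        rows.append({
            "node_id": nid, "valence": val,
            "node_radius": np.nan if n.radius is None else n.radius,
            "n_angles": len(itas),
            "mean_ita": np.nan if not itas else float(np.mean(itas)),
            "sd_ita": np.nan if not itas else float(np.std(itas, ddof=1)) if len(itas) > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["node_id", "valence", "node_radius",
                                       "n_angles", "mean_ita", "sd_ita"])


def node_angles(graph: SpatialGraph, direction_mode: str = "chord") -> pd.DataFrame:
    """Long-form table of every pairwise ITA, one row per angle."""
    rows = []
    for nid in sorted(graph.nodes):
        for a in inter_trabecular_angles(nid, graph, mode=direction_mode):
            rows.append({"node_id": nid, "valence": graph.valence(nid), "ita": a})
    return pd.DataFrame(rows, columns=["node_id", "valence", "ita"])


def histogram_mode(values, bin_width: float = 5.0, anchor: float = 0.0) -> float:
    """Midpoint of the tallest histogram bin (ties: lowest bin)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan
    lo = anchor + bin_width * math.floor((v.min() - anchor) / bin_width)
    hi = anchor + bin_width * math.ceil((v.max() - anchor) / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    return float(edges[k] + bin_width / 2)


def node_configuration_table(graph: SpatialGraph, bin_width: float = 5.0,
                             direction_mode: str = "chord") -> pd.DataFrame:
    """Valence-class breakdown: counts, fractions and per-class ITA stats.

    One row per observed valence class (plus a ``total`` row), with the
    count of nodes, their percentage of all nodes, and mean/sd/histogram
    mode of the per-node mean ITAs in the class.
    """
    nt = node_table(graph, direction_mode=direction_mode)
    if nt.empty:
        return pd.DataFrame(columns=["class", "n", "fraction_pct",
                                     "ita_mean", "ita_sd", "ita_mode"])
    total = len(nt)
    rows = []
    mean_itas = nt["mean_ita"].dropna()
    rows.append({
        "class": "total", "n": total, "fraction_pct": 100.0,
        "ita_mean": float(mean_itas.mean()) if len(mean_itas) else math.nan,
        "ita_sd": float(mean_itas.std(ddof=1)) if len(mean_itas) > 1 else math.nan,
        "ita_mode": histogram_mode(mean_itas, bin_width),
    })
    for val, grp in nt.groupby("valence"):
        m = grp["mean_ita"].dropna()
        rows.append({
            "class": f"{val}N", "n": len(grp),
            "fraction_pct": 100.0 * len(grp) / total,
            "ita_mean": float(m.mean()) if len(m) else math.nan,
            "ita_sd": float(m.std(ddof=1)) if len(m) > 1 else math.nan,
            "ita_mode": histogram_mode(m, bin_width),
        })
    return pd.DataFrame(rows)


@dataclass
class DescriptorSummary:
    """Median ± MAD table over descriptor columns (per-region summary)."""

    table: pd.DataFrame  # index: variable; columns median, mad, min, max, N

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def mad(values, scaled: bool = False) -> float:
    """Median absolute deviation; unscaled by default (no 1.4826 factor)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan
    m = float(np.median(np.abs(v - np.median(v))))
    return m * 1.4826 if scaled else m


def summarize(records: pd.DataFrame, variables: list[str] | None = None,
              scaled_mad: bool = False) -> DescriptorSummary:
    """Per-variable median, MAD, min, max and N over non-NaN values."""
    if variables is None:
        variables = [c for c in records.columns
                     if records[c].dtype.kind == "f"]
    rows = {}
    for var in variables:
        v = records[var].dropna().to_numpy()
        rows[var] = {
            "median": float(np.median(v)) if v.size else math.nan,
            "mad": mad(v, scaled=scaled_mad),
            "min": float(v.min()) if v.size else math.nan,
            "max": float(v.max()) if v.size else math.nan,
            "N": int(v.size),
        }
    return DescriptorSummary(pd.DataFrame(rows).T[["median", "mad", "min", "max", "N"]])


def point_radius_summary(graph: SpatialGraph) -> dict:
    """Median/MAD of the raw per-point radii over all segments (µm).

    Reported alongside the per-segment means because the two differ: every
    polyline point contributes here, so thin points near nodes dominate.
    """
    pts = np.concatenate([s.radii for s in graph.segments if s.radii is not None]) \
        if any(s.radii is not None for s in graph.segments) else np.array([])
    return {
        "median": float(np.median(pts)) if pts.size else math.nan,
        "mad": mad(pts) if pts.size else math.nan,
        "N": int(pts.size),
    }
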