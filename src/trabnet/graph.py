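"""Spatial graphs: the centerline representation of a trabecular network.

A :class:`SpatialGraph` stores intersection nodes (coordinate + radius) and
segments (trabeculae) as ordered polylines with per-point radii, all in
micrometres.  It is the product of skeletonization (:mod:`trabnet.skeleton`)
or of importing an Avizo SpatialGraph ASCII export, and the substrate for
every descriptor in :mod:`trabnet.descriptors`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: coordinate tolerance (µm) for node merging and round-trip comparison
COORD_TOL = 1e-6


@dataclass
class Node:
    """An intersection (or end-) point of the trabecular network."""

    id: int
    coord: np.ndarray  # (3,) µm, (x, y, z)
    radius: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError("node coordinate must be a 3-vector")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("node radius must be > 0")


@dataclass
class Segment:
    """A trabecula: an ordered centerline polyline between two nodes."""

    id: int
    start: int
    end: int
    points: np.ndarray  # (n, 3) µm
    radii: np.ndarray | None = None  # (n,) µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("segment polyline must be (n, 3)")
        if self.points.shape[0] < 2:
            raise ValueError("segment polyline needs at least 2 points")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (self.points.shape[0],):
                raise ValueError("radii must match polyline length")
            if np.any(self.radii <= 0):
                raise ValueError("all point radii must be > 0")

    @property
    def is_loop(self) -> bool:
        return self.start == self.end


@dataclass
class SpatialGraph:
    nodes: dict[int, Node] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)

    # -- construction ---------------------------------------------------
    def add_node(self, coord, radius: float | None = None, node_id: int | None = None) -> int:
        nid = node_id if node_id is not None else (max(self.nodes, default=-1) + 1)
        if nid in self.nodes:
            raise ValueError(f"node id {nid} already present")
        self.nodes[nid] = Node(nid, coord, radius)
        return nid

    def add_segment(self, start: int, end: int, points, radii=None,
                    segment_id: int | None = None) -> int:
        sid = segment_id if segment_id is not None else (
            max((s.id for s in self.segments), default=-1) + 1)
        seg = Segment(sid, start, end, points, radii)
        for nid, pt in ((start, seg.points[0]), (end, seg.points[-1])):
            if nid not in self.nodes:
                raise ValueError(f"segment references unknown node {nid}")
            if np.max(np.abs(self.nodes[nid].coord - pt)) > COORD_TOL:
                raise ValueError(
                    f"segment {sid} endpoint does not coincide with node {nid}")
        self.segments.append(seg)
        return sid

    # -- queries --------------------------------------------------------
    def incident_segments(self, node_id: int) -> list[Segment]:
        """Segments attached to a node; self-loops appear once in the list
        but count twice toward valence."""
        return [s for s in self.segments if node_id in (s.start, s.end)]

    def valence(self, node_id: int) -> int:
        v = 0
        for s in self.segments:
            v += (s.start == node_id) + (s.end == node_id)
        return v

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        for s in self.segments:
            for nid, pt in ((s.start, s.points[0]), (s.end, s.points[-1])):
                if nid not in self.nodes:
                    raise ValueError(f"segment {s.id}: unknown node {nid}")
                if np.max(np.abs(self.nodes[nid].coord - pt)) > COORD_TOL:
                    raise ValueError(f"segment {s.id}: endpoint/node mismatch")

    def transformed(self, rotation=None, translation=None) -> "SpatialGraph":
        """Return a rigidly transformed copy (rotation 3x3, translation (3,))."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        g = SpatialGraph()
        for nid, n in self.nodes.items():
            g.add_node(R @ n.coord + t, n.radius, node_id=nid)
        for s in self.segments:
            g.add_segment(s.start, s.end, s.points @ R.T + t,
                          None if s.radii is None else s.radii.copy(),
                          segment_id=s.id)
        return g


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _polylines_equal(a: np.ndarray, b: np.ndarray, tol: float) -> bool:
    if a.shape != b.shape:
        return False
    return (np.max(np.abs(a - b)) <= tol) or (np.max(np.abs(a - b[::-1])) <= tol)


def deduplicate(graph: SpatialGraph, tol: float = COORD_TOL) -> SpatialGraph:
    """Merge coincident nodes and drop duplicated segments.

    Nodes whose coordinates agree within ``tol`` are merged (keeping the
    smallest id); segments sharing the same unordered endpoint pair and the
    same polyline (up to reversal, within ``tol``) are reduced to one.
    Idempotent and independent of segment ordering.
    """
    ids = sorted(graph.nodes)
    coords = np.array([graph.nodes[i].coord for i in ids]) if ids else np.empty((0, 3))
    remap: dict[int, int] = {}
    kept: list[int] = []
    for idx, nid in enumerate(ids):
        target = nid
        for kidx in kept:
            if np.max(np.abs(coords[idx] - coords[kidx])) <= tol:
                target = ids[kidx]
                break
        if target == nid:
            kept.append(idx)
        remap[nid] = target

    out = SpatialGraph()
    for idx in kept:
        n = graph.nodes[ids[idx]]
        out.add_node(n.coord, n.radius, node_id=n.id)

    seen: list[Segment] = []
    for s in sorted(graph.segments, key=lambda s: s.id):
        a, b = remap[s.start], remap[s.end]
        dup = False
        for t in seen:
            if {t.start, t.end} == {a, b} and _polylines_equal(t.points, s.points, tol):
                dup = True
                break
        if dup:
            continue
        seg = Segment(s.id, a, b, s.points.copy(),
                      None if s.radii is None else s.radii.copy())
        # snap endpoints onto the surviving node coordinates
        seg.points[0] = out.nodes[a].coord
        seg.points[-1] = out.nodes[b].coord
        seen.append(seg)
        out.segments.append(seg)
    return out


# ---------------------------------------------------------------------------
# Avizo SpatialGraph ASCII (.am) import
# ---------------------------------------------------------------------------

class AvizoParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_avizo_spatialgraph(path, thickness_is_diameter: bool = False) -> SpatialGraph:
    """Parse an Avizo/AmiraMesh ASCII SpatialGraph export.

    Understands the VERTEX/EDGE/POINT dialect produced by Avizo's spatial
    graph statistics: ``VertexCoordinates``, ``EdgeConnectivity``,
    ``NumEdgePoints``, ``EdgePointCoordinates`` and a point ``thickness``
    attribute.  ``thickness`` is taken as a radius unless
    ``thickness_is_diameter`` is set.  Graphs load uncleaned; apply
    :func:`deduplicate` explicitly.
    """
    lines = Path(path).read_text().splitlines()
    counts: dict[str, int] = {}
    sections: dict[str, tuple[str, str]] = {}  # "@1" -> (group, field)
    data: dict[str, list[list[float]]] = {}
    ln = 0
    n = len(lines)
    while ln < n:
        raw = lines[ln].strip()
        ln += 1
        if not raw or raw.startswith("#"):
            continue
        if raw.startswith("define"):
            parts = raw.split()
            if len(parts) != 3:
                raise AvizoParseError("malformed define", ln)
            counts[parts[1]] = int(parts[2])
        elif raw.startswith(("VERTEX", "EDGE", "POINT")) and "@" in raw:
            group = raw.split()[0]
            fieldname = raw.split("}")[0].split()[-1]
            marker = raw.split("@")[-1].rstrip()
            sections["@" + marker.split()[0]] = (group, fieldname)
        elif raw.startswith("@"):
            marker = raw.split()[0]
            if marker not in sections:
                raise AvizoParseError(f"data block {marker} was never declared", ln)
            block: list[list[float]] = []
            while ln < n:
                row = lines[ln].strip()
                if row.startswith("@"):
                    break
                ln += 1
                if row:
                    block.append([float(v) for v in row.split()])
            data[marker] = block

    def find(fieldname: str) -> list[list[float]] | None:
        for marker, (_, f) in sections.items():
            if f == fieldname:
                return data.get(marker)
        return None

    verts = find("VertexCoordinates")
    conn = find("EdgeConnectivity")
    nump = find("NumEdgePoints")
    pts = find("EdgePointCoordinates")
    thick = find("thickness")
    for name, block, key in (("VertexCoordinates", verts, "VERTEX"),
                             ("EdgeConnectivity", conn, "EDGE"),
                             ("NumEdgePoints", nump, "EDGE"),
                             ("EdgePointCoordinates", pts, "POINT")):
        if block is None:
            raise AvizoParseError(f"missing section {name}", 0)
        if key in counts and len(block) != counts[key]:
            raise AvizoParseError(
                f"section {name} has {len(block)} rows, expected {counts[key]}", 0)

    scale = 0.5 if thickness_is_diameter else 1.0
    g = SpatialGraph()
    for i, v in enumerate(verts):
        g.add_node(v, node_id=i)
    cursor = 0
    for eid, ((a, b), (m,)) in enumerate(zip(conn, nump)):
        m = int(m)
        poly = np.array(pts[cursor:cursor + m], dtype=float)
        if poly.shape[0] != m:
            raise AvizoParseError("EdgePointCoordinates shorter than NumEdgePoints", 0)
        radii = None
        if thick is not None:
            radii = scale * np.array([r[0] for r in thick[cursor:cursor + m]])
        cursor += m
        # Avizo point lists repeat the vertex coordinates; trust the vertices
        poly[0] = verts[int(a)]
        poly[-1] = verts[int(b)]
        g.add_segment(int(a), int(b), poly, radii, segment_id=eid)
    return g


# ---------------------------------------------------------------------------
# JSON / CSV round-trip formats
# ---------------------------------------------------------------------------

def write_graph(graph: SpatialGraph, path, format: str = "json") -> None:
    """Serialize a graph to ``json`` (single file) or ``tabular-csv``.

    The CSV format writes one row per polyline point to ``path`` and a
    companion node table to ``<path>.nodes.csv``.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "nodes": [
                {"id": n.id, "coord": list(n.coord),
                 "radius": None if n.radius is None else float(n.radius)}
                for n in sorted(graph.nodes.values(), key=lambda n: n.id)
            ],
            "segments": [
                {"id": s.id, "start": s.start, "end": s.end,
                 "points": s.points.tolist(),
                 "radii": None if s.radii is None else s.radii.tolist()}
                for s in sorted(graph.segments, key=lambda s: s.id)
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif format in ("csv", "tabular-csv"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["segment_id", "start_node", "end_node",
                        "point_index", "x", "y", "z", "radius"])
            for s in sorted(graph.segments, key=lambda s: s.id):
                for i, p in enumerate(s.points):
                    r = "" if s.radii is None else repr(float(s.radii[i]))
                    w.writerow([s.id, s.start, s.end, i,
                                repr(float(p[0])), repr(float(p[1])),
                                repr(float(p[2])), r])
        with open(path.with_suffix(path.suffix + ".nodes.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "x", "y", "z", "radius"])
            for n in sorted(graph.nodes.values(), key=lambda n: n.id):
                r = "" if n.radius is None else repr(float(n.radius))
                w.writerow([n.id, repr(float(n.coord[0])),
                            repr(float(n.coord[1])),
                            repr(float(n.coord[2])), r])
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str | None = None) -> SpatialGraph:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    g = SpatialGraph()
    if format == "json":
        doc = json.loads(path.read_text())
        for n in doc["nodes"]:
            g.add_node(n["coord"], n.get("radius"), node_id=n["id"])
        for s in doc["segments"]:
            g.add_segment(s["start"], s["end"], np.array(s["points"]),
                          None if s.get("radii") is None else np.array(s["radii"]),
                          segment_id=s["id"])
    elif format in ("csv", "tabular-csv"):
        nodes_path = path.with_suffix(path.suffix + ".nodes.csv")
        with open(nodes_path, newline="") as fh:
            for row in csv.DictReader(fh):
                g.add_node([float(row["x"]), float(row["y"]), float(row["z"])],
                           float(row["radius"]) if row["radius"] else None,
                           node_id=int(row["node_id"]))
        segs: dict[int, dict] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sid = int(row["segment_id"])
                rec = segs.setdefault(sid, {"start": int(row["start_node"]),
                                            "end": int(row["end_node"]),
                                            "pts": [], "radii": []})
                rec["pts"].append([float(row["x"]), float(row["y"]), float(row["z"])])
                rec["radii"].append(float(row["radius"]) if row["radius"] else None)
        for sid in sorted(segs):
            rec = segs[sid]
            radii = None
            if all(r is not None for r in rec["radii"]):
                radii = np.array(rec["radii"])
            g.add_segment(rec["start"], rec["end"], np.array(rec["pts"]),
                          radii, segment_id=sid)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return g


def graphs_equal(a: SpatialGraph, b: SpatialGraph, tol: float = 1e-9) -> bool:
    """Structural equality within a coordinate tolerance (id-sensitive)."""
    if sorted(a.nodes) != sorted(b.nodes):
        return False
    for nid in a.nodes:
        na, nb = a.nodes[nid], b.nodes[nid]
        if np.max(np.abs(na.coord - nb.coord)) > tol:
            return False
        if (na.radius is None) != (nb.radius is None):
            return False
        if na.radius is not None and not math.isclose(na.radius, nb.radius,
                                                      rel_tol=0, abs_tol=tol):
            return False
    sa = sorted(a.segments, key=lambda s: s.id)
    sb = sorted(b.segments, key=lambda s: s.id)
    if [s.id for s in sa] != [s.id for s in sb]:
        return False
    for x, y in zip(sa, sb):
        if (x.start, x.end) != (y.start, y.end):
            return False
        if x.points.shape != y.points.shape or np.max(np.abs(x.points - y.points)) > tol:
            return False
        if (x.radii is None) != (y.radii is None):
            return False
        if x.radii is not None and np.max(np.abs(x.radii - y.radii)) > tol:
            return False
    return True
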