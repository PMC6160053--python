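"""Ground-truthed synthetic trabecular networks.

The generator emulates the statistical structure of echinoid stereom
subvolumes — a beam network in a 90 µm cube with median chord length
around 16 µm, median beam radius around 2.3 µm, tortuosity close to 1,
predominantly 3-valent nodes, theta spread over [0°, 90°] with its mode
at 90°, and optionally a directional (non-uniform) phi distribution —
so the full volume -> skeleton -> descriptor chain can be validated
against known truth without any scan data.

Nodes are placed on a jittered cubic lattice (so target valence mixes are
constructible deterministically), candidate edges come from the Delaunay
tetrahedralization of the nodes, and edges are selected greedily under
per-node valence targets with orientation- and length-dependent weights.
Tortuosity is injected as a single-period sinusoidal offset orthogonal to
each chord, with amplitude calibrated analytically to the target ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .graph import SpatialGraph
from .volume import BinaryVolume

#: default valence mix (3N/4N/5N+), echoing the dominance of 3-valent nodes
DEFAULT_VALENCE_MIX = {3: 0.66, 4: 0.21, 5: 0.13}

#: minimum node separation, as a fraction of the lattice pitch; node pairs
#: closer than this would fuse into a single blob at scan resolution
_MIN_SEPARATION_FRAC = 0.45


@dataclass
class NetworkSpec:
    """Statistical targets for a synthetic trabecular network.

    All lengths in µm.  ``tortuosity_target`` is the intended median
    curved/chord ratio (1.0 produces exactly straight beams);
    ``radius_sigma`` is the log-scale spread of the per-segment lognormal
    radius draw; ``min_radius`` floors the draw at half a scan voxel so
    voxelization stays well-posed.
    """

    domain_edge: float = 90.0
    median_chord: float = 16.4
    radius_median: float = 2.3
    radius_sigma: float = 0.35
    min_radius: float = 1.5
    valence_mix: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_VALENCE_MIX))
    tortuosity_target: float = 1.03
    min_arm_angle: float = 0.0          # smallest allowed ITA at a node (deg)
    theta_model: str = "isotropic"      # or "plate" (favors horizontal beams)
    phi_model: str = "uniform"          # or "directional"
    phi_kappa: float = 3.0              # concentration of the directional model
    phi_mu: float = 30.0                # preferred azimuth (degrees)
    jitter: float = 0.35                # node jitter, fraction of lattice spacing
    point_spacing: float = 2.0          # polyline sampling step (µm)
    seed: int | None = None

    def validate(self) -> None:
        if abs(sum(self.valence_mix.values()) - 1.0) > 1e-9:
            raise ValueError("valence mix fractions must sum to 1")
        for name in ("domain_edge", "median_chord", "radius_median",
                     "point_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tortuosity_target < 1.0:
            raise ValueError("tortuosity target must be >= 1")
        if self.theta_model not in ("isotropic", "plate"):
            raise ValueError(f"unknown theta model {self.theta_model!r}")
        if self.phi_model not in ("uniform", "directional"):
            raise ValueError(f"unknown phi model {self.phi_model!r}")


@dataclass
class GroundTruth:
    """Record-for-record truth for a generated network."""

    segments: pd.DataFrame  # id, chord, curved, tortuosity, radius, theta, phi
    nodes: pd.DataFrame     # id, valence, target_valence, is_interior
    spec: NetworkSpec
    seed: int | None

    def valence_fractions(self, interior_only: bool = True,
                          cap: int = 5) -> dict[str, float]:
        return _valence_fractions(self.nodes[self.nodes.is_interior]
                                  if interior_only else self.nodes, cap)


def _valence_fractions(nodes: pd.DataFrame, cap: int = 5) -> dict[str, float]:
    """Fractions per valence class, classes above ``cap`` pooled as '<cap>N+'."""
    if len(nodes) == 0:
        return {}
    v = nodes["valence"].to_numpy()
    out: dict[str, float] = {}
    for k in range(1, cap):
        out[f"{k}N"] = float(np.mean(v == k))
    out[f"{cap}N+"] = float(np.mean(v >= cap))
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _unit_orthogonal(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        w = r - np.dot(r, v) * v
        n = np.linalg.norm(w)
        if n > 1e-9:
            return w / n


def _edge_weight(vec: np.ndarray, length: float, spacing: float,
                 spec: NetworkSpec) -> float:
    w = math.exp(-(((length - spacing) / (0.45 * spacing)) ** 2))
    uz = abs(vec[2]) / length
    if spec.theta_model == "plate":
        w *= (1.0 - uz * uz) + 0.05
    if spec.phi_model == "directional":
        horiz = math.hypot(vec[0], vec[1])
        if horiz > 1e-12:
            phi = math.atan2(vec[1], vec[0])
            mu = math.radians(spec.phi_mu)
            # axial (period-180) concentration; scaled by how horizontal
            w *= math.exp(spec.phi_kappa *
                          (math.cos(2 * (phi - mu)) - 1.0) * (horiz / length))
    return w


def generate_network(spec: NetworkSpec,
                     seed: int | None = None) -> tuple[SpatialGraph, GroundTruth]:
    """Build a seeded synthetic trabecular network and its ground truth."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    # node jitter lengthens edges relative to the lattice pitch, so the
    # pitch is set below the chord target (factor calibrated once for the
    # default jitter of 0.35)
    a = spec.median_chord * (1.0 - 0.24 * spec.jitter)
    m = max(2, int(math.floor(spec.domain_edge / a)))
    offset = (spec.domain_edge - (m - 1) * a) / 2.0  # exact spacing, centered
    centers = offset + np.arange(m) * a
    gx, gy, gz = np.meshgrid(centers, centers, centers, indexing="ij")
    pos = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pos = pos + rng.normal(0.0, spec.jitter * a, size=pos.shape)
    pos = np.clip(pos, 0.5, spec.domain_edge - 0.5)
    n_nodes = len(pos)
    # enforce a minimum node separation (close node pairs would fuse into
    # one blob at scan resolution); push offending pairs apart symmetrically
    dmin = _MIN_SEPARATION_FRAC * a
    for _ in range(8):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(dmin)
        if not pairs:
            break
        for i, j in sorted(pairs):
            d = pos[j] - pos[i]
            dist = float(np.linalg.norm(d))
            u = d / dist if dist > 1e-9 else np.array([1.0, 0.0, 0.0])
            push = (dmin - dist) / 2.0 + 0.05 * a
            pos[i] -= push * u
            pos[j] += push * u
        pos = np.clip(pos, 0.5, spec.domain_edge - 0.5)

    tri = Delaunay(pos)
    edges = set()
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                u, v = sorted((simplex[i], simplex[j]))
                edges.add((u, v))
    cand = []
    for (u, v) in edges:
        vec = pos[v] - pos[u]
        L = float(np.linalg.norm(vec))
        if L <= 1.8 * a:
            cand.append((u, v, vec, L))
    if not cand:
        raise ValueError("no candidate edges: domain too small for the spacing")

    vals = np.array(sorted(spec.valence_mix))
    probs = np.array([spec.valence_mix[v] for v in vals], dtype=float)
    targets = rng.choice(vals, size=n_nodes, p=probs / probs.sum())
    if targets.sum() / 2 > len(cand):
        raise ValueError(
            f"valence mix infeasible: needs {targets.sum() / 2:.0f} edges, "
            f"only {len(cand)} candidates")

    weights = np.array([_edge_weight(vec, L, a, spec) for (_, _, vec, L) in cand])
    weights *= rng.uniform(0.7, 1.0, size=len(cand))
    order = np.argsort(-weights, kind="stable")

    # arms meeting at a node must be well separated (pairwise ITAs
    # concentrate near the 120-degree triangular motif; near-parallel
    # arms would also fuse at scan resolution)
    min_cos = math.cos(math.radians(spec.min_arm_angle))
    directions: list[list[np.ndarray]] = [[] for _ in range(n_nodes)]

    def arm_ok(node: int, unit: np.ndarray, cos_cap: float) -> bool:
        return all(float(np.dot(unit, d)) < cos_cap for d in directions[node])

    def register(k: int) -> None:
        u, v, vec, L = cand[k]
        directions[u].append(vec / L)
        directions[v].append(-vec / L)

    def unregister(k: int) -> None:
        u, v, vec, L = cand[k]
        directions[u] = [d for d in directions[u]
                         if not np.allclose(d, vec / L)]
        directions[v] = [d for d in directions[v]
                         if not np.allclose(d, -vec / L)]

    residual = targets.astype(int).copy()
    chosen: list[int] = []
    in_graph = np.zeros(len(cand), dtype=bool)
    for k in order:
        u, v, vec, L = cand[k]
        if residual[u] > 0 and residual[v] > 0 and \
                arm_ok(u, vec / L, min_cos) and arm_ok(v, -vec / L, min_cos):
            chosen.append(k)
            in_graph[k] = True
            register(k)
            residual[u] -= 1
            residual[v] -= 1

    # repair deficits while keeping interior nodes on target: first pair up
    # deficient nodes, then let interior deficits steal capacity from
    # boundary nodes (whose valence is not part of the emulated mix)
    margin = 0.6 * spec.median_chord
    lo, hi = margin, spec.domain_edge - margin
    is_interior = np.all((pos >= lo) & (pos <= hi), axis=1)
    cand_by_node: list[list[int]] = [[] for _ in range(n_nodes)]
    for k, (u, v, _, _) in enumerate(cand):
        cand_by_node[u].append(k)
        cand_by_node[v].append(k)
    edges_by_node: dict[int, set[int]] = {i: set() for i in range(n_nodes)}
    for k in chosen:
        edges_by_node[cand[k][0]].add(k)
        edges_by_node[cand[k][1]].add(k)

    def add_edge(k: int) -> None:
        in_graph[k] = True
        chosen.append(k)
        edges_by_node[cand[k][0]].add(k)
        edges_by_node[cand[k][1]].add(k)
        register(k)

    def drop_edge(k: int) -> None:
        in_graph[k] = False
        chosen.remove(k)
        edges_by_node[cand[k][0]].discard(k)
        edges_by_node[cand[k][1]].discard(k)
        unregister(k)

    relaxed_cos = math.cos(math.radians(max(spec.min_arm_angle - 15.0, 20.0)))

    def angle_fits(k: int, cos_cap: float) -> bool:
        u, v, vec, L = cand[k]
        return arm_ok(u, vec / L, cos_cap) and arm_ok(v, -vec / L, cos_cap)

    # pass 1: connect pairs of deficient nodes
    for u in np.nonzero(residual > 0)[0]:
        while residual[u] > 0:
            opts = [(cand[k][3], k) for k in cand_by_node[u] if not in_graph[k]
                    and residual[cand[k][0] + cand[k][1] - u] > 0
                    and angle_fits(k, relaxed_cos)]
            if not opts:
                break
            _, k = min(opts)
            add_edge(k)
            other = cand[k][0] + cand[k][1] - u
            residual[u] -= 1
            residual[other] -= 1
    # pass 2: interior deficits take an edge to (or steal one from) a
    # boundary node; boundary deficits are tolerated (subvolume truncation
    # leaves low-valence nodes at the faces of real scans too)
    for u in np.nonzero(residual > 0)[0]:
        if not is_interior[u]:
            continue
        while residual[u] > 0:
            free = [(cand[k][3], k) for k in cand_by_node[u] if not in_graph[k]
                    and not is_interior[cand[k][0] + cand[k][1] - u]
                    and angle_fits(k, relaxed_cos)]
            if free:
                _, k = min(free)
                add_edge(k)
                residual[u] -= 1
                continue
            # steal: use a full interior partner v but release one of v's
            # edges to a boundary node w, keeping v on target
            done = False
            for _, k in sorted((cand[k][3], k) for k in cand_by_node[u]
                               if not in_graph[k] and angle_fits(k, relaxed_cos)):
                v = cand[k][0] + cand[k][1] - u
                rel = [j for j in edges_by_node[v]
                       if not is_interior[cand[j][0] + cand[j][1] - v]]
                if rel:
                    drop_edge(rel[0])
                    add_edge(k)
                    residual[u] -= 1
                    done = True
                    break
            if not done:
                break

    # pass 3: remaining interior deficits migrate through the lattice by
    # taking an edge slot from an on-target interior neighbour, whose own
    # new deficit repeats the search; banning released edges prevents
    # oscillation, so the walk terminates at a node with boundary capacity
    banned: set[int] = set()

    def migrate(queue: list[int]) -> None:
      steps = 0
      while queue and steps < 4 * n_nodes:
        steps += 1
        u = queue.pop(0)
        while residual[u] > 0:
            opts = [(cand[k][3], k) for k in cand_by_node[u]
                    if not in_graph[k] and k not in banned
                    and residual[cand[k][0] + cand[k][1] - u] > 0]
            if opts:
                _, k = min(opts)
                add_edge(k)
                other = cand[k][0] + cand[k][1] - u
                residual[u] -= 1
                residual[other] -= 1
                continue
            opts = [(cand[k][3], k) for k in cand_by_node[u]
                    if not in_graph[k] and k not in banned
                    and not is_interior[cand[k][0] + cand[k][1] - u]]
            if opts:
                _, k = min(opts)
                add_edge(k)
                residual[u] -= 1
                continue
            moved = False
            for _, k in sorted((cand[k][3], k) for k in cand_by_node[u]
                               if not in_graph[k] and k not in banned):
                v = cand[k][0] + cand[k][1] - u
                if residual[v] != 0:
                    continue
                rel = sorted(edges_by_node[v] - {k},
                             key=lambda j: -cand[j][3])
                if not rel:
                    continue
                j = rel[0]
                w = cand[j][0] + cand[j][1] - v
                drop_edge(j)
                banned.add(j)
                add_edge(k)
                residual[u] -= 1
                residual[w] += 1
                if is_interior[w]:
                    queue.append(int(w))
                moved = True
                break
            if not moved:
                break

    migrate([int(u) for u in np.nonzero(residual > 0)[0] if is_interior[u]])

    # connectivity: bridge components with the shortest unused candidates
    parent = list(range(n_nodes))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for k in chosen:
        union(cand[k][0], cand[k][1])
    def bridge_penalty(k: int) -> int:
        # prefer bridges that do not overfill on-target interior nodes
        return sum(1 for n in cand[k][:2]
                   if is_interior[n] and residual[n] <= 0)

    unused = sorted((k for k in range(len(cand)) if not in_graph[k]),
                    key=lambda k: (bridge_penalty(k), cand[k][3]))
    for k in unused:
        u, v, _, _ = cand[k]
        if find(u) != find(v) and angle_fits(k, relaxed_cos):
            in_graph[k] = True
            chosen.append(k)
            register(k)
            union(u, v)
            residual[u] -= 1
            residual[v] -= 1
    # rebalance: bridging may have overfilled an interior node; shed one of
    # its other edges when that edge is redundant for connectivity
    def is_cut_edge(j: int) -> bool:
        par = list(range(n_nodes))

        def f(i: int) -> int:
            while par[i] != i:
                par[i] = par[par[i]]
                i = par[i]
            return i

        for k in chosen:
            if k == j:
                continue
            par[f(cand[k][0])] = f(cand[k][1])
        return f(cand[j][0]) != f(cand[j][1])

    requeue: list[int] = []
    for u in np.nonzero(residual < 0)[0]:
        if not is_interior[u]:
            continue
        while residual[u] < 0:
            shed = None
            # prefer shedding toward boundary / other overfilled nodes, but
            # accept making an on-target interior neighbour deficient: the
            # migration pass re-fills it from spare capacity elsewhere
            for prefer_interior in (False, True):
                for j in sorted(edges_by_node[u], key=lambda j: -cand[j][3]):
                    w = cand[j][0] + cand[j][1] - u
                    interior_target = is_interior[w] and residual[w] >= 0
                    if interior_target != prefer_interior:
                        continue
                    if not is_cut_edge(j):
                        shed = (j, w)
                        break
                if shed:
                    break
            if shed is None:
                break
            j, w = shed
            drop_edge(j)
            banned.add(j)
            residual[u] += 1
            residual[w] += 1
            if is_interior[w] and residual[w] > 0:
                requeue.append(int(w))
    if requeue:
        migrate(requeue)

    roots = {find(i) for i in range(n_nodes)}
    if len(roots) > 1:
        # lattice disconnection beyond the candidate set: join nearest pairs
        comp_of = np.array([find(i) for i in range(n_nodes)])
        comps = sorted(roots)
        base = np.nonzero(comp_of == comps[0])[0]
        tree = cKDTree(pos[base])
        for c in comps[1:]:
            idx = np.nonzero(comp_of == c)[0]
            d, j = tree.query(pos[idx])
            kbest = int(np.argmin(d))
            u, v = idx[kbest], base[j[kbest]]
            vec = pos[v] - pos[u]
            cand.append((u, v, vec, float(np.linalg.norm(vec))))
            chosen.append(len(cand) - 1)
            union(u, v)

    # --- realize geometry --------------------------------------------------
    graph = SpatialGraph()
    for i in range(n_nodes):
        graph.add_node(pos[i], node_id=i)

    seg_rows = []
    tau = spec.tortuosity_target
    for sid, k in enumerate(sorted(chosen, key=lambda k: (cand[k][0], cand[k][1]))):
        u, v, vec, L = cand[k]
        radius = float(np.clip(
            spec.radius_median * math.exp(rng.normal(0.0, spec.radius_sigma)),
            spec.min_radius, None))
        npts = max(5, int(math.ceil(L / spec.point_spacing)) + 1)
        t = np.linspace(0.0, 1.0, npts)
        pts = pos[u] + np.outer(t, vec)
        amp = 0.0
        if tau > 1.0:
            # l_t ~ L (1 + (2 pi A)^2 / (4 L^2))  =>  A for the target ratio
            amp = (L / (2.0 * math.pi)) * math.sqrt(4.0 * (tau - 1.0))
            ortho = _unit_orthogonal(vec / L, rng)
            pts = pts + np.outer(amp * np.sin(2.0 * math.pi * t), ortho)
            pts = np.clip(pts, 0.05, spec.domain_edge - 0.05)
        radii = np.full(npts, radius)
        graph.add_segment(u, v, pts, radii, segment_id=sid)

        chord = L
        curved = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        uz = abs(vec[2]) / L
        theta = math.degrees(math.acos(min(1.0, uz)))
        w = vec if (vec[2] > 0 or (vec[2] == 0 and vec[0] >= 0)) else -vec
        horiz = math.hypot(w[0], w[1])
        phi = math.degrees(math.atan2(w[1], w[0])) % 360.0 if horiz > 1e-12 else math.nan
        seg_rows.append({"segment_id": sid, "start": u, "end": v,
                         "chord": chord, "curved": curved,
                         "tortuosity": curved / chord, "radius": radius,
                         "theta": theta, "phi": phi})

    # node radii: median of incident segment radii
    incident: dict[int, list[float]] = {i: [] for i in range(n_nodes)}
    valence = np.zeros(n_nodes, dtype=int)
    for row in seg_rows:
        for nid in (row["start"], row["end"]):
            incident[nid].append(row["radius"])
            valence[nid] += 1
    for i in range(n_nodes):
        if incident[i]:
            graph.nodes[i].radius = float(np.median(incident[i]))

    truth = GroundTruth(
        segments=pd.DataFrame(seg_rows),
        nodes=pd.DataFrame({"node_id": np.arange(n_nodes),
                            "valence": valence,
                            "target_valence": targets,
                            "is_interior": is_interior}),
        spec=spec, seed=seed)
    return graph, truth


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_network(graph: SpatialGraph, voxel_size: float = 3.0,
                     domain_edge: float | None = None) -> BinaryVolume:
    """Rasterize a network as a union of tapered capsules.

    Foreground is exactly the set of voxels whose centers lie within the
    locally interpolated radius of the swept centerline.  The volume spans
    ``[0, domain_edge]^3`` (inferred from the graph extent when omitted);
    geometry outside the volume raises.
    """
    if domain_edge is None:
        if graph.segments:
            domain_edge = float(max(s.points.max() for s in graph.segments))
        elif graph.nodes:
            domain_edge = float(max(n.coord.max() for n in graph.nodes.values()))
        else:
            domain_edge = voxel_size
    n = int(math.ceil(domain_edge / voxel_size))
    mask = np.zeros((n, n, n), dtype=bool)
    if any(s.radii is not None and np.any(s.radii < voxel_size / 2) for s in graph.segments):
        warnings.warn("some radii are below half a voxel; thin beams may "
                      "rasterize discontinuously", stacklevel=2)
    for s in graph.segments:
        if s.points.min() < -voxel_size or s.points.max() > domain_edge + voxel_size:
            raise ValueError(f"segment {s.id} lies outside the requested volume")
        radii = s.radii if s.radii is not None else np.full(len(s.points), voxel_size)
        for p0, p1, r0, r1 in zip(s.points[:-1], s.points[1:], radii[:-1], radii[1:]):
            rmax = max(r0, r1)
            lo = np.floor((np.minimum(p0, p1) - rmax) / voxel_size - 0.5).astype(int)
            hi = np.ceil((np.maximum(p0, p1) + rmax) / voxel_size - 0.5).astype(int) + 1
            lo = np.clip(lo, 0, n)
            hi = np.clip(hi, 0, n)
            if np.any(lo >= hi):
                continue
            xs = (np.arange(lo[0], hi[0]) + 0.5) * voxel_size
            ys = (np.arange(lo[1], hi[1]) + 0.5) * voxel_size
            zs = (np.arange(lo[2], hi[2]) + 0.5) * voxel_size
            X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
            P = np.stack([X, Y, Z], axis=-1)
            d = p1 - p0
            L2 = float(np.dot(d, d))
            if L2 == 0:
                t = np.zeros(P.shape[:-1])
            else:
                t = np.clip(np.einsum("...k,k->...", P - p0, d) / L2, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            dist = np.linalg.norm(P - closest, axis=-1)
            rloc = r0 + (r1 - r0) * t
            sel = dist <= rloc
            # mask axes are [z, y, x]
            mask[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] |= np.transpose(sel, (2, 1, 0))
    return BinaryVolume(mask, voxel_size, np.zeros(3))


# ---------------------------------------------------------------------------
# recovery comparison
# ---------------------------------------------------------------------------

#: default tolerance bands for truth-vs-recovered medians
DEFAULT_TOLERANCES = {
    "median_chord_rel": 0.15,
    "median_radius_rel": 0.20,
    "median_tortuosity_abs": 0.05,
    "valence_fraction_abs": 0.07,
}


@dataclass
class RecoveryReport:
    rows: pd.DataFrame

    @property
    def passed(self) -> bool:
        return bool(self.rows["passed"].all())

    def __str__(self) -> str:
        return self.rows.to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}")


def recovery_report(truth: GroundTruth, seg_table: pd.DataFrame,
                    node_table: pd.DataFrame,
                    graph: SpatialGraph | None = None,
                    tolerances: dict | None = None,
                    margin: float | None = None) -> RecoveryReport:
    """Compare recovered descriptor medians against generator truth.

    ``seg_table``/``node_table`` are descriptor tables of the recovered
    graph (:func:`trabnet.descriptors.segment_table` /
    :func:`trabnet.descriptors.node_table`).  When the recovered
    ``graph`` is supplied, the comparison is restricted to the domain
    interior on both sides: voxelization clips beams at the volume faces,
    so boundary stubs carry no information about the emulated medians or
    valence mix.  Each row reports truth, recovered, delta and a pass
    flag against the tolerance bands.
    """
    return pooled_recovery_report([(truth, seg_table, node_table, graph)],
                                  tolerances=tolerances, margin=margin)


def pooled_recovery_report(runs: list[tuple],
                           tolerances: dict | None = None,
                           margin: float | None = None) -> RecoveryReport:
    """Recovery comparison pooled over several generated subvolumes.

    ``runs`` is a list of ``(truth, seg_table, node_table, graph)``
    tuples, each from an independent realization; descriptor values are
    pooled before taking medians and fractions, mirroring how the
    original protocol pooled several subvolumes per plate region.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    spec = runs[0][0].spec
    if margin is None:
        margin = 0.6 * spec.median_chord
    lo, hi = margin, spec.domain_edge - margin

    tsegs, tnodes, rsegs, rnodes = [], [], [], []
    for truth, st, nt, graph in runs:
        tseg = truth.segments
        tin = truth.nodes.set_index("node_id")["is_interior"]
        tsegs.append(tseg[tseg["start"].map(tin) & tseg["end"].map(tin)])
        tnodes.append(truth.nodes[truth.nodes.is_interior])
        if graph is not None:
            def inside(nid: int) -> bool:
                c = graph.nodes[nid].coord
                return bool(np.all((c >= lo) & (c <= hi)))
            keep_seg = st.apply(lambda r: inside(int(r.start_node)) and
                                inside(int(r.end_node)), axis=1)
            st = st[keep_seg] if len(st) else st
            nt = nt[nt["node_id"].map(inside)] if len(nt) else nt
        rsegs.append(st)
        rnodes.append(nt)
    tseg = pd.concat(tsegs, ignore_index=True)
    tnode = pd.concat(tnodes, ignore_index=True)
    st = pd.concat(rsegs, ignore_index=True)
    nt = pd.concat(rnodes, ignore_index=True)

    rows = []

    def add(name, true_v, rec_v, band, relative):
        delta = ((rec_v - true_v) / true_v if true_v else math.nan) \
            if relative else (rec_v - true_v)
        rows.append({"metric": name, "truth": true_v, "recovered": rec_v,
                     "delta": delta, "tolerance": band,
                     "passed": bool(abs(delta) <= band)})

    add("median_chord_length", float(tseg["chord"].median()),
        float(st["chord_length"].median()), tol["median_chord_rel"], True)
    add("median_radius", float(tseg["radius"].median()),
        float(st["mean_radius"].median()), tol["median_radius_rel"], True)
    add("median_tortuosity", float(tseg["tortuosity"].median()),
        float(st["tortuosity"].median()), tol["median_tortuosity_abs"], False)
    add("median_theta", float(tseg["theta"].median()),
        float(st["theta"].median()), 10.0, False)

    true_fracs = _valence_fractions(tnode)
    rec_fracs = _valence_fractions(nt)
    for cls in ("3N", "4N", "5N+"):
        add(f"valence_fraction_{cls}", true_fracs.get(cls, 0.0),
            rec_fracs.get(cls, 0.0), tol["valence_fraction_abs"], False)
    return RecoveryReport(pd.DataFrame(rows))


def spec_to_dict(spec: NetworkSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> NetworkSpec:
    known = {f for f in NetworkSpec.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown NetworkSpec keys: {sorted(unknown)}")
    d = dict(d)
    if "valence_mix" in d:
        d["valence_mix"] = {int(k): float(v) for k, v in d["valence_mix"].items()}
    return NetworkSpec(**d)
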