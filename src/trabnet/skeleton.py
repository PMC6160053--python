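"""Skeletonization of a binary stereom volume into a spatial graph.

The binary mask is thinned to a one-voxel-wide, topology-preserving
medial skeleton (homotopic thinning), each skeleton voxel is classified by
its 26-neighbor count (1 = endpoint, 2 = path, >= 3 = junction), adjacent
junction voxels are merged into a single node at their centroid, and
maximal path runs become segment polylines.  Per-point radii come from a
Euclidean distance field of the foreground, corrected for the half-voxel
offset between a surface voxel center and the true material boundary and
floored at half a voxel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .graph import SpatialGraph
from .volume import BinaryVolume

_OFFSETS = np.array([(dz, dy, dx)
                     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dz, dy, dx) != (0, 0, 0)])


def skeletonize(bin: BinaryVolume) -> BinaryVolume:
    """Homotopic medial-axis thinning of the foreground.

    The skeleton is a subset of the foreground, preserves its connected
    component count, and is one voxel thick away from junctions.
    """
    if not bin.mask.any():
        raise ValueError("empty foreground: nothing to skeletonize")
    skel = _sk_skeletonize(bin.mask)
    return BinaryVolume(skel.astype(bool), bin.voxel_size, bin.origin.copy())


def radius_map(bin: BinaryVolume, correction: str = "center") -> np.ndarray:
    """Local radius field (µm) of the foreground.

    The base quantity is the Euclidean distance from each foreground voxel
    center to the nearest background voxel center.  That distance brackets
    the true distance to the material boundary, which lies somewhere
    between the outermost foreground sample and the background center;
    ``correction`` picks the convention:

    - ``"center"``: subtract half a voxel (boundary at the midpoint
      between the two centers) and floor at ``voxel_size / 2``, so a
      single isolated voxel reads half a voxel.  Lower bracket; tends to
      underestimate beams thinner than a voxel.
    - ``"midpoint"``: subtract a quarter voxel (midpoint of the bracket),
      floored at ``voxel_size / 2``.  Least biased for sub-voxel beams.
    - ``"none"``: the raw distance.  Upper bracket.

    Background voxels are 0.
    """
    h = bin.voxel_size
    # the volume ends at its faces: treat outside as background so the
    # field is defined even for an all-foreground grid
    padded = np.pad(bin.mask, 1, mode="constant", constant_values=False)
    d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1] * h
    if correction == "center":
        d = np.where(bin.mask, np.maximum(d - h / 2.0, h / 2.0), 0.0)
    elif correction == "midpoint":
        d = np.where(bin.mask, np.maximum(d - h / 4.0, h / 2.0), 0.0)
    elif correction != "none":
        raise ValueError(f"unknown radius correction {correction!r}")
    return d


def _voxel_to_um(idx_zyx: np.ndarray, voxel_size: float, origin: np.ndarray) -> np.ndarray:
    """Voxel indices [z, y, x] -> physical (x, y, z) µm at voxel centers."""
    idx = np.atleast_2d(idx_zyx)
    return origin + (idx[:, ::-1] + 0.5) * voxel_size


def build_spatial_graph(skel: BinaryVolume, radii: np.ndarray | None = None) -> SpatialGraph:
    """Convert a skeleton mask (+ optional radius field, µm) to a graph.

    Junction voxel clusters (26-connected runs of voxels with >= 3
    skeleton neighbors) collapse to one node at the cluster centroid;
    degree-1 voxels become endpoint nodes; pure cycles with no junction
    are anchored at their lexicographically smallest voxel.  Polyline
    points carry the radius field sampled at their voxel; node radii are
    sampled at the node's nearest skeleton voxel.
    """
    mask = skel.mask
    if not mask.any():
        raise ValueError("empty skeleton")
    h, origin = skel.voxel_size, skel.origin
    vox = np.argwhere(mask)
    index = {tuple(v): i for i, v in enumerate(vox)}
    nv = len(vox)

    order: list[dict[int, int]] = [dict() for _ in range(nv)]  # j -> adjacency order
    for i, v in enumerate(vox):
        for off in _OFFSETS:
            j = index.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None and j > i:
                o = int(np.abs(off).sum())  # 1 face, 2 edge, 3 vertex
                order[i][j] = o
                order[j][i] = o
    # drop diagonal adjacencies that are implied by two lower-order steps:
    # a 26-connected digital path otherwise produces triangles whose corner
    # voxels read as spurious junctions
    for a in range(nv):
        for b, o in sorted(order[a].items()):
            if b < a or o == 1:
                continue
            for c in order[a]:
                if c in order[b] and max(order[a][c], order[b][c]) < o:
                    del order[a][b]
                    del order[b][a]
                    break
    neighbors: list[list[int]] = [sorted(order[i]) for i in range(nv)]
    degree = np.array([len(n) for n in neighbors])

    # --- node voxels: junctions (clustered), endpoints, isolated voxels ----
    is_junction = degree >= 3
    cluster = np.full(nv, -1, dtype=int)
    clusters: list[list[int]] = []
    for i in np.nonzero(is_junction)[0]:
        if cluster[i] >= 0:
            continue
        stack, members = [i], []
        cluster[i] = len(clusters)
        while stack:
            k = stack.pop()
            members.append(k)
            for j in neighbors[k]:
                if is_junction[j] and cluster[j] < 0:
                    cluster[j] = len(clusters)
                    stack.append(j)
        clusters.append(members)

    graph = SpatialGraph()
    vox_node = np.full(nv, -1, dtype=int)  # voxel -> node id (node voxels only)
    node_anchor: dict[int, int] = {}       # node id -> representative voxel

    def sample_radius(i: int) -> float | None:
        if radii is None:
            return None
        return float(max(radii[tuple(vox[i])], 1e-12))

    # junction-cluster nodes, ordered by lexicographically smallest member.
    # The node sits at the thickest member voxel (junctions are local
    # maxima of the radius field); a plain centroid drifts along the
    # incident beams when thinning leaves an asymmetric cluster.
    for members in sorted(clusters, key=lambda m: tuple(vox[min(m, key=lambda k: tuple(vox[k]))])):
        if radii is not None and len(members) > 1:
            rep = max(members, key=lambda k: (radii[tuple(vox[k])],
                                              tuple(-c for c in vox[k])))
            coord = _voxel_to_um(vox[rep], h, origin)[0]
        else:
            rep = min(members, key=lambda k: tuple(vox[k]))
            coord = _voxel_to_um(vox[members], h, origin).mean(axis=0)
        nid = graph.add_node(coord, sample_radius(rep))
        node_anchor[nid] = rep
        for k in members:
            vox_node[k] = nid
    # endpoint and isolated-voxel nodes
    for i in np.nonzero(degree <= 1)[0]:
        coord = _voxel_to_um(vox[i], h, origin)[0]
        nid = graph.add_node(coord, sample_radius(i))
        node_anchor[nid] = i
        vox_node[i] = nid

    # --- trace segments ----------------------------------------------------
    used = set()  # undirected voxel-adjacency pairs already consumed

    def consume(a: int, b: int) -> None:
        used.add((a, b) if a < b else (b, a))

    def is_used(a: int, b: int) -> bool:
        return ((a, b) if a < b else (b, a)) in used

    def trace(start_vox: int, first: int):
        """Walk from a node voxel through path voxels to the next node voxel."""
        chain = [start_vox, first]
        consume(start_vox, first)
        cur, prev = first, start_vox
        while vox_node[cur] < 0:
            nxt = [j for j in neighbors[cur] if j != prev and not is_used(cur, j)]
            # prefer continuing to an unvisited neighbor; a path voxel has
            # exactly two neighbors so this is deterministic
            if not nxt:
                return None  # dead end into consumed territory (shouldn't happen)
            step = nxt[0]
            consume(cur, step)
            chain.append(step)
            prev, cur = cur, step
        return chain

    def add_segment_from_chain(chain: list[int]) -> None:
        a, b = vox_node[chain[0]], vox_node[chain[-1]]
        pts = _voxel_to_um(vox[chain], h, origin)
        pts[0] = graph.nodes[a].coord
        pts[-1] = graph.nodes[b].coord
        rr = None
        if radii is not None:
            rr = np.array([max(radii[tuple(vox[k])], 1e-12) for k in chain])
        graph.add_segment(a, b, pts, rr)

    node_vox_order = sorted(np.nonzero(vox_node >= 0)[0], key=lambda i: tuple(vox[i]))
    for i in node_vox_order:
        for j in sorted(neighbors[i], key=lambda j: tuple(vox[j])):
            if is_used(i, j):
                continue
            if vox_node[j] >= 0:
                if vox_node[j] == vox_node[i]:
                    consume(i, j)  # intra-cluster adjacency, not a segment
                    continue
                consume(i, j)
                add_segment_from_chain([i, j])
            else:
                chain = trace(i, j)
                if chain is not None:
                    add_segment_from_chain(chain)

    # --- pure cycles: components of degree-2 voxels with no node ----------
    visited = np.zeros(nv, dtype=bool)
    visited[vox_node >= 0] = True
    order = sorted(range(nv), key=lambda i: tuple(vox[i]))
    for i in order:
        if visited[i] or vox_node[i] >= 0:
            continue
        # mark component reachable through path voxels
        comp = [i]
        visited[i] = True
        stack = [i]
        touches_node = False
        while stack:
            k = stack.pop()
            for j in neighbors[k]:
                if vox_node[j] >= 0:
                    touches_node = True
                elif not visited[j]:
                    visited[j] = True
                    comp.append(j)
                    stack.append(j)
        if touches_node:
            continue  # already traced from a node
        # anchor the cycle at its lexicographically smallest voxel
        anchor = min(comp, key=lambda k: tuple(vox[k]))
        coord = _voxel_to_um(vox[anchor], h, origin)[0]
        nid = graph.add_node(coord, sample_radius(anchor))
        node_anchor[nid] = anchor
        vox_node[anchor] = nid
        nbrs = sorted(neighbors[anchor], key=lambda j: tuple(vox[j]))
        if nbrs:
            chain = trace(anchor, nbrs[0])
            if chain is not None:
                add_segment_from_chain(chain)
    return graph


def merge_close_nodes(graph: SpatialGraph, radius: float) -> SpatialGraph:
    """Merge nodes closer than ``radius`` (µm, single-link), in place.

    Thinning can split one anatomical junction into a few nearby nodes;
    clusters are replaced by a node at their centroid and incident
    segments are re-anchored (their end point snaps to the new
    coordinate).  Segments that collapse to zero extent are dropped.
    """
    ids = sorted(graph.nodes)
    if not ids:
        return graph
    coords = np.array([graph.nodes[i].coord for i in ids])
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(radius)):
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(ids)):
        groups.setdefault(find(i), []).append(i)
    remap: dict[int, int] = {}
    for members in groups.values():
        keep = ids[min(members)]
        centroid = coords[members].mean(axis=0)
        radii = [graph.nodes[ids[m]].radius for m in members
                 if graph.nodes[ids[m]].radius is not None]
        for m in members:
            remap[ids[m]] = keep
            if ids[m] != keep:
                del graph.nodes[ids[m]]
        graph.nodes[keep].coord = centroid
        if radii:
            graph.nodes[keep].radius = float(np.median(radii))
    for s in list(graph.segments):
        s.start = remap[s.start]
        s.end = remap[s.end]
        s.points[0] = graph.nodes[s.start].coord
        s.points[-1] = graph.nodes[s.end].coord
        if s.start == s.end and len(s.points) <= 3:
            graph.segments.remove(s)
    return graph


def drop_short_loops(graph: SpatialGraph, max_length: float) -> SpatialGraph:
    """Remove self-loop segments shorter than ``max_length`` (µm), in place.

    Sub-resolution tunnels at thick junction regions survive homotopic
    thinning as tiny cycles; genuine anatomical loops are far longer.
    """
    for s in list(graph.segments):
        if not s.is_loop:
            continue
        L = float(np.sum(np.linalg.norm(np.diff(s.points, axis=0), axis=1)))
        if L < max_length:
            graph.segments.remove(s)
    return graph


def merge_parallel_segments(graph: SpatialGraph) -> SpatialGraph:
    """Reduce multi-edges to the shortest strand per node pair, in place.

    Trabecular networks are simple graphs at the segment scale; multiple
    recovered strands between one node pair are double-stranded thinning
    artifacts.  The strand with the shortest curved length survives (ties:
    smallest id).
    """
    by_pair: dict[tuple[int, int], list] = {}
    for s in graph.segments:
        if not s.is_loop:
            by_pair.setdefault((min(s.start, s.end), max(s.start, s.end)), []).append(s)
    for segs in by_pair.values():
        if len(segs) < 2:
            continue
        def key(s):
            return (float(np.sum(np.linalg.norm(np.diff(s.points, axis=0), axis=1))), s.id)
        for s in sorted(segs, key=key)[1:]:
            graph.segments.remove(s)
    return graph


def contract_short_junction_edges(graph: SpatialGraph, max_length: float) -> SpatialGraph:
    """Contract junction-junction segments shorter than ``max_length`` (µm).

    Thinning can split one anatomical junction into two nearby nodes
    joined by a stub much shorter than any real trabecula; contracting
    the stub merges the pair at the stub midpoint.  Repeats until stable.
    """
    changed = True
    while changed:
        changed = False
        valence = {nid: graph.valence(nid) for nid in graph.nodes}
        for s in sorted(graph.segments, key=lambda s: s.id):
            if s.is_loop:
                continue
            if valence.get(s.start, 0) < 3 or valence.get(s.end, 0) < 3:
                continue
            L = float(np.sum(np.linalg.norm(np.diff(s.points, axis=0), axis=1)))
            if L >= max_length:
                continue
            a, b = s.start, s.end
            mid = (graph.nodes[a].coord + graph.nodes[b].coord) / 2.0
            graph.segments.remove(s)
            for t in graph.segments:
                if t.start == b:
                    t.start = a
                if t.end == b:
                    t.end = a
            del graph.nodes[b]
            graph.nodes[a].coord = mid
            for t in graph.segments:
                if t.start == a:
                    t.points[0] = mid
                if t.end == a:
                    t.points[-1] = mid
                if t.start == a and t.end == a and len(t.points) <= 3:
                    graph.segments.remove(t)
            changed = True
            break
    return graph


def split_fused_junctions(graph: SpatialGraph, min_valence: int = 6,
                          attach_dist: float = 4.5,
                          min_separation: float = 4.5) -> SpatialGraph:
    """Split implausibly high-valence nodes whose arms form two bundles.

    Two anatomical junctions closer than the beam thickness fuse into one
    thick blob during rasterization and thinning, producing nodes of
    valence >= ``min_valence`` that are rare in real trabecular lattices.
    For each such node the incident arms are represented by the polyline
    point about ``attach_dist`` µm out; the best two-group partition
    (minimal within-group scatter, exhaustive, deterministic) is accepted
    when the group centroids are at least ``min_separation`` µm apart and
    each group keeps two arms.  The node is replaced by two nodes at the
    group centroids joined by a new straight segment.
    """
    from itertools import combinations
    next_seg_id = max((s.id for s in graph.segments), default=-1) + 1
    for nid in sorted(graph.nodes):
        if nid not in graph.nodes or graph.valence(nid) < min_valence:
            continue
        arms = []  # (segment, end_flag) end_flag True if segment.end == nid
        for s in graph.incident_segments(nid):
            if s.is_loop:
                arms = []
                break
            arms.append((s, s.end == nid))
        if len(arms) < min_valence:
            continue

        def attach_point(s, at_end):
            pts = s.points[::-1] if at_end else s.points
            acc = 0.0
            for i in range(1, len(pts)):
                acc += float(np.linalg.norm(pts[i] - pts[i - 1]))
                if acc >= attach_dist:
                    return pts[i]
            return pts[-1]

        att = np.array([attach_point(s, e) for s, e in arms])
        n = len(arms)
        best = None
        for k in range(2, n - 1):
            for subset in combinations(range(n), k):
                a = np.array(subset)
                b = np.setdiff1d(np.arange(n), a)
                ca, cb = att[a].mean(axis=0), att[b].mean(axis=0)
                score = float(((att[a] - ca) ** 2).sum() + ((att[b] - cb) ** 2).sum())
                if best is None or score < best[0]:
                    best = (score, a, b, ca, cb)
        _, a, b, ca, cb = best
        if np.linalg.norm(ca - cb) < min_separation:
            continue
        node = graph.nodes[nid]
        # place the split pair halfway between the blob center and the
        # bundle centroids: far enough to restore the lost beam, close
        # enough not to eat into the arms' lengths
        ca = node.coord + 0.5 * (ca - node.coord)
        cb = node.coord + 0.5 * (cb - node.coord)
        nid_b = max(graph.nodes) + 1
        graph.add_node(cb, node.radius, node_id=nid_b)
        node.coord = ca
        for idx in b:
            s, at_end = arms[idx]
            if at_end:
                s.end = nid_b
            else:
                s.start = nid_b
        for s, at_end in arms:
            target = graph.nodes[s.end if at_end else s.start].coord
            if at_end:
                s.points[-1] = target
            else:
                s.points[0] = target
        graph.add_segment(nid, nid_b, np.array([ca, cb]),
                          None if node.radius is None else
                          np.array([node.radius, node.radius]),
                          segment_id=next_seg_id)
        next_seg_id += 1
    return graph


def bridge_gaps(graph: SpatialGraph, max_gap: float) -> SpatialGraph:
    """Reconnect facing leaf tips separated by less than ``max_gap`` (µm).

    Beams thinner than a voxel can rasterize with small gaps; the two
    resulting free ends point at each other and are rejoined into a
    single segment.  A pair qualifies when each tip's outgoing segment
    direction is broadly aligned with the straight line to the other tip.
    """
    from scipy.spatial import cKDTree
    while True:
        leaves = [nid for nid in sorted(graph.nodes) if graph.valence(nid) == 1]
        if len(leaves) < 2:
            return graph
        coords = np.array([graph.nodes[n].coord for n in leaves])
        tree = cKDTree(coords)
        merged = False
        for i, j in sorted(tree.query_pairs(max_gap)):
            a, b = leaves[i], leaves[j]
            sa = graph.incident_segments(a)[0]
            sb = graph.incident_segments(b)[0]
            if sa is sb:
                continue
            gap = graph.nodes[b].coord - graph.nodes[a].coord
            gap_n = gap / max(np.linalg.norm(gap), 1e-12)
            da = _tip_direction(sa, a)
            db = _tip_direction(sb, b)
            if np.dot(da, gap_n) < 0.3 or np.dot(db, -gap_n) < 0.3:
                continue
            pa = sa.points if sa.end == a else sa.points[::-1]
            ra = None if sa.radii is None else (sa.radii if sa.end == a else sa.radii[::-1])
            pb = sb.points if sb.start == b else sb.points[::-1]
            rb = None if sb.radii is None else (sb.radii if sb.start == b else sb.radii[::-1])
            start = sa.start if sa.end == a else sa.end
            end = sb.end if sb.start == b else sb.start
            pts = np.vstack([pa, pb])
            rr = None
            if ra is not None and rb is not None:
                rr = np.concatenate([ra, rb])
            graph.segments.remove(sa)
            graph.segments.remove(sb)
            graph.segments.append(type(sa)(sa.id, start, end, pts, rr))
            del graph.nodes[a]
            del graph.nodes[b]
            merged = True
            break
        if not merged:
            return graph


def _tip_direction(segment, leaf_id: int) -> np.ndarray:
    """Outgoing unit direction at a leaf tip (from last interior point)."""
    p = segment.points if segment.end == leaf_id else segment.points[::-1]
    v = p[-1] - p[max(len(p) - 3, 0)]
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.zeros(3)


def prune_spurs(graph: SpatialGraph, min_length: float,
                bounds: tuple[np.ndarray, np.ndarray] | None = None,
                boundary_margin: float = 0.0) -> SpatialGraph:
    """Remove artifact leaf segments, in place.

    Leaf segments shorter than ``min_length`` (µm) are dead-end twigs
    left by thinning of thick junction regions.  When ``bounds`` (low and
    high corner of the volume, µm) is given, interior free ends are
    removed regardless of length: the stereom is a fully connected
    lattice, so a trabecula ending freely away from the subvolume faces
    (farther than ``boundary_margin``) is a reconstruction artifact,
    whereas beams truncated by the faces are real and survive.  Iterates
    until stable, then removes orphaned nodes.
    """
    changed = True
    while changed:
        changed = False
        valence = {nid: graph.valence(nid) for nid in graph.nodes}
        for s in list(graph.segments):
            if s.is_loop:
                continue
            leaf_ends = [n for n in (s.start, s.end) if valence.get(n) == 1]
            if not leaf_ends:
                continue
            L = float(np.sum(np.linalg.norm(np.diff(s.points, axis=0), axis=1)))
            remove = L < min_length
            if not remove and bounds is not None:
                lo, hi = bounds
                tips_interior = all(
                    np.all(graph.nodes[n].coord - lo > boundary_margin) and
                    np.all(hi - graph.nodes[n].coord > boundary_margin)
                    for n in leaf_ends)
                remove = tips_interior
            if remove:
                graph.segments.remove(s)
                changed = True
                break
    used = {n for s in graph.segments for n in (s.start, s.end)}
    for nid in [n for n in graph.nodes if n not in used]:
        del graph.nodes[nid]
    return graph


def weld_pass_through(graph: SpatialGraph) -> SpatialGraph:
    """Join the two segments at every 2-valent node, in place.

    Spur pruning and tracing artifacts leave pass-through nodes that
    artificially split trabeculae; welding restores maximal segments.
    Nodes carried by a self-loop are left alone.
    """
    changed = True
    while changed:
        changed = False
        for nid in sorted(graph.nodes):
            inc = graph.incident_segments(nid)
            if len(inc) != 2 or any(s.is_loop for s in inc):
                continue
            s1, s2 = inc
            p1 = s1.points if s1.end == nid else s1.points[::-1]
            r1 = None if s1.radii is None else (s1.radii if s1.end == nid else s1.radii[::-1])
            p2 = s2.points if s2.start == nid else s2.points[::-1]
            r2 = None if s2.radii is None else (s2.radii if s2.start == nid else s2.radii[::-1])
            a = s1.start if s1.end == nid else s1.end
            b = s2.end if s2.start == nid else s2.start
            pts = np.vstack([p1, p2[1:]])
            rr = None
            if r1 is not None and r2 is not None:
                rr = np.concatenate([r1, r2[1:]])
            graph.segments.remove(s1)
            graph.segments.remove(s2)
            graph.segments.append(type(s1)(s1.id, a, b, pts, rr))
            del graph.nodes[nid]
            changed = True
            break
    return graph


def refine_junction_positions(graph: SpatialGraph, fit_from: float,
                              fit_to: float, max_shift: float) -> SpatialGraph:
    """Re-estimate junction coordinates from incident arm directions.

    Thinning places junction voxels inside the thick blob where arms
    meet, biased toward the widest incident beam, which systematically
    shortens chords.  Each arm's centerline is fit over the arc-length
    window [``fit_from``, ``fit_to``] µm from the node (outside the
    blob), the node is moved to the least-squares intersection of the
    fitted arm lines (clamped to ``max_shift``), and incident endpoints
    are re-snapped.  Nodes with fewer than 3 fittable arms keep their
    position.
    """
    new_coords: dict[int, np.ndarray] = {}
    for nid in sorted(graph.nodes):
        arms = [s for s in graph.incident_segments(nid) if not s.is_loop]
        if len(arms) < 3:
            continue
        A = np.zeros((3, 3))
        b = np.zeros(3)
        n_fit = 0
        for s in arms:
            pts = s.points if s.start == nid else s.points[::-1]
            arc = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            sel = (arc >= fit_from) & (arc <= fit_to)
            if sel.sum() < 2:
                continue
            seg_pts = pts[sel]
            centroid = seg_pts.mean(axis=0)
            d = seg_pts[-1] - seg_pts[0]
            norm = np.linalg.norm(d)
            if norm < 1e-9:
                continue
            d = d / norm
            P = np.eye(3) - np.outer(d, d)
            A += P
            b += P @ centroid
            n_fit += 1
        if n_fit < 3:
            continue
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        shift = x - graph.nodes[nid].coord
        norm = np.linalg.norm(shift)
        if norm > max_shift:
            x = graph.nodes[nid].coord + shift * (max_shift / norm)
        new_coords[nid] = x
    for nid, x in new_coords.items():
        graph.nodes[nid].coord = x
        for s in graph.incident_segments(nid):
            if s.start == nid:
                s.points[0] = x
            if s.end == nid:
                s.points[-1] = x
    return graph


def smooth_polylines(graph: SpatialGraph, iterations: int = 2,
                     lam: float = 0.5) -> SpatialGraph:
    """Laplacian smoothing of interior polyline points (endpoints fixed).

    Voxel-center polylines follow the digital staircase of the grid, which
    inflates curved length (and hence tortuosity) by several percent; a few
    relaxation passes remove the staircase while leaving genuine curvature
    at the segment scale mostly intact.  Operates in place and returns the
    graph.
    """
    for s in graph.segments:
        if len(s.points) < 3:
            continue
        p = s.points
        for _ in range(iterations):
            p[1:-1] += lam * ((p[:-2] + p[2:]) / 2.0 - p[1:-1])
    return graph


def skeleton_to_graph(bin: BinaryVolume, radius_correction: str = "midpoint",
                      smooth_iterations: int = 2,
                      spur_length_vox: float = 2.0,
                      weld: bool = True) -> SpatialGraph:
    """Full chain: skeletonize, radius field, graph, cleaning, smoothing.

    Cleaning removes leaf twigs shorter than ``spur_length_vox`` voxels
    and welds the resulting pass-through nodes back into maximal
    segments.  ``radius_correction`` selects the boundary convention of
    :func:`radius_map` ("midpoint", "center", or "none").
    """
    h = bin.voxel_size
    skel = skeletonize(bin)
    radii = radius_map(bin, correction=radius_correction)
    g = build_spatial_graph(skel, radii)
    merge_close_nodes(g, 1.5 * h)
    drop_short_loops(g, 5.0 * h)
    merge_parallel_segments(g)
    contract_short_junction_edges(g, 2.0 * h)
    bridge_gaps(g, 3.0 * h)
    if spur_length_vox:
        lo = bin.origin
        hi = bin.origin + np.array(bin.mask.shape[::-1]) * h
        prune_spurs(g, spur_length_vox * h, bounds=(lo, hi),
                    boundary_margin=2.0 * h)
    if weld:
        weld_pass_through(g)
    merge_parallel_segments(g)
    drop_short_loops(g, 5.0 * h)
    refine_junction_positions(g, fit_from=1.0 * h, fit_to=3.5 * h,
                              max_shift=1.5 * h)
    if smooth_iterations:
        smooth_polylines(g, smooth_iterations)
    return g
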