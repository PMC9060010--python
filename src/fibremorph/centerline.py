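"""Centreline extraction: thinning, skeleton graph, refinement, resampling.

The binary mask is resampled to an isotropic grid (3D thinning assumes
isotropy), homotopically thinned to a one-voxel skeleton, and converted
into a spatial graph of endpoint/junction nodes and polyline edges in
physical (x, y, z) µm. Centrelines are then refined toward the local
centre of gravity of the fibre cross-section and resampled at a fixed
1 µm arc-length step — the sampling on which length and curvature are
defined.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from fibremorph.segmentation import BinaryMask

logger = logging.getLogger(__name__)

_NEIGH = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=int,
)


@dataclass
class FibrePath:
    """One fibre centreline resampled at fixed arc-length step.

    ``points`` is (N, 3) in (x, y, z) µm; consecutive points are
    ``step_um`` apart except possibly the final, shorter interval.
    """

    points: np.ndarray
    step_um: float = 1.0
    source_edge: tuple | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("FibrePath needs >= 2 points of (x, y, z)")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SkeletonGraph:
    """Spatial graph of fibre centrelines.

    Wraps a networkx MultiGraph whose nodes carry ``position`` ((x, y, z)
    µm) and ``kind`` (endpoint | junction | isolated), and whose edges
    carry ``polyline`` ((N, 3) µm, including both node positions) and
    ``length`` (µm).
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    @property
    def junctions(self) -> list[int]:
        return self.nodes_of_kind("junction")

    @property
    def endpoints(self) -> list[int]:
        return self.nodes_of_kind("endpoint")

    def edge_polylines(self):
        """Yield (u, v, key, polyline) for every edge."""
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            yield u, v, k, d["polyline"]

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def junction_positions(self) -> np.ndarray:
        js = self.junctions
        if not js:
            return np.empty((0, 3))
        return np.array([self.graph.nodes[j]["position"] for j in js])

    def to_json(self) -> str:
        obj = {
            "spacing_um": list(self.spacing),
            "nodes": [
                {"id": int(n), "position_um": list(map(float, d["position"])), "kind": d["kind"]}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"id": int(k), "nodes": [int(u), int(v)],
                 "length_um": float(d["length"]),
                 "polyline_um": np.asarray(d["polyline"]).round(4).tolist()}
                for u, v, k, d in self.graph.edges(keys=True, data=True)
            ],
        }
        return json.dumps(obj)

    def to_swc(self) -> str:
        """SWC-like text (id, type, x, y, z, radius, parent) for viewers."""
        lines = []
        idx = 1
        for u, v, k, poly in self.edge_polylines():
            parent = -1
            for p in poly:
                lines.append(f"{idx} 0 {p[0]:.3f} {p[1]:.3f} {p[2]:.3f} 1.0 {parent}")
                parent = idx
                idx += 1
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Thinning
# ---------------------------------------------------------------------------

def skeletonize(mask: BinaryMask) -> tuple[np.ndarray, float]:
    """Thin a mask to a one-voxel skeleton on an isotropic working grid.

    The mask is resampled by nearest neighbour to an isotropic grid at
    ``min(spacing)`` and thinned by 3D homotopic thinning (topology is
    preserved: the component count does not change). Returns the skeleton
    boolean grid and its isotropic spacing (µm).
    """
    if not mask.voxels.any():
        raise ValueError("cannot skeletonize an empty mask")
    iso = float(min(mask.spacing))
    factors = [s / iso for s in mask.spacing]
    if any(abs(f - 1.0) > 1e-9 for f in factors):
        vol = ndimage.zoom(mask.voxels, zoom=factors, order=0)
    else:
        vol = mask.voxels
    skel = np.asarray(_sk_skeletonize(vol), dtype=bool)

    # The Lee thinning implementation can annihilate a component whose
    # cross-section is mirror-symmetric about a half-integer centre
    # (e.g. an even-diameter tube dead on the grid): every component of
    # the mask must keep at least one skeleton voxel. Failing components
    # are re-thinned with a one-voxel directional smear that breaks the
    # parity; the resulting half-voxel bias is removed downstream by the
    # centre-of-gravity refinement.
    struct = np.ones((3, 3, 3), dtype=int)
    labels, n = ndimage.label(vol, structure=struct)
    for comp in range(1, n + 1):
        sel = labels == comp
        if skel[sel].any():
            continue
        for axis in (1, 0, 2):
            smear = sel | _shift_bool(sel, axis, 1)
            s2 = np.asarray(_sk_skeletonize(smear), dtype=bool)
            if not s2.any():
                continue
            stray = s2 & ~sel
            if stray.any():
                s2 = (s2 & sel) | (_shift_bool(stray, axis, -1) & sel)
            if s2.any():
                logger.info(
                    "skeletonize: parity fallback (axis %d) for component %d", axis, comp
                )
                skel |= s2
                break
        else:  # pragma: no cover - last resort, keep the component visible
            com = np.round(ndimage.center_of_mass(sel)).astype(int)
            if sel[tuple(com)]:
                skel[tuple(com)] = True
    return skel, iso


def _shift_bool(a: np.ndarray, axis: int, by: int) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if by > 0:
        src[axis] = slice(0, a.shape[axis] - by)
        dst[axis] = slice(by, None)
    else:
        src[axis] = slice(-by, None)
        dst[axis] = slice(0, a.shape[axis] + by)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    counts = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    return counts * skel


def _vox_to_um(vox: np.ndarray, spacing) -> np.ndarray:
    """(z, y, x) integer indices -> (x, y, z) µm."""
    vox = np.atleast_2d(vox)
    dz, dy, dx = spacing
    return np.stack([vox[:, 2] * dx, vox[:, 1] * dy, vox[:, 0] * dz], axis=1)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(skeleton: np.ndarray, spacing) -> SkeletonGraph:
    """Convert a voxel skeleton into a SkeletonGraph.

    Voxels are classified by 26-neighbour count (1 endpoint, >= 3 junction
    candidate); 26-connected clusters of junction candidates merge into a
    single junction node at their centroid (prevents double counting at
    thick crossings); edges are traced voxel to voxel between nodes.
    Closed loops without any node receive one anchor node of kind
    "isolated".
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise ValueError("empty skeleton")
    counts = _neighbor_counts(skel)

    g = nx.MultiGraph()
    node_label = np.full(skel.shape, -1, dtype=np.int64)
    next_id = 0

    # junction clusters
    jmask = skel & (counts >= 3)
    struct = np.ones((3, 3, 3), dtype=int)
    jlabels, nj = ndimage.label(jmask, structure=struct)
    for lab in range(1, nj + 1):
        vox = np.argwhere(jlabels == lab)
        pos = _vox_to_um(vox, spacing).mean(axis=0)
        g.add_node(next_id, position=pos, kind="junction")
        node_label[tuple(vox.T)] = next_id
        next_id += 1

    # endpoints and isolated voxels
    for kind, sel in (("endpoint", counts == 1), ("isolated", counts == 0)):
        for vox in np.argwhere(skel & sel):
            pos = _vox_to_um(vox, spacing)[0]
            g.add_node(next_id, position=pos, kind=kind)
            node_label[tuple(vox)] = next_id
            next_id += 1

    shape = skel.shape

    def neighbors(v):
        cand = v + _NEIGH
        ok = np.all((cand >= 0) & (cand < shape), axis=1)
        cand = cand[ok]
        return cand[skel[tuple(cand.T)]]

    visited = np.zeros(skel.shape, dtype=bool)  # regular voxels consumed by a trace
    direct = set()  # deduped node-voxel-to-node-voxel adjacencies

    def add_edge(u, v, poly_vox):
        pts = _vox_to_um(np.asarray(poly_vox), spacing)
        # anchor polyline at the (possibly centroid-merged) node positions
        pts[0] = g.nodes[u]["position"]
        pts[-1] = g.nodes[v]["position"]
        pts = _dedup_consecutive(pts)
        if len(pts) < 2:
            pts = np.vstack([g.nodes[u]["position"], g.nodes[v]["position"]])
            if np.allclose(pts[0], pts[1]):
                return
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        g.add_edge(u, v, polyline=pts, length=length)

    node_voxels = np.argwhere(node_label >= 0)
    for nv in node_voxels:
        u = node_label[tuple(nv)]
        for w in neighbors(nv):
            wl = node_label[tuple(w)]
            if wl >= 0:
                if wl != u:
                    key = (min(tuple(nv), tuple(w)), max(tuple(nv), tuple(w)))
                    if key not in direct:
                        direct.add(key)
                        add_edge(u, wl, [nv, w])
                continue
            if visited[tuple(w)]:
                continue
            # walk the degree-2 chain starting into w
            path = [nv, w]
            visited[tuple(w)] = True
            prev, cur = nv, w
            while True:
                nbrs = neighbors(cur)
                nxt = None
                # prefer finishing on a node voxel, else continue the chain
                for cand in nbrs:
                    if np.array_equal(cand, prev):
                        continue
                    if node_label[tuple(cand)] >= 0:
                        nxt = cand
                        break
                if nxt is None:
                    for cand in nbrs:
                        if np.array_equal(cand, prev) or visited[tuple(cand)]:
                            continue
                        nxt = cand
                        break
                if nxt is None:
                    # dead end inside a chain (rare thinning artefact)
                    pos = _vox_to_um(cur[None], spacing)[0]
                    nonlocal_id = node_label[tuple(cur)]
                    if nonlocal_id < 0:
                        vl = g.number_of_nodes()
                        while vl in g:
                            vl += 1
                        g.add_node(vl, position=pos, kind="endpoint")
                        node_label[tuple(cur)] = vl
                    break
                path.append(nxt)
                if node_label[tuple(nxt)] >= 0:
                    break
                visited[tuple(nxt)] = True
                prev, cur = cur, nxt
            end = node_label[tuple(path[-1])]
            add_edge(u, end, path)

    # closed loops with no nodes: remaining unvisited regular voxels
    regular = skel & (counts == 2) & ~visited & (node_label < 0)
    llabels, nl = ndimage.label(regular, structure=struct)
    for lab in range(1, nl + 1):
        vox = np.argwhere(llabels == lab)
        anchor = vox[0]
        aid = max(g.nodes, default=-1) + 1
        g.add_node(aid, position=_vox_to_um(anchor[None], spacing)[0], kind="isolated")
        node_label[tuple(anchor)] = aid
        # trace the loop from the anchor back to itself
        nbrs = neighbors(anchor)
        nbrs = [n for n in nbrs if node_label[tuple(n)] < 0]
        if not nbrs:
            continue
        path = [anchor, nbrs[0]]
        visited[tuple(nbrs[0])] = True
        prev, cur = anchor, nbrs[0]
        while True:
            stepped = False
            for cand in neighbors(cur):
                if np.array_equal(cand, prev):
                    continue
                if np.array_equal(cand, anchor):
                    path.append(anchor)
                    stepped = False
                    break
                if not visited[tuple(cand)] and node_label[tuple(cand)] < 0:
                    path.append(cand)
                    visited[tuple(cand)] = True
                    prev, cur = cur, cand
                    stepped = True
                    break
            if not stepped:
                break
        if not np.array_equal(path[-1], anchor):
            path.append(anchor)
        add_edge(aid, aid, path)

    sg = SkeletonGraph(graph=g, spacing=tuple(spacing))
    _reclassify_and_merge(sg)
    return sg


def _dedup_consecutive(pts: np.ndarray) -> np.ndarray:
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > 1e-12:
            keep.append(i)
    return pts[keep]


def _reclassify_and_merge(sg: SkeletonGraph) -> None:
    """Set node kinds from actual degree; splice out degree-2 nodes."""
    g = sg.graph
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            deg = g.degree(n)
            if deg == 2 and g.nodes[n]["kind"] != "isolated":
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:  # self-loop counts double; leave it
                    continue
                (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                a = v1 if u1 == n else u1
                b = v2 if u2 == n else u2
                p1 = d1["polyline"] if np.allclose(d1["polyline"][-1], g.nodes[n]["position"]) \
                    else d1["polyline"][::-1]
                p2 = d2["polyline"] if np.allclose(d2["polyline"][0], g.nodes[n]["position"]) \
                    else d2["polyline"][::-1]
                merged = _dedup_consecutive(np.vstack([p1, p2]))
                g.remove_edge(u1, v1, k1)
                g.remove_edge(u2, v2, k2)
                g.remove_node(n)
                g.add_edge(a, b, polyline=merged,
                           length=float(np.linalg.norm(np.diff(merged, axis=0), axis=1).sum()))
                changed = True
                break
    for n in g.nodes:
        deg = g.degree(n)
        if deg >= 3:
            g.nodes[n]["kind"] = "junction"
        elif deg == 1:
            g.nodes[n]["kind"] = "endpoint"
        else:
            g.nodes[n]["kind"] = "isolated"


def prune_spurs(sg: SkeletonGraph, min_length_um: float = 3.0) -> SkeletonGraph:
    """Remove short terminal edges emanating from junctions.

    Thinning produces spurious short branches where the tube is thick;
    terminal edges shorter than ``min_length_um`` whose other end is a
    junction are deleted, degree-2 remnants are spliced, and the pass
    repeats until stable.
    """
    g = sg.graph
    n_pruned = 0
    changed = True
    while changed:
        changed = False
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if d["length"] >= min_length_um or u == v:
                continue
            du, dv = g.degree(u), g.degree(v)
            tip, hub = None, None
            if du == 1 and dv >= 3:
                tip, hub = u, v
            elif dv == 1 and du >= 3:
                tip, hub = v, u
            if tip is None:
                continue
            g.remove_edge(u, v, k)
            g.remove_node(tip)
            n_pruned += 1
            changed = True
        if changed:
            _reclassify_and_merge(sg)
    if n_pruned:
        logger.info("prune_spurs: removed %d spurs < %g µm", n_pruned, min_length_um)
    _reclassify_and_merge(sg)
    return sg


# ---------------------------------------------------------------------------
# Centre-of-gravity refinement
# ---------------------------------------------------------------------------

def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents: central differences inside, one-sided at the ends."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _plane_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(t)
    t = t / n if n > 0 else np.array([1.0, 0.0, 0.0])
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    return u, np.cross(t, u)


def cross_section_cog(
    mask: BinaryMask, point: np.ndarray, tangent: np.ndarray,
    r_max: float, step: float,
) -> tuple[np.ndarray, float] | None:
    """Centre of gravity and area of the fibre cross-section at ``point``.

    The plane normal to ``tangent`` is sampled on a grid (trilinear mask
    coverage); the connected blob containing the point is kept, other
    fibres passing through the plane are discarded. Returns the (x, y, z)
    µm centroid of that blob and its coverage-integrated area (µm²), or
    None when the point is outside the fibre.
    """
    from skimage import measure as _measure

    u, v = _plane_frame(tangent)
    n = int(math.ceil(r_max / step))
    coords_1d = np.arange(-n, n + 1) * step
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    plane = point[None, None] + uu[..., None] * u[None, None] + vv[..., None] * v[None, None]
    dz, dy, dx = mask.spacing
    idx = np.stack([plane[..., 2] / dz, plane[..., 1] / dy, plane[..., 0] / dx], axis=0)
    vals = ndimage.map_coordinates(
        mask.voxels.astype(float), idx.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(uu.shape)
    if vals[n, n] < 0.5:
        return None
    support = _measure.label(vals >= 0.1, connectivity=2)
    region = support == support[n, n]
    w = vals * region
    total = w.sum()
    if total <= 0:
        return None
    du = (w * uu).sum() / total
    dv = (w * vv).sum() / total
    return point + du * u + dv * v, float(total * step * step)


def refine_centerline(
    sg: SkeletonGraph, mask: BinaryMask, iterations: int = 2,
    refine_endpoint_nodes: bool = False,
) -> SkeletonGraph:
    """Move interior polyline points to the cross-sectional centre of gravity.

    At each interior point the mask is sampled (trilinear coverage) on the
    plane normal to the local tangent out to the local radial extent, and
    the point moves to the coverage-weighted centroid of the connected
    cross-section containing it — strictly within the normal plane, so
    points cannot migrate along the fibre. Tangents are estimated on a
    lightly pre-smoothed copy of the polyline to keep the section planes
    stable against voxel jitter. Node positions are fixed; points whose
    cross-section comes up empty stay put. Iterated ``iterations`` times
    (default 2; further iterations move points by well under a tenth of a
    voxel on tube phantoms).
    """
    dz, dy, dx = mask.spacing
    edt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    vox_max = float(max(mask.spacing))
    shape = mask.voxels.shape
    step = 0.5 * min(mask.spacing)

    def um_to_idx(p):  # (x, y, z) µm -> fractional (z, y, x) index
        return np.array([p[2] / dz, p[1] / dy, p[0] / dx])

    def inside(p):
        idx = np.round(um_to_idx(p)).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(mask.voxels[tuple(idx)])

    def local_radius(p):
        idx = um_to_idx(p)[None]
        return float(ndimage.map_coordinates(edt, idx.T, order=1, mode="nearest")[0])

    g = sg.graph
    out = SkeletonGraph(graph=g.copy(), spacing=sg.spacing)
    gg = out.graph
    for u, v, k, d in gg.edges(keys=True, data=True):
        poly = np.array(d["polyline"], dtype=float)
        if len(poly) < 3:
            continue
        # which polyline end belongs to which node (MultiGraph orientation
        # is not guaranteed to match insertion order)
        first_node = u if np.allclose(poly[0], gg.nodes[u]["position"]) else v
        last_node = v if first_node == u else u
        idx = list(range(1, len(poly) - 1))
        if refine_endpoint_nodes:
            # fibre-tip nodes are thinning artefacts off the true axis;
            # junctions stay anchored
            if gg.degree(first_node) == 1:
                idx = [0] + idx
            if gg.degree(last_node) == 1:
                idx = idx + [len(poly) - 1]
        for _ in range(iterations):
            tang = _tangents(_presmooth(poly))
            newpoly = poly.copy()
            for i in idx:
                p, t = poly[i], tang[i]
                r_s = max(3.0 * local_radius(p) + 2 * vox_max, 4 * vox_max)
                res = cross_section_cog(mask, p, t, r_s, step)
                if res is None:
                    logger.warning("refine_centerline: empty cross-section, point kept")
                    continue
                cand, _ = res
                if inside(cand):
                    newpoly[i] = cand
            poly = newpoly
        d["polyline"] = poly
        d["length"] = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        if refine_endpoint_nodes:
            if gg.degree(first_node) == 1:
                gg.nodes[first_node]["position"] = poly[0].copy()
            if gg.degree(last_node) == 1:
                gg.nodes[last_node]["position"] = poly[-1].copy()
    return out


def _presmooth(poly: np.ndarray, window: int = 5) -> np.ndarray:
    if len(poly) <= window:
        return poly
    half = window // 2
    pad = np.pad(poly, ((half, half), (0, 0)), mode="reflect", reflect_type="odd")
    k = np.ones(window) / window
    return np.stack([np.convolve(pad[:, d], k, "valid") for d in range(3)], axis=1)


def extend_terminal_edges(sg: SkeletonGraph, mask: BinaryMask) -> SkeletonGraph:
    """Extend endpoint edges along their end tangent to the mask boundary.

    Homotopic thinning retreats from fibre tips by roughly the tube
    radius, which would bias fibre length low by ~2r per fibre. Each
    terminal polyline is prolonged from its endpoint node along a
    least-squares local tangent, in half-voxel steps, until the trace
    leaves the mask or has covered the local fibre radius; the endpoint
    node moves to the new tip. Extended segments recover tip length but
    are not centred on the axis, so the caller records their extent and
    keeps them out of curvature and diameter estimates (see
    ``SkeletonGraph`` edge attribute ``ext_um``).
    """
    out = SkeletonGraph(graph=sg.graph.copy(), spacing=sg.spacing)
    g = out.graph
    dz, dy, dx = mask.spacing
    shape = mask.voxels.shape
    step = 0.5 * min(mask.spacing)
    edt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)

    def inside(p):
        idx = np.array([round(p[2] / dz), round(p[1] / dy), round(p[0] / dx)], dtype=int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(mask.voxels[tuple(idx)])

    def local_radius(p):
        idx = np.array([[p[2] / dz], [p[1] / dy], [p[0] / dx]])
        return float(ndimage.map_coordinates(edt, idx, order=1, mode="nearest")[0])

    for n in [n for n, d in g.nodes(data=True) if d["kind"] == "endpoint"]:
        edges = list(g.edges(n, keys=True, data=True))
        if len(edges) != 1:
            continue
        u, v, k, d = edges[0]
        poly = np.array(d["polyline"], dtype=float)
        at_start = np.allclose(poly[0], g.nodes[n]["position"])
        if not at_start:
            poly = poly[::-1]
        # outward tangent: least-squares line through the first few µm of path
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])
        m = max(int(np.searchsorted(arc, 3.0)), 1)
        seg = poly[: m + 1]
        t = seg[0] - seg.mean(axis=0)
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t /= norm
        tip = poly[0].copy()
        extended = []
        # thinning retreats by about the tube radius; cap the extension there
        max_ext = local_radius(tip) + 2 * min(mask.spacing)
        cog_step = 0.5 * min(mask.spacing)
        for _ in range(int(max_ext / step)):
            cand = tip + step * t
            if not inside(cand):
                break
            tip = cand
            extended.append(tip.copy())
        if extended:
            ext_len = float(len(extended) * step)
            poly = np.vstack([extended[::-1], poly])
            g.nodes[n]["position"] = poly[0].copy()
            e0, e1 = d.get("ext_um", (0.0, 0.0))
            if not at_start:
                poly = poly[::-1]
                d["ext_um"] = (e0, e1 + ext_len)
            else:
                d["ext_um"] = (e0 + ext_len, e1)
            d["polyline"] = poly
            d["length"] = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
    return out


# ---------------------------------------------------------------------------
# Resampling and smoothing
# ---------------------------------------------------------------------------

def resample_arclength(
    polyline: np.ndarray, step_um: float = 1.0, source_edge=None
) -> FibrePath:
    """Resample a polyline at fixed arc-length steps by linear interpolation.

    Points sit at cumulative arc lengths 0, Δs, 2Δs, …; the original end
    point is always kept, so the final interval may be shorter than Δs.
    """
    poly = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = int(math.floor(total / step_um + 1e-9))
    targets = np.arange(k + 1) * step_um
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    pts = np.empty((len(targets), 3))
    for d in range(3):
        pts[:, d] = np.interp(targets, cum, poly[:, d])
    pts[0] = poly[0]
    pts[-1] = poly[-1]
    return FibrePath(points=pts, step_um=step_um, source_edge=source_edge)


def smooth_path(path: FibrePath, window: int = 5) -> FibrePath:
    """Moving-average smoothing of the coordinates with reflective ends.

    Stabilizes second differences against voxel-scale jitter; window 1 is
    the identity and the first and last points are preserved exactly.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window == 1 or len(path) <= 2:
        return FibrePath(path.points.copy(), path.step_um, path.source_edge)
    half = window // 2
    eff = min(half, len(path) - 1)
    # odd reflection continues the path linearly past its ends, so straight
    # paths stay exactly straight under the moving average
    padded = np.pad(path.points, ((eff, eff), (0, 0)), mode="reflect", reflect_type="odd")
    kernel = np.ones(2 * eff + 1) / (2 * eff + 1)
    sm = np.stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(3)], axis=1
    )
    sm[0] = path.points[0]
    sm[-1] = path.points[-1]
    return FibrePath(sm, path.step_um, path.source_edge)


def trim_polyline(poly: np.ndarray, start_um: float, end_um: float) -> np.ndarray:
    """Cut ``start_um`` / ``end_um`` of arc length off the polyline's ends.

    Cut points are interpolated on the polyline; returns at least the
    middle point when the trims would consume the whole line.
    """
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s0, s1 = max(start_um, 0.0), total - max(end_um, 0.0)
    if s1 - s0 <= 1e-9:
        mid = np.searchsorted(cum, total / 2)
        return poly[max(mid - 1, 0):mid + 1]
    out = [np.array([np.interp(s0, cum, poly[:, d]) for d in range(3)])]
    inner = (cum > s0 + 1e-12) & (cum < s1 - 1e-12)
    out.extend(poly[inner])
    out.append(np.array([np.interp(s1, cum, poly[:, d]) for d in range(3)]))
    return np.asarray(out)


def fit_path(path: FibrePath, max_window: int = 21) -> FibrePath:
    """Local quadratic (Savitzky-Golay) fit of the path coordinates.

    A quadratic-preserving filter leaves the curvature of circular paths
    intact while suppressing voxel-scale jitter far more strongly than a
    short moving average — jitter enters the second difference at 1/Δs²
    and otherwise dominates gently curved fibres. The window spans the
    whole path up to ``max_window`` points (short fibres get a single
    quadratic fit, which keeps their curvature estimate stable); paths
    too short for a window of 5 fall back to the moving average.
    """
    from scipy.signal import savgol_filter

    n = len(path)
    w = min(n - (1 - n % 2), max_window)
    if w < 5:
        return smooth_path(path, window=min(5, n | 1))
    sm = savgol_filter(path.points, w, 2, axis=0, mode="interp")
    return FibrePath(sm, path.step_um, path.source_edge)
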