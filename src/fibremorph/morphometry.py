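"""Per-fibre and per-field structural metrics.

Implements the six fibre metrics — volume fraction, surface area, branch
count, length, diameter (thickness) and mean curvature — plus the
two-channel fluorescence intensity ratio, and the ``analyze_field``
pipeline that ties segmentation, skeletonization and measurement
together.

Curvature is defined as the mean norm of the vector second difference of
the 1 µm arc-length-resampled centreline, ‖p_{i+1} − 2p_i + p_{i−1}‖/Δs²,
which estimates geometric curvature (1/R for a circle, a/(a²+c²) for a
helix). Thickness is reported as the equivalent-circle diameter
2√(A/π) of the fibre cross-section in the plane perpendicular to the
local tangent; a distance-transform fallback (2× the EDT value at the
centreline point) is available and must agree within one voxel on
straight tubes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import measure

from fibremorph.centerline import (
    FibrePath,
    SkeletonGraph,
    _tangents,
    build_graph,
    extend_terminal_edges,
    fit_path,
    prune_spurs,
    refine_centerline,
    resample_arclength,
    skeletonize,
    smooth_path,
    trim_polyline,
)
from fibremorph.segmentation import BinaryMask, binarize, preprocess, remove_small_components
from fibremorph.volume_io import ImageStack, crop_to_depth

logger = logging.getLogger(__name__)


@dataclass
class FieldMetrics:
    """Structural metrics of one imaged field."""

    volume_fraction: float = 0.0
    surface_area_um2: float = 0.0
    n_branches: int = 0
    n_fibres: int = 0
    lengths_um: list[float] = field(default_factory=list)
    diameters_um: list[float] = field(default_factory=list)
    curvatures_per_um: list[float] = field(default_factory=list)
    intensity_ratio: float | None = None
    empty: bool = False

    @property
    def mean_length_um(self) -> float | None:
        return float(np.mean(self.lengths_um)) if self.lengths_um else None

    @property
    def mean_diameter_um(self) -> float | None:
        vals = [d for d in self.diameters_um if d is not None and math.isfinite(d)]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_curvature_per_um(self) -> float | None:
        vals = [c for c in self.curvatures_per_um if c is not None and math.isfinite(c)]
        return float(np.mean(vals)) if vals else None

    def as_dict(self) -> dict:
        d = asdict(self)
        d["mean_length_um"] = self.mean_length_um
        d["mean_diameter_um"] = self.mean_diameter_um
        d["mean_curvature_per_um"] = self.mean_curvature_per_um
        return d


# ---------------------------------------------------------------------------
# Field-level metrics
# ---------------------------------------------------------------------------

def volume_fraction(mask: BinaryMask) -> float:
    """Foreground fraction of the imaged field (dimensionless, in [0, 1])."""
    return float(mask.voxels.sum() / mask.voxels.size)


def surface_area(mask: BinaryMask) -> float:
    """Fibre surface area (µm²) from the marching-cubes isosurface.

    The mask is lightly smoothed (σ = 0.8 voxel) before extracting the
    0.5-level surface: on digitized smooth shapes this removes the
    staircase overestimate of a raw binary marching-cubes mesh (which
    runs near +10% on spheres and +18% on thin tubes at 1 µm voxels)
    while moving the surface by well under half a voxel. Voxel-face
    counting is deliberately not used (it overestimates smooth surfaces
    by up to ~50%).
    """
    if not mask.voxels.any():
        warnings.warn("surface_area of an empty mask is 0")
        return 0.0
    vol = np.pad(mask.voxels.astype(float), 2)
    smoothed = ndimage.gaussian_filter(vol, sigma=0.8)
    if smoothed.max() < 0.5:
        # tiny objects get washed out by the smoothing; measure them raw
        smoothed = vol
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=mask.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def branch_count(sg: SkeletonGraph) -> int:
    """Number of fibre branch points = junction nodes of the skeleton graph."""
    return len(sg.junctions)


def channel_intensity_ratio(
    mask: BinaryMask, numerator: np.ndarray, denominator: np.ndarray
) -> float:
    """Mean-intensity ratio of two channels over the fibre mask.

    For fibrillin-1 over tropoelastin this quantifies the microfibril
    content of the segmented fibres.
    """
    if numerator.shape != mask.voxels.shape or denominator.shape != mask.voxels.shape:
        raise ValueError("channels must share the mask's grid")
    if not mask.voxels.any():
        raise ValueError("empty mask")
    den = float(np.asarray(denominator, dtype=float)[mask.voxels].mean())
    if den <= 0:
        raise ValueError("denominator channel has zero mean over the mask")
    num = float(np.asarray(numerator, dtype=float)[mask.voxels].mean())
    return num / den


# ---------------------------------------------------------------------------
# Per-fibre metrics
# ---------------------------------------------------------------------------

def fibre_length(path: FibrePath) -> float:
    """Fibre length (µm): sum of consecutive point distances."""
    if len(path) < 2:
        raise ValueError("need >= 2 points")
    L = path.length_um
    if L <= 0:
        raise ValueError("degenerate path of coincident points")
    return L


def fibre_curvature(
    path: FibrePath,
    exclude: np.ndarray | None = None,
    end_margin_um: float = 2.0,
) -> float | None:
    """Mean curvature (µm⁻¹): average second-difference norm over interior
    points of the arc-length-resampled path.

    Points whose flanking intervals deviate from the nominal step (the
    shortened final interval) are skipped, as are points within
    ``end_margin_um`` of the path ends (fibre tips carry residual
    skeletonization error); ``exclude`` optionally masks out further
    points (e.g. near junctions). Returns None (metric absent) when fewer
    than 3 usable points remain.
    """
    if len(path) < 3:
        return None
    p = path.points
    ds = path.step_um
    d_prev = np.linalg.norm(p[1:-1] - p[:-2], axis=1)
    d_next = np.linalg.norm(p[2:] - p[1:-1], axis=1)
    second = p[2:] - 2 * p[1:-1] + p[:-2]
    kappa = np.linalg.norm(second, axis=1) / ds**2
    # smoothing perturbs spacing slightly; only drop genuinely short intervals
    ok = (d_prev > 0.5 * ds) & (d_next > 0.5 * ds)
    if end_margin_um > 0:
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(p, axis=0), axis=1))]
        )
        interior = (arc >= end_margin_um) & (arc <= arc[-1] - end_margin_um)
        if (ok & interior[1:-1]).any():
            ok &= interior[1:-1]
    if exclude is not None:
        ok &= ~exclude[1:-1]
    if not ok.any():
        return None
    return float(kappa[ok].mean())


def _orthonormal_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(t)
    t = t / n if n > 0 else np.array([1.0, 0.0, 0.0])
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _cross_section_area(
    mask: BinaryMask, point: np.ndarray, tangent: np.ndarray, r_max: float, step: float
) -> float | None:
    """Area (µm²) of the connected cross-section region containing ``point``
    in the plane normal to ``tangent``, by trilinear sampling on a grid."""
    u, v = _orthonormal_frame(tangent)
    n = int(math.ceil(r_max / step))
    coords_1d = np.arange(-n, n + 1) * step
    uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    plane = point[None, None] + uu[..., None] * u[None, None] + vv[..., None] * v[None, None]
    dz, dy, dx = mask.spacing
    idx = np.stack(
        [plane[..., 2] / dz, plane[..., 1] / dy, plane[..., 0] / dx], axis=0
    )
    vals = ndimage.map_coordinates(
        mask.voxels.astype(float), idx.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(uu.shape)
    if vals[n, n] < 0.5:
        return None
    # integrate the interpolated coverage over the connected blob around the
    # centre: thresholding at 0.5 would bias the radius up by ~half a voxel
    support = measure.label(vals >= 0.1, connectivity=2)
    region = support == support[n, n]
    return float(vals[region].sum() * step * step)


def fibre_diameter(
    path: FibrePath,
    mask: BinaryMask,
    method: str = "cross_section",
    exclude: np.ndarray | None = None,
    end_margin_um: float = 2.0,
) -> float | None:
    """Mean fibre thickness (µm) as equivalent-circle diameter.

    ``cross_section``: at each sampled point the mask is intersected with
    the plane normal to the local tangent; the connected region
    containing the point gives area A and d = 2√(A/π). ``edt``: 2× the
    Euclidean distance transform at each point (robust fallback; agrees
    within one voxel on straight tubes). Points near the path ends
    (truncated sections) and any ``exclude``-masked points are skipped.
    Returns None when every section is degenerate.
    """
    pts = path.points
    n = len(pts)
    use = np.ones(n, dtype=bool)
    if exclude is not None:
        use &= ~exclude
    # end sections are clipped by the fibre tip; skip a short margin
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    interior = (arc >= end_margin_um) & (arc <= arc[-1] - end_margin_um)
    if (use & interior).any():
        use &= interior
    idx_sel = np.where(use)[0]
    if idx_sel.size == 0:
        idx_sel = np.arange(n)

    dz, dy, dx = mask.spacing
    if method == "edt":
        edt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
        coords = np.stack(
            [pts[idx_sel, 2] / dz, pts[idx_sel, 1] / dy, pts[idx_sel, 0] / dx], axis=0
        )
        r = ndimage.map_coordinates(edt, coords, order=1, mode="nearest")
        r = r[r > 0]
        return float(2 * r.mean()) if r.size else None
    if method != "cross_section":
        raise ValueError(f"unknown diameter method {method!r}")

    edt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    tang = _tangents(pts)
    step = 0.5 * min(mask.spacing)
    areas = []
    for i in idx_sel:
        p = pts[i]
        coords = np.array([[p[2] / dz], [p[1] / dy], [p[0] / dx]])
        r_local = float(ndimage.map_coordinates(edt, coords, order=1, mode="nearest")[0])
        r_max = max(3.0 * r_local + 2 * max(mask.spacing), 4 * max(mask.spacing))
        a = _cross_section_area(mask, p, tang[i], r_max, step)
        if a is not None and a > 0:
            areas.append(a)
    if not areas:
        return None
    d = 2 * np.sqrt(np.asarray(areas) / math.pi)
    return float(d.mean())


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Parameters of the field analysis pipeline, all logged when used."""

    fibre_channel: str = "tropoelastin"
    ratio_numerator: str = "fibrillin1"
    max_depth_um: float = 100.0
    smooth_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_radius_um: float | None = None
    method: str | float = "otsu"
    min_volume_um3: float = 10.0
    connectivity: int = 26
    prune_length_um: float = 3.0
    resample_step_um: float = 1.0
    path_smoothing: str = "fit"  # "fit" | "movavg" | "none"
    smoothing_window: int = 5
    refine_iterations: int = 2
    junction_margin_um: float = 2.0
    diameter_method: str = "cross_section"
    curvature_pooled: bool = False  # pool points across fibres instead of per-fibre means


def fibre_paths(
    sg: SkeletonGraph,
    step_um: float = 1.0,
    smoothing: str = "fit",
    smoothing_window: int = 5,
    min_length_um: float = 0.0,
) -> list[FibrePath]:
    """Resample every skeleton edge at fixed arc length and smooth it.

    ``smoothing``: "fit" (adaptive local quadratic, the default), "movavg"
    (moving average of ``smoothing_window``), or "none".
    """
    paths = []
    for u, v, k, poly in sg.edge_polylines():
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        if seg <= max(min_length_um, 0) or len(poly) < 2:
            continue
        path = resample_arclength(poly, step_um=step_um, source_edge=(u, v, k))
        if smoothing == "fit":
            path = fit_path(path)
        elif smoothing == "movavg":
            path = smooth_path(path, window=smoothing_window)
        elif smoothing != "none":
            raise ValueError(f"unknown smoothing {smoothing!r}")
        paths.append(path)
    return paths


def _junction_exclusion(path: FibrePath, junction_pos: np.ndarray, margin: float) -> np.ndarray:
    if junction_pos.size == 0 or margin <= 0:
        return np.zeros(len(path), dtype=bool)
    d = np.linalg.norm(path.points[:, None, :] - junction_pos[None, :, :], axis=2)
    return d.min(axis=1) < margin


def segment_stack(stack: ImageStack, config: AnalysisConfig) -> BinaryMask:
    """Depth-crop, preprocess and binarize the fibre channel of a stack."""
    cropped = crop_to_depth(stack, config.max_depth_um)
    channel = cropped.channel(config.fibre_channel)
    pre = preprocess(
        channel, cropped.spacing, config.smooth_sigma_um, config.background_radius_um
    )
    mask = binarize(pre, cropped.spacing, method=config.method)
    return remove_small_components(mask, config.min_volume_um3, config.connectivity)


def analyze_mask(
    mask: BinaryMask,
    config: AnalysisConfig | None = None,
) -> tuple[FieldMetrics, SkeletonGraph, list[FibrePath]]:
    """Skeletonize a segmented mask and measure every metric on it."""
    config = config or AnalysisConfig()
    metrics = FieldMetrics()
    metrics.volume_fraction = volume_fraction(mask)
    if not mask.voxels.any():
        metrics.empty = True
        return metrics, SkeletonGraph(), []
    metrics.surface_area_um2 = surface_area(mask)

    skel, iso = skeletonize(mask)
    sg = build_graph(skel, iso)
    sg = prune_spurs(sg, config.prune_length_um)
    iso_m = _isotropic_mask(mask, iso)
    sg = refine_centerline(sg, iso_m, config.refine_iterations)
    # fibre-tip nodes sit off-axis after thinning; re-centre them too
    sg = refine_centerline(sg, iso_m, 1, refine_endpoint_nodes=True)
    sg = extend_terminal_edges(sg, iso_m)
    metrics.n_branches = branch_count(sg)

    # Full polylines (tip extensions included) give fibre length; the
    # refined core (extensions trimmed away, they are straight guesses not
    # centred paths) gives curvature and diameter.
    jpos = sg.junction_positions()
    step = config.resample_step_um
    paths: list[FibrePath] = []
    pooled_vals: list[tuple[float, int]] = []
    for u, v, k, poly in sg.edge_polylines():
        d = sg.graph.edges[u, v, k]
        if d["length"] <= step or len(poly) < 2:
            continue
        full = resample_arclength(poly, step_um=step, source_edge=(u, v, k))
        metrics.lengths_um.append(fibre_length(full))
        e0, e1 = d.get("ext_um", (0.0, 0.0))
        core_poly = trim_polyline(poly, e0, e1)
        core_len = float(np.linalg.norm(np.diff(core_poly, axis=0), axis=1).sum())
        if len(core_poly) < 2 or core_len <= step:
            paths.append(full)
            continue
        core = resample_arclength(core_poly, step_um=step, source_edge=(u, v, k))
        if config.path_smoothing == "fit":
            core = fit_path(core)
        elif config.path_smoothing == "movavg":
            core = smooth_path(core, window=config.smoothing_window)
        paths.append(core)
        excl = _junction_exclusion(core, jpos, config.junction_margin_um)
        diam = fibre_diameter(core, iso_m, method=config.diameter_method, exclude=excl)
        if diam is not None:
            metrics.diameters_um.append(diam)
        curv = fibre_curvature(core, exclude=excl)
        if curv is not None:
            metrics.curvatures_per_um.append(curv)
            pooled_vals.append((curv, max(len(core) - 2, 1)))
    metrics.n_fibres = len(metrics.lengths_um)
    if config.curvature_pooled and pooled_vals:
        # pooled mode: every 1 µm point counts equally across the field
        total_w = sum(w for _, w in pooled_vals)
        metrics.curvatures_per_um = [
            sum(c * w for c, w in pooled_vals) / total_w
        ]
    return metrics, sg, paths


def _isotropic_mask(mask: BinaryMask, iso: float) -> BinaryMask:
    """Nearest-neighbour resample of the mask to the skeleton's iso grid."""
    factors = [s / iso for s in mask.spacing]
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return mask
    vox = ndimage.zoom(mask.voxels, zoom=factors, order=0)
    return BinaryMask(vox, (iso, iso, iso), mask.threshold)


def analyze_field(
    stack: ImageStack, config: AnalysisConfig | None = None
) -> FieldMetrics:
    """Full pipeline on one stack: segment, skeletonize, measure.

    Deterministic for fixed input and config. An empty segmentation
    yields zeroed metrics with the ``empty`` flag set, never silent
    zeros mixed into group statistics.
    """
    config = config or AnalysisConfig()
    cropped0 = crop_to_depth(stack, config.max_depth_um)
    if np.ptp(cropped0.channel(config.fibre_channel)) == 0 and config.method == "otsu":
        # blank field: no threshold exists, report explicitly empty metrics
        logger.warning("analyze_field: constant fibre channel, empty field")
        return FieldMetrics(empty=True)
    mask = segment_stack(stack, config)
    metrics, sg, paths = analyze_mask(mask, config)
    if metrics.empty:
        logger.warning("analyze_field: empty mask after segmentation")
        return metrics
    roles = stack.channels
    if config.ratio_numerator in roles and config.fibre_channel in roles:
        cropped = crop_to_depth(stack, config.max_depth_um)
        metrics.intensity_ratio = channel_intensity_ratio(
            mask,
            cropped.channel(config.ratio_numerator),
            cropped.channel(config.fibre_channel),
        )
    return metrics
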