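"""Synthetic tubular fibre phantoms with analytic ground truth.

The study's human tissue stacks are not deposited, so validation rests on
phantoms: tubes of known centreline geometry (segments, circular arcs,
helices, polylines), branching trees, and "candelabra" figures emulating
oxytalan fibre cascades — an arched base fibre parallel to the epidermal
surface with upward prongs. Each phantom is paired with analytic truth
(length, curvature, radius, branch count, volume, surface area) and can be
rendered through a confocal-like imaging model (PSF blur, noise,
depth-dependent attenuation).

Conventions: curve geometry is specified in physical ``(x, y, z)`` µm;
voxel grids are ``(z, y, x)`` with the voxel of index ``(k, j, i)``
centred at ``(k·dz, j·dy, i·dx)``. Analytic tube volume is ``π r² L`` and
lateral surface ``2π r L`` (end caps excluded; documented because
marching-cubes measurements include caps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from fibremorph.segmentation import BinaryMask
from fibremorph.volume_io import ImageStack


# ---------------------------------------------------------------------------
# Centreline curves
# ---------------------------------------------------------------------------

class Curve:
    """Arc-length-parametrized space curve in (x, y, z) µm."""

    length: float
    mean_curvature: float

    def point(self, s: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, step: float) -> np.ndarray:
        """Points at arc-length steps <= ``step``, endpoints included."""
        n = max(int(math.ceil(self.length / step)) + 1, 2)
        s = np.linspace(0.0, self.length, n)
        return self.point(s)


@dataclass
class Segment(Curve):
    """Straight segment from p0 to p1; curvature 0."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]

    def __post_init__(self) -> None:
        self._a = np.asarray(self.p0, dtype=float)
        self._b = np.asarray(self.p1, dtype=float)
        self.length = float(np.linalg.norm(self._b - self._a))
        if self.length <= 0:
            raise ValueError("segment has zero length")
        self.mean_curvature = 0.0

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        t = (s / self.length)[:, None]
        return self._a + t * (self._b - self._a)


@dataclass
class CircularArc(Curve):
    """Circular arc of radius R in the plane spanned by (u, v) at ``centre``.

    ``point(θ) = centre + R (cos θ · u + sin θ · v)`` for
    θ ∈ [theta0, theta0 + span]. Curvature is 1/R everywhere.
    """

    centre: tuple[float, float, float]
    radius: float
    span: float  # angular span, radians
    u: tuple[float, float, float] = (1.0, 0.0, 0.0)
    v: tuple[float, float, float] = (0.0, 1.0, 0.0)
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.span <= 0:
            raise ValueError("arc radius and span must be positive")
        self._c = np.asarray(self.centre, dtype=float)
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        self._u = u / np.linalg.norm(u)
        # Gram-Schmidt so u, v are orthonormal even for sloppy input
        v = v - (v @ self._u) * self._u
        self._v = v / np.linalg.norm(v)
        self.length = self.radius * self.span
        self.mean_curvature = 1.0 / self.radius

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        th = self.theta0 + s / self.radius
        return self._c + self.radius * (np.cos(th)[:, None] * self._u + np.sin(th)[:, None] * self._v)


@dataclass
class Helix(Curve):
    """Circular helix ``(a cos t, a sin t, c t)`` translated to ``origin``.

    ``a`` is the helix radius (µm), ``c`` the pitch parameter (µm/rad;
    one turn rises 2πc). Curvature is the standard ``a / (a² + c²)``.
    """

    a: float
    c: float
    turns: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.turns <= 0:
            raise ValueError("helix radius and turns must be positive")
        self._o = np.asarray(self.origin, dtype=float)
        self._speed = math.hypot(self.a, self.c)  # |dp/dt|
        self.length = 2 * math.pi * self.turns * self._speed
        self.mean_curvature = self.a / (self.a**2 + self.c**2)

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        t = s / self._speed
        return self._o + np.stack(
            [self.a * np.cos(t), self.a * np.sin(t), self.c * t], axis=1
        )


@dataclass
class PolylineCurve(Curve):
    """Piecewise-linear curve through the given (x, y, z) points."""

    points: Sequence[Sequence[float]]

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 3:
            raise ValueError("polyline needs >= 2 points of (x, y, z)")
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("polyline has repeated consecutive points")
        self._p = p
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self._cum[-1])
        self.mean_curvature = 0.0  # piecewise straight; corners are measure zero

    def point(self, s):
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0, self.length)
        out = np.empty((len(s), 3))
        for d in range(3):
            out[:, d] = np.interp(s, self._cum, self._p[:, d])
        return out


@dataclass
class TubeSpec:
    """A tube: a centreline curve swept by a disc of radius ``tube_radius`` µm."""

    centreline: Curve
    tube_radius: float

    def __post_init__(self) -> None:
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        r_bend = None
        if isinstance(self.centreline, CircularArc):
            r_bend = self.centreline.radius
        elif isinstance(self.centreline, Helix):
            r_bend = self.centreline.a
        if r_bend is not None and r_bend <= 2 * self.tube_radius:
            raise ValueError(
                f"bend radius {r_bend} must exceed 2 x tube radius {self.tube_radius} "
                "(self-intersecting tube)"
            )


@dataclass
class TreeSpec:
    """A branching fibre: a rooted tree of straight tube edges.

    ``parents[i]`` is the index of node i's parent (root has parent -1);
    ``edge_radius[i]`` is the tube radius of the edge (parents[i] -> i),
    ignored at the root.
    """

    nodes: Sequence[Sequence[float]]  # (x, y, z) µm
    parents: Sequence[int]
    edge_radius: Sequence[float]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        n = len(self.nodes)
        if len(self.parents) != n or len(self.edge_radius) != n:
            raise ValueError("nodes, parents, edge_radius must have equal length")
        if sum(1 for p in self.parents if p < 0) != 1:
            raise ValueError("tree must have exactly one root")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, p in enumerate(self.parents):
            if p >= 0:
                deg[i] += 1
                deg[p] += 1
        return deg

    @property
    def branch_count(self) -> int:
        """Number of junction nodes (degree >= 3)."""
        return int(np.sum(self.degrees() >= 3))


@dataclass
class PhantomTruth:
    """Analytic ground truth paired with a rasterized phantom."""

    length_um: float
    mean_curvature_per_um: float
    tube_radius_um: float
    branch_count: int
    volume_um3: float
    surface_area_um2: float  # lateral surface only, end caps excluded
    lengths_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("length_um", "mean_curvature_per_um", "tube_radius_um",
                     "volume_um3", "surface_area_um2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class ImagingModel:
    """Confocal-like forward model: PSF blur, depth attenuation, noise.

    intensity = blur(peak·mask) · exp(−z/attenuation_length) + background
    + noise, clipped at 0. Identical (parameters, seed) give identical
    output.
    """

    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (σz, σy, σx) µm
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    attenuation_length: float | None = None  # ζ µm; None disables attenuation
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.psf_sigma) or self.gaussian_sd < 0 \
                or self.poisson_scale < 0 or self.background < 0:
            raise ValueError("imaging model parameters must be non-negative")
        if self.attenuation_length is not None and self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be positive or None")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _voxel_centres(shape, spacing):
    """Physical (x, y, z) centres of all voxels, and the (z, y, x) index grid."""
    dz, dy, dx = spacing
    z, y, x = np.meshgrid(
        np.arange(shape[0]) * dz,
        np.arange(shape[1]) * dy,
        np.arange(shape[2]) * dx,
        indexing="ij",
    )
    return np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)


def _check_fits(points_xyz: np.ndarray, r: float, shape, spacing) -> None:
    dz, dy, dx = spacing
    hi = np.array([(shape[2] - 1) * dx, (shape[1] - 1) * dy, (shape[0] - 1) * dz])
    clearance = 2 * np.array([dx, dy, dz])
    lo_ok = np.all(points_xyz - r >= clearance - 1e-9, axis=1)
    hi_ok = np.all(points_xyz + r <= hi - clearance + 1e-9, axis=1)
    if not (lo_ok.all() and hi_ok.all()):
        raise ValueError("tube exits grid (needs >= 2 voxels clearance)")


def _rasterize_curves(curves_and_radii, shape, spacing) -> np.ndarray:
    """Union of tubes: voxel centre within radius r of any curve.

    Tubes are capless: voxels beyond the end planes (normal to the end
    tangents) are excluded, so a straight tube is an exact cylinder of
    volume π r² L.
    """
    mask = np.zeros(shape, dtype=bool)
    centres = _voxel_centres(shape, spacing)
    min_sp = min(spacing)
    for curve, r in curves_and_radii:
        if r < min_sp:
            warnings.warn(f"tube radius {r} µm below voxel size {min_sp} µm (sub-resolution)")
        dense = curve.sample(step=0.2 * min_sp)
        _check_fits(dense, r, shape, spacing)
        tree = cKDTree(dense)
        d, _ = tree.query(centres, distance_upper_bound=r + 0.5 * min_sp)
        member = d <= r
        # cut the rounded caps at the end planes
        closed = np.linalg.norm(dense[0] - dense[-1]) < 0.5 * min_sp
        if not closed:
            t0 = dense[1] - dense[0]
            t0 /= np.linalg.norm(t0)
            t1 = dense[-1] - dense[-2]
            t1 /= np.linalg.norm(t1)
            member &= (centres - dense[0]) @ t0 >= -1e-9
            member &= (centres - dense[-1]) @ t1 <= 1e-9
        mask |= member.reshape(shape)
    return mask


def rasterize_tube(spec: TubeSpec, shape, spacing=(1.0, 1.0, 1.0)) -> tuple[BinaryMask, PhantomTruth]:
    """Rasterize a single tube; voxel membership is centre-within-radius.

    Returns the crisp binary mask plus analytic truth. No anti-aliasing:
    partial-volume effects are modelled downstream by the imaging model.
    """
    mask = _rasterize_curves([(spec.centreline, spec.tube_radius)], shape, spacing)
    c, r = spec.centreline, spec.tube_radius
    truth = PhantomTruth(
        length_um=c.length,
        mean_curvature_per_um=c.mean_curvature,
        tube_radius_um=r,
        branch_count=0,
        volume_um3=math.pi * r**2 * c.length,
        surface_area_um2=2 * math.pi * r * c.length,
        lengths_um=[c.length],
    )
    return BinaryMask(mask, spacing), truth


def rasterize_tree(spec: TreeSpec, shape, spacing=(1.0, 1.0, 1.0)) -> tuple[BinaryMask, PhantomTruth]:
    """Rasterize a branching tree as the union of its edge tubes."""
    curves = []
    total_len = 0.0
    volume = 0.0
    area = 0.0
    lengths = []
    r_mean = []
    for i, p in enumerate(spec.parents):
        if p < 0:
            continue
        seg = Segment(tuple(spec.nodes[p]), tuple(spec.nodes[i]))
        r = float(spec.edge_radius[i])
        curves.append((seg, r))
        total_len += seg.length
        lengths.append(seg.length)
        volume += math.pi * r**2 * seg.length
        area += 2 * math.pi * r * seg.length
        r_mean.append(r)
    mask = _rasterize_curves(curves, shape, spacing)
    truth = PhantomTruth(
        length_um=total_len,
        mean_curvature_per_um=0.0,
        tube_radius_um=float(np.mean(r_mean)),
        branch_count=spec.branch_count,
        volume_um3=volume,
        surface_area_um2=area,
        lengths_um=lengths,
    )
    return BinaryMask(mask, spacing), truth


def make_candelabra(
    n_prongs: int,
    base_depth: float = 30.0,
    prong_length: float = 20.0,
    tube_radius: float = 2.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    arc_radius: float | None = None,
    spacing=(1.0, 1.0, 1.0),
    shape=None,
) -> tuple[BinaryMask, PhantomTruth]:
    """Candelabra phantom: an arched base fibre with upward prongs.

    Emulates the oxytalan cascade: the base runs parallel to the top face
    (z = 0, the epidermal surface) at depth ``base_depth``, gently arched;
    ``n_prongs`` straight prongs rise toward the surface from evenly
    spaced points along the base. ``jitter_sd`` perturbs prong tips
    laterally (µm). Ground-truth branch count equals ``n_prongs``.
    """
    if n_prongs < 2:
        raise ValueError("n_prongs must be >= 2")
    rng = np.random.default_rng(seed)
    span_x = max(10.0 * (n_prongs + 1), 40.0)
    R = arc_radius if arc_radius is not None else 2.0 * span_x
    span_x = min(span_x, 1.8 * R)  # keep the chord feasible for small bend radii
    half_angle = math.asin(span_x / (2 * R))
    margin = 4 * tube_radius + 4 * max(spacing)
    y0 = margin + 6.0
    cx = margin + span_x / 2
    sagitta = R * (1 - math.cos(half_angle))
    base_z = base_depth
    # smooth base arc in the x-z plane, apex bowed toward the surface:
    # point(theta) = (cx + R sin(theta), y0, cz - R cos(theta))
    cz = base_z + R * math.cos(half_angle)
    base = CircularArc(
        centre=(cx, y0, cz),
        radius=R,
        span=2 * half_angle,
        u=(0.0, 0.0, -1.0),
        v=(1.0, 0.0, 0.0),
        theta0=-half_angle,
    )
    curves: list[tuple[Curve, float]] = [(base, tube_radius)]
    prong_lengths = []
    thetas = np.linspace(-half_angle, half_angle, n_prongs + 2)[1:-1]
    for th in thetas:
        bx = cx + R * math.sin(th)
        bz = cz - R * math.cos(th)
        tip_z = max(bz - prong_length, margin)
        tip = (
            bx + rng.normal(0, jitter_sd),
            y0 + rng.normal(0, jitter_sd),
            tip_z,
        )
        seg = Segment((bx, y0, bz), tip)
        curves.append((seg, tube_radius))
        prong_lengths.append(seg.length)
    if shape is None:
        pts = np.concatenate([c.sample(step=1.0) for c, _ in curves])
        hi = pts.max(axis=0) + margin  # (x, y, z)
        dz, dy, dx = spacing
        shape = (
            int(math.ceil(hi[2] / dz)) + 1,
            int(math.ceil(hi[1] / dy)) + 1,
            int(math.ceil(hi[0] / dx)) + 1,
        )
    mask = _rasterize_curves(curves, shape, spacing)
    total_len = base.length + sum(prong_lengths)
    truth = PhantomTruth(
        length_um=total_len,
        mean_curvature_per_um=1.0 / R,
        tube_radius_um=tube_radius,
        branch_count=n_prongs,
        volume_um3=math.pi * tube_radius**2 * total_len,
        surface_area_um2=2 * math.pi * tube_radius * total_len,
        lengths_um=[base.length, *prong_lengths],
    )
    return BinaryMask(mask, spacing), truth


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------

def render_acquisition(
    mask: BinaryMask | np.ndarray,
    model: ImagingModel,
    peak_intensity: float = 100.0,
    spacing=None,
    depth_origin: float = 0.0,
    channel_role: str = "tropoelastin",
    _rng=None,
) -> ImageStack:
    """Render a phantom through the imaging model into an ImageStack.

    Deterministic for fixed (mask, model, peak): the random stream is
    seeded from ``model.seed`` alone.
    """
    if peak_intensity <= 0:
        raise ValueError("peak_intensity must be positive")
    if isinstance(mask, BinaryMask):
        grid = mask.voxels.astype(float)
        spacing = mask.spacing
    else:
        grid = np.asarray(mask, dtype=float)
        if spacing is None:
            raise ValueError("spacing required for a bare array")
    from scipy.ndimage import gaussian_filter

    img = peak_intensity * grid
    sigma_vox = [s / d for s, d in zip(model.psf_sigma, spacing)]
    if any(s > 0 for s in sigma_vox):
        img = gaussian_filter(img, sigma=sigma_vox)
    if model.attenuation_length is not None:
        z = depth_origin + np.arange(img.shape[0]) * spacing[0]
        img *= np.exp(-z / model.attenuation_length)[:, None, None]
    img += model.background
    rng = _rng if _rng is not None else np.random.default_rng(model.seed)
    if model.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * model.poisson_scale) / model.poisson_scale
    if model.gaussian_sd > 0:
        img = img + rng.normal(0.0, model.gaussian_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return ImageStack(img[None], spacing, [channel_role], depth_origin=depth_origin)


def make_two_channel(
    mask: BinaryMask,
    model: ImagingModel,
    ratio: float,
    peak_intensity: float = 100.0,
) -> ImageStack:
    """Two-channel phantom for the fibrillin-1/tropoelastin intensity ratio.

    Channel "tropoelastin" is rendered at ``peak_intensity`` and channel
    "fibrillin1" at ``ratio ×`` that peak, on the same geometry with
    independent seed-derived noise streams.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rngs = [np.random.default_rng([model.seed, k]) for k in (0, 1)]
    ch1 = render_acquisition(mask, model, peak_intensity, _rng=rngs[0])
    ch2 = render_acquisition(mask, model, ratio * peak_intensity, _rng=rngs[1])
    voxels = np.concatenate([ch1.voxels, ch2.voxels], axis=0)
    return ImageStack(voxels, mask.spacing, ["tropoelastin", "fibrillin1"])


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationTemplate:
    """Distribution parameters for a cohort of candelabra-like phantoms.

    Arc (bend) radius and tube radius are lognormal with the given means
    and coefficients of variation; prong count is Poisson (clipped >= 2).
    Smaller ``arc_radius_um`` means more curved fibres; larger
    ``tube_radius_um`` means thicker fibres.
    """

    arc_radius_um: float = 40.0
    arc_radius_cv: float = 0.15
    tube_radius_um: float = 1.5
    tube_radius_cv: float = 0.10
    n_prongs_mean: float = 4.0
    prong_length_um: float = 15.0
    base_depth_um: float = 35.0
    jitter_sd_um: float = 0.5
    fibres_per_field: int = 3  # candelabra figures per imaged field
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _lognormal(rng, mean, cv):
    if cv <= 0:
        return mean
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = math.log(mean) - sigma**2 / 2
    return float(rng.lognormal(mu, sigma))


def make_population(
    template: PopulationTemplate, n: int, seed: int = 0
) -> list[tuple[BinaryMask, PhantomTruth]]:
    """Draw ``n`` synthetic fields from the template's distributions.

    Each field holds ``template.fibres_per_field`` candelabra figures
    stacked side by side (an imaged field of tissue contains many fibres,
    and per-field metric means average over them). Reproducible per
    ``seed``; field k of a population depends only on (seed, k).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for k in range(n):
        rng = np.random.default_rng([seed, k])
        fibre_masks: list[BinaryMask] = []
        truths: list[PhantomTruth] = []
        for _ in range(max(template.fibres_per_field, 1)):
            arc_r = _lognormal(rng, template.arc_radius_um, template.arc_radius_cv)
            tube_r = _lognormal(rng, template.tube_radius_um, template.tube_radius_cv)
            if template.n_prongs_mean > 0:
                n_prongs = max(2, int(rng.poisson(template.n_prongs_mean)))
            else:
                n_prongs = 2
            arc_r = max(arc_r, 2.5 * tube_r + 1.0)  # keep the tube self-avoiding
            mask, truth = make_candelabra(
                n_prongs=n_prongs,
                base_depth=template.base_depth_um,
                prong_length=template.prong_length_um,
                tube_radius=tube_r,
                jitter_sd=template.jitter_sd_um,
                seed=int(rng.integers(2**31 - 1)),
                arc_radius=arc_r,
                spacing=template.spacing,
            )
            fibre_masks.append(mask)
            truths.append(truth)
        out.append((_compose_field(fibre_masks, template.spacing), _merge_truths(truths)))
    return out


def _compose_field(masks: list[BinaryMask], spacing) -> BinaryMask:
    """Stack fibre masks side by side along y with a separating gap."""
    if len(masks) == 1:
        return masks[0]
    gap = 4  # voxels between fibres, keeps components disconnected
    nz = max(m.shape[0] for m in masks)
    nx = max(m.shape[2] for m in masks)
    ny = sum(m.shape[1] for m in masks) + gap * (len(masks) - 1)
    vox = np.zeros((nz, ny, nx), dtype=bool)
    y0 = 0
    for m in masks:
        sz, sy, sx = m.shape
        vox[:sz, y0:y0 + sy, :sx] |= m.voxels
        y0 += sy + gap
    return BinaryMask(vox, spacing)


def _merge_truths(truths: list[PhantomTruth]) -> PhantomTruth:
    return PhantomTruth(
        length_um=sum(t.length_um for t in truths),
        mean_curvature_per_um=float(np.mean([t.mean_curvature_per_um for t in truths])),
        tube_radius_um=float(np.mean([t.tube_radius_um for t in truths])),
        branch_count=sum(t.branch_count for t in truths),
        volume_um3=sum(t.volume_um3 for t in truths),
        surface_area_um2=sum(t.surface_area_um2 for t in truths),
        lengths_um=[L for t in truths for L in t.lengths_um],
    )


#: Study-condition cohort templates. The aged cohort encodes the reported
#: direction of aging in dermal fibres: more curved (smaller bend radius),
#: thicker, with fewer branches.
YOUNG_TEMPLATE = PopulationTemplate(
    arc_radius_um=40.0, tube_radius_um=1.5, n_prongs_mean=5.0
)
AGED_TEMPLATE = PopulationTemplate(
    arc_radius_um=40.0 / 2.65, tube_radius_um=1.5 * 2.65, n_prongs_mean=2.0
)
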