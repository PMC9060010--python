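"""Binarization of a fibre channel into a clean 3D mask.

The pipeline step is deliberately simple: optional Gaussian smoothing and
background subtraction in physical units, a per-volume Otsu (or fixed)
threshold, then removal of speckle components below a physical volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import white_tophat, ball

logger = logging.getLogger(__name__)

_CONNECTIVITY_STRUCT = {6: 1, 18: 2, 26: 3}


@dataclass
class BinaryMask:
    """A 3D boolean foreground mask on a physical grid.

    ``voxels`` is indexed (z, y, x); ``spacing`` is (dz, dy, dx) in µm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    threshold: float | None = None  # the threshold that produced it, if any

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def count(self) -> int:
        return int(self.voxels.sum())


def preprocess(
    channel: np.ndarray,
    spacing: tuple[float, float, float],
    smooth_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    background_radius_um: float | None = None,
) -> np.ndarray:
    """Gaussian smoothing (σ in µm, converted per-axis to voxels) and
    optional top-hat background subtraction. Output is float, >= 0."""
    if any(s < 0 for s in smooth_sigma_um):
        raise ValueError("smoothing sigma must be >= 0")
    out = np.asarray(channel, dtype=float)
    sigma_vox = [s / d for s, d in zip(smooth_sigma_um, spacing)]
    if any(s > 0 for s in sigma_vox):
        out = ndimage.gaussian_filter(out, sigma=sigma_vox)
    if background_radius_um is not None and background_radius_um > 0:
        r_vox = max(1, int(round(background_radius_um / min(spacing))))
        out = white_tophat(out, footprint=ball(r_vox))
    return np.clip(out, 0.0, None)


def binarize(
    channel: np.ndarray,
    spacing: tuple[float, float, float],
    method: str | float = "otsu",
    nbins: int = 256,
) -> BinaryMask:
    """Threshold a fibre channel into a BinaryMask (``channel > threshold``).

    ``method`` is "otsu" (per-volume, 256-bin histogram — the default; a
    single volume-wide threshold avoids slice-to-slice flicker) or a fixed
    numeric threshold. The chosen threshold is recorded on the mask.
    """
    channel = np.asarray(channel)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown binarization method {method!r}")
        if np.ptp(channel) == 0:
            raise ValueError("constant channel: Otsu threshold does not exist")
        thr = float(threshold_otsu(channel, nbins=nbins))
    else:
        thr = float(method)
        lo, hi = float(channel.min()), float(channel.max())
        if thr < lo or thr >= hi:
            warnings.warn(
                f"fixed threshold {thr} outside intensity range [{lo}, {hi}]: "
                "mask will be empty or full"
            )
    logger.info("binarize: threshold=%g", thr)
    return BinaryMask(channel > thr, spacing, threshold=thr)


def remove_small_components(
    mask: BinaryMask, min_volume_um3: float = 10.0, connectivity: int = 26
) -> BinaryMask:
    """Drop connected components whose physical volume is below the cutoff.

    Idempotent and anti-extensive; ``min_volume_um3 = 0`` is the identity.
    Default connectivity 26 matches diagonal fibre continuity.
    """
    if min_volume_um3 < 0:
        raise ValueError("min_volume_um3 must be >= 0")
    if connectivity not in _CONNECTIVITY_STRUCT:
        raise ValueError("connectivity must be 6, 18 or 26")
    if min_volume_um3 == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing, mask.threshold)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCT[connectivity])
    labels, n = ndimage.label(mask.voxels, structure=struct)
    if n == 0:
        return BinaryMask(mask.voxels.copy(), mask.spacing, mask.threshold)
    counts = np.bincount(labels.ravel())
    keep = counts * mask.voxel_volume_um3 >= min_volume_um3
    keep[0] = False
    out = keep[labels]
    n_removed = int(n - (keep.sum()))
    if n_removed:
        logger.info(
            "remove_small_components: dropped %d components < %g µm³", n_removed, min_volume_um3
        )
    return BinaryMask(out, mask.spacing, mask.threshold)
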