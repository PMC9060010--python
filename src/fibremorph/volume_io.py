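"""Reading and writing multichannel confocal Z-stacks and metric tables.

Axis convention: voxel grids are indexed ``(z, y, x)`` and spacing is
``(dz, dy, dx)`` in micrometres; physical coordinates in outputs are
reported as ``(x, y, z)`` µm. Depth is measured from the first acquired
slice (``depth_origin``, default 0 = epidermal surface).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Names of the numeric metric columns carried by :class:`MetricsRecord`.
METRIC_FIELDS = (
    "volume_fraction",
    "surface_area_um2",
    "n_branches",
    "mean_length_um",
    "mean_diameter_um",
    "mean_curvature_per_um",
    "intensity_ratio",
)


@dataclass
class ImageStack:
    """A multichannel 3D intensity volume on a physical grid.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities, one 3D grid per channel.
    spacing : (dz, dy, dx)
        Voxel spacing in µm, all strictly positive.
    channels : list of str
        Role label per channel, e.g. ``["nuclei", "tropoelastin",
        "fibrillin1"]``, in the order of the first voxel axis.
    depth_origin : float
        z-position (µm) of the first slice relative to the epidermal
        surface.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channels: list[str] = field(default_factory=list)
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (C, Z, Y, X), got ndim={self.voxels.ndim}")
        if not self.channels:
            self.channels = [f"channel{i}" for i in range(self.voxels.shape[0])]
        if len(self.channels) != self.voxels.shape[0]:
            raise ValueError(
                f"channel count mismatch: {self.voxels.shape[0]} channels in data, "
                f"{len(self.channels)} role labels"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values (dz, dy, dx), got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the 3D grid for the channel with the given role label."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}") from None
        return self.voxels[idx]

    def z_positions(self) -> np.ndarray:
        """Physical z-position (µm) of each slice."""
        return self.depth_origin + np.arange(self.shape[0]) * self.spacing[0]


@dataclass
class MetricsRecord:
    """One analysed field: identifiers plus the structural metrics.

    Missing metrics are ``None`` (serialized as empty CSV cells), never
    silently zero.
    """

    sample_id: str
    group: str = ""
    site: str = ""
    volume_fraction: float | None = None
    surface_area_um2: float | None = None
    n_branches: float | None = None
    mean_length_um: float | None = None
    mean_diameter_um: float | None = None
    mean_curvature_per_um: float | None = None
    intensity_ratio: float | None = None

    def __post_init__(self) -> None:
        for name in METRIC_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(float(v)):
                raise ValueError(f"metric {name} must be finite where defined, got {v}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multipage TIFF (CZYX) plus a JSON metadata sidecar.

    The sidecar carries spacing, channel roles and depth origin so that
    :func:`read_stack` round-trips exactly even when TIFF metadata is
    stripped by other tools.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.voxels,
        photometric="minisblack",
        metadata={"axes": "CZYX", "spacing_um": list(stack.spacing), "channels": stack.channels},
    )
    meta = {
        "spacing_um": list(stack.spacing),
        "channels": stack.channels,
        "depth_origin_um": stack.depth_origin,
        "axes": "CZYX",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    channel_roles: Sequence[str] | None = None,
) -> ImageStack:
    """Read a multipage TIFF stack into an :class:`ImageStack`.

    Spacing comes from the JSON sidecar or TIFF metadata; an explicit
    ``spacing_override`` always wins (and is logged). Channel roles are
    caller-supplied via ``channel_roles``; file metadata roles are used
    only when the caller gives none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if arr.ndim == 3:
        arr = arr[None]
    elif arr.ndim != 4:
        raise ValueError(f"expected a 3D or 4D TIFF, got ndim={arr.ndim}")

    axes = meta.get("axes", "CZYX")
    if axes == "ZCYX":
        arr = np.moveaxis(arr, 1, 0)
        logger.info("read_stack: detected ZCYX page order, transposed to CZYX")

    spacing = meta.get("spacing_um")
    if spacing_override is not None:
        if spacing is not None and tuple(spacing) != tuple(spacing_override):
            logger.info(
                "read_stack: spacing override %s replaces file spacing %s",
                tuple(spacing_override), tuple(spacing),
            )
        spacing = tuple(spacing_override)
    if spacing is None:
        raise ValueError(f"no voxel spacing in metadata for {path}; pass spacing_override")

    roles = list(channel_roles) if channel_roles is not None else meta.get("channels")
    if roles is not None and len(roles) != arr.shape[0]:
        raise ValueError(
            f"channel count mismatch: file has {arr.shape[0]} channels, "
            f"{len(roles)} roles given"
        )
    return ImageStack(
        voxels=arr,
        spacing=tuple(spacing),
        channels=list(roles) if roles else [],
        depth_origin=float(meta.get("depth_origin_um", 0.0)),
    )


def crop_to_depth(stack: ImageStack, max_depth_um: float = 100.0) -> ImageStack:
    """Keep only slices at depth <= ``max_depth_um`` (inclusive).

    Signal quality degrades beyond ~100 µm in cleared-skin confocal
    stacks, so analysis is restricted to the first 100 µm by default.
    The retained slice count is ``floor((max_depth - depth_origin)/dz) + 1``,
    capped at the available slices.
    """
    if max_depth_um <= stack.depth_origin:
        raise ValueError(
            f"max_depth_um={max_depth_um} <= depth_origin={stack.depth_origin}: no slices remain"
        )
    dz = stack.spacing[0]
    n_keep = int(math.floor((max_depth_um - stack.depth_origin) / dz + 1e-9)) + 1
    n_keep = min(n_keep, stack.shape[0])
    return replace(stack, voxels=stack.voxels[:, :n_keep])


def write_metrics(records: Sequence[MetricsRecord], path: str | Path) -> None:
    """Write metric records as RFC-4180 CSV (UTF-8, '.' decimal)."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "group": r.group, "site": r.site}
        for name in METRIC_FIELDS:
            row[name] = getattr(r, name)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sample_id", "group", "site", *METRIC_FIELDS])
    df.to_csv(path, index=False, float_format="%.15g", encoding="utf-8")


def read_metrics(path: str | Path) -> list[MetricsRecord]:
    """Read a metric table written by :func:`write_metrics`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "site": str})
    required = {"sample_id", *METRIC_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"malformed metrics CSV {path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {
            "sample_id": row["sample_id"],
            "group": "" if pd.isna(row.get("group", "")) else str(row.get("group", "")),
            "site": "" if pd.isna(row.get("site", "")) else str(row.get("site", "")),
        }
        for name in METRIC_FIELDS:
            v = row[name]
            kwargs[name] = None if pd.isna(v) else float(v)
        records.append(MetricsRecord(**kwargs))
    return records
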