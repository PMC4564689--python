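"""Reading and writing multi-channel z-stack volumes and seed tables.

Volumes are stored internally as float arrays indexed ``(channel, z, y, x)``
with explicit physical voxel sizes in nanometres.  On disk, volumes are
OME-TIFF (preferred) or ImageJ-style TIFF; seed tables are plain CSV.

Coordinate conventions
----------------------
All indices are 0-based.  An integer index names the *center* of its voxel,
so the continuous physical position of index ``i`` along an axis with
spacing ``s`` nm is ``i * s`` nm.  Lateral sampling must be isotropic
(``dy == dx``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume",
    "SeedPair",
    "read_volume",
    "write_volume",
    "read_seeds",
    "write_seeds",
    "VolumeReadError",
]


class VolumeReadError(ValueError):
    """Raised when a TIFF cannot be interpreted as a multi-channel z-stack."""


@dataclass
class Volume:
    """A multi-channel 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    data : ndarray, shape (channels, z, y, x)
        Non-negative, finite intensities.  Always stored as float.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in nanometres; ``dy`` must equal ``dx``.
    channel_labels : list of str
        One label per channel.
    image_id : str
        Identifier used to join volumes with seed tables.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_labels: list[str] = field(default_factory=list)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"volume data must be 4D (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")
        dz, dy, dx = self.voxel_size
        if not (dz > 0 and dy > 0 and dx > 0):
            raise ValueError(f"voxel sizes must be positive; got {self.voxel_size}")
        if abs(dy - dx) > 1e-9 * max(dy, dx):
            raise ValueError(f"lateral sampling must be isotropic (dy == dx); got dy={dy}, dx={dx}")
        self.voxel_size = (float(dz), float(dy), float(dx))
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def dz(self) -> float:
        return self.voxel_size[0]

    @property
    def dx(self) -> float:
        return self.voxel_size[2]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given either its index or its label."""
        if isinstance(channel, str):
            try:
                return self.channel_labels.index(channel)
            except ValueError:
                raise ValueError(
                    f"unknown channel label {channel!r}; have {self.channel_labels}"
                ) from None
        idx = int(channel)
        if not 0 <= idx < self.n_channels:
            raise ValueError(f"channel index {idx} out of range for {self.n_channels} channels")
        return idx


@dataclass
class SeedPair:
    """A manually (or synthetically) picked mother/distal spot pair.

    Lateral coordinates are in pixels of the volume named by ``image_id``;
    the mother seed comes first by convention.
    """

    image_id: str
    fit_channel: int
    mother_seed: tuple[float, float]
    distal_seed: tuple[float, float]
    reference_channel: Optional[int] = None

    def __post_init__(self) -> None:
        self.mother_seed = (float(self.mother_seed[0]), float(self.mother_seed[1]))
        self.distal_seed = (float(self.distal_seed[0]), float(self.distal_seed[1]))
        if self.mother_seed == self.distal_seed:
            raise ValueError(f"degenerate seed pair for image {self.image_id!r}: seeds coincide")
        if self.reference_channel is not None and self.reference_channel == self.fit_channel:
            raise ValueError("reference_channel must differ from fit_channel")


_UNIT_TO_NM = {
    "nm": 1.0,
    "nanometer": 1.0,
    "um": 1000.0,
    "µm": 1000.0,
    "µm": 1000.0,
    "micron": 1000.0,
    "micrometer": 1000.0,
    "mm": 1e6,
}


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as an OME-TIFF readable by :func:`read_volume`.

    The re-read data is bit-identical to ``volume.data`` (stored as float64)
    and the voxel size, channel labels, and image id round-trip exactly.
    """
    path = Path(path)
    dz, dy, dx = volume.voxel_size
    metadata = {
        "axes": "CZYX",
        "Name": volume.image_id,
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "nm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "nm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "nm",
        "Channel": {"Name": list(volume.channel_labels)},
    }
    tifffile.imwrite(path, volume.data, ome=True, metadata=metadata)


def _axis_size_nm(pixels: dict, axis: str) -> Optional[float]:
    size = pixels.get(f"PhysicalSize{axis}")
    if size is None:
        return None
    unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
    factor = _UNIT_TO_NM.get(str(unit).lower(), _UNIT_TO_NM.get(str(unit)))
    if factor is None:
        raise VolumeReadError(f"unsupported physical unit {unit!r}")
    return float(size) * factor


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand TIFF series data to canonical (C, Z, Y, X)."""
    axes = axes.upper()
    # interleaved samples (trailing S) are channels; any other anonymous page
    # axis (S/Q/I leading) is a z stack
    if axes.endswith("S"):
        axes = axes[:-1] + "C"
    for anon in "SQI":
        axes = axes.replace(anon, "Z")
    if "T" in axes:
        t_pos = axes.index("T")
        if data.shape[t_pos] != 1:
            raise VolumeReadError("time series volumes are not supported")
        data = np.squeeze(data, axis=t_pos)
        axes = axes.replace("T", "")
    for needed in "CZ":
        if needed not in axes:
            data = data[np.newaxis]
            axes = needed + axes
    if set(axes) != set("CZYX") or len(axes) != 4:
        raise VolumeReadError(f"cannot interpret TIFF axes {axes!r} as (C, Z, Y, X)")
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def read_volume(
    path: str | Path,
    voxel_size_override: Optional[tuple[float, float, float]] = None,
) -> Volume:
    """Read a TIFF z-stack into a canonical ``(channel, z, y, x)`` Volume.

    Voxel sizes (nm) are taken from OME metadata, from ImageJ metadata
    (resolution tags + ``spacing``), or from ``voxel_size_override``.
    Missing voxel metadata without an override is an error.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # pragma: no cover - exercised via error test
        raise VolumeReadError(f"unreadable TIFF {path}: {exc}") from exc
    with tif:
        series = tif.series[0]
        data = _normalize_axes(series.asarray(), series.axes)
        labels: list[str] = []
        dz = dy = dx = None
        image_id = path.stem
        if tif.is_ome and tif.ome_metadata:
            ome = tifffile.xml2dict(tif.ome_metadata)
            image = ome.get("OME", {}).get("Image", {})
            if isinstance(image, list):
                image = image[0]
            image_id = image.get("Name") or image_id
            pixels = image.get("Pixels", {})
            dx = _axis_size_nm(pixels, "X")
            dy = _axis_size_nm(pixels, "Y")
            dz = _axis_size_nm(pixels, "Z")
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            labels = [c.get("Name") for c in chans if isinstance(c, dict) and c.get("Name")]
        elif tif.is_imagej:
            meta = tif.imagej_metadata or {}
            unit = _UNIT_TO_NM.get(str(meta.get("unit", "")).lower())
            page = tif.pages[0]
            if unit and "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                if num:
                    dx = dy = den / num * unit
            if unit and "spacing" in meta:
                dz = float(meta["spacing"]) * unit
            if "Labels" in meta:
                labels = list(meta["Labels"])[: data.shape[0]]
    if voxel_size_override is not None:
        dz, dy, dx = voxel_size_override
    if dz is None or dy is None or dx is None:
        raise VolumeReadError(
            f"voxel size unknown for {path}: no usable metadata and no override given"
        )
    if len(labels) != data.shape[0]:
        labels = []
    return Volume(
        data=data,
        voxel_size=(float(dz), float(dy), float(dx)),
        channel_labels=labels,
        image_id=image_id,
    )


_REQUIRED_SEED_COLUMNS = ("image_id", "fit_channel", "mother_x", "mother_y", "distal_x", "distal_y")


def read_seeds(path: str | Path) -> list[SeedPair]:
    """Read a seed-pair table from CSV, preserving row order.

    Required columns: ``image_id, fit_channel, mother_x, mother_y, distal_x,
    distal_y``; ``reference_channel`` is optional and may be blank.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed table {path} is missing required columns: {missing}")
    for col in ("mother_x", "mother_y", "distal_x", "distal_y"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"seed column {col!r} must be numeric")
    pairs: list[SeedPair] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        ref = None
        if "reference_channel" in df.columns and pd.notna(row["reference_channel"]):
            ref = int(row["reference_channel"])
        pair = SeedPair(
            image_id=str(row["image_id"]),
            fit_channel=int(row["fit_channel"]),
            mother_seed=(row["mother_x"], row["mother_y"]),
            distal_seed=(row["distal_x"], row["distal_y"]),
            reference_channel=ref,
        )
        key = (pair.image_id, pair.mother_seed, pair.distal_seed)
        if key in seen:
            warnings.warn(f"duplicate seed row for image {pair.image_id!r}", stacklevel=2)
        seen.add(key)
        pairs.append(pair)
    return pairs


def write_seeds(pairs: Sequence[SeedPair], path: str | Path) -> None:
    """Write seed pairs to CSV in the layout accepted by :func:`read_seeds`."""
    rows = [
        {
            "image_id": p.image_id,
            "fit_channel": p.fit_channel,
            "reference_channel": p.reference_channel,
            "mother_x": p.mother_seed[0],
            "mother_y": p.mother_seed[1],
            "distal_x": p.distal_seed[0],
            "distal_y": p.distal_seed[1],
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
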