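"""Particle realignment, orientation, and probability-map accumulation.

Each fitted particle is resampled onto a common 2D frame: the horizontal
axis runs from the mother to the distal spot (origin at their midpoint) and
the vertical axis is the projection of the optical z axis into the plane
containing both the particle axis and z.  Sampling is trilinear at a pitch
four times finer than the lateral voxel size.  Oriented planes are summed —
not averaged — into dual-color probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .detection import fit_gaussian_1d
from .fit3d import DualSpotFit
from .io_volumes import Volume

__all__ = [
    "Particle",
    "AlignedPlane",
    "ProbabilityMap",
    "assign_mother",
    "extract_aligned_plane",
    "orient_plane",
    "accumulate_map",
    "register_maps",
    "PoleAxisAmbiguousError",
    "OrientationError",
]

DEFAULT_GRID_SIZE = 641
DEFAULT_UPSAMPLE = 4
MAX_AXIS_TILT_FROM_PLANE_DEG = 60.0  # reject axes within 30 deg of vertical


class PoleAxisAmbiguousError(ValueError):
    """The mother–distal axis is too close to the optical axis to define a frame."""


class OrientationError(ValueError):
    """Orientation is indeterminate (e.g. a zero-intensity channel)."""


@dataclass
class Particle:
    """A fitted two-spot particle with a resolved mother assignment.

    Centers are physical ``(x, y, z)`` positions in nm.
    """

    image_id: str
    mother_center: np.ndarray
    distal_center: np.ndarray
    fit: DualSpotFit
    reference_center: Optional[np.ndarray] = None
    mother_rule: str = "seed-order"
    tie_flag: bool = False

    def __post_init__(self) -> None:
        self.mother_center = np.asarray(self.mother_center, dtype=float)
        self.distal_center = np.asarray(self.distal_center, dtype=float)
        if np.allclose(self.mother_center, self.distal_center):
            raise ValueError("mother and distal centers coincide")

    @property
    def separation_nm(self) -> float:
        return float(np.linalg.norm(self.distal_center - self.mother_center))


@dataclass
class AlignedPlane:
    """One particle resampled into the mother–distal / pole frame."""

    grid: np.ndarray  # (channels, ny, nx)
    pixel_size: float  # nm
    origin: tuple[int, int]  # (row, col) of the frame origin
    separation_nm: float
    particle_id: str
    coverage: np.ndarray = field(repr=False)  # (ny, nx) bool, True where in-volume
    h_flipped: bool = False
    v_flipped: bool = False
    channel_labels: list[str] = field(default_factory=list)


@dataclass
class ProbabilityMap:
    """Per-channel sum of realigned particle planes."""

    grid: np.ndarray  # (channels, ny, nx)
    n_particles: int
    pixel_size: float
    particle_ids: list[str]
    coverage: np.ndarray = field(repr=False)  # per-pixel count of contributing planes
    origin: tuple[int, int] = (0, 0)
    channel_labels: list[str] = field(default_factory=list)
    reference_channel: Optional[int] = None


def assign_mother(
    fit: DualSpotFit, reference_center: Optional[np.ndarray] = None
) -> Particle:
    """Resolve which fitted spot is the mother.

    With a reference (fiducial) center the mother is the spot closer to it in
    3D; without one the brighter spot wins.  Exact ties fall back to seed
    order (``spot_a``) with a warning flag.
    """
    if not fit.converged:
        raise ValueError("assign_mother requires a converged fit")
    if fit.degenerate:
        raise ValueError("assign_mother: fit is degenerate")
    ca = np.asarray(fit.spot_a.center, dtype=float)
    cb = np.asarray(fit.spot_b.center, dtype=float)
    tie = False
    if reference_center is not None:
        ref = np.asarray(reference_center, dtype=float)
        da, db = np.linalg.norm(ca - ref), np.linalg.norm(cb - ref)
        rule = "fiducial-proximity"
        scale = max(da, db, 1e-300)
        if abs(da - db) <= 1e-9 * scale:
            a_is_mother, tie = True, True
        else:
            a_is_mother = da < db
    else:
        aa, ab = fit.spot_a.amplitude, fit.spot_b.amplitude
        rule = "brightness"
        if abs(aa - ab) <= 1e-9 * max(aa, ab):
            a_is_mother, tie = True, True
        else:
            a_is_mother = aa > ab
    mother, distal = (ca, cb) if a_is_mother else (cb, ca)
    return Particle(
        image_id=fit.seeds.image_id,
        mother_center=mother,
        distal_center=distal,
        fit=fit,
        reference_center=None if reference_center is None else np.asarray(reference_center, dtype=float),
        mother_rule=rule,
        tie_flag=tie,
    )


def particle_frame(particle: Particle) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (midpoint, u, v): the frame origin and in-plane unit axes (nm).

    ``u`` points mother → distal; ``v`` is the unit projection of the z axis
    orthogonal to ``u`` (so the sampled plane contains both spot centers and
    the optical axis direction).
    """
    mother, distal = particle.mother_center, particle.distal_center
    u = distal - mother
    u = u / np.linalg.norm(u)
    tilt_from_plane = np.degrees(np.arcsin(min(abs(u[2]), 1.0)))
    if tilt_from_plane > MAX_AXIS_TILT_FROM_PLANE_DEG:
        raise PoleAxisAmbiguousError(
            f"pole-axis ambiguous: particle axis tilted {tilt_from_plane:.1f} deg out of plane "
            f"(limit {MAX_AXIS_TILT_FROM_PLANE_DEG} deg)"
        )
    zhat = np.array([0.0, 0.0, 1.0])
    v = zhat - (zhat @ u) * u
    v = v / np.linalg.norm(v)
    return (mother + distal) / 2.0, u, v


def extract_aligned_plane(
    volume: Volume,
    particle: Particle,
    upsample: int = DEFAULT_UPSAMPLE,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> AlignedPlane:
    """Trilinear-resample all channels onto the particle's 2D frame.

    The plane is sampled at a pitch of ``dx / upsample`` on a
    ``grid_size`` x ``grid_size`` grid centered on the spot midpoint; the
    mother center lands at (−d/2, 0) and the distal center at (+d/2, 0).
    Samples outside the volume contribute 0 and are excluded from the
    coverage mask.
    """
    mid, u, v = particle_frame(particle)
    dz, dy, dxv = volume.voxel_size
    pitch = dxv / upsample
    half = grid_size // 2
    offsets = (np.arange(grid_size) - half) * pitch
    # physical sample positions: mid + x*u + y*v, arranged (row=y, col=x)
    pos = (
        mid[None, None, :]
        + offsets[None, :, None] * u[None, None, :]
        + offsets[:, None, None] * v[None, None, :]
    )
    zi = pos[..., 2] / dz
    yi = pos[..., 1] / dy
    xi = pos[..., 0] / dxv
    nzv, nyv, nxv = volume.data.shape[1:]
    coverage = (
        (zi >= 0) & (zi <= nzv - 1) & (yi >= 0) & (yi <= nyv - 1) & (xi >= 0) & (xi <= nxv - 1)
    )
    coords = np.stack([zi.ravel(), yi.ravel(), xi.ravel()])
    grid = np.empty((volume.n_channels, grid_size, grid_size), dtype=float)
    for ch in range(volume.n_channels):
        grid[ch] = ndimage.map_coordinates(
            volume.data[ch], coords, order=1, mode="constant", cval=0.0
        ).reshape(grid_size, grid_size)
    return AlignedPlane(
        grid=grid,
        pixel_size=pitch,
        origin=(half, half),
        separation_nm=particle.separation_nm,
        particle_id=particle.image_id,
        coverage=coverage,
        channel_labels=list(volume.channel_labels),
    )


def _axis_coords(plane: AlignedPlane) -> tuple[np.ndarray, np.ndarray]:
    """(x positions, y positions) of grid columns/rows in nm."""
    r0, c0 = plane.origin
    ny, nx = plane.grid.shape[1:]
    x = (np.arange(nx) - c0) * plane.pixel_size
    y = (np.arange(ny) - r0) * plane.pixel_size
    return x, y


def orient_plane(
    plane: AlignedPlane,
    query_channel: int,
    reference_channel: Optional[int] = None,
    v_window_nm: float = 500.0,
) -> AlignedPlane:
    """Apply the canonical horizontal/vertical flips to a plane.

    Horizontal: the reference channel (or the query channel when no
    reference exists) must carry more total intensity on the negative-x
    half — the mother side.  Vertical: the query channel's y centroid inside
    ``|x| < d/2 + 100 nm``, ``|y| < v_window_nm`` must be non-negative.
    Flips are recorded; applying the operation twice is a no-op.
    """
    x, y = _axis_coords(plane)
    out = plane
    ref_ch = query_channel if reference_channel is None else reference_channel
    ref = out.grid[ref_ch]
    total = float(ref.sum())
    if total <= 0:
        raise OrientationError("reference channel carries no intensity; orientation indeterminate")
    left = float(ref[:, x < 0].sum())
    right = float(ref[:, x > 0].sum())
    if right > left:
        out = replace(
            out,
            grid=out.grid[:, :, ::-1].copy(),
            coverage=out.coverage[:, ::-1].copy(),
            h_flipped=not out.h_flipped,
        )
    qx, qy = _axis_coords(out)
    window_x = np.abs(qx) < out.separation_nm / 2.0 + 100.0
    window_y = np.abs(qy) < v_window_nm
    sub = out.grid[query_channel][np.ix_(window_y, window_x)]
    mass = float(sub.sum())
    if mass <= 0:
        raise OrientationError("query channel carries no intensity; orientation indeterminate")
    centroid_y = float((sub.sum(axis=1) @ qy[window_y]) / mass)
    if centroid_y < 0:
        out = replace(
            out,
            grid=out.grid[:, ::-1, :].copy(),
            coverage=out.coverage[::-1, :].copy(),
            v_flipped=not out.v_flipped,
        )
    return out


def accumulate_map(planes: Sequence[AlignedPlane]) -> ProbabilityMap:
    """Elementwise per-channel sum of aligned planes (raw sums, no scaling)."""
    if not planes:
        raise ValueError("cannot accumulate an empty list of planes")
    first = planes[0]
    for p in planes[1:]:
        if p.grid.shape != first.grid.shape:
            raise ValueError("all planes must share the grid shape")
        if abs(p.pixel_size - first.pixel_size) > 1e-9:
            raise ValueError("all planes must share the pixel size")
    grid = np.sum([p.grid for p in planes], axis=0)
    coverage = np.sum([p.coverage.astype(int) for p in planes], axis=0)
    return ProbabilityMap(
        grid=grid,
        n_particles=len(planes),
        pixel_size=first.pixel_size,
        particle_ids=[p.particle_id for p in planes],
        coverage=coverage,
        origin=first.origin,
        channel_labels=list(first.channel_labels),
    )


def _fiducial_y_center(pmap: ProbabilityMap, channel: int) -> float:
    """Gaussian-fitted y center (grid rows) of a map channel's y profile."""
    profile = pmap.grid[channel].mean(axis=1)
    fit = fit_gaussian_1d(profile)
    if fit is None:
        raise ValueError("fiducial y-profile fit failed")
    return fit[1]


def register_maps(
    maps: Sequence[ProbabilityMap], fiducial_channel: int | str
) -> list[ProbabilityMap]:
    """Vertically shift maps (bilinear) so fiducial y centers coincide.

    The first map is the registration target; x origins are untouched.
    """
    if not maps:
        return []
    resolved: list[int] = []
    for m in maps:
        if isinstance(fiducial_channel, str):
            resolved.append(m.channel_labels.index(fiducial_channel))
        else:
            resolved.append(int(fiducial_channel))
    target = _fiducial_y_center(maps[0], resolved[0])
    out: list[ProbabilityMap] = []
    for m, ch in zip(maps, resolved):
        center = _fiducial_y_center(m, ch)
        shift = target - center
        if abs(shift) < 1e-9:
            out.append(m)
            continue
        shifted = np.stack(
            [
                ndimage.shift(m.grid[c], (shift, 0.0), order=1, mode="constant", cval=0.0)
                for c in range(m.grid.shape[0])
            ]
        )
        out.append(replace(m, grid=shifted))
    return out
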