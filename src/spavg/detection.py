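"""Semi-automated candidate-particle detection on projection images.

The detector sum-projects a channel, blurs the projection, and greedily
accepts local maxima in descending blurred intensity subject to a fractional
threshold and a minimum mutual distance.  Accepted candidates get a boxed
z profile which is Gaussian-fitted to eliminate particles whose axial peak
sits at the first or last slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .io_volumes import Volume

__all__ = [
    "DetectionParams",
    "Candidate",
    "sum_project",
    "find_candidates",
    "extract_z_profile",
    "passes_z_filter",
    "fit_gaussian_1d",
]


@dataclass
class DetectionParams:
    """Detection tuning parameters (pixel units)."""

    blur_sigma: float = 1.0
    threshold_fraction: float = 0.15
    min_distance: float = 30.0
    box: int = 30

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.box < 3:
            raise ValueError("box must be >= 3 pixels")


@dataclass
class Candidate:
    """A candidate particle found in a projection image."""

    image_id: str
    channel: int
    xy: tuple[float, float]
    peak_value: float
    z_profile: Optional[np.ndarray] = None
    z_edge_ok: Optional[bool] = None


def sum_project(volume: Volume, channel: int | str) -> np.ndarray:
    """Sum a channel over z. Returns a (ny, nx) image."""
    ch = volume.channel_index(channel)
    return volume.data[ch].sum(axis=0)


def find_candidates(
    projection: np.ndarray,
    params: DetectionParams = DetectionParams(),
    image_id: str = "",
    channel: int = 0,
) -> list[Candidate]:
    """Greedy local-maximum detection with minimum-distance suppression.

    The projection is blurred with a Gaussian of ``params.blur_sigma``; local
    maxima (>= their 8 neighbours) whose blurred value exceeds
    ``threshold_fraction`` times the blurred-image maximum are visited in
    descending value (ties broken by (y, x) order) and accepted iff they lie
    at least ``min_distance`` (Euclidean, pixels) from every previously
    accepted maximum.  Candidates are returned in acceptance order.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.ndim != 2:
        raise ValueError("projection must be 2D")
    if not np.all(np.isfinite(projection)):
        raise ValueError("projection must be finite")
    blurred = ndimage.gaussian_filter(projection, params.blur_sigma) if params.blur_sigma > 0 else projection
    peak = blurred.max()
    if peak <= blurred.min():  # constant image: no maxima
        return []
    threshold = params.threshold_fraction * peak
    is_max = blurred == ndimage.maximum_filter(blurred, size=3, mode="nearest")
    ys, xs = np.nonzero(is_max & (blurred > threshold))
    values = blurred[ys, xs]
    order = np.lexsort((xs, ys, -values))
    accepted: list[Candidate] = []
    acc_yx: list[tuple[int, int]] = []
    min_d2 = params.min_distance**2
    for k in order:
        y, x = int(ys[k]), int(xs[k])
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_d2 for ay, ax in acc_yx):
            acc_yx.append((y, x))
            accepted.append(
                Candidate(image_id=image_id, channel=channel, xy=(float(x), float(y)), peak_value=float(values[k]))
            )
    return accepted


def extract_z_profile(
    volume: Volume, channel: int | str, xy: tuple[float, float], box: int = 30
) -> np.ndarray:
    """Axial intensity profile over a ``box`` x ``box`` lateral window.

    ``profile[z]`` is the sum of the channel's slice ``z`` over a window
    whose start index is ``round(center) - box // 2`` on each lateral axis,
    clipped at the image borders.
    """
    ch = volume.channel_index(channel)
    ny, nx = volume.lateral_shape
    x, y = xy
    if not (0 <= x < nx and 0 <= y < ny):
        raise ValueError(f"xy {xy} outside lateral bounds {(nx, ny)}")
    half = box // 2
    xs, ys = int(round(x)) - half, int(round(y)) - half
    x0, x1 = max(xs, 0), min(xs + box, nx)
    y0, y1 = max(ys, 0), min(ys + box, ny)
    return volume.data[ch, :, y0:y1, x0:x1].sum(axis=(1, 2))


def _gauss1d(x: np.ndarray, amplitude: float, center: float, sigma: float, offset: float) -> np.ndarray:
    return offset + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_gaussian_1d(
    profile: np.ndarray, positions: Optional[np.ndarray] = None
) -> Optional[tuple[float, float, float, float]]:
    """Least-squares fit of ``offset + A exp(-(x-c)^2 / 2 sigma^2)``.

    Returns ``(amplitude, center, sigma, offset)`` or None on failure.
    ``positions`` defaults to sample indices.
    """
    y = np.asarray(profile, dtype=float)
    x = np.arange(y.size, dtype=float) if positions is None else np.asarray(positions, dtype=float)
    if y.size < 4:
        return None
    offset0 = float(y.min())
    amp0 = float(y.max() - y.min())
    if amp0 <= 0:
        return None
    center0 = float(x[int(np.argmax(y))])
    sigma0 = max((x.max() - x.min()) / 6.0, 1e-6)

    def resid(p: np.ndarray) -> np.ndarray:
        return _gauss1d(x, *p) - y

    try:
        result = optimize.least_squares(
            resid,
            x0=[amp0, center0, sigma0, offset0],
            bounds=([0.0, -np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=2000,
        )
    except Exception:
        return None
    if not result.success:
        return None
    return tuple(float(v) for v in result.x)  # type: ignore[return-value]


def passes_z_filter(profile: np.ndarray) -> bool:
    """True iff the Gaussian-fitted axial center is away from the stack ends.

    A particle fails when the fitted center lies within the first slice
    ``[0, 1)``, within the last slice ``(L-2, L-1]`` (or beyond), or when the
    1D fit does not converge — truncated particles are dropped conservatively.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    if n < 3:
        raise ValueError("z profile must cover at least 3 slices")
    fit = fit_gaussian_1d(profile)
    if fit is None:
        return False
    center = fit[1]
    return 1.0 <= center <= n - 2.0


def candidates_for_volume(
    volume: Volume,
    channel: int | str,
    params: DetectionParams = DetectionParams(),
) -> list[Candidate]:
    """Full detection pass: project, find maxima, attach z profiles & filter."""
    ch = volume.channel_index(channel)
    projection = sum_project(volume, ch)
    cands = find_candidates(projection, params, image_id=volume.image_id, channel=ch)
    for cand in cands:
        cand.z_profile = extract_z_profile(volume, ch, cand.xy, box=params.box)
        cand.z_edge_ok = passes_z_filter(cand.z_profile) if cand.z_profile.size >= 3 else False
    return cands
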