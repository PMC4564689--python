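"""Constrained single- and dual-spot 3D Gaussian fitting.

Both spots share one lateral and one axial width (they are imaged by the
same PSF) and sit on a single constant background.  Lateral centers are
box-constrained to ±2 pixels around the seed positions; axial centers are
initialized at the brightest slice of a 3x3 z profile and constrained to
±2 slices.  Optimization is trust-region nonlinear least squares (the
box-constrained Levenberg–Marquardt variant provided by
``scipy.optimize.least_squares``).

All fitted quantities are in physical units: centers and widths in nm,
amplitudes and background in the image's intensity units.

Parameter uncertainties come from a residual-noise Monte Carlo: synthetic
datasets are built from the fitted model plus i.i.d. Gaussian noise with the
residual variance, refit from the original initialization, and per-parameter
standard deviations taken over the replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .io_volumes import SeedPair, Volume

__all__ = [
    "Gaussian3D",
    "SingleSpotFit",
    "DualSpotFit",
    "MonteCarloErrors",
    "init_axial_center",
    "fit_single_spot",
    "fit_dual_spot",
    "monte_carlo_errors",
    "intensity_ratio",
    "DegenerateFitError",
]

LATERAL_CONSTRAINT_PX = 2.0
AXIAL_CONSTRAINT_SLICES = 2.0
CROP_MARGIN_PX = 15

DUAL_PARAM_NAMES = (
    "background",
    "amp_a",
    "amp_b",
    "x_a",
    "y_a",
    "z_a",
    "x_b",
    "y_b",
    "z_b",
    "sigma_xy",
    "sigma_z",
)
SINGLE_PARAM_NAMES = ("background", "amplitude", "x", "y", "z", "sigma_xy", "sigma_z")


class DegenerateFitError(ValueError):
    """Raised when a fit is too degenerate for the requested quantity."""


@dataclass
class Gaussian3D:
    """An isotropic-lateral 3D Gaussian spot in physical units (nm)."""

    amplitude: float
    center: tuple[float, float, float]  # (cx, cy, cz) nm
    sigma_xy: float
    sigma_z: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("widths must be positive")
        self.center = tuple(float(c) for c in self.center)  # type: ignore[assignment]


@dataclass
class _FitContext:
    """Everything needed to re-evaluate and re-run a fit (for Monte Carlo)."""

    coords: tuple[np.ndarray, np.ndarray, np.ndarray]  # broadcastable (z, y, x) nm grids
    data: np.ndarray
    x0: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    model_fn: Callable[[np.ndarray], np.ndarray]


@dataclass
class SingleSpotFit:
    spot: Gaussian3D
    background: float
    residual_variance: float
    converged: bool
    crop_origin: tuple[int, int, int]  # (z, y, x) voxel offset of the crop
    rss: float
    n_points: int
    params: np.ndarray
    voxel_size: tuple[float, float, float]
    context: _FitContext = field(repr=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return SINGLE_PARAM_NAMES


@dataclass
class DualSpotFit:
    """Joint two-spot fit; ``spot_a`` is the mother-seeded spot."""

    spot_a: Gaussian3D
    spot_b: Gaussian3D
    background: float
    residual_variance: float
    converged: bool
    degenerate: bool
    crop_origin: tuple[int, int, int]
    seeds: SeedPair
    rss: float
    n_points: int
    params: np.ndarray
    voxel_size: tuple[float, float, float]
    context: _FitContext = field(repr=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return DUAL_PARAM_NAMES

    @property
    def separation_nm(self) -> float:
        a = np.asarray(self.spot_a.center)
        b = np.asarray(self.spot_b.center)
        return float(np.linalg.norm(a - b))

    @property
    def lateral_crop(self) -> tuple[int, int, int, int]:
        """(x0, x1, y0, y1) of the fitted sub-volume, for same-crop refits."""
        _, ny, nx = self.context.data.shape
        _, y0, x0 = self.crop_origin
        return x0, x0 + nx, y0, y0 + ny


@dataclass
class MonteCarloErrors:
    """Per-parameter SDs over residual-noise Monte Carlo replicates."""

    sds: dict[str, float]
    n_replicates: int
    n_excluded: int
    rng_seed: int
    unreliable: bool


def _crop_bounds(volume: Volume, xs: Sequence[float], ys: Sequence[float], margin: int) -> tuple:
    ny, nx = volume.lateral_shape
    x0 = max(int(np.floor(min(xs))) - margin, 0)
    x1 = min(int(np.ceil(max(xs))) + margin + 1, nx)
    y0 = max(int(np.floor(min(ys))) - margin, 0)
    y1 = min(int(np.ceil(max(ys))) + margin + 1, ny)
    return x0, x1, y0, y1


def _coord_grids(volume: Volume, z0: int, z1: int, y0: int, y1: int, x0: int, x1: int):
    dz, dy, dx = volume.voxel_size
    zc = (np.arange(z0, z1) * dz)[:, None, None]
    yc = (np.arange(y0, y1) * dy)[None, :, None]
    xc = (np.arange(x0, x1) * dx)[None, None, :]
    return zc, yc, xc


def init_axial_center(volume: Volume, channel: int | str, xy: tuple[float, float]) -> int:
    """Brightest slice of the 3x3 lateral z profile at ``xy`` (ties → lower z)."""
    ch = volume.channel_index(channel)
    ny, nx = volume.lateral_shape
    x, y = int(round(xy[0])), int(round(xy[1]))
    if not (0 <= x < nx and 0 <= y < ny):
        raise ValueError(f"xy {xy} outside lateral bounds")
    x0, x1 = max(x - 1, 0), min(x + 2, nx)
    y0, y1 = max(y - 1, 0), min(y + 2, ny)
    profile = volume.data[ch, :, y0:y1, x0:x1].sum(axis=(1, 2))
    return int(np.argmax(profile))


def _gauss3d(coords, amp, cx, cy, cz, sxy, sz):
    zc, yc, xc = coords
    return amp * np.exp(
        -((xc - cx) ** 2 + (yc - cy) ** 2) / (2.0 * sxy**2) - (zc - cz) ** 2 / (2.0 * sz**2)
    )


def _run_least_squares(ctx: _FitContext, data: Optional[np.ndarray] = None):
    data = ctx.data if data is None else data
    flat = data.ravel()

    def resid(p: np.ndarray) -> np.ndarray:
        return ctx.model_fn(p).ravel() - flat

    result = optimize.least_squares(
        resid,
        x0=ctx.x0,
        bounds=(ctx.lower, ctx.upper),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=4000,
    )
    return result


def fit_single_spot(
    volume: Volume,
    channel: int | str,
    seed: tuple[float, float],
    margin: int = CROP_MARGIN_PX,
    lateral_bounds: Optional[tuple[int, int, int, int]] = None,
) -> SingleSpotFit:
    """Fit one constrained 3D Gaussian plus constant background around a seed.

    ``lateral_bounds`` (x0, x1, y0, y1) overrides the automatic crop — used
    to fit on exactly the same crop as a dual fit for nested-model tests.
    """
    ch = volume.channel_index(channel)
    dz, dy, dx = volume.voxel_size
    if lateral_bounds is not None:
        x0i, x1i, y0i, y1i = lateral_bounds
    else:
        x0i, x1i, y0i, y1i = _crop_bounds(volume, [seed[0]], [seed[1]], margin)
    nz = volume.n_slices
    crop = volume.data[ch, :, y0i:y1i, x0i:x1i]
    coords = _coord_grids(volume, 0, nz, y0i, y1i, x0i, x1i)
    z_init = init_axial_center(volume, ch, seed)

    bg0 = float(np.percentile(crop, 10.0))
    peak = float(
        crop[z_init, int(round(seed[1])) - y0i, int(round(seed[0])) - x0i]
    )
    amp0 = max(peak - bg0, 1e-6)
    x0 = np.array([bg0, amp0, seed[0] * dx, seed[1] * dy, z_init * dz, 1.2 * dx, 1.0 * dz])
    lower = np.array(
        [
            -np.inf,
            1e-12,
            (seed[0] - LATERAL_CONSTRAINT_PX) * dx,
            (seed[1] - LATERAL_CONSTRAINT_PX) * dy,
            (z_init - AXIAL_CONSTRAINT_SLICES) * dz,
            0.05 * dx,
            0.05 * dz,
        ]
    )
    upper = np.array(
        [
            np.inf,
            np.inf,
            (seed[0] + LATERAL_CONSTRAINT_PX) * dx,
            (seed[1] + LATERAL_CONSTRAINT_PX) * dy,
            (z_init + AXIAL_CONSTRAINT_SLICES) * dz,
            np.inf,
            np.inf,
        ]
    )

    def model_fn(p: np.ndarray) -> np.ndarray:
        return p[0] + _gauss3d(coords, p[1], p[2], p[3], p[4], p[5], p[6])

    ctx = _FitContext(coords, crop, x0, lower, upper, model_fn)
    result = _run_least_squares(ctx)
    p = result.x
    resid = model_fn(p) - crop
    return SingleSpotFit(
        spot=Gaussian3D(amplitude=p[1], center=(p[2], p[3], p[4]), sigma_xy=p[5], sigma_z=p[6]),
        background=float(p[0]),
        residual_variance=float(np.var(resid)),
        converged=bool(result.success),
        crop_origin=(0, y0i, x0i),
        rss=float(np.sum(resid**2)),
        n_points=int(crop.size),
        params=np.asarray(p, dtype=float),
        voxel_size=volume.voxel_size,
        context=ctx,
    )


def fit_dual_spot(
    volume: Volume,
    seedpair: SeedPair,
    margin: int = CROP_MARGIN_PX,
) -> DualSpotFit:
    """Joint constrained fit of two 3D Gaussians with shared widths.

    ``spot_a`` corresponds to ``seedpair.mother_seed``.  The fit is flagged
    degenerate when the two centers collapse onto each other (within half a
    voxel on every axis) or one amplitude vanishes.
    """
    ch = volume.channel_index(seedpair.fit_channel)
    dz, dy, dx = volume.voxel_size
    (mx, my), (dx_s, dy_s) = seedpair.mother_seed, seedpair.distal_seed
    ny, nx = volume.lateral_shape
    for sx, sy in (seedpair.mother_seed, seedpair.distal_seed):
        if not (0 <= sx < nx and 0 <= sy < ny):
            raise ValueError(f"seed ({sx}, {sy}) outside lateral bounds")
    x0i, x1i, y0i, y1i = _crop_bounds(volume, [mx, dx_s], [my, dy_s], margin)
    nz = volume.n_slices
    crop = volume.data[ch, :, y0i:y1i, x0i:x1i]
    coords = _coord_grids(volume, 0, nz, y0i, y1i, x0i, x1i)
    za = init_axial_center(volume, ch, seedpair.mother_seed)
    zb = init_axial_center(volume, ch, seedpair.distal_seed)

    bg0 = float(np.percentile(crop, 10.0))

    def _peak(sx: float, sy: float, z: int) -> float:
        return float(crop[z, int(round(sy)) - y0i, int(round(sx)) - x0i])

    amp_a0 = max(_peak(mx, my, za) - bg0, 1e-6)
    amp_b0 = max(_peak(dx_s, dy_s, zb) - bg0, 1e-6)
    x0 = np.array(
        [bg0, amp_a0, amp_b0, mx * dx, my * dy, za * dz, dx_s * dx, dy_s * dy, zb * dz, 1.2 * dx, 1.0 * dz]
    )
    cpx = LATERAL_CONSTRAINT_PX
    csl = AXIAL_CONSTRAINT_SLICES
    lower = np.array(
        [
            -np.inf,
            1e-12,
            1e-12,
            (mx - cpx) * dx,
            (my - cpx) * dy,
            (za - csl) * dz,
            (dx_s - cpx) * dx,
            (dy_s - cpx) * dy,
            (zb - csl) * dz,
            0.05 * dx,
            0.05 * dz,
        ]
    )
    upper = np.array(
        [
            np.inf,
            np.inf,
            np.inf,
            (mx + cpx) * dx,
            (my + cpx) * dy,
            (za + csl) * dz,
            (dx_s + cpx) * dx,
            (dy_s + cpx) * dy,
            (zb + csl) * dz,
            np.inf,
            np.inf,
        ]
    )

    def model_fn(p: np.ndarray) -> np.ndarray:
        return (
            p[0]
            + _gauss3d(coords, p[1], p[3], p[4], p[5], p[9], p[10])
            + _gauss3d(coords, p[2], p[6], p[7], p[8], p[9], p[10])
        )

    ctx = _FitContext(coords, crop, x0, lower, upper, model_fn)
    result = _run_least_squares(ctx)
    p = result.x
    resid = model_fn(p) - crop
    center_a = np.array([p[3], p[4], p[5]])
    center_b = np.array([p[6], p[7], p[8]])
    lateral_sep_px = np.hypot(p[3] - p[6], p[4] - p[7]) / dx
    axial_sep_slices = abs(p[5] - p[8]) / dz
    collapsed = lateral_sep_px < 0.5 and axial_sep_slices < 0.5
    amp_lost = min(p[1], p[2]) < 1e-6 * max(p[1], p[2])
    return DualSpotFit(
        spot_a=Gaussian3D(amplitude=p[1], center=tuple(center_a), sigma_xy=p[9], sigma_z=p[10]),
        spot_b=Gaussian3D(amplitude=p[2], center=tuple(center_b), sigma_xy=p[9], sigma_z=p[10]),
        background=float(p[0]),
        residual_variance=float(np.var(resid)),
        converged=bool(result.success),
        degenerate=bool(collapsed or amp_lost),
        crop_origin=(0, y0i, x0i),
        seeds=seedpair,
        rss=float(np.sum(resid**2)),
        n_points=int(crop.size),
        params=np.asarray(p, dtype=float),
        voxel_size=volume.voxel_size,
        context=ctx,
    )


def _mc_refit_sds(
    ctx: _FitContext,
    fitted_params: np.ndarray,
    residual_variance: float,
    n: int,
    rng_seed: int,
) -> tuple[np.ndarray, int]:
    """Shared residual-noise Monte Carlo engine. Returns (SDs, n_excluded)."""
    model = ctx.model_fn(fitted_params)
    sd = float(np.sqrt(residual_variance))
    rng = np.random.default_rng(rng_seed)
    samples: list[np.ndarray] = []
    excluded = 0
    for _ in range(n):
        synthetic = model + rng.normal(0.0, sd, size=model.shape)
        result = _run_least_squares(ctx, data=synthetic)
        if result.success:
            samples.append(result.x)
        else:
            excluded += 1
    if not samples:
        return np.full_like(fitted_params, np.nan, dtype=float), excluded
    return np.std(np.asarray(samples), axis=0, ddof=0), excluded


def monte_carlo_errors(
    fit: SingleSpotFit | DualSpotFit,
    volume: Optional[Volume] = None,
    n: int = 100,
    rng_seed: int = 0,
) -> MonteCarloErrors:
    """Residual-noise Monte Carlo parameter SDs (default 100 replicates).

    Each replicate is the fitted model plus i.i.d. Gaussian noise at the
    fit's residual variance, refit from the original initialization.
    ``volume`` is accepted for API symmetry but the fit carries its own crop.
    Non-converged replicates are excluded and counted; if more than 10% fail
    the estimate is flagged unreliable.  A zero residual variance short-cuts
    to exact zeros.
    """
    if not fit.converged:
        raise ValueError("monte_carlo_errors requires a converged fit")
    names = fit.param_names
    if fit.residual_variance == 0.0:
        return MonteCarloErrors(
            sds={k: 0.0 for k in names}, n_replicates=n, n_excluded=0, rng_seed=rng_seed, unreliable=False
        )
    sds, excluded = _mc_refit_sds(fit.context, fit.params, fit.residual_variance, n, rng_seed)
    return MonteCarloErrors(
        sds=dict(zip(names, (float(s) for s in sds))),
        n_replicates=n,
        n_excluded=excluded,
        rng_seed=rng_seed,
        unreliable=excluded > 0.1 * n,
    )


def intensity_ratio(fit: DualSpotFit) -> float:
    """Mother-to-distal amplitude ratio (== integrated ratio; shared widths)."""
    if not fit.converged:
        raise ValueError("intensity_ratio requires a converged fit")
    if fit.degenerate:
        raise DegenerateFitError("fit is degenerate; intensity ratio undefined")
    a, b = fit.spot_a.amplitude, fit.spot_b.amplitude
    if b < 1e-6 * a:
        raise DegenerateFitError("distal amplitude vanishes; ratio would diverge")
    return a / b
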