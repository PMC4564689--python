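"""Quantification of probability maps.

Axis profiles (mean over the perpendicular axis), multi-Gaussian profile
decomposition with residual-noise Monte Carlo errors, FWHM / 95%-integral
conversions, 3D distances and bend angles, fractional-threshold contour
outlines, display rendering, and a one-vs-two foci classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, signal, stats
from skimage import measure, transform

from .alignment import ProbabilityMap
from .fit3d import DualSpotFit, SingleSpotFit

__all__ = [
    "AxisProfile",
    "ProfileComponent",
    "ProfileFit",
    "ContourSet",
    "axis_profile",
    "fit_profile",
    "fwhm_from_sigma",
    "ci95_from_fwhm",
    "distance_3d",
    "bend_angle",
    "contour_set",
    "render_display",
    "classify_foci",
    "FociDecision",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class AxisProfile:
    """A 1D intensity profile along one map axis; positions in nm."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "x"
    channel: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")


@dataclass
class ProfileComponent:
    center: float  # nm
    sigma: float  # nm
    amplitude: float

    @property
    def fwhm(self) -> float:
        return fwhm_from_sigma(self.sigma)


@dataclass
class ProfileFit:
    """Multi-Gaussian decomposition of an axis profile."""

    axis: str
    components: list[ProfileComponent]
    offset: float
    broad_bg_component: Optional[ProfileComponent]
    trim_px: int
    errors: dict[str, float]
    n_components: int
    converged: bool
    collapsed: bool
    residual_variance: float
    rss: float
    mc_excluded: int = 0


@dataclass
class ContourOutline:
    channel: int
    distribution: int  # 0-based index of the distribution within the channel
    polygon: np.ndarray  # (N, 2) array of (x, y) nm vertices
    peak_xy: tuple[float, float]  # nm


@dataclass
class ContourSet:
    outlines: list[ContourOutline]
    threshold_fraction: float


def axis_profile(
    pmap: ProbabilityMap,
    channel: int | str,
    axis: str = "x",
    perp_window_nm: Optional[float] = None,
) -> AxisProfile:
    """Mean of a map channel over the perpendicular axis, positions in nm.

    ``perp_window_nm`` restricts the averaging to perpendicular positions
    within that distance of the frame origin; by default the full grid is
    averaged.  Restricting the window avoids diluting the structure with
    empty frame area when the grid is much larger than the particle.
    """
    if isinstance(channel, str):
        ch = pmap.channel_labels.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < pmap.grid.shape[0]:
            raise ValueError(f"channel {ch} out of range")
    r0, c0 = pmap.origin
    ny, nx = pmap.grid.shape[1:]
    ypos = (np.arange(ny) - r0) * pmap.pixel_size
    xpos = (np.arange(nx) - c0) * pmap.pixel_size
    if axis == "x":
        rows = np.ones(ny, dtype=bool) if perp_window_nm is None else np.abs(ypos) <= perp_window_nm
        values = pmap.grid[ch][rows, :].mean(axis=0)
        positions = xpos
    elif axis == "y":
        cols = np.ones(nx, dtype=bool) if perp_window_nm is None else np.abs(xpos) <= perp_window_nm
        values = pmap.grid[ch][:, cols].mean(axis=1)
        positions = ypos
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return AxisProfile(positions=positions, values=values, axis=axis, channel=ch)


def _multi_gauss(x: np.ndarray, params: np.ndarray, n_comp: int, broad: bool) -> np.ndarray:
    out = np.full_like(x, params[0])
    idx = 1
    for _ in range(n_comp):
        a, c, s = params[idx : idx + 3]
        out = out + a * np.exp(-((x - c) ** 2) / (2.0 * s**2))
        idx += 3
    if broad:
        a, s = params[idx : idx + 2]
        out = out + a * np.exp(-(x**2) / (2.0 * s**2))
    return out


def _init_peaks(x: np.ndarray, y: np.ndarray, n_comp: int) -> list[tuple[float, float, float]]:
    """Heuristic (amplitude, center, sigma) starts from the profile's peaks."""
    baseline = float(y.min())
    span = x.max() - x.min()
    sigma0 = max(span / (6.0 * n_comp), 1e-6)
    smooth = ndimage.gaussian_filter1d(y, max(y.size / 200.0, 1.0)) if y.size > 20 else y
    peaks, props = signal.find_peaks(smooth, prominence=0.05 * (smooth.max() - smooth.min() + 1e-300))
    if len(peaks) >= n_comp:
        top = peaks[np.argsort(props["prominences"])[::-1][:n_comp]]
        top = np.sort(top)
        return [(float(y[i] - baseline), float(x[i]), sigma0) for i in top]
    # fall back to evenly spaced quantile positions
    qs = np.linspace(0.25, 0.75, n_comp)
    return [
        (float(y.max() - baseline), float(x.min() + q * span), sigma0) for q in qs
    ]


def fit_profile(
    profile: AxisProfile,
    n_components: int = 1,
    trim_px: int = 0,
    broad_bg: bool = False,
    mc_seed: int = 0,
    n_mc: int = 100,
    window_nm: Optional[float] = None,
) -> ProfileFit:
    """Least-squares multi-Gaussian fit of an axis profile.

    The model is a constant offset plus ``n_components`` Gaussians and,
    optionally, a broad component fixed at x = 0 whose width is bounded
    below at 1.5x the peak width (preventing collapse onto a peak).
    ``trim_px`` samples are dropped from each end before fitting; if
    ``window_nm`` is given the profile is first restricted to
    ``|position| <= window_nm`` (useful when the map frame is much wider
    than the structure).  Widths are reported as FWHM = 2*sqrt(2 ln 2) *
    sigma.  Parameter SDs come from the residual-noise Monte Carlo
    procedure (``n_mc`` replicates).
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    x = profile.positions
    y = profile.values
    if window_nm is not None:
        keep = np.abs(x) <= window_nm
        if not np.any(keep):
            raise ValueError("window_nm excludes the entire profile")
        x, y = x[keep], y[keep]
    if trim_px > 0:
        if 2 * trim_px >= x.size:
            raise ValueError("trim removes the entire profile")
        x = x[trim_px:-trim_px]
        y = y[trim_px:-trim_px]
    n_free = 1 + 3 * n_components + (2 if broad_bg else 0)
    if x.size < 5 * n_free:
        raise ValueError(
            f"profile too short after trimming: {x.size} samples for {n_free} free parameters"
        )

    starts = _init_peaks(x, y, n_components)
    x0 = [float(y.min())]
    lower = [-np.inf]
    upper = [np.inf]
    for a0, c0, s0 in starts:
        x0 += [max(a0, 1e-9), c0, s0]
        lower += [0.0, float(x.min()), 1e-9]
        upper += [np.inf, float(x.max()), np.inf]
    if broad_bg:
        # a coarse peak-only prefit sets the lower width bound for the broad term
        pre = optimize.least_squares(
            lambda p: _multi_gauss(x, p, n_components, False) - y,
            x0=np.asarray(x0),
            bounds=(np.asarray(lower), np.asarray(upper)),
            method="trf",
            max_nfev=2000,
        )
        peak_sigmas = [pre.x[1 + 3 * k + 2] for k in range(n_components)]
        broad_floor = 1.5 * max(peak_sigmas)
        x0 += [max(float(y.max() - y.min()) * 0.2, 1e-9), 2.0 * broad_floor]
        lower += [0.0, broad_floor]
        upper += [np.inf, np.inf]
    x0v, lo, hi = np.asarray(x0), np.asarray(lower), np.asarray(upper)

    def resid(p: np.ndarray) -> np.ndarray:
        return _multi_gauss(x, p, n_components, broad_bg) - y

    result = optimize.least_squares(
        resid, x0=x0v, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, max_nfev=5000
    )
    p = result.x
    res = resid(p)
    s2 = float(np.var(res))
    comps = sorted(
        (ProfileComponent(amplitude=float(p[1 + 3 * k]), center=float(p[2 + 3 * k]), sigma=float(p[3 + 3 * k]))
         for k in range(n_components)),
        key=lambda c: c.center,
    )
    collapsed = False
    if n_components == 2:
        pitch = abs(float(np.median(np.diff(x)))) if x.size > 1 else 1.0
        collapsed = abs(comps[0].center - comps[1].center) < pitch
    broad_comp = None
    if broad_bg:
        broad_comp = ProfileComponent(amplitude=float(p[-2]), center=0.0, sigma=float(p[-1]))

    names = ["offset"]
    for k in range(n_components):
        names += [f"amp_{k}", f"center_{k}", f"sigma_{k}"]
    if broad_bg:
        names += ["broad_amp", "broad_sigma"]
    errors = {k: 0.0 for k in names}
    mc_excluded = 0
    if s2 > 0 and n_mc > 0:
        rng = np.random.default_rng(mc_seed)
        model = _multi_gauss(x, p, n_components, broad_bg)
        sd = np.sqrt(s2)
        samples = []
        for _ in range(n_mc):
            synth = model + rng.normal(0.0, sd, size=model.shape)
            r = optimize.least_squares(
                lambda q: _multi_gauss(x, q, n_components, broad_bg) - synth,
                x0=x0v,
                bounds=(lo, hi),
                method="trf",
                max_nfev=5000,
            )
            if r.success:
                samples.append(r.x)
            else:
                mc_excluded += 1
        if samples:
            sds = np.std(np.asarray(samples), axis=0, ddof=0)
            errors = dict(zip(names, (float(s) for s in sds)))
    return ProfileFit(
        axis=profile.axis,
        components=comps,
        offset=float(p[0]),
        broad_bg_component=broad_comp,
        trim_px=trim_px,
        errors=errors,
        n_components=n_components,
        converged=bool(result.success),
        collapsed=collapsed,
        residual_variance=s2,
        rss=float(np.sum(res**2)),
        mc_excluded=mc_excluded,
    )


def fwhm_from_sigma(sigma: float) -> float:
    """FWHM of a Gaussian: 2*sqrt(2 ln 2) * sigma (~2.35 sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_PER_SIGMA * sigma


def ci95_from_fwhm(fwhm: float) -> float:
    """Width containing the central 95% of a Gaussian's integral (~1.7 x FWHM)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return 2.0 * stats.norm.ppf(0.975) / FWHM_PER_SIGMA * fwhm


def distance_3d(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two physical positions (nm)."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def bend_angle(mother: Sequence[float], middle: Sequence[float], distal: Sequence[float]) -> float:
    """Deviation from collinearity at ``middle``, in degrees [0, 180).

    0 means the three points are collinear; 90 means a right-angle kink.
    """
    m = np.asarray(mother, dtype=float)
    c = np.asarray(middle, dtype=float)
    d = np.asarray(distal, dtype=float)
    va, vb = m - c, d - c
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("bend_angle requires three distinct points")
    cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    return 180.0 - float(np.degrees(np.arccos(cosang)))


def _split_column(pmap: ProbabilityMap, channel: int) -> Optional[int]:
    """Column index of the x-profile minimum between the two strongest peaks."""
    prof = pmap.grid[channel].mean(axis=0)
    peaks, props = signal.find_peaks(prof, prominence=0.05 * (prof.max() - prof.min() + 1e-300))
    if len(peaks) < 2:
        return None
    top2 = np.sort(peaks[np.argsort(props["prominences"])[::-1][:2]])
    lo, hi = int(top2[0]), int(top2[1])
    return lo + int(np.argmin(prof[lo : hi + 1]))


def contour_set(
    maps: ProbabilityMap | Sequence[ProbabilityMap],
    threshold_fraction: float = 0.75,
) -> ContourSet:
    """Fractional-threshold contour outlines per channel per distribution.

    Each channel is thresholded at ``threshold_fraction`` of its own maximum
    and the mask outlined.  Channels with two peaks along x are split at the
    x-profile minimum between them and each side is thresholded against its
    own maximum, so a dimmer distribution is still outlined.  Polygon
    vertices are in (x, y) nm map coordinates.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if isinstance(maps, ProbabilityMap):
        maps = [maps]
    outlines: list[ContourOutline] = []
    for pmap in maps:
        r0, c0 = pmap.origin
        for ch in range(pmap.grid.shape[0]):
            img = pmap.grid[ch]
            if img.max() <= img.min():
                raise ValueError(f"channel {ch} is flat; no contour")
            split = _split_column(pmap, ch)
            regions = [(0, img.shape[1])] if split is None else [(0, split), (split, img.shape[1])]
            for di, (a, b) in enumerate(regions):
                sub = img[:, a:b]
                if sub.size == 0 or sub.max() <= 0:
                    continue
                level = threshold_fraction * sub.max()
                mask = (sub >= level).astype(float)
                contours = measure.find_contours(mask, 0.5)
                if not contours:
                    continue
                peak_r, peak_c = np.unravel_index(np.argmax(sub), sub.shape)
                # keep the outline around this distribution's peak (largest if ambiguous)
                best = max(contours, key=lambda c: c.shape[0])
                for cont in contours:
                    rr, cc = cont[:, 0], cont[:, 1]
                    if (rr.min() - 1 <= peak_r <= rr.max() + 1) and (cc.min() - 1 <= peak_c <= cc.max() + 1):
                        best = cont
                        break
                poly = np.column_stack(
                    [
                        (best[:, 1] + a - c0) * pmap.pixel_size,
                        (best[:, 0] - r0) * pmap.pixel_size,
                    ]
                )
                outlines.append(
                    ContourOutline(
                        channel=ch,
                        distribution=di,
                        polygon=poly,
                        peak_xy=((peak_c + a - c0) * pmap.pixel_size, (peak_r - r0) * pmap.pixel_size),
                    )
                )
    return ContourSet(outlines=outlines, threshold_fraction=threshold_fraction)


def render_display(image: np.ndarray, upsample: int = 2, blur_radius: float = 0.8) -> np.ndarray:
    """Display rendering: 2x2 bilinear upscale then Gaussian blur (sigma 0.8).

    Presentation only — never feed the output back into quantitation.
    Constant images are preserved (DC-preserving resampling).
    """
    image = np.asarray(image, dtype=float)
    up = transform.rescale(
        image, upsample, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return ndimage.gaussian_filter(up, blur_radius, mode="nearest")


@dataclass
class FociDecision:
    label: str  # "one" | "two"
    f_statistic: float
    p_value: float
    separation_nm: float
    reliable: bool = True


def classify_foci(
    fit_single: SingleSpotFit,
    fit_dual: DualSpotFit,
    alpha: float = 0.01,
) -> FociDecision:
    """Decide one vs two foci from nested single/dual fits of the same crop.

    "two" requires the dual fit to reduce the residual sum of squares beyond
    an F-ratio criterion (default p < alpha for the 4 extra parameters) and
    a fitted separation above one lateral pixel.
    """
    if not (fit_single.converged and fit_dual.converged):
        return FociDecision(label="one", f_statistic=np.nan, p_value=np.nan, separation_nm=np.nan, reliable=False)
    if fit_single.n_points != fit_dual.n_points:
        raise ValueError("classify_foci requires fits on the same crop")
    n = fit_dual.n_points
    p_single = len(fit_single.params)
    p_dual = len(fit_dual.params)
    df_extra = p_dual - p_single
    df_resid = n - p_dual
    rss1, rss2 = fit_single.rss, fit_dual.rss
    if rss2 <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((rss1 - rss2) / df_extra) / (rss2 / df_resid)
        p_value = float(stats.f.sf(f_stat, df_extra, df_resid))
    dx = fit_dual.voxel_size[2]
    sep = fit_dual.separation_nm
    label = "two" if (p_value < alpha and sep > dx) else "one"
    return FociDecision(label=label, f_statistic=float(f_stat), p_value=p_value, separation_nm=sep)
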