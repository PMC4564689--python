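"""Ground-truthed synthetic two-color particle volumes.

Scenes emulate reconstructed super-resolution z-stacks: two channels, an
anisotropic Gaussian PSF (lateral sigma ~50 nm, axial ~130 nm), ~40 nm
lateral voxels with ~125 nm axial steps, constant background, and optional
additive Gaussian noise.  Particles are built from point emitters and
uniform line (segment) emitters; every derived geometric truth (separation,
amplitude ratio, bend angle, query offset) is recorded alongside the volume.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .io_volumes import SeedPair, Volume

__all__ = [
    "Emitter",
    "ParticleTruth",
    "SceneSpec",
    "make_scene",
    "render_scene",
    "generate_dataset",
    "PRESETS",
]

SEGMENT_SAMPLES = 64


@dataclass
class Emitter:
    """A point or uniform-line emitter; positions are physical (x, y, z) nm."""

    kind: str  # "point" | "segment"
    position: Optional[tuple[float, float, float]] = None  # point
    amplitude: float = 0.0  # point: peak amplitude
    endpoints: Optional[tuple[tuple[float, float, float], tuple[float, float, float]]] = None
    total_intensity: float = 0.0  # segment: integrated voxel-sum intensity

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.position is None or self.amplitude <= 0:
                raise ValueError("point emitter needs a position and positive amplitude")
        elif self.kind == "segment":
            if self.endpoints is None or self.total_intensity <= 0:
                raise ValueError("segment emitter needs endpoints and positive total intensity")
            a, b = (np.asarray(e, dtype=float) for e in self.endpoints)
            if np.allclose(a, b):
                raise ValueError("segment endpoints coincide")
        else:
            raise ValueError(f"unknown emitter kind {self.kind!r}")


@dataclass
class ParticleTruth:
    """Emitters per channel plus the particle frame and derived truths."""

    emitters: dict[int, list[Emitter]]
    mother_position: tuple[float, float, float]
    distal_position: Optional[tuple[float, float, float]]
    axis_u: Optional[tuple[float, float, float]]  # unit mother->distal
    tilt_deg: float
    separation_nm: Optional[float]
    amplitude_ratio: Optional[float]
    bend_angle_deg: Optional[float]
    query_offset_nm: Optional[tuple[float, float]]  # (along-axis, perpendicular) nm
    middle_position: Optional[tuple[float, float, float]] = None

    def validate(self) -> None:
        if self.distal_position is not None:
            sep = float(
                np.linalg.norm(np.asarray(self.distal_position) - np.asarray(self.mother_position))
            )
            if self.separation_nm is None or abs(sep - self.separation_nm) > 1e-9 * max(sep, 1.0):
                raise ValueError("stored separation inconsistent with emitter geometry")


@dataclass
class SceneSpec:
    """A fully resolved synthetic scene; rendering is deterministic."""

    volume_shape: tuple[int, int, int, int]  # (channels, nz, ny, nx)
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) nm
    psf_sigma: list[tuple[float, float]]  # per channel (sigma_xy, sigma_z) nm
    background: list[float]  # per channel
    noise_sd: float
    particles: list[ParticleTruth]
    rng_seed: int
    image_id: str = "scene"
    preset: str = "custom"
    fit_channel: int = 0
    reference_channel: Optional[int] = None
    query_channel: int = 0

    def __post_init__(self) -> None:
        nch = self.volume_shape[0]
        if len(self.psf_sigma) != nch or len(self.background) != nch:
            raise ValueError("psf_sigma and background must have one entry per channel")
        if any(s <= 0 for pair in self.psf_sigma for s in pair):
            raise ValueError("PSF widths must be positive")
        if min(self.volume_shape) < 1:
            raise ValueError("volume shape entries must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in self.particles:
            p.validate()


DEFAULTS: dict[str, Any] = {
    "volume_shape": (2, 16, 64, 64),
    "voxel_size": (125.0, 40.0, 40.0),
    "psf_sigma_xy": 50.0,
    "psf_sigma_z": 130.0,
    "background": 20.0,
    "noise_sd": 0.0,
    "separation_nm": 225.0,
    "amplitude": 100.0,
    "amplitude_ratio": 1.9,
    "bend_angle_deg": 17.0,
    "line_length_nm": 160.0,
    "line_intensity": 50000.0,
    "max_tilt_deg": 30.0,
    "query_offset_nm": (0.0, 0.0),
}

PRESETS = ("pair", "bent_triplet", "line_bridge", "single")


def _orientation(rng: np.random.Generator, max_tilt_deg: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Random particle axis u (unit) and its in-plane-of-(u,z) perpendicular v."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    tilt = rng.uniform(0.0, np.radians(max_tilt_deg))
    u = np.array([np.cos(tilt) * np.cos(phi), np.cos(tilt) * np.sin(phi), np.sin(tilt)])
    zhat = np.array([0.0, 0.0, 1.0])
    v = zhat - (zhat @ u) * u
    v = v / np.linalg.norm(v)
    return u, v, float(np.degrees(tilt))


def make_scene(
    preset: str,
    params: Optional[dict[str, Any]] = None,
    rng_seed: int = 0,
) -> SceneSpec:
    """Build a fully resolved :class:`SceneSpec` for one of the presets.

    Presets: ``pair`` (mother + satellite spots, fiducial at the mother in
    the second channel), ``bent_triplet`` (two reference spots plus a query
    emitter displaced off-axis to plant a bend), ``line_bridge`` (reference
    spots plus a uniform line source along the axis), ``single`` (one
    emitter).  The orientation is drawn uniformly in-plane with a z tilt
    uniform in [0, ``max_tilt_deg``].
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    p = dict(DEFAULTS)
    if params:
        unknown = set(params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown scene parameters: {sorted(unknown)}")
        p.update(params)
    rng = np.random.default_rng(rng_seed)
    nch, nz, ny, nx = p["volume_shape"]
    dz, dy, dxv = p["voxel_size"]
    center = np.array(
        [
            (nx - 1) / 2.0 * dxv,
            (ny - 1) / 2.0 * dy,
            (nz - 1) / 2.0 * dz,
        ]
    )
    center[:2] += rng.uniform(-0.5, 0.5, size=2) * dxv
    u, v, tilt_deg = _orientation(rng, p["max_tilt_deg"])
    sep = float(p["separation_nm"])
    amp = float(p["amplitude"])
    ratio = float(p["amplitude_ratio"])
    mother = center - (sep / 2.0) * u
    distal = center + (sep / 2.0) * u

    emitters: dict[int, list[Emitter]] = {c: [] for c in range(nch)}
    bend = None
    middle = None
    qoff = None
    fit_channel, ref_channel, query_channel = 0, (1 if nch > 1 else None), 0

    if preset == "pair":
        emitters[0] = [
            Emitter("point", position=tuple(mother), amplitude=amp),
            Emitter("point", position=tuple(distal), amplitude=amp / ratio),
        ]
        if nch > 1:
            emitters[1] = [Emitter("point", position=tuple(mother), amplitude=amp)]
    elif preset == "bent_triplet":
        if nch < 2:
            raise ValueError("bent_triplet needs two channels")
        bend = float(p["bend_angle_deg"])
        h = (sep / 2.0) * np.tan(np.radians(bend) / 2.0)
        qx, qy = (float(q) for q in p["query_offset_nm"])
        middle_pos = center + qx * u + (h + qy) * v
        middle = tuple(middle_pos)
        qoff = (qx, float(h + qy))
        emitters[1] = [
            Emitter("point", position=tuple(mother), amplitude=amp),
            Emitter("point", position=tuple(distal), amplitude=amp / ratio),
        ]
        emitters[0] = [Emitter("point", position=tuple(middle_pos), amplitude=amp)]
        fit_channel, ref_channel, query_channel = 1, None, 0
    elif preset == "line_bridge":
        if nch < 2:
            raise ValueError("line_bridge needs two channels")
        emitters[1] = [
            Emitter("point", position=tuple(mother), amplitude=amp),
            Emitter("point", position=tuple(distal), amplitude=amp / ratio),
        ]
        half_len = float(p["line_length_nm"]) / 2.0
        emitters[0] = [
            Emitter(
                "segment",
                endpoints=(tuple(center - half_len * u), tuple(center + half_len * u)),
                total_intensity=float(p["line_intensity"]),
            )
        ]
        fit_channel, ref_channel, query_channel = 1, None, 0
    elif preset == "single":
        emitters[0] = [Emitter("point", position=tuple(center), amplitude=amp)]
        if nch > 1:
            emitters[1] = [Emitter("point", position=tuple(center), amplitude=amp)]
        truth = ParticleTruth(
            emitters=emitters,
            mother_position=tuple(center),
            distal_position=None,
            axis_u=None,
            tilt_deg=tilt_deg,
            separation_nm=None,
            amplitude_ratio=None,
            bend_angle_deg=None,
            query_offset_nm=None,
        )
        return SceneSpec(
            volume_shape=tuple(p["volume_shape"]),
            voxel_size=tuple(p["voxel_size"]),
            psf_sigma=[(p["psf_sigma_xy"], p["psf_sigma_z"])] * nch,
            background=[float(p["background"])] * nch,
            noise_sd=float(p["noise_sd"]),
            particles=[truth],
            rng_seed=rng_seed,
            image_id=f"{preset}-{rng_seed}",
            preset=preset,
            fit_channel=0,
            reference_channel=ref_channel,
            query_channel=0,
        )

    truth = ParticleTruth(
        emitters=emitters,
        mother_position=tuple(mother),
        distal_position=tuple(distal),
        axis_u=tuple(u),
        tilt_deg=tilt_deg,
        separation_nm=sep,
        amplitude_ratio=ratio,
        bend_angle_deg=bend,
        query_offset_nm=qoff,
        middle_position=middle,
    )
    return SceneSpec(
        volume_shape=tuple(p["volume_shape"]),
        voxel_size=tuple(p["voxel_size"]),
        psf_sigma=[(p["psf_sigma_xy"], p["psf_sigma_z"])] * nch,
        background=[float(p["background"])] * nch,
        noise_sd=float(p["noise_sd"]),
        particles=[truth],
        rng_seed=rng_seed,
        image_id=f"{preset}-{rng_seed}",
        preset=preset,
        fit_channel=fit_channel,
        reference_channel=ref_channel,
        query_channel=query_channel,
    )


def _render_point(
    grid: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    position: np.ndarray,
    amplitude: float,
    sxy: float,
    sz: float,
) -> None:
    zc, yc, xc = coords
    cx, cy, cz = position
    grid += amplitude * (
        np.exp(-((zc - cz) ** 2) / (2.0 * sz**2))
        * np.exp(-((yc - cy) ** 2) / (2.0 * sxy**2))
        * np.exp(-((xc - cx) ** 2) / (2.0 * sxy**2))
    )


def render_scene(spec: SceneSpec) -> tuple[Volume, dict[str, Any]]:
    """Render a scene to a Volume plus a JSON-serializable truth record.

    Point emitters contribute ``A * exp(-dx^2/2s_xy^2 - dy^2/2s_xy^2 -
    dz^2/2s_z^2)`` evaluated at voxel centers; segments are integrated with
    64 midpoint samples so that the voxel-sum of a segment's contribution
    equals its total intensity (flux conservation).  Noise and background
    are added last; negative values are clipped at zero.
    """
    nch, nz, ny, nx = spec.volume_shape
    dz, dy, dxv = spec.voxel_size
    zc = (np.arange(nz) * dz)[:, None, None]
    yc = (np.arange(ny) * dy)[None, :, None]
    xc = (np.arange(nx) * dxv)[None, None, :]
    coords = (zc, yc, xc)
    data = np.zeros((nch, nz, ny, nx), dtype=float)
    extent = np.array([(nx - 1) * dxv, (ny - 1) * dy, (nz - 1) * dz])
    warnings_: list[str] = []
    for particle in spec.particles:
        for ch, emitters in particle.emitters.items():
            sxy, sz = spec.psf_sigma[ch]
            for em in emitters:
                if em.kind == "point":
                    pos = np.asarray(em.position, dtype=float)
                    if np.any(pos < 0) or np.any(pos > extent):
                        warnings_.append(f"emitter at {tuple(pos)} outside the volume")
                    _render_point(data[ch], coords, pos, em.amplitude, sxy, sz)
                else:
                    a, b = (np.asarray(e, dtype=float) for e in em.endpoints)
                    ts = (np.arange(SEGMENT_SAMPLES) + 0.5) / SEGMENT_SAMPLES
                    # unit-peak Gaussian voxel-sum; divides total intensity into per-sample peaks
                    voxel_sum = (2.0 * np.pi) ** 1.5 * sxy**2 * sz / (dxv * dy * dz)
                    peak = em.total_intensity / SEGMENT_SAMPLES / voxel_sum
                    for t in ts:
                        _render_point(data[ch], coords, a + t * (b - a), peak, sxy, sz)
    for ch in range(nch):
        data[ch] += spec.background[ch]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    volume = Volume(
        data=data,
        voxel_size=spec.voxel_size,
        channel_labels=[f"ch{i}" for i in range(nch)],
        image_id=spec.image_id,
    )
    truth = scene_truth(spec)
    if warnings_:
        truth["warnings"] = warnings_
    return volume, truth


def scene_truth(spec: SceneSpec) -> dict[str, Any]:
    """JSON-serializable ground-truth record for a scene."""
    record = asdict(spec)
    record["n_particles"] = len(spec.particles)
    return json.loads(json.dumps(record, default=lambda o: list(o) if isinstance(o, tuple) else o))


def generate_dataset(
    preset: str,
    n_particles: int,
    rng_seed: int = 0,
    params: Optional[dict[str, Any]] = None,
    seed_jitter_px: float = 1.0,
) -> list[tuple[Volume, SeedPair, dict[str, Any]]]:
    """Generate ``n_particles`` independent scenes with click-like seeds.

    Scene seeds derive deterministically from ``rng_seed``; seed pairs are
    the true lateral spot positions perturbed uniformly by up to
    ``seed_jitter_px`` pixels to emulate manual selection (mother first).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    master = np.random.SeedSequence(rng_seed)
    children = master.spawn(n_particles)
    out: list[tuple[Volume, SeedPair, dict[str, Any]]] = []
    for i, child in enumerate(children):
        scene_seed, jitter_seed = (int(s.generate_state(1)[0]) for s in child.spawn(2))
        spec = make_scene(preset, params=params, rng_seed=scene_seed)
        spec.image_id = f"{preset}-{i:03d}"
        volume, truth = render_scene(spec)
        particle = spec.particles[0]
        dxv = spec.voxel_size[2]
        dyv = spec.voxel_size[1]
        jrng = np.random.default_rng(jitter_seed)
        if particle.distal_position is None:
            # single-emitter scenes still get a (degenerate-free) seed pair for
            # classifier tests: distal seed offset by 2 px from the mother.
            mx, my, _ = particle.mother_position
            mother_px = (mx / dxv + jrng.uniform(-seed_jitter_px, seed_jitter_px),
                         my / dyv + jrng.uniform(-seed_jitter_px, seed_jitter_px))
            distal_px = (mother_px[0] + 2.0, mother_px[1])
        else:
            mx, my, _ = particle.mother_position
            sx, sy, _ = particle.distal_position
            jitter = jrng.uniform(-seed_jitter_px, seed_jitter_px, size=4)
            mother_px = (mx / dxv + jitter[0], my / dyv + jitter[1])
            distal_px = (sx / dxv + jitter[2], sy / dyv + jitter[3])
        seedpair = SeedPair(
            image_id=spec.image_id,
            fit_channel=spec.fit_channel,
            reference_channel=spec.reference_channel,
            mother_seed=mother_px,
            distal_seed=distal_px,
        )
        out.append((volume, seedpair, truth))
    return out


def write_truth(truths: list[dict[str, Any]], path: str | Path) -> None:
    """Write ground-truth records as a JSON sidecar."""
    Path(path).write_text(json.dumps(truths, indent=2))
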