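"""End-to-end orchestration: detect -> fit -> align -> average -> profile -> report.

A run is described by a :class:`RunConfig` (built in code or loaded from
YAML).  Inputs are either simulated from a preset or loaded from TIFF
volumes plus a seed CSV.  All randomness flows from one master seed via
named substreams, so a run is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .alignment import (
    PoleAxisAmbiguousError,
    accumulate_map,
    assign_mother,
    extract_aligned_plane,
    orient_plane,
)
from .detection import DetectionParams, extract_z_profile, passes_z_filter
from .fit3d import fit_dual_spot, fit_single_spot, intensity_ratio, monte_carlo_errors
from .io_volumes import SeedPair, Volume, read_seeds, read_volume
from .mapstats import axis_profile, bend_angle, fit_profile
from .synthetic import generate_dataset

logger = logging.getLogger("spavg")

__all__ = ["RunConfig", "RunReport", "run_spa", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    # input: either a simulation preset, or volume paths + a seed CSV
    simulate_preset: Optional[str] = None
    n_particles: int = 0
    simulate_params: dict[str, Any] = field(default_factory=dict)
    volume_paths: list[str] = field(default_factory=list)
    seeds_path: Optional[str] = None
    voxel_size_override: Optional[tuple[float, float, float]] = None
    # channel roles
    fit_channel: int = 0
    reference_channel: Optional[int] = None
    query_channel: int = 0
    # stage parameters
    detection: DetectionParams = field(default_factory=DetectionParams)
    upsample: int = 4
    grid_size: int = 641
    profile_components: int = 2
    profile_trim_px: int = 0
    profile_window_nm: Optional[float] = 600.0
    profile_perp_window_nm: Optional[float] = 300.0
    broad_bg: bool = False
    n_mc: int = 100
    rng_seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.simulate_preset is None and not self.volume_paths:
            raise ValueError("config must name either a simulation preset or input volumes")
        if self.simulate_preset is not None and self.n_particles < 1:
            raise ValueError("simulation requires n_particles >= 1")
        if self.volume_paths and self.seeds_path is None:
            raise ValueError("volume inputs require a seed table")


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "detection" in raw and isinstance(raw["detection"], dict):
        raw["detection"] = DetectionParams(**raw["detection"])
    if "voxel_size_override" in raw and raw["voxel_size_override"] is not None:
        raw["voxel_size_override"] = tuple(raw["voxel_size_override"])
    return RunConfig(**raw)


@dataclass
class ParticleRecord:
    image_id: str
    status: str  # used | rejected-z-edge | rejected-tilt | non-converged | degenerate
    separation_nm: Optional[float] = None
    intensity_ratio: Optional[float] = None
    mother_rule: Optional[str] = None


@dataclass
class RunReport:
    """Summary of one run; every number traces to a stage output."""

    n_detected: int
    n_used: int
    n_rejected_z_edge: int
    n_rejected_tilt: int
    n_non_converged: int
    particles: list[ParticleRecord]
    separation_nm: Optional[float]  # from the map profile fit (fit channel, x axis)
    separation_sd_nm: Optional[float]
    intensity_ratio: Optional[float]  # from the map profile fit amplitudes
    mean_pairwise_ratio: Optional[float]  # mean of per-particle amplitude ratios
    query_x_nm: Optional[float]
    query_y_nm: Optional[float]
    query_fwhm_x_nm: Optional[float]
    query_fwhm_y_nm: Optional[float]
    bend_angle_deg: Optional[float]
    profile_tables: dict[str, Any]
    version: str
    config_hash: str

    def counts_consistent(self) -> bool:
        return self.n_detected == (
            self.n_used + self.n_rejected_z_edge + self.n_rejected_tilt + self.n_non_converged
        )


def _load_inputs(config: RunConfig) -> list[tuple[Volume, SeedPair]]:
    if config.simulate_preset is not None:
        data = generate_dataset(
            config.simulate_preset,
            config.n_particles,
            rng_seed=config.rng_seed,
            params=config.simulate_params or None,
        )
        return [(volume, seeds) for volume, seeds, _ in data]
    volumes = {}
    for path in config.volume_paths:
        if not Path(path).exists():
            raise FileNotFoundError(f"input volume not found: {path}")
    seeds = read_seeds(config.seeds_path)
    for path in config.volume_paths:
        vol = read_volume(path, voxel_size_override=config.voxel_size_override)
        volumes[vol.image_id] = vol
    pairs = []
    for sp in seeds:
        if sp.image_id not in volumes:
            raise ValueError(f"seed row references unknown image {sp.image_id!r}")
        pairs.append((volumes[sp.image_id], sp))
    return pairs


def run_spa(config: RunConfig) -> RunReport:
    """Execute the full averaging pipeline and return a report.

    Stages: per-particle z-edge QC, dual 3D Gaussian fit (plus reference
    single-spot fit when a reference channel exists), mother assignment,
    plane extraction and orientation, probability-map accumulation, and
    multi-Gaussian profile fits of the map axes.  Fails fast on stage errors;
    per-particle rejections are recorded, not fatal.
    """
    config.validate()
    inputs = _load_inputs(config)
    # channel roles: simulation presets carry their own roles in the seeds
    records: list[ParticleRecord] = []
    planes = []
    pair_ratios = []
    mc_rng = np.random.SeedSequence(config.rng_seed).spawn(1)[0]
    profile_seed = int(mc_rng.generate_state(1)[0])
    query_channel = config.query_channel
    fit_channel = config.fit_channel
    for volume, seedpair in inputs:
        image_id = seedpair.image_id
        fit_channel = seedpair.fit_channel
        # z-edge QC at both seeds
        z_ok = True
        for seed in (seedpair.mother_seed, seedpair.distal_seed):
            prof = extract_z_profile(volume, seedpair.fit_channel, seed, box=config.detection.box)
            if prof.size >= 3 and not passes_z_filter(prof):
                z_ok = False
        if not z_ok:
            records.append(ParticleRecord(image_id, "rejected-z-edge"))
            logger.info("%s: rejected (z edge)", image_id)
            continue
        fit = fit_dual_spot(volume, seedpair)
        if not fit.converged or fit.degenerate:
            records.append(ParticleRecord(image_id, "non-converged"))
            logger.info("%s: rejected (fit non-converged or degenerate)", image_id)
            continue
        reference_center = None
        if seedpair.reference_channel is not None:
            ref_fit = fit_single_spot(volume, seedpair.reference_channel, seedpair.mother_seed)
            if ref_fit.converged:
                reference_center = np.asarray(ref_fit.spot.center)
        particle = assign_mother(fit, reference_center)
        try:
            plane = extract_aligned_plane(
                volume, particle, upsample=config.upsample, grid_size=config.grid_size
            )
        except PoleAxisAmbiguousError:
            records.append(ParticleRecord(image_id, "rejected-tilt"))
            logger.info("%s: rejected (axis too vertical)", image_id)
            continue
        ref_for_orient = (
            seedpair.reference_channel
            if seedpair.reference_channel is not None
            else seedpair.fit_channel
        )
        plane = orient_plane(plane, query_channel, reference_channel=ref_for_orient)
        planes.append(plane)
        ratio = intensity_ratio(fit)
        pair_ratios.append(ratio)
        records.append(
            ParticleRecord(
                image_id,
                "used",
                separation_nm=particle.separation_nm,
                intensity_ratio=ratio,
                mother_rule=particle.mother_rule,
            )
        )

    n_detected = len(inputs)
    n_used = sum(1 for r in records if r.status == "used")
    counts = dict(
        n_detected=n_detected,
        n_used=n_used,
        n_rejected_z_edge=sum(1 for r in records if r.status == "rejected-z-edge"),
        n_rejected_tilt=sum(1 for r in records if r.status == "rejected-tilt"),
        n_non_converged=sum(1 for r in records if r.status in ("non-converged", "degenerate")),
    )

    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    if not planes:
        return RunReport(
            **counts,
            particles=records,
            separation_nm=None,
            separation_sd_nm=None,
            intensity_ratio=None,
            mean_pairwise_ratio=None,
            query_x_nm=None,
            query_y_nm=None,
            query_fwhm_x_nm=None,
            query_fwhm_y_nm=None,
            bend_angle_deg=None,
            profile_tables={},
            version=__version__,
            config_hash=config_hash,
        )

    pmap = accumulate_map(planes)
    tables: dict[str, Any] = {}

    # fit-channel x profile: two peaks -> separation + map intensity ratio
    fit_x = fit_profile(
        axis_profile(pmap, fit_channel, "x", perp_window_nm=config.profile_perp_window_nm),
        n_components=2,
        mc_seed=profile_seed,
        n_mc=config.n_mc,
        window_nm=config.profile_window_nm,
    )
    tables["fit_channel_x"] = _table(fit_x)
    separation = sep_sd = map_ratio = None
    if fit_x.converged and not fit_x.collapsed and len(fit_x.components) == 2:
        c0, c1 = fit_x.components  # sorted by center; mother is on the negative side
        separation = c1.center - c0.center
        sep_sd = float(
            np.hypot(fit_x.errors.get("center_0", 0.0), fit_x.errors.get("center_1", 0.0))
        )
        if c1.amplitude > 0:
            map_ratio = c0.amplitude / c1.amplitude

    # query-channel profiles: position and widths of the query distribution
    qx = fit_profile(
        axis_profile(pmap, query_channel, "x", perp_window_nm=config.profile_perp_window_nm),
        n_components=config.profile_components if query_channel == fit_channel else 1,
        trim_px=config.profile_trim_px,
        broad_bg=config.broad_bg,
        mc_seed=profile_seed + 1,
        n_mc=config.n_mc,
        window_nm=config.profile_window_nm,
    )
    qy = fit_profile(
        axis_profile(pmap, query_channel, "y", perp_window_nm=config.profile_perp_window_nm),
        n_components=1,
        mc_seed=profile_seed + 2,
        n_mc=config.n_mc,
        window_nm=config.profile_window_nm,
    )
    tables["query_x"] = _table(qx)
    tables["query_y"] = _table(qy)
    query_x = qx.components[0].center if qx.converged else None
    query_y = qy.components[0].center if qy.converged else None
    query_fwhm_x = qx.components[0].fwhm if qx.converged else None
    query_fwhm_y = qy.components[0].fwhm if qy.converged else None

    bend = None
    if (
        separation is not None
        and query_channel != fit_channel
        and query_x is not None
        and query_y is not None
    ):
        bend = bend_angle(
            (-separation / 2.0, 0.0), (query_x, query_y), (separation / 2.0, 0.0)
        )

    report = RunReport(
        **counts,
        particles=records,
        separation_nm=separation,
        separation_sd_nm=sep_sd,
        intensity_ratio=map_ratio,
        mean_pairwise_ratio=float(np.mean(pair_ratios)) if pair_ratios else None,
        query_x_nm=query_x,
        query_y_nm=query_y,
        query_fwhm_x_nm=query_fwhm_x,
        query_fwhm_y_nm=query_fwhm_y,
        bend_angle_deg=bend,
        profile_tables=tables,
        version=__version__,
        config_hash=config_hash,
    )
    if config.out_dir:
        _write_outputs(config, report, pmap)
    return report


def _table(pf) -> dict[str, Any]:
    return {
        "axis": pf.axis,
        "offset": pf.offset,
        "components": [
            {"center": c.center, "fwhm": c.fwhm, "amplitude": c.amplitude} for c in pf.components
        ],
        "broad_bg": None
        if pf.broad_bg_component is None
        else {"fwhm": pf.broad_bg_component.fwhm, "amplitude": pf.broad_bg_component.amplitude},
        "errors": pf.errors,
        "converged": pf.converged,
    }


def _write_outputs(config: RunConfig, report: RunReport, pmap) -> None:
    import tifffile

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    body = asdict(report)
    (out / "report.json").write_text(json.dumps(body, indent=2, default=str))
    tifffile.imwrite(out / "map.tiff", pmap.grid.astype(np.float32))
    (out / "map.json").write_text(
        json.dumps(
            {
                "n_particles": pmap.n_particles,
                "pixel_size_nm": pmap.pixel_size,
                "origin": list(pmap.origin),
                "particle_ids": pmap.particle_ids,
            },
            indent=2,
        )
    )
    provenance = asdict(config)
    provenance["version"] = __version__
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True, default_flow_style=False))
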