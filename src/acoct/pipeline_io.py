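"""End-to-end orchestration of the four-stage process (preparation ->
focus -> digital focusing -> registration/fusion), plus container I/O and
configuration handling."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
from pydantic import BaseModel, Field

from .beam_optics import MM, BeamGeometry
from .digital_focusing import MatchedFilterBank, apply_digital_focusing, refine_filter_depth
from .metrics import HFMaskSpec, r_hf, relative_std, segment_beads
from .phantom_simulator import (ComplexBScanStack, make_bead_phantom,
                                make_speckle_phantom, simulate_angular_set)
from .registration import (AngularImageSet, TargetGrid, build_models,
                           correct_bulk_motion, detect_surface, estimate_focus,
                           fuse, register_image)

__all__ = [
    "GeometryConfig",
    "SimulationConfig",
    "PipelineConfig",
    "load_config",
    "write_stack",
    "read_stack",
    "export_tiff",
    "run_preparation",
    "run_pipeline",
]

log = logging.getLogger("acoct")

DEFAULT_OFFSETS_MM = [-2.5, -2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 2.5]


class GeometryConfig(BaseModel):
    """Optical constants in instrument-native units."""

    wavelength_nm: float = 920.0
    bandwidth_nm: float = 200.0
    beam_diameter_mm: float = 5.4
    focal_length_mm: float = 36.0
    galvo_lens_distance_mm: float = 59.0
    refractive_index: float = 1.34
    axial_resolution_um: float = 2.0
    scan_step_um: float = 0.976

    def to_beam_geometry(self) -> BeamGeometry:
        return BeamGeometry(
            wavelength=self.wavelength_nm / 1000.0,
            beam_diameter=self.beam_diameter_mm * MM,
            focal_length=self.focal_length_mm * MM,
            galvo_lens_distance=self.galvo_lens_distance_mm * MM,
            refractive_index=self.refractive_index,
            axial_resolution=self.axial_resolution_um,
            scan_step=self.scan_step_um,
        )


class SimulationConfig(BaseModel):
    phantom: str = "bead"            # "bead" | "speckle"
    bead_density_per_ml: float = 2.0e9
    scatterers_per_voxel: float = 3.0
    n_u: int = 256
    n_v: int = 256
    focus_depth_um: float = 120.0
    surface_row: float = 30.0
    noise_level: float = 0.02
    repeats: int = 5
    pixel_pitch_v_um: float = 1.0


class PipelineConfig(BaseModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    offsets_mm: list[float] = Field(default_factory=lambda: list(DEFAULT_OFFSETS_MM))
    seed: int = 0
    variant: str = "mf"              # "mf" | "mfu"
    apply_digital_focusing: bool = True
    focus_search_range: int = 6
    hf_width_fraction: float = 0.02
    hf_height_fraction: float = 0.05
    out_dir: str | None = None

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_stack(path, stack: ComplexBScanStack) -> None:
    """Lossless HDF5 round trip of a complex stack plus metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=stack.data.real, compression="gzip")
        f.create_dataset("imag", data=stack.data.imag, compression="gzip")
        f.attrs["pixel_pitch_u"] = stack.pixel_pitch_u
        f.attrs["pixel_pitch_v"] = stack.pixel_pitch_v
        f.attrs["offset_d"] = stack.offset_d
        if stack.seed is not None:
            f.attrs["seed"] = stack.seed
        if stack.focus_pixel is not None:
            f.attrs["focus_pixel"] = list(stack.focus_pixel)
        f.attrs["geometry"] = json.dumps({
            k: v for k, v in stack.geometry.__dict__.items()})
        f.attrs["extra"] = json.dumps(stack.attrs)


def read_stack(path) -> ComplexBScanStack:
    try:
        with h5py.File(path, "r") as f:
            data = f["real"][...] + 1j * f["imag"][...]
            geo = BeamGeometry(**json.loads(f.attrs["geometry"]))
            fp = f.attrs.get("focus_pixel")
            return ComplexBScanStack(
                data=data,
                pixel_pitch_u=float(f.attrs["pixel_pitch_u"]),
                pixel_pitch_v=float(f.attrs["pixel_pitch_v"]),
                offset_d=float(f.attrs["offset_d"]),
                geometry=geo,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                focus_pixel=tuple(fp) if fp is not None else None,
                attrs=json.loads(f.attrs.get("extra", "{}")),
            )
    except (OSError, KeyError) as exc:
        raise IOError(f"not a valid complex-stack container: {path}: {exc}") from exc


def export_tiff(path, images) -> None:
    """Magnitude preview as a (multi-page) 32-bit TIFF."""
    import tifffile

    arr = np.asarray(images, dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def run_preparation(stacks, geometry: BeamGeometry | None = None) -> AngularImageSet:
    """Per-offset magnitude averages over repeats (the angular images)."""
    if not stacks:
        raise ValueError("no stacks supplied")
    images = [s.magnitude_mean() for s in stacks]
    return AngularImageSet(
        images=images,
        offsets_d=np.asarray([s.offset_d for s in stacks], dtype=float),
        geometry=geometry or stacks[0].geometry,
        pixel_pitch_v=stacks[0].pixel_pitch_v,
    )


def _make_phantom(cfg: PipelineConfig, extent):
    sim = cfg.simulation
    if sim.phantom == "bead":
        ph = make_bead_phantom(sim.bead_density_per_ml, extent,
                               seed=cfg.seed,
                               refractive_index=cfg.geometry.refractive_index)
    elif sim.phantom == "speckle":
        ph = make_speckle_phantom(sim.scatterers_per_voxel, extent,
                                  seed=cfg.seed,
                                  refractive_index=cfg.geometry.refractive_index)
    else:
        raise ValueError(f"unknown phantom type {sim.phantom!r}")
    return ph.with_surface_line(amplitude=1.5)


def run_pipeline(config: PipelineConfig, stacks=None):
    """Execute the full flow; returns ``(composite, report)``.

    When ``stacks`` is None the configured synthetic acquisition is
    simulated first.  The report carries seeds, the config hash, the focus
    pixel, bulk-motion shifts, and before/after quality metrics.
    """
    t0 = time.time()
    geometry = config.geometry.to_beam_geometry()
    sim = config.simulation
    offsets_um = [d * MM for d in config.offsets_mm]
    if stacks is None:
        span = geometry.scan_step * sim.n_u
        extent = ((-0.75 * span, 0.75 * span),
                  (0.0, sim.n_v * sim.pixel_pitch_v_um / geometry.refractive_index))
        phantom = _make_phantom(config, extent)
        stacks = simulate_angular_set(
            phantom, geometry, offsets_um, seed=config.seed, n_u=sim.n_u,
            n_v=sim.n_v, focus_depth=sim.focus_depth_um,
            pixel_pitch_v=sim.pixel_pitch_v_um, surface_row=sim.surface_row,
            noise_level=sim.noise_level, repeats=sim.repeats)
    else:
        missing = [i for i, s in enumerate(stacks) if s is None]
        if missing:
            raise ValueError(f"missing stacks for offsets at positions {missing}")
    log.info("preparation: %d offsets, %d repeats", len(stacks), stacks[0].n_repeats)
    aset = run_preparation(stacks, geometry)

    aligned, shifts = correct_bulk_motion(aset.images)
    for s, sh in zip(stacks, shifts):
        if sh:
            s.data = np.roll(s.data, -sh, axis=1)
    aset = AngularImageSet(images=aligned, offsets_d=aset.offsets_d,
                           geometry=geometry, pixel_pitch_v=aset.pixel_pitch_v)

    hf = HFMaskSpec(width_fraction=config.hf_width_fraction,
                    height_fraction=config.hf_height_fraction)
    focus_pixel, surface_row = estimate_focus(aset, r_hf_spec=hf)
    log.info("focus pixel %s, surface row %.1f", focus_pixel, surface_row)

    images = aset.images
    df_offset = 0
    if config.apply_digital_focusing:
        bank = MatchedFilterBank.build(
            stacks[0].data.shape[1], geometry, focus_pixel[1],
            geometry.scan_step, aset.pixel_pitch_v, variant=config.variant)
        centre = int(np.argmin(np.abs(aset.offsets_d)))
        df_offset = refine_filter_depth(stacks[centre].data, bank,
                                        search_range=config.focus_search_range)
        bank = bank.shifted(df_offset)
        images = [np.abs(apply_digital_focusing(s.data, bank)).mean(axis=0)
                  for s in stacks]

    models = build_models(geometry, aset.offsets_d, focus_pixel, surface_row,
                          pixel_pitch_v=aset.pixel_pitch_v)
    n_v, n_u = images[0].shape
    ri = geometry.refractive_index
    grid = TargetGrid.from_extent(
        (-geometry.scan_step * n_u / 2, geometry.scan_step * n_u / 2),
        (2 * aset.pixel_pitch_v, aset.pixel_pitch_v * (n_v - surface_row) / ri),
        geometry.scan_step, aset.pixel_pitch_v / ri)
    registered = [register_image(img, m, grid) for img, m in zip(images, models)]
    composite = fuse(registered)
    composite.grid = grid

    mag = composite.magnitude
    valid = composite.valid_mask
    filled = mag.copy()
    filled[~valid] = mag[valid].mean() if valid.any() else 0.0
    signal, background = segment_beads(filled)
    background &= valid
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "focus_pixel": list(focus_pixel),
        "surface_row": float(surface_row),
        "bulk_shifts_px": shifts,
        "df_depth_offset_px": int(df_offset),
        "r_hf_composite": r_hf(filled, hf),
        "r_hf_single_angle": r_hf(aset.images[len(images) // 2], hf),
        "background_relative_std": relative_std(filled, background),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        export_tiff(out / "composite.tif", mag)
        export_tiff(out / "valid_mask.tif", valid.astype(np.float32))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return composite, report
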