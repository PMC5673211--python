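"""End-to-end workflows: phantom generation, projection, reconstruction.

A single master seed spawns independent substreams per stage (boundary,
ducts, ligaments, texture), so changing e.g. duct parameters does not
perturb the boundary draws of the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .ductal_network import DuctParams, draw_tree_count, grow_network
from .fixtures import FixtureSpec, make_cylinder_fixture
from .glands_ligaments import (assemble_phantom, gen_filtered_noise,
                               glandular_fraction, threshold_glandular,
                               tile_ligaments)
from .phantom_boundary import AnatomyParams, generate_support
from .physics_data import make_spectrum
from .projector import (ScanGeometry, mono_project, poly_project,
                        relative_error_map, thickness_project)
from .recon_fbp import Sinogram, fbp_fan
from .volume import LabelVolume

logger = logging.getLogger(__name__)

__all__ = ["generate_phantom", "simulate_sinograms", "run_pipeline"]

DESK_PRESET = {
    "shape": (128, 128, 128), "voxel_mm": 0.8,
    "detector": {"n_rows": 256, "n_cols": 256, "pixel_mm": 1.2},
    "n_angles": 64,
}
FULL_SCALE_PRESET = {
    "shape": (512, 512, 512), "voxel_mm": 0.4,
    "detector": {"n_rows": 1024, "n_cols": 1024, "pixel_mm": 0.3},
    "n_angles": 360,
}


def generate_phantom(seed: int | np.random.SeedSequence,
                     anatomy: AnatomyParams | None = None,
                     ducts: DuctParams | None = None,
                     shape: tuple[int, int, int] = (128, 128, 128),
                     voxel_mm: float = 0.8,
                     n_ellipsoids: int = 5,
                     noise_alpha: float = 1.0,
                     noise_beta: float = 2.0,
                     gland_threshold: float | None = None,
                     coverage: float = 0.99,
                     ) -> tuple[LabelVolume, dict]:
    """Generate one randomized labelled breast phantom.

    Returns the phantom and a metadata dict (lobe/unit counts, glandular
    fraction, per-stage timings).
    """
    anatomy = anatomy or AnatomyParams()
    ducts = ducts or DuctParams()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng_boundary, rng_ducts, rng_lig, rng_noise = \
        (np.random.default_rng(s) for s in ss.spawn(4))
    info: dict = {"seed": getattr(ss, "entropy", None)}
    t0 = time.perf_counter()

    support = generate_support(anatomy, rng_boundary, voxel_mm, shape)
    info["t_boundary_s"] = round(time.perf_counter() - t0, 3)

    n_lobes = draw_tree_count(anatomy, rng_ducts)
    trees = grow_network(n_lobes, ducts, support, rng_ducts)
    info["n_lobes"] = n_lobes
    info["n_terminal_ducts"] = sum(len(t.terminal_cylinders()) for t in trees)
    t1 = time.perf_counter()
    info["t_ducts_s"] = round(t1 - t0 - info["t_boundary_s"], 3)

    tiled = support.copy()
    units = tile_ligaments(tiled, rng_lig, n_ellipsoids=n_ellipsoids,
                           coverage=coverage)
    info["n_ligament_units"] = len(units)
    t2 = time.perf_counter()
    info["t_ligaments_s"] = round(t2 - t1, 3)

    noise = gen_filtered_noise(shape, voxel_mm, noise_alpha, noise_beta,
                               rng_noise)
    binary = threshold_glandular(noise, gland_threshold)
    phantom = assemble_phantom(tiled, trees, units, binary)
    info["n_units_duct_passed"] = sum(u.duct_passed for u in units)
    info["glandular_fraction"] = round(glandular_fraction(phantom), 5)
    info["t_texture_s"] = round(time.perf_counter() - t2, 3)
    info["t_total_s"] = round(time.perf_counter() - t0, 3)
    logger.info("phantom done: %s", info)
    return phantom, info


def simulate_sinograms(volume: LabelVolume, geom: ScanGeometry,
                       kvp: float = 60.0, mono_kev: float = 35.0,
                       ) -> tuple[Sinogram, Sinogram]:
    """Central-row fan sinograms, polychromatic and monochromatic.

    Both are derived from the same per-angle thickness projections (one
    Siddon pass per angle) and are log-transformed.
    """
    spectrum = make_spectrum(kvp)
    poly_rows, mono_rows = [], []
    for angle in geom.angles_deg:
        t = thickness_project(volume, geom, angle, central_row_only=True)
        poly_rows.append(poly_project(t, spectrum).log_attenuation()[0])
        mono_rows.append(mono_project(t, mono_kev).log_attenuation()[0])
    return (Sinogram(np.array(poly_rows), geom),
            Sinogram(np.array(mono_rows), geom))


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _geometry_from(config: dict) -> ScanGeometry:
    scan = config.get("scan", {})
    n_angles = int(scan.get("n_angles", 64))
    return ScanGeometry(
        sdd_mm=float(scan.get("sdd_mm", 700.0)),
        sad_mm=float(scan.get("sad_mm", 500.0)),
        n_rows=int(scan.get("n_rows", 256)),
        n_cols=int(scan.get("n_cols", 256)),
        pixel_mm=float(scan.get("pixel_mm", 1.2)),
        angles_deg=np.arange(n_angles) * (360.0 / n_angles))


def run_pipeline(config: dict, outdir: str | Path,
                 dry_run: bool = False) -> dict:
    """Run phantom -> projections -> error map -> sinogram -> FBP.

    ``config`` keys: ``seed`` (required), ``phantom`` (breast parameters
    or ``{"kind": "cylinder"}``), ``scan`` (geometry, ``kvp``,
    ``mono_kev``), ``recon`` (``grid_n``, ``window``).  Writes all
    artifacts plus ``manifest.json`` into ``outdir`` and returns the
    manifest.  ``dry_run`` validates the configuration only.
    """
    import tifffile

    if "seed" not in config:
        raise ValueError("config must define a master seed")
    seed = int(config["seed"])
    geom = _geometry_from(config)
    scan = config.get("scan", {})
    kvp = float(scan.get("kvp", 60.0))
    mono_kev = float(scan.get("mono_kev", 35.0))
    recon_cfg = config.get("recon", {})
    phantom_cfg = dict(config.get("phantom", {}))
    kind = phantom_cfg.pop("kind", "breast")
    if kind not in ("breast", "cylinder"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    make_spectrum(kvp)  # validates the tube potential
    manifest = {"version": __version__, "seed": seed,
                "config_sha256": _config_hash(config), "stages": {}}
    if dry_run:
        manifest["dry_run"] = True
        return manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed") from err
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %.2fs", name, manifest["stages"][name])
            return result
        return wrap

    if kind == "cylinder":
        volume = stage("phantom")(
            lambda: make_cylinder_fixture(FixtureSpec(**phantom_cfg)))
    else:
        def gen():
            vol, info = generate_phantom(seed, **_phantom_kwargs(phantom_cfg))
            manifest["phantom_info"] = info
            return vol
        volume = stage("phantom")(gen)
    volume.save(outdir / "phantom.mhd")

    def project():
        t = thickness_project(volume, geom, float(geom.angles_deg[0]))
        spectrum = make_spectrum(kvp)
        return poly_project(t, spectrum), mono_project(t, mono_kev)
    poly_img, mono_img = stage("projection")(project)
    tifffile.imwrite(outdir / "projection_poly.tif",
                     poly_img.data.astype(np.float32))
    tifffile.imwrite(outdir / "projection_mono.tif",
                     mono_img.data.astype(np.float32))

    err = stage("error_map")(
        lambda: relative_error_map(poly_img, mono_img, domain="log"))
    tifffile.imwrite(outdir / "error_map_pct.tif", err.astype(np.float32))
    manifest["max_error_pct"] = float(np.nanmax(err))

    sino_poly, sino_mono = stage("sinogram")(
        lambda: simulate_sinograms(volume, geom, kvp, mono_kev))
    tifffile.imwrite(outdir / "sinogram_poly.tif",
                     sino_poly.data.astype(np.float32))
    tifffile.imwrite(outdir / "sinogram_mono.tif",
                     sino_mono.data.astype(np.float32))

    def recon():
        kwargs = {"grid_n": int(recon_cfg.get("grid_n", 256)),
                  "window": recon_cfg.get("window", "hanning")}
        if recon_cfg.get("fov_mm"):
            kwargs["fov_mm"] = float(recon_cfg["fov_mm"])
        return fbp_fan(sino_poly, **kwargs), fbp_fan(sino_mono, **kwargs)
    rec_poly, rec_mono = stage("reconstruction")(recon)
    tifffile.imwrite(outdir / "recon_poly.tif", rec_poly.astype(np.float32))
    tifffile.imwrite(outdir / "recon_mono.tif", rec_mono.astype(np.float32))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _phantom_kwargs(cfg: dict) -> dict:
    cfg = dict(cfg)
    kwargs = {}
    if "shape" in cfg:
        kwargs["shape"] = tuple(cfg.pop("shape"))
    for key in ("voxel_mm", "n_ellipsoids", "noise_alpha", "noise_beta",
                "gland_threshold", "coverage"):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    anatomy_fields = set(AnatomyParams.__dataclass_fields__)
    duct_fields = set(DuctParams.__dataclass_fields__)
    anat = {k: cfg.pop(k) for k in list(cfg) if k in anatomy_fields}
    duct = {k: cfg.pop(k) for k in list(cfg) if k in duct_fields}
    if cfg:
        raise ValueError(f"unknown phantom config keys: {sorted(cfg)}")
    if anat:
        kwargs["anatomy"] = AnatomyParams(**anat)
    if duct:
        kwargs["ducts"] = DuctParams(**duct)
    return kwargs
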