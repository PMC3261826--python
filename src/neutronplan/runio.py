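"""Run configuration, result files and the end-to-end simulation driver.

Formats:

* run configuration: YAML/JSON (validated by :class:`RunConfig`);
* dose grids: HDF5 with shape/voxel/units/provenance attributes;
* chamber and depth-dose tables: CSV;
* run manifest: JSON with the config hash, seed, package version, wall time
  and the list of outputs, so every result is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__ as _version
from .geometry import (RoomShell, build_head_geometry, build_solid_water_geometry,
                       build_voxel_water_geometry, crop_upper, load_voxel_phantom)
from .spectra import (NEUTRON_FLUENCE_RATE, PHOTON_FLUENCE_RATE, BeamConfig,
                      load_spectrum, synthetic_medapp_spectrum)
from .tallies import finalize_dose, to_absolute, to_dose_rate
from .transport import TAG_NAMES, TransportConfig, run

__all__ = ["RunConfig", "simulate", "save_dose_grid", "load_dose_grid",
           "config_hash", "write_manifest"]


class RunConfig(BaseModel):
    """Declarative description of one simulation run."""

    geometry: Literal["water-solid", "water-voxel", "head"] = "water-solid"
    room: bool = False
    beam_width: float = 9.0
    beam_height: float = 9.0
    beam_center_y: float = 0.0
    beam_center_z: float = 0.0
    n_histories: int = 100_000
    seed: int = 1
    irradiation_s: float = 180.0
    neutron_rate: float = NEUTRON_FLUENCE_RATE
    photon_rate: float = PHOTON_FLUENCE_RATE
    # spectrum source: "synthetic", "none", or a path to a spectrum file
    neutron_spectrum: str = "synthetic"
    photon_spectrum: str = "none"
    phantom_path: str | None = None        # head geometry: phantom grid file
    organ_map_path: str | None = None
    crop_slices: int | None = None
    woodcock: bool = False
    fluence: bool = False
    outdir: str = "results"

    @field_validator("n_histories")
    @classmethod
    def _n_pos(cls, v):
        if v < 2:
            raise ValueError("n_histories must be >= 2")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _spectrum(kind: str, source: str, rate: float):
    if source == "none":
        return None
    if source == "synthetic":
        return synthetic_medapp_spectrum(kind, rate)
    spec = load_spectrum(source)
    if spec.particle != kind:
        raise ValueError(f"{source} holds a {spec.particle} spectrum, not {kind}")
    return spec.rescaled(rate)


def save_dose_grid(path: str | Path, dose: np.ndarray, se: np.ndarray,
                   meta: dict) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dose", data=dose, compression="gzip")
        f.create_dataset("se", data=se, compression="gzip")
        for k, v in meta.items():
            f.attrs[k] = v


def load_dose_grid(path: str | Path):
    with h5py.File(path, "r") as f:
        dose = f["dose"][...]
        se = f["se"][...]
        meta = dict(f.attrs)
    return dose, se, meta


def write_manifest(path: str | Path, cfg: RunConfig, outputs: list[str],
                   wall_s: float) -> None:
    manifest = {
        "package": "neutronplan",
        "version": _version,
        "config": cfg.model_dump(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "wall_time_s": round(wall_s, 2),
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def _log(msg: str) -> None:
    print(f"[neutronplan] {msg}", file=sys.stderr)


def simulate(cfg: RunConfig) -> dict:
    """Run the configured simulation and write all outputs.

    Returns a dict with the output paths and in-memory results.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    room = RoomShell() if cfg.room else None

    phantom = None
    if cfg.geometry == "water-solid":
        geo = build_solid_water_geometry(room=room)
    elif cfg.geometry == "water-voxel":
        geo = build_voxel_water_geometry(room=room)
    else:
        if cfg.phantom_path is None:
            raise ValueError("head geometry needs phantom_path")
        phantom = load_voxel_phantom(cfg.phantom_path, cfg.organ_map_path)
        if cfg.crop_slices:
            phantom = crop_upper(phantom, cfg.crop_slices)
        geo = build_head_geometry(phantom)
    _log(f"geometry: {geo.description}, {geo.n_regions} scoring regions")

    runs = []
    if cfg.neutron_spectrum != "none":
        runs.append(("neutron", _spectrum("neutron", cfg.neutron_spectrum,
                                          cfg.neutron_rate), cfg.neutron_rate))
    if cfg.photon_spectrum != "none":
        runs.append(("photon", _spectrum("photon", cfg.photon_spectrum,
                                         cfg.photon_rate), cfg.photon_rate))
    if not runs:
        raise ValueError("both spectra disabled; nothing to simulate")

    tcfg = TransportConfig(n_histories=cfg.n_histories, seed=cfg.seed,
                           woodcock=cfg.woodcock, fluence=cfg.fluence)
    outputs: list[str] = []
    results = {}
    for kind, spec, rate in runs:
        beam = BeamConfig(cfg.beam_width, cfg.beam_height,
                          center=(0.0, cfg.beam_center_y, cfg.beam_center_z),
                          neutron_spectrum=spec if kind == "neutron" else None,
                          photon_spectrum=spec if kind == "photon" else None)

        def progress(done, total, kind=kind):
            _log(f"{kind}: {done}/{total} histories")

        res = run(tcfg, beam, geo, progress=progress)
        dr = finalize_dose(res)
        meta = dict(seed=cfg.seed, n_histories=cfg.n_histories,
                    config_hash=config_hash(cfg), particle=kind,
                    fluence_rate=rate, irradiation_s=cfg.irradiation_s,
                    version=_version)
        if geo.score_mode == 0:
            depths = geo.chambers.depths
            rows = {"depth_cm": depths,
                    "dose_gycm2": dr.total, "se_gycm2": dr.total_se}
            for i, tag in enumerate(TAG_NAMES):
                rows[f"dose_{tag}_gycm2"] = dr.dose[:, i]
                rows[f"se_{tag}_gycm2"] = dr.se[:, i]
            df = pd.DataFrame(rows)
            df["dose_rate_gys"] = to_dose_rate(df["dose_gycm2"], rate)
            df["dose_gy"] = to_absolute(df["dose_rate_gys"], cfg.irradiation_s)
            path = outdir / f"chambers_{kind}.csv"
            header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
            with open(path, "w") as f:
                f.write(header)
                df.to_csv(f, index=False)
            outputs.append(str(path))
            results[kind] = df
        else:
            shape = geo.grid_shape or (geo.n_regions, 1, 1)
            if geo.n_regions == int(np.prod(shape)):
                dose = dr.total.reshape(shape)
                se = dr.total_se.reshape(shape)
            else:
                dose = dr.total
                se = dr.total_se
            meta.update(voxel_cm=list(geo.gvoxel), origin_cm=list(geo.gorigin),
                        units="Gy*cm^2 per primary fluence")
            path = outdir / f"dose_{kind}.h5"
            save_dose_grid(path, dose, se, meta)
            outputs.append(str(path))
            results[kind] = (dose, se)
        _log(f"{kind}: energy balance "
             f"{abs(res.e_source_ev + res.q_released_ev - res.e_deposited_ev - res.e_escaped_ev) / res.e_source_ev:.2e}")

    write_manifest(outdir / "manifest.json", cfg, outputs, time.time() - t0)
    outputs.append(str(outdir / "manifest.json"))
    _log(f"wrote {len(outputs)} outputs to {outdir}")
    results["outputs"] = outputs
    return results
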