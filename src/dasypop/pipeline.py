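"""Pipeline orchestration: simulate → fit → delineate → weight → allocate →
calibrate → validate, with a provenance manifest.

Configuration is a YAML mapping (or an equivalent dict). A minimal
synthetic run:

.. code-block:: yaml

    seed: 7
    world:
      grid: {n_rows: 90, n_cols: 90}
      n_divisions: 3
      counties_per_division: 4
    models: [M1, M2, M3, M4, M5]
    calibrate: true
    out_dir: outputs/

Every stage writes under ``out_dir`` and registers its products (with
SHA-256 hashes) in ``manifest.json``, so reruns with the same seed/config
are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allocation as al
from . import validation as va
from .errors import ConfigError
from .grids import GridSpec, write_raster
from .synthetic import WorldConfig, generate_world

__all__ = ["load_config", "world_config_from_dict", "run_pipeline", "write_world"]

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a YAML mapping")
    return cfg


def world_config_from_dict(d: dict, seed: int | None = None) -> WorldConfig:
    d = dict(d)
    grid = d.pop("grid", None)
    kwargs = {}
    if grid is not None:
        kwargs["grid"] = GridSpec(**grid)
    if seed is not None:
        d.setdefault("seed", seed)
    try:
        return WorldConfig(**kwargs, **d)
    except TypeError as exc:
        raise ConfigError(f"invalid world config: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_world(world, out_dir: str | Path) -> list[Path]:
    """Write a synthetic world's rasters and tables to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = world.study
    written = []
    for name, raster in [
        ("counties.asc", s.county_labels), ("divisions.asc", s.division_labels),
        ("regions.asc", s.region_labels), ("tracts.asc", s.tract_labels),
        ("subdivisions.asc", s.subdivision_labels), ("elevation.asc", s.elevation),
    ]:
        write_raster(raster, out / name)
        written.append(out / name)
    from .grids import LabelRaster

    for name, mask in [("water.asc", s.water_mask), ("protected.asc", s.protected_mask)]:
        write_raster(LabelRaster(s.spec, mask.astype(np.int64), "mask"), out / name)
        written.append(out / name)
    s.county_census.to_csv(out / "county_census.csv")
    written.append(out / "county_census.csv")
    for level in ("tract", "subdivision"):
        tbl = getattr(s, f"{level}_census")
        if tbl is not None:
            tbl.to_csv(out / f"{level}_census.csv")
            written.append(out / f"{level}_census.csv")
    urban_rows = [
        {"urban_id": ua.urban_id, "division_id": ua.division_id,
         "county_id": ua.county_id, "decade": t, "population": p}
        for ua in s.registry for t, p in sorted(ua.population_by_decade.items())
    ]
    pd.DataFrame(urban_rows).to_csv(out / "urban_census.csv", index=False)
    written.append(out / "urban_census.csv")
    write_raster(s.extent_raster(s.baseline_decade)
                 if s.scaling_fits is not None else _footprint_raster(s),
                 out / "urban_footprints.asc")
    written.append(out / "urban_footprints.asc")
    for t, truth in world.truth_by_decade.items():
        p = out / f"truth_{t}.asc"
        write_raster(truth, p)
        written.append(p)
    return written


def _footprint_raster(study):
    from .grids import LabelRaster

    labels = np.zeros(study.spec.shape, dtype=np.int64)
    for ua in study.registry:
        if ua.footprint is not None:
            labels[ua.footprint[:, 0], ua.footprint[:, 1]] = ua.urban_id
    return LabelRaster(study.spec, labels, "urban")


def run_pipeline(config: "dict | str | Path") -> dict:
    """Run the full synthetic pipeline described by ``config``.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    Stages: simulate, fit-scaling, delineate, weights, allocate (all
    requested models × decades), optional calibrate, validate.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "pipeline_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    models = tuple(config.get("models", al.MODELS))
    skip = tuple(config.get("skip_decades", ()))
    manifest: dict = {"seed": seed, "config": {k: v for k, v in config.items()},
                      "stages": {}, "outputs": {}}

    def _stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def _done(name, t0, **info):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    # simulate ------------------------------------------------------------
    t0 = _stage("simulate")
    wcfg = world_config_from_dict(config.get("world", {}), seed=seed)
    world = generate_world(wcfg)
    study = world.study
    files = write_world(world, out_dir / "world")
    _done("simulate", t0, n_counties=len(study.county_ids()),
          n_urban=len(study.registry))

    # fit-scaling ----------------------------------------------------------
    t0 = _stage("fit_scaling")
    fits = study.ensure_scaling_fits()
    scaling_df = pd.DataFrame(
        [{"division": f.division_id, "alpha": f.alpha, "beta": f.beta,
          "lambda": f.lambda_, "n": f.n_fit, "r2": f.r_squared}
         for f in fits.values()]
    )
    scaling_df.to_csv(out_dir / "scaling.csv", index=False)
    files.append(out_dir / "scaling.csv")
    _done("fit_scaling", t0, n_divisions=len(fits))

    # delineate ------------------------------------------------------------
    t0 = _stage("delineate")
    series = study.ensure_extents()
    decades = [t for t in study.decades if t not in skip]
    ext_dir = out_dir / "extents"
    ext_dir.mkdir(exist_ok=True)
    for t in decades:
        write_raster(study.extent_raster(t), ext_dir / f"urban_{t}.asc")
        files.append(ext_dir / f"urban_{t}.asc")
    _done("delineate", t0, n_series=len(series))

    # weights --------------------------------------------------------------
    t0 = _stage("weights")
    wdir = out_dir / "weights"
    wdir.mkdir(exist_ok=True)
    write_raster(study.ensure_w0(), wdir / "w0.asc")
    write_raster(study.ensure_w1(), wdir / "w1.asc")
    files += [wdir / "w0.asc", wdir / "w1.asc"]
    for t in decades:
        write_raster(study.w2_for(t), wdir / f"w2_{t}.asc")
        files.append(wdir / f"w2_{t}.asc")
    _done("weights", t0)

    # calibrate ------------------------------------------------------------
    s_by_div: "float | dict" = config.get("s", 1.0)
    d_by_div: "float | dict" = config.get("d", 1.0)
    if config.get("calibrate", False):
        t0 = _stage("calibrate")
        s_grid = tuple(config.get("s_grid", va.S_GRID))
        d_grid = tuple(config.get("d_grid", va.D_GRID))
        s_by_div, d_by_div = va.calibrate_study(study, s_grid=s_grid, d_grid=d_grid)
        with open(out_dir / "calibration.json", "w") as fh:
            json.dump({"s": {str(k): v for k, v in s_by_div.items()},
                       "d": {str(k): v for k, v in d_by_div.items()}}, fh, indent=2)
        files.append(out_dir / "calibration.json")
        _done("calibrate", t0, s=s_by_div, d=d_by_div)

    # allocate -------------------------------------------------------------
    t0 = _stage("allocate")
    pop_dir = out_dir / "population"
    pop_dir.mkdir(exist_ok=True)
    n_out = 0
    for m in models:
        spec = al.ModelSpec(m, s=s_by_div, d=d_by_div)
        for t, res in al.run_history(study, spec, decades=decades).items():
            p = pop_dir / f"pop_{m}_{t}.asc"
            write_raster(res.population, p)
            files.append(p)
            n_out += 1
    _done("allocate", t0, n_rasters=n_out)

    # validate -------------------------------------------------------------
    t0 = _stage("validate")
    report = va.validate_models(study, s=s_by_div, d=d_by_div, models=models)
    with open(out_dir / "validation.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    files.append(out_dir / "validation.json")
    _done("validate", t0, mare=report.mare_by_model)

    manifest["outputs"] = {str(p.relative_to(out_dir)): _sha256(p) for p in files}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
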