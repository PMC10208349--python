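"""Stage orchestration over an output directory tree.

Each stage reads the previous stage's files and writes its own
subdirectory, so any stage can be re-run in isolation:

    simulate     fixture/                synthetic scenes + truth + MTL
    calibrate    reflectance/<epoch>/    DOS1-corrected reflectance bands
    separability separability/jm.csv    per-band J–M + selection flags
    classify     classified/<epoch>.tif  predicted class maps + model file
    assess       assessment/             confusion matrices + metrics
    change       change/                 areas, percent change, transitions
    project      projection/             multi-horizon projections + chi²

A missing upstream directory raises :class:`StageError` naming the stage to
run first.  All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assess as assess_mod
from . import change as change_mod
from . import classify as classify_mod
from . import radiometry, separability, synthetic
from .raster import (CLASS_CODES, BandRaster, ClassRaster, MultiBandScene,
                     read_raster, write_raster)

log = logging.getLogger("tidemark")

STAGES = ("simulate", "calibrate", "separability", "classify", "assess",
          "change", "project")


class StageError(RuntimeError):
    """A stage was invoked before its upstream stage produced outputs."""


@dataclass
class PipelineConfig:
    """Run settings; loadable from a YAML file (flat keys, documented in the
    README worked example)."""

    out: Path = Path("tidemark_run")
    seed: int = 42
    landscape: dict = field(default_factory=dict)
    g: float = 0.091
    C: float = 100.0
    n_per_class: int = 400
    pixel_area_ha: float = 0.09
    horizons_years: tuple = (10.0, 30.0)
    selected_bands: tuple | None = None
    n_keep: int = 3
    removal_threshold: float = 1.0
    ndvi_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        cfg.out = Path(cfg.out)
        return cfg

    def landscape_config(self) -> synthetic.LandscapeConfig:
        kw = dict(self.landscape)
        kw.setdefault("seed", self.seed)
        return synthetic.LandscapeConfig(**kw)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing {path}; run the '{stage}' stage first")
    return path


def _epochs(cfg: PipelineConfig) -> list[int]:
    manifest = synthetic.load_fixture_manifest(
        _require(cfg.out / "fixture", "simulate"))
    return [int(e) for e in manifest["epochs"]]


def _load_scene(cfg: PipelineConfig, year: int, kind: str) -> MultiBandScene:
    root = cfg.out / ("fixture/scenes" if kind == "dn" else "reflectance")
    stage = "simulate" if kind == "dn" else "calibrate"
    scene_dir = _require(root / str(year), stage)
    cal, sensor, _ = radiometry.read_mtl(
        _require(cfg.out / "fixture/metadata" / f"{year}.mtl", "simulate"))
    bands = {}
    for tif in sorted(scene_dir.glob("*.tif")):
        band = read_raster(tif)
        bands[band.band_label] = band
    return MultiBandScene(bands, sensor_id=sensor, epoch=year, calibration=cal)


def _load_truth(cfg: PipelineConfig, year: int) -> ClassRaster:
    r = read_raster(_require(cfg.out / "fixture/truth" / f"{year}.tif",
                             "simulate"))
    assert isinstance(r, ClassRaster)
    return r


def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate the synthetic fixture (scenes, truth, masks, metadata)."""
    fixture = cfg.out / "fixture"
    fixture.mkdir(parents=True, exist_ok=True)
    manifest = synthetic.make_fixture(cfg.landscape_config(), fixture)
    log.info("simulate: %d epochs at %s", len(manifest["epochs"]), fixture)
    return manifest


def run_calibrate(cfg: PipelineConfig) -> None:
    """DN → radiance → DOS1 → TOA reflectance for every epoch and band,
    honouring cloud masks as nodata."""
    for year in _epochs(cfg):
        scene = _load_scene(cfg, year, "dn")
        cal = scene.calibration
        mask_file = cfg.out / "fixture/masks" / f"{year}.tif"
        cloud = None
        if mask_file.exists():
            cloud = read_raster(mask_file).values.astype(bool)
        out_dir = cfg.out / "reflectance" / str(year)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, band in scene.bands.items():
            if cloud is not None:
                band = BandRaster(band.values, band.geometry, label,
                                  band.validity_mask & ~cloud)
            with warnings.catch_warnings():
                # negative-L_p warnings are per-band noise at scale; the
                # contract is exercised and logged in dos1_correct itself
                warnings.simplefilter("ignore", UserWarning)
                rho = radiometry.calibrate_band(band, cal.per_band[label], cal)
            write_raster(rho, out_dir / f"{label}.tif")
        log.info("calibrate: epoch %d -> %s", year, out_dir)


def run_separability(cfg: PipelineConfig) -> pd.DataFrame:
    """Pooled J–M separability across epochs and the band selection."""
    samples = separability.ClassSampleSet()
    for year in _epochs(cfg):
        scene = _load_scene(cfg, year, "reflectance")
        truth = _load_truth(cfg, year)
        per_scene = separability.samples_from_scene(scene, truth)
        for code, per_band in per_scene.samples.items():
            for band, vals in per_band.items():
                samples.add(code, band, vals)
    table = separability.jm_table(samples)
    selected = separability.select_bands(table, cfg.removal_threshold,
                                         cfg.n_keep)
    df = pd.DataFrame(
        [{"band": b, "jm": v, "selected": int(b in selected)}
         for b, v in table.items()])
    out_dir = cfg.out / "separability"
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "jm.csv", index=False)
    log.info("separability: selected %s", selected)
    return df


def _selected_bands(cfg: PipelineConfig) -> tuple[str, ...]:
    if cfg.selected_bands:
        return tuple(cfg.selected_bands)
    jm = _require(cfg.out / "separability/jm.csv", "separability")
    df = pd.read_csv(jm)
    sel = df[df.selected == 1].sort_values("jm", ascending=False)
    return tuple(sel.band)


def run_classify(cfg: PipelineConfig) -> None:
    """Train on the first epoch against truth; predict every epoch."""
    bands = _selected_bands(cfg)
    epochs = _epochs(cfg)
    first = _load_scene(cfg, epochs[0], "reflectance")
    truth = _load_truth(cfg, epochs[0])
    ts = classify_mod.sample_training(truth, first, bands,
                                      cfg.n_per_class, cfg.seed)
    model = classify_mod.train(ts, classify_mod.SVMConfig(g=cfg.g, C=cfg.C))
    out_dir = cfg.out / "classified"
    out_dir.mkdir(parents=True, exist_ok=True)
    classify_mod.save_model(model, out_dir / "model.npz")
    for year in epochs:
        scene = _load_scene(cfg, year, "reflectance")
        pred = classify_mod.predict_map(model, scene)
        write_raster(pred, out_dir / f"{year}.tif")
        log.info("classify: epoch %d mapped with bands %s", year, bands)


def run_assess(cfg: PipelineConfig) -> pd.DataFrame:
    """Confusion matrix + accuracy metrics per epoch, against the truth."""
    rows = []
    out_dir = cfg.out / "assessment"
    out_dir.mkdir(parents=True, exist_ok=True)
    for year in _epochs(cfg):
        pred = read_raster(_require(cfg.out / "classified" / f"{year}.tif",
                                    "classify"))
        truth = _load_truth(cfg, year)
        cm = assess_mod.confusion(truth, pred)
        cm.to_frame().to_csv(out_dir / f"confusion_{year}.csv")
        m = assess_mod.accuracy_metrics(cm)
        rows.append({"epoch": year, "overall": m.overall, "kappa": m.kappa,
                     **{f"producers_{c}": m.producers[c] for c in CLASS_CODES},
                     **{f"users_{c}": m.users[c] for c in CLASS_CODES}})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "metrics.csv", index=False)
    return df


def run_change(cfg: PipelineConfig) -> pd.DataFrame:
    """Area series, consecutive percent changes and transition matrices
    from the classified maps."""
    epochs = _epochs(cfg)
    out_dir = cfg.out / "change"
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = {y: read_raster(_require(cfg.out / "classified" / f"{y}.tif",
                                    "classify")) for y in epochs}
    areas = pd.concat([
        change_mod.class_areas(maps[y], cfg.pixel_area_ha, epoch=y).to_frame()
        for y in epochs])
    areas.to_csv(out_dir / "areas.csv", index=False)

    changes = []
    for y1, y2 in zip(epochs[:-1], epochs[1:]):
        a1 = change_mod.class_areas(maps[y1], cfg.pixel_area_ha, y1)
        a2 = change_mod.class_areas(maps[y2], cfg.pixel_area_ha, y2)
        for c in CLASS_CODES:
            rec = change_mod.percent_change(a1.areas_ha[c], a2.areas_ha[c])
            changes.append({"from": y1, "to": y2, "class": c,
                            "area_initial_ha": rec.S_i, "area_final_ha": rec.S_j,
                            "delta_ha": rec.delta, "percent": rec.percent,
                            "direction": rec.direction})
        _, tm = change_mod.estimate_transition(maps[y1], maps[y2], y2 - y1)
        tm.to_frame().to_csv(out_dir / f"transition_{y1}_{y2}.csv")
    df = pd.DataFrame(changes)
    df.to_csv(out_dir / "changes.csv", index=False)
    return df


def run_project(cfg: PipelineConfig) -> pd.DataFrame:
    """Markov projection from the final transition matrix, plus a
    back-validation: project the last observed epoch from the first matrix
    and chi-square it against the observation."""
    epochs = _epochs(cfg)
    change_dir = _require(cfg.out / "change", "change")
    out_dir = cfg.out / "projection"
    out_dir.mkdir(parents=True, exist_ok=True)

    maps = {y: read_raster(cfg.out / "classified" / f"{y}.tif")
            for y in (epochs[0], epochs[1], epochs[-2], epochs[-1])}
    _, tm_last = change_mod.estimate_transition(
        maps[epochs[-2]], maps[epochs[-1]], epochs[-1] - epochs[-2])
    v_last = change_mod.ClassProportions.from_areas(
        change_mod.class_areas(maps[epochs[-1]], cfg.pixel_area_ha,
                               epochs[-1]))
    proj = change_mod.project_series(v_last, tm_last, cfg.horizons_years)
    proj["epoch"] = epochs[-1] + proj["horizon_years"]
    proj.to_csv(out_dir / "projections.csv", index=False)

    # Validation: first-interval matrix projected to the final epoch.
    _, tm_first = change_mod.estimate_transition(
        maps[epochs[0]], maps[epochs[1]], epochs[1] - epochs[0])
    v0 = change_mod.ClassProportions.from_areas(
        change_mod.class_areas(maps[epochs[0]], cfg.pixel_area_ha, epochs[0]))
    sim = change_mod.project_markov(v0, tm_first, epochs[-1] - epochs[0])
    observed = change_mod.class_areas(maps[epochs[-1]], cfg.pixel_area_ha,
                                      epochs[-1])
    O = [sim.areas_ha()[c] for c in CLASS_CODES]
    E = [observed.areas_ha[c] for c in CLASS_CODES]
    chi = change_mod.chi_square_validate(O, E, q=len(CLASS_CODES))
    pd.DataFrame([{"statistic": chi.statistic, "df": chi.df,
                   "critical": chi.critical, "alpha": chi.alpha,
                   "reject": chi.reject}]).to_csv(
        out_dir / "chi_square.csv", index=False)
    log.info("project: chi2=%.2f (critical %.3f)", chi.statistic, chi.critical)
    return proj


_RUNNERS = {
    "simulate": run_simulate, "calibrate": run_calibrate,
    "separability": run_separability, "classify": run_classify,
    "assess": run_assess, "change": run_change, "project": run_project,
}


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> None:
    """Run the requested stages in canonical order."""
    cfg.out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            log.info("== stage %s ==", stage)
            _RUNNERS[stage](cfg)
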