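"""Readers, writers, run configuration and the pipeline driver.

Raster interchange is multi-page 32-bit-float TIFF with a JSON sidecar
carrying acquisition metadata and, for simulated data, the ground truth.
Tabular outputs are CSV; structured outputs JSON.  Every pipeline run
serializes its exact configuration and seed into the output directory and
writes a manifest with SHA-256 hashes of all inputs and outputs, so reruns
with the same config and seed are bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frap import FrapMovie, RoiSpec

logger = logging.getLogger("condyn")

__all__ = [
    "RunConfig",
    "read_movie",
    "write_movie",
    "read_image",
    "write_image",
    "read_rois",
    "write_rois",
    "run_pipeline",
    "configure_logging",
]


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return Path(path).with_suffix(".json")


def write_movie(path: str | Path, movie: FrapMovie,
                extra: dict | None = None) -> Path:
    """Write a movie as multi-page float32 TIFF plus a JSON sidecar holding
    pixel_size (um), frame_interval (s) and the bleach frame span."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval,
            "n_pre": movie.n_pre, "n_bleach": movie.n_bleach}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> FrapMovie:
    """Read a movie from multi-page TIFF; metadata comes from the JSON
    sidecar.  A missing metadata field raises an error naming that field."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar {side} not found")
    meta = json.loads(side.read_text())
    for key in ("pixel_size_um", "frame_interval_s", "n_pre", "n_bleach"):
        if key not in meta:
            raise ValueError(f"sidecar {side} is missing required "
                             f"metadata field {key!r}")
    return FrapMovie(frames=frames, pixel_size=meta["pixel_size_um"],
                     frame_interval=meta["frame_interval_s"],
                     n_pre=meta["n_pre"], n_bleach=meta["n_bleach"])


def write_image(path: str | Path, image: np.ndarray,
                pixel_size: float | None = None,
                extra: dict | None = None) -> Path:
    """Single image (or channel stack) as float32 TIFF + sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, np.float32))
    meta = dict(extra or {})
    if pixel_size is not None:
        meta["pixel_size"] = pixel_size
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = tifffile.imread(path)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return img, meta


def write_rois(path: str | Path, rois: list[RoiSpec]) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.to_dict() for r in rois], indent=1))
    return path


def read_rois(path: str | Path) -> list[RoiSpec]:
    return [RoiSpec.from_dict(d) for d in json.loads(Path(path).read_text())]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``stages`` is an ordered subset of {"simulate", "frap", "coloc",
    "morph"}.  Stage parameter dicts hold keyword arguments for the
    underlying generators/analyses; anything omitted uses the library
    defaults.
    """

    stages: list[str] = field(default_factory=lambda: ["simulate", "frap",
                                                       "coloc", "morph"])
    seed: int = 0
    out_dir: str = "condyn_run"
    verbosity: int = 0
    frap_designs: list[str] = field(default_factory=lambda: [
        "full", "inner", "nucleoplasmic", "fiber"])
    n_frap_replicates: int = 3
    n_frap_post: int = 500
    frap_noise_sd: float = 0.05
    frap_acq_bleach_rate: float = 0.02
    n_coloc_cells: int = 6
    coloc_shared_fraction: float = 0.7
    coloc_noise_sd: float = 0.05
    coloc_threshold_policy: str = "zero"
    n_phenotype_per_class: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order, writing per-stage outputs, a
    manifest of output hashes and a human-readable report.

    Per-stage errors are collected (later stages still run when their
    inputs exist) and reported; the returned bundle carries stage results,
    errors and the manifest.  Prior outputs are never modified by a failing
    stage.
    """
    from . import __version__
    from .simulate import (NoiseModel, ColocSimConfig, frap_config_for_design,
                           simulate_coloc_pair, simulate_frap_movie,
                           simulate_phenotype_image)
    from .coloc import ColocImagePair, coloc_experiment
    from .morphology import classify_phenotype, detect_fibers, fiber_thickness

    configure_logging(config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logger.info("condyn %s pipeline, seed=%d, stages=%s",
                __version__, config.seed, config.stages)

    bundle: dict = {"stages": {}, "errors": {}, "version": __version__}
    outputs: list[Path] = [out / "config.yaml"]
    report_lines = [f"condyn {__version__} pipeline run",
                    f"seed: {config.seed}"]
    order = ["simulate", "frap", "coloc", "morph"]
    unknown = set(config.stages) - set(order)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in order if s in config.stages]

    for stage in stages:
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        try:
            if stage == "simulate":
                res = _stage_simulate(config, sdir, outputs)
            elif stage == "frap":
                res = _stage_frap(config, out, sdir, outputs)
            elif stage == "coloc":
                res = _stage_coloc(config, sdir, outputs)
            else:
                res = _stage_morph(config, sdir, outputs)
            bundle["stages"][stage] = res
            report_lines.append(f"{stage}: ok — {res.get('summary', '')}")
        except Exception as exc:  # collected, not propagated
            logger.error("stage %s failed: %s", stage, exc)
            bundle["errors"][stage] = str(exc)
            report_lines.append(f"{stage}: FAILED — {exc}")

    manifest = {"config": "config.yaml", "seed": config.seed,
                "version": __version__,
                "outputs": {str(p.relative_to(out)): _sha256(p)
                            for p in outputs if p.exists()}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    bundle["manifest"] = manifest
    return bundle


def _stage_simulate(cfg: RunConfig, sdir: Path, outputs: list[Path]) -> dict:
    from .simulate import (NoiseModel, ColocSimConfig, frap_config_for_design,
                           simulate_coloc_pair, simulate_frap_movie,
                           simulate_phenotype_image)
    n_movies = 0
    for design in cfg.frap_designs:
        for rep in range(cfg.n_frap_replicates):
            sim = frap_config_for_design(
                design, seed=cfg.seed + 1000 * n_movies + rep,
                noise_sd=cfg.frap_noise_sd, n_post=cfg.n_frap_post,
                acq_bleach_rate=cfg.frap_acq_bleach_rate)
            movie, gt = simulate_frap_movie(sim)
            extra = {"design": design,
                     "ground_truth": {
                         "mobile_fraction": gt.mobile_fraction,
                         "half_times_s": list(gt.half_times or ()),
                         "amplitudes": list(gt.amplitudes or ())},
                     "bleach_roi": sim.bleach_roi.to_dict()}
            p = write_movie(sdir / f"frap_{design}_{rep:02d}.tif", movie,
                            extra=extra)
            outputs += [p, _sidecar(p)]
            n_movies += 1
    for i in range(cfg.n_coloc_cells):
        pair, gt = simulate_coloc_pair(ColocSimConfig(
            shared_fraction=cfg.coloc_shared_fraction,
            noise_model=NoiseModel.gaussian(cfg.coloc_noise_sd),
            seed=cfg.seed + 77 + i))
        stack = np.stack([pair.channel_1, pair.channel_2,
                          pair.mask.astype(float)])
        p = write_image(sdir / f"coloc_cell_{i:02d}.tif", stack,
                        pixel_size=pair.pixel_size,
                        extra={"pages": ["channel_1", "channel_2", "mask"],
                               "shared_fraction": gt.shared_fraction})
        outputs += [p, _sidecar(p)]
    for klass in ("diffuse", "condensed", "fibrous"):
        for i in range(cfg.n_phenotype_per_class):
            img, gt = simulate_phenotype_image(
                klass, seed=cfg.seed + 555 + i)
            stack = np.stack([img, gt.nucleus_mask.astype(float)])
            p = write_image(sdir / f"phenotype_{klass}_{i:02d}.tif", stack,
                            pixel_size=0.065,
                            extra={"pages": ["image", "nucleus_mask"],
                                   "class": klass})
            outputs += [p, _sidecar(p)]
    return {"summary": f"{n_movies} FRAP movies, {cfg.n_coloc_cells} coloc "
                       f"cells, {3 * cfg.n_phenotype_per_class} phenotype "
                       f"images", "dir": str(sdir)}


def _stage_frap(cfg: RunConfig, out: Path, sdir: Path,
                outputs: list[Path]) -> dict:
    from .frap import (DESIGN_MODEL, extract_roi_trace,
                       correct_acquisition_bleach, normalize_recovery,
                       fit_biexponential, fit_single_exponential,
                       summarize_replicates)
    sim_dir = out / "simulate"
    rows = []
    fits_by_design: dict[str, list] = {}
    for tif in sorted(sim_dir.glob("frap_*.tif")):
        movie = read_movie(tif)
        meta = json.loads(_sidecar(tif).read_text())
        design = meta["design"]
        roi = RoiSpec.from_dict(meta["bleach_roi"])
        trace = extract_roi_trace(movie, roi)
        ref = _reference_roi(roi, movie)
        corrected = (correct_acquisition_bleach(
            trace, extract_roi_trace(movie, ref), movie.n_pre)
            if ref is not None else trace)
        curve = normalize_recovery(corrected, movie.n_pre, movie.n_bleach,
                                   movie.frame_interval)
        fit = (fit_biexponential(curve) if DESIGN_MODEL[design] == "biexp"
               else fit_single_exponential(curve))
        fits_by_design.setdefault(design, []).append(fit)
        df = pd.DataFrame({"time_s": curve.times, "raw": trace[-len(curve.times):],
                           "corrected": corrected[-len(curve.times):],
                           "normalized": curve.values})
        pcsv = sdir / (tif.stem + "_curve.csv")
        df.to_csv(pcsv, index=False)
        pjson = sdir / (tif.stem + "_fit.json")
        pjson.write_text(json.dumps(fit.to_dict(), indent=1))
        outputs += [pcsv, pjson]
        rows.append({"movie": tif.name, "design": design,
                     "model": fit.model, "fit_ok": fit.fit_ok,
                     "mobile_fraction": fit.mobile_fraction,
                     "half_time_s": fit.half_times[-1]})
    summary_rows = []
    for design, fits in fits_by_design.items():
        s = summarize_replicates(fits)
        summary_rows.append({
            "design": design, "n": s.n_fits, "n_failed": s.n_failed,
            "model": s.model,
            "mean_half_time_s": s.mean_half_times[-1],
            "sd_half_time_s": (s.sd_half_times[-1]
                               if s.sd_half_times else None),
            "mean_mobile_fraction": s.mean_mobile,
            "sd_mobile_fraction": s.sd_mobile})
    p1 = sdir / "fits.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = sdir / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(p2, index=False)
    outputs += [p1, p2]
    return {"summary": f"{len(rows)} curves fitted across "
                       f"{len(fits_by_design)} designs",
            "summary_csv": str(p2)}


def _reference_roi(roi: RoiSpec, movie: FrapMovie) -> RoiSpec | None:
    """Unbleached reference circle of the same size, placed away from the
    bleach ROI; None when it cannot fit inside the frame."""
    if roi.kind != "circle":
        return None
    h, w = movie.shape
    px = movie.pixel_size
    r_roi_px = roi.radius / px
    cx, cy = roi.center
    # same size preferred; shrink until a corner placement clears the
    # bleached region and stays inside the frame
    for shrink in (1.0, 0.5, 0.25, 0.1):
        r_px = max(3.0, r_roi_px * shrink)
        for fx, fy in ((0.12, 0.12), (0.88, 0.12), (0.12, 0.88),
                       (0.88, 0.88)):
            nx, ny = fx * (w - 1), fy * (h - 1)
            if np.hypot(nx - cx, ny - cy) > r_roi_px + r_px + 2 and \
                    r_px <= nx <= w - 1 - r_px and \
                    r_px <= ny <= h - 1 - r_px:
                return RoiSpec(kind="circle", center=(nx, ny),
                               radius=r_px * px, design="reference")
    return None


def _stage_coloc(cfg: RunConfig, sdir: Path, outputs: list[Path]) -> dict:
    from .coloc import ColocImagePair, coloc_experiment
    sim_dir = sdir.parent / "simulate"
    pairs = []
    for tif in sorted(sim_dir.glob("coloc_cell_*.tif")):
        stack, meta = read_image(tif)
        pairs.append(ColocImagePair(channel_1=stack[0], channel_2=stack[1],
                                    mask=stack[2] > 0.5,
                                    pixel_size=meta.get("pixel_size", 28.0)))
    if not pairs:
        raise ValueError("no coloc cell images found; run the simulate "
                         "stage first")
    comps = coloc_experiment(pairs,
                             threshold_policy=cfg.coloc_threshold_policy)
    rows = []
    for coeff, gc in comps.items():
        for v in gc.real:
            rows.append({"coefficient": coeff, "group": "real", "value": v})
        for v in gc.randomized:
            rows.append({"coefficient": coeff, "group": "randomized",
                         "value": v})
    p1 = sdir / "coefficients.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = sdir / "group_comparison.json"
    p2.write_text(json.dumps({k: g.to_dict() for k, g in comps.items()},
                             indent=1))
    outputs += [p1, p2]
    return {"summary": f"{len(pairs)} cells; spearman p="
                       f"{comps['spearman_rho'].p_value:.3g}",
            "group_json": str(p2)}


def _stage_morph(cfg: RunConfig, sdir: Path, outputs: list[Path]) -> dict:
    from .morphology import (classify_phenotype, detect_fibers,
                             fiber_thickness, segment_condensates)
    sim_dir = sdir.parent / "simulate"
    calls = []
    tables = []
    for tif in sorted(sim_dir.glob("phenotype_*.tif")):
        stack, meta = read_image(tif)
        img, mask = stack[0], stack[1] > 0.5
        px_um = meta.get("pixel_size", 0.065)
        call = classify_phenotype(img, px_um, mask=mask)
        calls.append({"image": tif.name, "true_class": meta.get("class"),
                      "called_class": call.phenotype,
                      "condensate_area_fraction": call.condensate_area_fraction,
                      "ridge_area_fraction": call.ridge_area_fraction})
        table = segment_condensates(img, px_um, mask=mask)
        table.insert(0, "image", tif.name)
        tables.append(table)
        if call.phenotype == "fibrous":
            rmask, skel = detect_fibers(img, px_um * 1000.0, mask=mask)
            if skel.any():
                rep = fiber_thickness(img, skel, px_um * 1000.0)
                calls[-1]["fiber_median_thickness_nm"] = rep.median_nm
    p1 = sdir / "phenotype_calls.json"
    p1.write_text(json.dumps(calls, indent=1))
    p2 = sdir / "object_tables.csv"
    pd.concat(tables, ignore_index=True).to_csv(p2, index=False) if tables \
        else pd.DataFrame().to_csv(p2, index=False)
    outputs += [p1, p2]
    n_ok = sum(c["true_class"] == c["called_class"] for c in calls)
    return {"summary": f"{n_ok}/{len(calls)} phenotype calls correct",
            "calls_json": str(p1)}
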