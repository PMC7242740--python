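"""End-to-end pipeline driver: simulate -> fit -> segment -> quantify ->
heterogeneity -> respond -> report.

Each stage reads its inputs from, and writes versioned outputs into, the
configured output directory, so stages can be run individually from the CLI
or all at once with :func:`run_pipeline`.  Every CSV output starts with a
``#`` metadata line carrying the config hash and seed; re-running with the
same configuration and seed reproduces the CSVs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as omio
from . import heterogeneity as het
from . import response as resp
from .config import PipelineConfig
from .flim import DecayStack, FitOptions, bin_decays, fit_stack, LifetimeImage
from .quantify import (SegmentationOptions, extract_cell_endpoints,
                       normalize_to_control, omi_index, segment_cytoplasms)
from .simulate import (CHANNELS, NADPH, FAD, CellGeometry, ChannelTruth,
                       FlimSimSpec, generate_flim_stack, generate_irf)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _header(cfg: PipelineConfig) -> str:
    return f"# omihet config={cfg.digest()} seed={cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> Path:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _image_grid(cfg: PipelineConfig) -> list[tuple[float, float]]:
    """Fixed non-overlapping disc centers for the simulated field of view."""
    s = cfg.image_size
    positions = [(s * 0.25, s * 0.25), (s * 0.25, s * 0.75), (s * 0.72, s * 0.5),
                 (s * 0.75, s * 0.85)]
    return positions[: cfg.cells_per_image]


def _cell_truth(rng: np.random.Generator, treated_effect: float,
                photons: float) -> dict[str, ChannelTruth]:
    """Ground-truth decay parameters for one cell, with biological jitter.

    ``treated_effect > 0`` plants a drug response: more free NAD(P)H (shorter
    NAD(P)H tau_m), more bound FAD (longer FAD tau_m), lower NAD(P)H
    intensity (lower redox ratio).
    """
    jit = rng.normal(0.0, 0.02, size=3)
    nadph_alpha = float(np.clip(0.75 + 0.10 * treated_effect + jit[0], 0.05, 0.95))
    fad_alpha = float(np.clip(0.65 - 0.10 * treated_effect + jit[1], 0.05, 0.95))
    nadph_photons = photons * (1.0 - 0.15 * treated_effect) * (1.0 + jit[2])
    return {
        NADPH: ChannelTruth(0.4, 2.5, nadph_alpha, max(nadph_photons, 600.0)),
        FAD: ChannelTruth(0.3, 2.0, fad_alpha, photons),
    }


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic cohort of FLIM fields of view.

    One image per organoid; each patient contributes ``organoids_per_patient``
    control and as many treated organoids.
    """
    out = Path(cfg.out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    arms = ["control", cfg.treatment_name]
    manifest = []
    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        organoid_no = 0
        for arm in arms:
            effect = 0.0 if arm == "control" else -cfg.treatment_shift
            for _ in range(cfg.organoids_per_patient):
                organoid_no += 1
                organoid = f"{patient}-O{organoid_no:03d}"
                cells = []
                for center in _image_grid(cfg):
                    jitter = rng.uniform(-1.0, 1.0, size=2)
                    cells.append(CellGeometry(
                        center=(center[0] + jitter[0], center[1] + jitter[1]),
                        radius=cfg.image_size * 0.16,
                        truth=_cell_truth(rng, effect, cfg.photons_per_pixel),
                    ))
                spec = FlimSimSpec(
                    image_width=cfg.image_size, image_height=cfg.image_size,
                    n_time_bins=cfg.n_time_bins, bin_width=cfg.bin_width_ns,
                    irf_fwhm=cfg.irf_fwhm_ns, background_rate=cfg.background_rate,
                    cells=cells, seed=int(rng.integers(0, 2**31 - 1)),
                )
                stacks, mask, truth = generate_flim_stack(spec)
                irf = generate_irf(cfg.irf_fwhm_ns, cfg.n_time_bins, cfg.bin_width_ns)
                base = f"{organoid}"
                for ch in CHANNELS:
                    stack = DecayStack(stacks[ch], cfg.bin_width_ns, ch, irf)
                    omio.write_decay_stack(stack, img_dir / f"{base}_{ch}.tif")
                omio.write_mask(mask, img_dir / f"{base}_truthmask.tif")
                truth.to_csv(img_dir / f"{base}_truth.csv", index=False)
                manifest.append({"patient_id": patient, "organoid_id": organoid,
                                 "treatment": arm, "timepoint_h": 72.0,
                                 "image_base": base})
    mpath = out / "manifest.csv"
    _write_csv(pd.DataFrame(manifest), mpath, cfg)
    log.info("simulate: wrote %d organoid images", len(manifest))
    return mpath


def _load_manifest(cfg: PipelineConfig, stage: str) -> pd.DataFrame:
    mpath = Path(cfg.out_dir) / "manifest.csv"
    if not mpath.exists():
        raise PipelineError(stage, f"missing manifest {mpath}; run simulate first")
    return read_csv(mpath)


def stage_fit(cfg: PipelineConfig) -> Path:
    """Bin and fit every decay stack; lifetime images stored per organoid."""
    out = Path(cfg.out_dir)
    fit_dir = out / "fits"
    fit_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(cfg, "fit-flim")
    n_pixels = 0
    for row in manifest.itertuples():
        for ch in CHANNELS:
            path = out / "images" / f"{row.image_base}_{ch}.tif"
            if not path.exists():
                raise PipelineError("fit-flim", f"missing input {path}")
            stack = bin_decays(omio.read_decay_stack(path), cfg.bin_radius)
            opts = FitOptions.for_channel(ch, min_photons=cfg.min_photons)
            img = fit_stack(stack, opts)
            n_pixels += int(img.valid.sum())
            np.savez(
                fit_dir / f"{row.image_base}_{ch}.npz",
                alpha1_frac=img.alpha1_frac, alpha2_frac=img.alpha2_frac,
                tau1=img.tau1, tau2=img.tau2, background_c=img.background_c,
                tau_m=img.tau_m, intensity=img.intensity,
                chi2_reduced=img.chi2_reduced, valid=img.valid,
            )
    log.info("fit-flim: %d pixels fit across %d organoids", n_pixels, len(manifest))
    return fit_dir


def _load_lifetime(fit_dir: Path, base: str, ch: str) -> LifetimeImage:
    data = np.load(fit_dir / f"{base}_{ch}.npz")
    return LifetimeImage(**{k: data[k] for k in data.files}, channel=ch)


def stage_segment(cfg: PipelineConfig) -> Path:
    """Segment cytoplasms from each NAD(P)H intensity image."""
    out = Path(cfg.out_dir)
    seg_dir = out / "masks"
    seg_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(cfg, "segment")
    opts = SegmentationOptions(
        smoothing_sigma=cfg.smoothing_sigma, min_area=cfg.min_area,
        min_marker_distance=cfg.min_marker_distance,
    )
    n_labels = 0
    for row in manifest.itertuples():
        path = out / "images" / f"{row.image_base}_{NADPH}.tif"
        if not path.exists():
            raise PipelineError("segment", f"missing input {path}")
        stack = omio.read_decay_stack(path)
        intensity = stack.counts.sum(axis=2).astype(float)
        mask = segment_cytoplasms(intensity, opts)
        n_labels += int(mask.max())
        omio.write_mask(mask, seg_dir / f"{row.image_base}_mask.tif")
    log.info("segment: %d cells labeled", n_labels)
    return seg_dir


def stage_quantify(cfg: PipelineConfig) -> Path:
    """Per-cell endpoints, control normalization, and the OMI index."""
    out = Path(cfg.out_dir)
    manifest = _load_manifest(cfg, "quantify")
    fit_dir, seg_dir = out / "fits", out / "masks"
    frames, dropped = [], 0
    for row in manifest.itertuples():
        try:
            mask = omio.read_mask(seg_dir / f"{row.image_base}_mask.tif")
            nadph = _load_lifetime(fit_dir, row.image_base, NADPH)
            fad = _load_lifetime(fit_dir, row.image_base, FAD)
        except FileNotFoundError as exc:
            raise PipelineError("quantify", str(exc)) from exc
        meta = {"patient_id": row.patient_id, "organoid_id": row.organoid_id,
                "treatment": row.treatment, "timepoint_h": row.timepoint_h,
                "morphology": "unknown"}
        table, report = extract_cell_endpoints(
            mask, nadph, fad, meta, min_valid_pixels=cfg.min_valid_pixels)
        dropped += report["n_dropped"]
        if not table.empty:
            frames.append(table)
    if not frames:
        raise PipelineError("quantify", "no cells survived quantification")
    cells = pd.concat(frames, ignore_index=True)
    try:
        cells = omi_index(normalize_to_control(cells))
    except ValueError as exc:
        raise PipelineError("quantify", str(exc)) from exc
    cpath = out / "cells.csv"
    _write_csv(cells, cpath, cfg)
    omio.write_cell_table_long(cells.assign(true_component=0), out / "cells_long.csv")
    (out / "quantify_report.json").write_text(json.dumps(
        {"n_cells": len(cells), "n_dropped": dropped}))
    log.info("quantify: %d cells kept, %d dropped", len(cells), dropped)
    return cpath


def stage_heterogeneity(cfg: PipelineConfig) -> Path:
    """Heterogeneity profile of the OMI index per patient/treatment group."""
    out = Path(cfg.out_dir)
    cpath = out / "cells.csv"
    if not cpath.exists():
        raise PipelineError("heterogeneity", f"missing cell table {cpath}")
    cells = read_csv(cpath)
    rows = []
    for (patient, treatment, timepoint), grp in cells.groupby(
            ["patient_id", "treatment", "timepoint_h"]):
        values = grp["omi_index"].dropna().to_numpy()
        if len(values) < 5:
            log.warning("heterogeneity: skipping %s/%s (only %d cells)",
                        patient, treatment, len(values))
            continue
        prof = het.profile(values, n_bins=cfg.qe_bins, g_max=cfg.g_max)
        rows.append({"patient_id": patient, "treatment": treatment,
                     "timepoint_h": timepoint, "n_cells": len(values),
                     "g": prof.model.g, "wh_index": prof.wh_index, "qe": prof.qe,
                     "ks": prof.ks, "ol_pct": prof.ol_pct, "sd": prof.sd,
                     "cv": prof.cv, "aic": prof.model.aic})
    hpath = out / "heterogeneity.csv"
    _write_csv(pd.DataFrame(rows), hpath, cfg)
    log.info("heterogeneity: %d groups profiled", len(rows))
    return hpath


def stage_respond(cfg: PipelineConfig) -> Path:
    """Glass's Delta, Wilcoxon, wH change and responder calls per treatment."""
    out = Path(cfg.out_dir)
    cpath = out / "cells.csv"
    if not cpath.exists():
        raise PipelineError("respond", f"missing cell table {cpath}")
    cells = read_csv(cpath)
    report = resp.response_report(
        cells, threshold=cfg.delta_threshold, g_max=cfg.g_max)
    rpath = out / "response.csv"
    _write_csv(report, rpath, cfg)
    log.info("respond: %d treatment arms evaluated", len(report))
    return rpath


def stage_report(cfg: PipelineConfig) -> list[Path]:
    """Render the effect-size heatmap and density plots with CSV twins."""
    from .reporting import render_density, render_heatmap

    out = Path(cfg.out_dir)
    rpath = out / "response.csv"
    cpath = out / "cells.csv"
    if not rpath.exists() or not cpath.exists():
        raise PipelineError("report", "missing response.csv or cells.csv; run earlier stages")
    report = read_csv(rpath)
    cells = read_csv(cpath)
    outputs = [*render_heatmap(report, out / "heatmap.png", out / "heatmap.csv",
                               threshold=cfg.delta_threshold)]
    for (patient, timepoint), stratum in cells.groupby(["patient_id", "timepoint_h"]):
        control = stratum.loc[stratum["treatment"] == "control", "omi_index"].dropna()
        for treatment, arm in stratum[stratum["treatment"] != "control"].groupby("treatment"):
            treated = arm["omi_index"].dropna()
            if len(control) < 5 or len(treated) < 5:
                continue
            cm = het.select_model(control.to_numpy())
            tm = het.select_model(treated.to_numpy())
            base = out / f"density_{patient}_{treatment}"
            outputs.extend(render_density(cm, tm, base.with_suffix(".png"),
                                          base.with_suffix(".csv")))
    log.info("report: wrote %d files", len(outputs))
    return outputs


STAGES = {
    "simulate": stage_simulate,
    "fit-flim": stage_fit,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "heterogeneity": stage_heterogeneity,
    "respond": stage_respond,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Run every stage in order; any failure aborts with the stage name."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "config.txt")
    results = {}
    for name, fn in STAGES.items():
        try:
            results[name] = fn(cfg)
        except PipelineError:
            raise
        except Exception as exc:  # annotate unexpected failures with the stage
            raise PipelineError(name, str(exc)) from exc
    return results
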