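"""End-to-end reproducible runs: simulate scenario batches, analyse them,
and report recovered statistics against generator truth.

A run is driven by a single config (YAML file or dict); every stage logs one
structured line with its seed, parameters and counts, intermediate artifacts
are persisted, and the report can be recomputed from them. Outputs carry no
timestamps so identical configs and seeds give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dlsinv, forcespec, imagetex, io, synthgen

log = logging.getLogger("ommech.pipeline")

DEFAULT_TOLERANCES = {
    "force_mean_rel": 0.05,
    "step_count_abs": 0.1,
    "coverage_abs": 0.03,
    "rq_abs": 0.05,
    "stripe_bins": 1.0,
    "vesicle_mean_rel": 0.10,
    "dls_grid_cells": 1.0,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    force_scenarios: list = field(default_factory=list)
    image_scenes: list = field(default_factory=list)
    dls_cases: list = field(default_factory=list)  # [{"diameter": nm, "noise_sd": ...}]
    n_curves: int = 400
    seed: int = 1
    min_force: float = 0.1
    min_thickness: float = 0.1
    noise_sd: float | None = None
    out_dir: str = "ommech-run"
    tolerances: dict = field(default_factory=lambda: dict(DEFAULT_TOLERANCES))
    save_intermediates: bool = True

    def validate(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        for name in self.force_scenarios:
            synthgen.get_force_preset(name)
        for name in self.image_scenes:
            synthgen.get_scene_preset(name)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("out_dir", "save_intermediates")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _force_batch_report(name: str, cfg: RunConfig, out: Path) -> dict:
    preset = synthgen.get_force_preset(name)
    curves, truths = synthgen.gen_force_batch(preset, cfg.n_curves, cfg.seed,
                                              noise_sd=cfg.noise_sd)
    log.info("stage=simulate scenario=%s n=%d seed=%d noise_sd=%s",
             name, cfg.n_curves, cfg.seed, cfg.noise_sd)
    results = forcespec.analyze_batch(curves, min_force=cfg.min_force,
                                      min_thickness=cfg.min_thickness)
    forcespec.classify_events(results)
    summary = forcespec.summarize_curves(results, batch=name)
    true_finals = [t.events[-1].rupture_force for t in truths if t.events]
    true_mean = float(np.mean(true_finals)) if true_finals else np.nan
    expected_steps = float(np.sum([l.presence_probability for l in preset.layers]))
    delta_rel = (abs(summary["mean_final_rupture_force"] - true_mean) / true_mean
                 if true_mean and true_mean == true_mean else np.nan)
    report = {
        "kind": "force",
        "scenario": name,
        "summary": summary,
        "truth_mean_final_rupture_force": true_mean,
        "expected_step_count": expected_steps,
        "delta_rel_force": delta_rel,
        "delta_step_count": abs(summary["mean_step_count"] - expected_steps),
        "pass_force": bool(delta_rel <= cfg.tolerances["force_mean_rel"]),
    }
    log.info("stage=analyze-fs scenario=%s events=%d mean_final=%.4g truth=%.4g",
             name, sum(r.step_count for r in results),
             summary["mean_final_rupture_force"], true_mean)
    if cfg.save_intermediates:
        io.write_curves_tsv(curves, out / f"curves_{name}.tsv")
        io.events_frame(results).to_csv(out / f"events_{name}.csv", index=False)
        io.write_json([t for t in truths], out / f"truth_{name}.json")
    return report


def _image_scene_report(name: str, cfg: RunConfig, out: Path) -> dict:
    scene = synthgen.get_scene_preset(name)
    hm, truth = synthgen.gen_height_map(scene, cfg.seed)
    log.info("stage=simulate scene=%s px=%d seed=%d", name, scene.pixels_per_side, cfg.seed)
    flat = imagetex.flatten_map(hm, order=1)
    report: dict = {"kind": "image", "scene": name}
    if truth.coverages_lipid:
        seg = imagetex.segment_heights(flat)
        try:
            cov = imagetex.coverage_fractions(seg, denominator="lipid")
        except ValueError:
            cov = {}
        report["coverage"] = cov
        report["coverage_truth"] = truth.coverages_lipid
    mask = truth.labels != 0 if truth.coverages_lipid else None
    try:
        report["rq_nm"] = imagetex.roughness_rq(flat, mask)
    except ValueError:
        pass
    if scene.stripe is not None:
        spec = imagetex.stripe_period(flat)
        report["stripe_wavelength_nm"] = spec.dominant_wavelength
        report["stripe_amplitude_nm"] = spec.dominant_amplitude
        report["stripe_truth_nm"] = scene.stripe.period
    if scene.vesicles is not None:
        det = imagetex.detect_vesicles(flat)
        report["vesicles"] = imagetex.vesicle_summary(det)
        report["vesicle_truth_mean_nm"] = float(np.mean(
            [v["diameter"] for v in truth.vesicles])) if truth.vesicles else np.nan
    if cfg.save_intermediates:
        io.write_heightmap_tiff(hm, out / f"map_{name}.tif")
    log.info("stage=analyze-image scene=%s", name)
    return report


def _dls_case_report(case: dict, cfg: RunConfig, out: Path) -> dict:
    diameter = float(case.get("diameter", 40.0))
    noise_sd = float(case.get("noise_sd", 0.01))
    inst = dlsinv.InstrumentSpec()
    grid = dlsinv.default_diameter_grid()
    dist = synthgen.monodisperse(diameter)
    corr = synthgen.gen_correlogram(dist, inst, noise_sd=noise_sd, seed=cfg.seed)
    res = dlsinv.invert_mem(corr, inst, grid=grid)
    modes = dlsinv.peak_stats(res)
    top = modes[0]["diameter"] if modes else np.nan
    cells = abs(np.log(top / diameter) / np.log(grid[1] / grid[0])) if top == top else np.nan
    log.info("stage=analyze-dls d=%g recovered=%.4g chi2=%.4g", diameter, top, res.chi2)
    if cfg.save_intermediates:
        io.write_correlogram_tsv(corr, out / f"corr_{diameter:g}nm.tsv")
        io.write_distribution_csv(res, out / f"dist_{diameter:g}nm.csv")
    return {
        "kind": "dls",
        "true_diameter_nm": diameter,
        "recovered_mode_nm": float(top),
        "grid_cell_error": float(cells),
        "chi2": res.chi2,
        "converged": res.converged,
        "pass_mode": bool(cells <= cfg.tolerances["dls_grid_cells"]),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Generate, analyse and summarise every configured batch.

    Returns the report dict; also writes ``report.json``, ``report.csv``
    and ``report.txt`` under the configured output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not (config.force_scenarios or config.image_scenes or config.dls_cases):
        import warnings

        warnings.warn("empty run configuration: no scenarios requested", stacklevel=2)
    batches = []
    for name in config.force_scenarios:
        batches.append(_force_batch_report(name, config, out))
    for name in config.image_scenes:
        batches.append(_image_scene_report(name, config, out))
    for case in config.dls_cases:
        batches.append(_dls_case_report(dict(case), config, out))
    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_curves": config.n_curves,
        "batches": batches,
    }
    io.write_json(report, out / "report.json")
    _write_report_tables(report, out)
    return report


def _write_report_tables(report: dict, out: Path) -> None:
    import pandas as pd

    rows = []
    lines = [f"ommech run (config {report['config_digest']}, seed {report['seed']})", ""]
    for b in report["batches"]:
        if b["kind"] == "force":
            s = b["summary"]
            rows.append({
                "batch": b["scenario"], "kind": "force",
                "measured": s["mean_final_rupture_force"],
                "expected": b["truth_mean_final_rupture_force"],
                "metric": "mean_final_rupture_force_nN",
                "passed": b["pass_force"],
            })
            lines.append(
                f"[force] {b['scenario']}: mean final rupture "
                f"{s['mean_final_rupture_force']:.3f} nN (truth "
                f"{b['truth_mean_final_rupture_force']:.3f}), steps "
                f"{s['mean_step_count']:.2f} (expected {b['expected_step_count']:.2f})"
                f" -> {'ok' if b['pass_force'] else 'FAIL'}"
            )
        elif b["kind"] == "image":
            for key in ("rq_nm", "stripe_wavelength_nm"):
                if b.get(key) is not None and key in b:
                    rows.append({"batch": b["scene"], "kind": "image",
                                 "measured": b[key], "expected": np.nan,
                                 "metric": key, "passed": True})
            lines.append(f"[image] {b['scene']}: " + ", ".join(
                f"{k}={v}" for k, v in b.items() if k not in ("kind", "scene")))
        else:
            rows.append({"batch": f"dls-{b['true_diameter_nm']:g}nm", "kind": "dls",
                         "measured": b["recovered_mode_nm"],
                         "expected": b["true_diameter_nm"],
                         "metric": "mode_nm", "passed": b["pass_mode"]})
            lines.append(
                f"[dls] {b['true_diameter_nm']:g} nm -> mode "
                f"{b['recovered_mode_nm']:.1f} nm ({b['grid_cell_error']:.2f} cells)"
                f" -> {'ok' if b['pass_mode'] else 'FAIL'}"
            )
    pd.DataFrame(rows).to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text("\n".join(lines) + "\n")
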