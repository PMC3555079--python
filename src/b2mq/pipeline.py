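"""End-to-end synthetic pipeline driver.

Runs generator -> TIRF quantification -> morphometry -> ephys -> report on
seeded synthetic data and writes CSV tables plus a JSON report.  Output is
bit-for-bit reproducible under a fixed config (the report header records
the package version, a config hash and the seeds, never wall-clock time).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ephys, morphometry, stats, tirf
from .config import PipelineConfig
from .synthetic import (
    NeuronSpec,
    TirfCellSpec,
    VcCellSpec,
    generate_neuron_image,
    generate_tirf_pair,
    simulate_vc,
)

STAGES = ("tirf", "morphometry", "ephys", "report")


def _stage_fail(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"pipeline stage '{stage}' failed: {exc}")


def cell_mean_ratio(beta, fm, truth, n_segments: int, seed: int) -> float:
    """Per-cell mean border-to-center ratio on the protein channel."""
    mask = tirf.detect_cell_edge(fm)
    segments = tirf.place_radial_segments(
        mask, n_segments, seed, beta.pixel_size_um, avoid_masks=truth.process_masks)
    ratios = []
    for seg in segments:
        profile = tirf.radial_profile(beta, seg, mask)
        ratios.append(tirf.border_to_center_ratio(profile))
    return float(np.mean(ratios))


def _tirf_stage(config: PipelineConfig, out: Path) -> dict:
    rows = []
    groups = {}
    for label, rho in (("enriched", config.enrichment_rho), ("uniform", 1.0)):
        ratios = []
        for i in range(config.n_tirf_cells):
            spec = TirfCellSpec(enrichment_rho=rho, seed=config.seed * 10007 + i,
                                pixel_size_um=config.pixel_size_um)
            beta, fm, truth = generate_tirf_pair(spec)
            r = cell_mean_ratio(beta, fm, truth, config.n_segments,
                                seed=config.seed * 10007 + i)
            ratios.append(r)
            rows.append({"condition": label, "cell": i, "ratio_mean": r,
                         "n_segments": config.n_segments})
        groups[label] = ratios
    pd.DataFrame(rows).to_csv(out / "border_to_center.csv", index=False)
    return groups


def _morphometry_stage(config: PipelineConfig, out: Path) -> dict:
    rows = []
    groups = {}
    for label, density in (("high", config.filopodia_density_high),
                           ("low", config.filopodia_density_low)):
        counts = []
        for i in range(config.n_neurons):
            spec = NeuronSpec(filopodia_density=density,
                              seed=config.seed * 20011 + i,
                              pixel_size_um=config.pixel_size_um)
            img, truth = generate_neuron_image(spec)
            _, processes, _ = morphometry.segment_processes(img)
            selections = morphometry.sample_dendrite_selections(
                truth, config.n_segments, seed=config.seed * 20011 + i,
                length_um=config.selection_length_um)
            per_sel = [
                morphometry.count_filopodia_per_selection(
                    sel, processes, truth.pixel_size_um,
                    expected_length_um=config.selection_length_um)
                for sel in selections
            ]
            index = morphometry.branching_area_index(
                img, truth.soma_mask, sigma_highpass_um=config.highpass_sigma_um)
            counts.append(float(np.mean(per_sel)))
            rows.append({"condition": label, "neuron": i,
                         "mean_count_per_20um": counts[-1],
                         "branching_index_percent": index.value_percent})
        groups[label] = counts
    pd.DataFrame(rows).to_csv(out / "morphometry.csv", index=False)
    return groups


def _ephys_stage(config: PipelineConfig, out: Path) -> dict:
    rows = []
    v_halves = []
    rng = np.random.default_rng(config.seed)
    results = []
    for i in range(config.n_vc_cells):
        spec = VcCellSpec(
            Gmax_nS=float(rng.uniform(5, 25)),
            Ra_MOhm=float(rng.uniform(5, 12)),
            Cm_pF=float(rng.uniform(8, 15)),
            seed=config.seed * 30013 + i,
        )
        sweeps = simulate_vc(spec)
        res = ephys.analyze_cell(sweeps, e_rev_mV=config.e_rev_mV,
                                 temperature_K=config.temperature_K,
                                 cell_id=f"cell{i}")
        results.append(res)
    retained, exclusions = ephys.qc_filter(results, ra_max_MOhm=config.ra_max_MOhm)
    for res in retained:
        v_halves.append(res.fit.v_half_mV)
        rows.append({
            "cell": res.cell_id, "Ra_MOhm": res.passive.Ra_MOhm,
            "Cm_pF": res.passive.Cm_pF, "V_half_mV": res.fit.v_half_mV,
            "slope_mV": res.fit.slope_mV, "q_gating": res.fit.q_gating,
            "Gmax_nS": res.fit.gmax_nS,
            "specific_nS_per_pF": res.specific_nS_per_pF,
        })
    pd.DataFrame(rows).to_csv(out / "ephys.csv", index=False)
    (out / "ephys_exclusions.json").write_text(json.dumps(
        [{"cell": c, "reason": r} for c, r in exclusions], indent=2))
    return {"v_half": v_halves}


def run_pipeline(config: PipelineConfig, out_dir, stages=None) -> Path:
    """Run the synthetic end-to-end pipeline; returns the report directory."""
    stages = tuple(stages) if stages else STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report_groups: dict = {}
    if "tirf" in stages:
        try:
            g = _tirf_stage(config, out)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise _stage_fail("tirf", exc) from exc
        report_groups["border_to_center"] = {
            "groups": [stats.summarize(v, k) for k, v in g.items() if v]}
    if "morphometry" in stages:
        try:
            g = _morphometry_stage(config, out)
        except Exception as exc:  # noqa: BLE001
            raise _stage_fail("morphometry", exc) from exc
        payload = {"groups": [stats.summarize(v, k, "per 20 um") for k, v in g.items() if v]}
        if all(len(v) >= 2 for v in g.values()):
            payload["comparisons"] = [stats.compare(g["high"], g["low"], "high", "low",
                                                    unit="per 20 um")]
        report_groups["filopodia_counts"] = payload
    if "ephys" in stages:
        try:
            g = _ephys_stage(config, out)
        except Exception as exc:  # noqa: BLE001
            raise _stage_fail("ephys", exc) from exc
        report_groups["activation"] = {
            "groups": [stats.summarize(v, k, "mV") for k, v in g.items() if v]}

    if "report" in stages:
        report = stats.build_report(report_groups)
        header = {
            "package": "b2mq",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        }
        payload = {"header": header, "notices": report["notices"], "tables": {}}
        for name, df in report["tables"].items():
            df.to_csv(out / f"report_{name}.csv", index=False)
            payload["tables"][name] = json.loads(df.to_json(orient="records"))
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "config.json").write_text(config.to_json())
    return out
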