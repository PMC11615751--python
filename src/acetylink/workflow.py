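"""Stage orchestration: the full synthetic experiment as one pipeline run.

Stages: simulate -> quantify (ChIP signal + FPKM) -> differential (ChIP, RNA)
-> link -> correlate -> classify -> summarize -> rank, with a machine-readable
run manifest. Each stage is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .differential_stats import nb_differential, write_differential_table
from .genomic_io import write_integration_table
from .integration import (
    IntegrationConfig,
    attach_fold_changes,
    classify_quadrants,
    correlate_links,
    link_peaks_to_genes,
    quadrant_summary,
    rank_top_peak_genes,
)
from .signal_quant import compute_fpkm, estimate_background_scale, normalize_peak_signal
from .synthetic_data import SimulatedDataset, SimulationConfig, evaluate_recovery, simulate_dataset

logger = logging.getLogger("acetylink")

__all__ = ["PipelineConfig", "PipelineResult", "run_integration_stages", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "acetylink_run"
    seed: int = 0
    top_k: int = 20
    correlation_method: str = "pearson"
    use_background_scale: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = SimulationConfig(**{
            **raw.get("simulation", {}),
            **({"seed": overrides["seed"]} if "seed" in overrides else {}),
        })
        integ = IntegrationConfig(**raw.get("integration", {}))
        top = {k: v for k, v in raw.items() if k not in {"simulation", "integration"}}
        top.update(overrides)
        return cls(simulation=sim, integration=integ, **top)


@dataclass
class PipelineResult:
    links: list
    chip_diff: list
    rna_diff: list
    summary: dict
    top_links: list
    recovery: object  # RecoveryReport when truth is available
    manifest: dict


def run_integration_stages(
    dataset: SimulatedDataset,
    config: IntegrationConfig = IntegrationConfig(),
    correlation_method: str = "pearson",
    use_background_scale: bool = True,
):
    """Quantify, test, link, correlate and classify one (simulated) dataset."""
    background = None
    if use_background_scale:
        estimates = estimate_background_scale(
            dataset.chip_bins,
            dataset.input_bins,
            dataset.sample_sheet,
            dataset.pairing,
            bin_width=dataset.config.bin_width,
            region_span=dataset.config.bin_width * dataset.config.n_background_bins,
        )
        background = {e.sample_id: e for e in estimates}
    signal = normalize_peak_signal(
        dataset.chip_counts,
        dataset.input_counts,
        dataset.peaks,
        dataset.sample_sheet,
        dataset.pairing,
        background=background,
    )
    fpkm = compute_fpkm(dataset.gene_counts, dataset.genes, dataset.sample_sheet)
    chip_diff = nb_differential(dataset.chip_counts, dataset.sample_sheet, assay="chip")
    rna_diff = nb_differential(dataset.gene_counts, dataset.sample_sheet, assay="rna")
    links = link_peaks_to_genes(dataset.peaks, dataset.genes, config.window_bp)
    links = attach_fold_changes(links, chip_diff, rna_diff)
    links = correlate_links(
        links, signal, fpkm, dataset.chip_samples, dataset.rna_samples,
        config=config, method=correlation_method,
    )
    links = classify_quadrants(links, config)
    return links, chip_diff, rna_diff, signal, fpkm


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic experiment and write all stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    failure_marker = out / "FAILED"

    def stage(name):
        logger.info("stage %s: start", name)
        return time.perf_counter()

    try:
        t = stage("simulate")
        sim_cfg = config.simulation
        if sim_cfg.seed != config.seed:
            sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "seed": config.seed})
        dataset = simulate_dataset(sim_cfg)
        dataset.write(out / "simulated")
        timings["simulate"] = time.perf_counter() - t

        t = stage("integrate")
        links, chip_diff, rna_diff, _, _ = run_integration_stages(
            dataset,
            config.integration,
            correlation_method=config.correlation_method,
            use_background_scale=config.use_background_scale,
        )
        write_differential_table(chip_diff, out / "chip_differential.tsv")
        write_differential_table(rna_diff, out / "rna_differential.tsv")
        write_integration_table(links, out / "integration.tsv")
        timings["integrate"] = time.perf_counter() - t

        t = stage("summarize")
        summary = quadrant_summary(links)
        top = rank_top_peak_genes(links, config.top_k)
        write_integration_table(top, out / "top_peak_genes.tsv")
        recovery = evaluate_recovery(dataset.truth, links)
        with open(out / "quadrant_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(out / "recovery.json", "w") as fh:
            json.dump(recovery.to_dict(), fh, indent=2)
        timings["summarize"] = time.perf_counter() - t
    except Exception as exc:
        failure_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "simulation": asdict(sim_cfg),
        "integration": asdict(config.integration),
        "correlation_method": config.correlation_method,
        "differential_thresholds": {"p_max": 0.05, "lfc_min": 1.0},
        "timings_s": timings,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        links=links,
        chip_diff=chip_diff,
        rna_diff=rna_diff,
        summary=summary,
        top_links=top,
        recovery=recovery,
        manifest=manifest,
    )
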