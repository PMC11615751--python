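"""Coupled ChIP/input/RNA count simulator with planted PP/NN/PN/NP structure.

Stands in for the unavailable rat sequencing data: two conditions with a
configurable number of replicates, negative-binomial counts for peaks, input,
background bins and genes, condition effects on the log2 scale, and planted
peak-gene couplings whose cross-correlation is induced by a shared per-sample
latent factor. Fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import (
    CountMatrix,
    GeneRecord,
    PeakRecord,
    SampleRecord,
    SampleSheet,
    write_gene_annotation_gtf,
    write_peaks,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "RecoveryReport",
    "simulate_dataset",
    "evaluate_recovery",
]

CLASSES = ("PP", "NN", "PN", "NP")
# (chip sign, rna sign) per planted class
_CLASS_SIGNS = {"PP": (1, 1), "NN": (-1, -1), "PN": (1, -1), "NP": (-1, 1)}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_per_group: int = 3
    n_genes: int = 400
    n_peaks: int = 350
    n_coupled: int = 200
    frac_pp: float = 0.25
    frac_nn: float = 0.25
    frac_pn: float = 0.25
    frac_np: float = 0.25
    n_null_pairs: int = 100
    chip_effect_log2: float = 2.0
    rna_effect_log2: float = 6.0
    nb_dispersion: float = 0.1
    base_mean_chip: float = 100.0
    base_mean_rna: float = 200.0
    latent_sd_log2: float = 0.3
    input_enrichment: float = 3.0
    bin_mean: float = 10.0
    n_background_bins: int = 2000
    bin_width: int = 20
    genome: tuple = (("chr1", 60_000_000), ("chr2", 60_000_000))
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        fracs = self.frac_pp + self.frac_nn + self.frac_pn + self.frac_np
        if fracs > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        if self.n_coupled + self.n_null_pairs > min(self.n_genes, self.n_peaks):
            raise ValueError("n_coupled + n_null_pairs exceeds n_genes or n_peaks")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 replicates per group")


@dataclass
class SimulationTruth:
    """Planted pair labels and per-feature log2 effects."""

    pairs: list  # (peak_id, gene_id, class in CLASSES + ("null",))
    peak_effects: dict
    gene_effects: dict

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("peak_id\tgene_id\tplanted_class\tchip_effect_log2\trna_effect_log2\n")
            for pid, gid, cls in self.pairs:
                fh.write(
                    f"{pid}\t{gid}\t{cls}\t{self.peak_effects.get(pid, 0.0)!r}\t"
                    f"{self.gene_effects.get(gid, 0.0)!r}\n"
                )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    peaks: list
    genes: list
    chip_counts: CountMatrix
    input_counts: CountMatrix
    chip_bins: CountMatrix
    input_bins: CountMatrix
    gene_counts: CountMatrix
    sample_sheet: SampleSheet
    pairing: dict  # chip sample -> input sample
    chip_samples: list  # bio-ordered chip sample ids
    rna_samples: list  # matching rna sample ids
    truth: SimulationTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_peaks(self.peaks, out / "peaks.bed")
        write_gene_annotation_gtf(self.genes, out / "genes.gtf")
        self.chip_counts.write_tsv(out / "chip_counts.tsv")
        self.input_counts.write_tsv(out / "input_counts.tsv")
        self.chip_bins.write_tsv(out / "chip_bins.tsv")
        self.input_bins.write_tsv(out / "input_bins.tsv")
        self.gene_counts.write_tsv(out / "gene_counts.tsv")
        self.sample_sheet.write_tsv(out / "samples.tsv")
        self.truth.write_tsv(out / "truth.tsv")
        with open(out / "pairing.tsv", "w") as fh:
            fh.write("chip_sample\tinput_sample\trna_sample\n")
            for c, r in zip(self.chip_samples, self.rna_samples):
                fh.write(f"{c}\t{self.pairing[c]}\t{r}\n")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha*mean^2; Poisson limit at alpha ~ 0."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion <= 1e-12:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    cfg = config
    for chrom, length in cfg.genome:
        if length < 2 * cfg.window_bp + 20_000:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) too small to place features "
                f"within a {cfg.window_bp} bp window"
            )

    # --- planted class assignment -------------------------------------------------
    n_per_class = [int(round(cfg.n_coupled * f)) for f in
                   (cfg.frac_pp, cfg.frac_nn, cfg.frac_pn, cfg.frac_np)]
    while sum(n_per_class) > cfg.n_coupled:
        n_per_class[int(np.argmax(n_per_class))] -= 1
    classes = [c for c, n in zip(CLASSES, n_per_class) for _ in range(n)]
    classes += ["null"] * (cfg.n_coupled - len(classes) + cfg.n_null_pairs)
    n_pairs = len(classes)

    # --- geometry -----------------------------------------------------------------
    chrom_names = [c for c, _ in cfg.genome]
    chrom_lens = np.array([l for _, l in cfg.genome], dtype=float)
    genes: list[GeneRecord] = []
    peaks: list[PeakRecord] = []

    def place_gene(i: int) -> GeneRecord:
        ci = int(rng.integers(len(chrom_names)))
        lo, hi = cfg.window_bp, int(chrom_lens[ci]) - cfg.window_bp
        tss = int(rng.integers(lo, hi))
        length = int(rng.integers(1_000, 10_001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss + 1 - length, tss + 1
        return GeneRecord(f"gene{i:05d}", chrom_names[ci], start, end, strand)

    def place_peak_near(i: int, gene: GeneRecord) -> PeakRecord:
        width = int(rng.integers(500, 2_001))
        offset = int(rng.integers(-cfg.window_bp // 2, cfg.window_bp // 2 + 1))
        start = max(0, gene.tss + offset - width // 2)
        return PeakRecord(f"peak{i:05d}", gene.chrom, start, start + width)

    pairs: list[tuple[str, str, str]] = []
    for i, cls in enumerate(classes):
        g = place_gene(i)
        p = place_peak_near(i, g)
        genes.append(g)
        peaks.append(p)
        pairs.append((p.peak_id, g.gene_id, cls))
    for i in range(n_pairs, cfg.n_genes):
        genes.append(place_gene(i))
    for i in range(n_pairs, cfg.n_peaks):
        ci = int(rng.integers(len(chrom_names)))
        width = int(rng.integers(500, 2_001))
        start = int(rng.integers(0, int(chrom_lens[ci]) - width))
        peaks.append(PeakRecord(f"peak{i:05d}", chrom_names[ci], start, start + width))

    # --- samples ------------------------------------------------------------------
    n = cfg.n_per_group
    bio = [f"control{k + 1}" for k in range(n)] + [f"case{k + 1}" for k in range(n)]
    is_case = np.array([0] * n + [1] * n, dtype=float)
    nominal = {"chip": 20_000_000, "input": 20_000_000, "rna": 30_000_000}
    records, libscale = [], {}
    for b in bio:
        cond = "control" if b.startswith("control") else "case"
        for assay in ("chip", "input", "rna"):
            sid = f"{b}_{assay}"
            size = int(round(nominal[assay] * rng.uniform(0.9, 1.1)))
            records.append(SampleRecord(sid, cond, assay, size))
            libscale[sid] = size / nominal[assay]
    sheet = SampleSheet(records)
    chip_samples = [f"{b}_chip" for b in bio]
    input_samples = [f"{b}_input" for b in bio]
    rna_samples = [f"{b}_rna" for b in bio]
    pairing = dict(zip(chip_samples, input_samples))
    chip_lib = np.array([libscale[s] for s in chip_samples])
    input_lib = np.array([libscale[s] for s in input_samples])
    rna_lib = np.array([libscale[s] for s in rna_samples])

    # --- per-feature baselines and effects ----------------------------------------
    peak_base = cfg.base_mean_chip * 2.0 ** rng.normal(0.0, 0.25, size=cfg.n_peaks)
    gene_base = cfg.base_mean_rna * 2.0 ** rng.normal(0.0, 0.25, size=cfg.n_genes)
    peak_effect = np.zeros(cfg.n_peaks)
    gene_effect = np.zeros(cfg.n_genes)
    corr_sign = np.zeros(n_pairs)
    for i, cls in enumerate(classes):
        if cls == "null":
            continue
        cs, rs = _CLASS_SIGNS[cls]
        peak_effect[i] = cs * cfg.chip_effect_log2
        gene_effect[i] = rs * cfg.rna_effect_log2
        corr_sign[i] = cs * rs

    # --- count matrices -----------------------------------------------------------
    # shared per-sample latent factor couples peak and gene counts of planted pairs
    latent = rng.normal(0.0, cfg.latent_sd_log2, size=(n_pairs, 2 * n))

    chip_mu = peak_base[:, None] * 2.0 ** (peak_effect[:, None] * is_case[None, :])
    chip_mu[:n_pairs] *= 2.0 ** (np.abs(corr_sign)[:, None] * latent)
    chip_mu *= chip_lib[None, :]
    chip_counts = CountMatrix(
        [p.peak_id for p in peaks], chip_samples,
        _nb_draw(rng, chip_mu, cfg.nb_dispersion), "peak",
    )

    input_mu = (peak_base / cfg.input_enrichment)[:, None] * input_lib[None, :]
    input_counts = CountMatrix(
        [p.peak_id for p in peaks], input_samples,
        _nb_draw(rng, input_mu, cfg.nb_dispersion), "peak",
    )

    gene_mu = gene_base[:, None] * 2.0 ** (gene_effect[:, None] * is_case[None, :])
    gene_mu[:n_pairs] *= 2.0 ** (corr_sign[:, None] * latent)
    gene_mu *= rna_lib[None, :]
    gene_counts = CountMatrix(
        [g.gene_id for g in genes], rna_samples,
        _nb_draw(rng, gene_mu, cfg.nb_dispersion), "gene",
    )

    bin_ids = [f"bin{i:06d}" for i in range(cfg.n_background_bins)]
    bin_mu_chip = np.full((cfg.n_background_bins, 2 * n), cfg.bin_mean) * chip_lib[None, :]
    bin_mu_input = np.full((cfg.n_background_bins, 2 * n), cfg.bin_mean) * input_lib[None, :]
    chip_bins = CountMatrix(bin_ids, chip_samples, _nb_draw(rng, bin_mu_chip, cfg.nb_dispersion), "bin")
    input_bins = CountMatrix(bin_ids, input_samples, _nb_draw(rng, bin_mu_input, cfg.nb_dispersion), "bin")

    truth = SimulationTruth(
        pairs=pairs,
        peak_effects={peaks[i].peak_id: float(peak_effect[i]) for i in range(n_pairs)},
        gene_effects={genes[i].gene_id: float(gene_effect[i]) for i in range(n_pairs)},
    )
    return SimulatedDataset(
        config=cfg,
        peaks=peaks,
        genes=genes,
        chip_counts=chip_counts,
        input_counts=input_counts,
        chip_bins=chip_bins,
        input_bins=input_bins,
        gene_counts=gene_counts,
        sample_sheet=sheet,
        pairing=pairing,
        chip_samples=chip_samples,
        rna_samples=rna_samples,
        truth=truth,
    )


@dataclass
class RecoveryReport:
    recall: dict
    precision: dict
    null_false_rate: float
    confusion: dict  # truth class -> {label: count}
    n_truth_pairs: int

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "null_false_rate": self.null_false_rate,
            "confusion": self.confusion,
            "n_truth_pairs": self.n_truth_pairs,
        }


def evaluate_recovery(truth: SimulationTruth, links: Sequence) -> RecoveryReport:
    """Score classified links against the planted pair labels.

    Every planted pair must appear among the links (they are placed within the
    window by construction); links with no planted label count as truth-null
    for precision purposes.
    """
    labels = {(ln.peak_id, ln.gene_id): ln.quadrant for ln in links}
    confusion: dict[str, dict[str, int]] = {}
    for pid, gid, cls in truth.pairs:
        if (pid, gid) not in labels:
            raise ValueError(f"planted pair ({pid!r}, {gid!r}) missing from links")
        lab = labels[(pid, gid)]
        confusion.setdefault(cls, {}).setdefault(lab, 0)
        confusion[cls][lab] += 1
    truth_by_pair = {(pid, gid): cls for pid, gid, cls in truth.pairs}
    recall, precision = {}, {}
    for cls in CLASSES:
        planted = [p for p, c in truth_by_pair.items() if c == cls]
        hit = sum(1 for p in planted if labels[p] == cls)
        recall[cls] = hit / len(planted) if planted else float("nan")
        labeled = [p for p, lab in labels.items() if lab == cls]
        tp = sum(1 for p in labeled if truth_by_pair.get(p) == cls)
        precision[cls] = tp / len(labeled) if labeled else float("nan")
    nulls = [p for p, c in truth_by_pair.items() if c == "null"]
    null_false = sum(1 for p in nulls if labels[p] != "NS")
    null_false_rate = null_false / len(nulls) if nulls else 0.0
    return RecoveryReport(
        recall=recall,
        precision=precision,
        null_false_rate=null_false_rate,
        confusion=confusion,
        n_truth_pairs=len(truth.pairs),
    )
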