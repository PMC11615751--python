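"""Normalization of raw counts into per-peak signal and per-gene FPKM.

Per-peak ChIP signal is depth- and length-normalized (RPKM-style constant
K = 1e9), background-scaled input density is subtracted, and the result is
floored at zero. Differential testing operates on raw counts elsewhere; the
matrices produced here feed the correlation stage only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import CountMatrix, GeneRecord, PeakRecord, SampleSheet

__all__ = [
    "NormalizedSignalMatrix",
    "BackgroundEstimate",
    "read_signal_matrix",
    "compute_fpkm",
    "normalize_peak_signal",
    "estimate_background_scale",
    "quantify_bam_over_intervals",
]

SCALE_K = 1e9  # per-kilobase-per-million style constant; cancels in fold changes


@dataclass
class NormalizedSignalMatrix:
    """Features x samples matrix of non-negative real signal."""

    feature_ids: list[str]
    sample_ids: list[str]
    signal: np.ndarray
    normalization_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("signal shape does not match feature/sample ids")
        if (self.signal < 0).any():
            raise ValueError("normalized signal must be non-negative")

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError as exc:
            raise KeyError(f"feature {feature_id!r} not in signal matrix") from exc
        return self.signal[i]

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"sample {sample_id!r} not in signal matrix") from exc
        return self.signal[:, j]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\t" + "\t".join(self.sample_ids) + "\n")
            for fid, row in zip(self.feature_ids, self.signal):
                fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_signal_matrix(path) -> NormalizedSignalMatrix:
    with open(path) as fh:
        sample_ids = fh.readline().rstrip("\n").split("\t")[1:]
        feature_ids, rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(sample_ids) + 1:
                raise ValueError(f"{path}: line {lineno}: ragged row")
            feature_ids.append(cols[0])
            rows.append([float(v) for v in cols[1:]])
    return NormalizedSignalMatrix(feature_ids, sample_ids, np.array(rows))


@dataclass(frozen=True)
class BackgroundEstimate:
    """ChIP-to-input coverage ratio estimated over background bins."""

    sample_id: str
    scale_factor: float
    n_bins_used: int
    bin_width: int = 20
    region_span: int = 1_000_000

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.n_bins_used < 1:
            raise ValueError("n_bins_used must be >= 1")


def compute_fpkm(
    gene_counts: CountMatrix,
    genes: Sequence[GeneRecord],
    samples: SampleSheet,
) -> NormalizedSignalMatrix:
    """FPKM(g, s) = count(g, s) * 1e9 / (gene_length(g) * library_size(s))."""
    by_id = {g.gene_id: g for g in genes}
    lengths = np.empty(len(gene_counts.feature_ids))
    for i, gid in enumerate(gene_counts.feature_ids):
        gene = by_id.get(gid)
        if gene is None:
            raise ValueError(f"gene {gid!r} has no annotation record (missing gene_length)")
        lengths[i] = gene.gene_length
    libsizes = np.empty(len(gene_counts.sample_ids))
    for j, sid in enumerate(gene_counts.sample_ids):
        if sid not in samples:
            raise ValueError(f"sample {sid!r} missing from sample sheet")
        libsizes[j] = samples.library_size(sid)
    fpkm = gene_counts.counts * SCALE_K / (lengths[:, None] * libsizes[None, :])
    return NormalizedSignalMatrix(
        list(gene_counts.feature_ids),
        list(gene_counts.sample_ids),
        fpkm,
        normalization_meta={"method": "fpkm", "scale_constant": SCALE_K},
    )


def normalize_peak_signal(
    chip: CountMatrix,
    input_: CountMatrix,
    peaks: Sequence[PeakRecord],
    samples: SampleSheet,
    pairing: Mapping[str, str],
    background: Mapping[str, BackgroundEstimate] | None = None,
) -> NormalizedSignalMatrix:
    """Depth/length-normalized ChIP density minus scaled input density, floored at 0.

    For peak p, ChIP sample s paired to input sample t:
    ``signal = max(0, c(p,s)*K/(N_s*L_p) - beta * i(p,t)*K/(N_t*L_p))`` with
    beta the background scale factor (1.0 when no estimate is supplied).
    """
    if chip.feature_ids != input_.feature_ids:
        raise ValueError("chip and input matrices must share feature_ids")
    by_id = {p.peak_id: p for p in peaks}
    lengths = np.empty(len(chip.feature_ids))
    for i, pid in enumerate(chip.feature_ids):
        peak = by_id.get(pid)
        if peak is None:
            raise ValueError(f"peak {pid!r} in count matrix missing from peak list")
        lengths[i] = peak.length
    betas: dict[str, float] = {}
    signal = np.empty_like(chip.counts, dtype=float)
    for j, s in enumerate(chip.sample_ids):
        t = pairing.get(s)
        if t is None:
            raise ValueError(f"chip sample {s!r} has no paired input sample")
        beta = 1.0
        if background is not None and s in background:
            beta = background[s].scale_factor
        betas[s] = beta
        dens_chip = chip.column(s) * SCALE_K / (samples.library_size(s) * lengths)
        dens_input = input_.column(t) * SCALE_K / (samples.library_size(t) * lengths)
        signal[:, j] = np.maximum(0.0, dens_chip - beta * dens_input)
    return NormalizedSignalMatrix(
        list(chip.feature_ids),
        list(chip.sample_ids),
        signal,
        normalization_meta={
            "method": "input_subtracted_density",
            "scale_constant": SCALE_K,
            "background_scale": betas,
            "pairing": dict(pairing),
        },
    )


def estimate_background_scale(
    chip_bins: CountMatrix,
    input_bins: CountMatrix,
    samples: SampleSheet,
    pairing: Mapping[str, str],
    stat: str = "median",
    bin_width: int = 20,
    region_span: int = 1_000_000,
) -> list[BackgroundEstimate]:
    """Per ChIP/input pair, the median (or mean) over background bins of the
    depth-normalized coverage ratio; bins with zero input are excluded."""
    if chip_bins.feature_ids != input_bins.feature_ids:
        raise ValueError("chip and input bin matrices must share features")
    if chip_bins.feature_kind != "bin" or input_bins.feature_kind != "bin":
        raise ValueError("background matrices must have feature_kind 'bin'")
    if stat not in {"median", "mean"}:
        raise ValueError(f"unknown stat {stat!r}")
    reduce = np.median if stat == "median" else np.mean
    estimates = []
    for s in chip_bins.sample_ids:
        t = pairing.get(s)
        if t is None:
            raise ValueError(f"chip sample {s!r} has no paired input sample")
        c = chip_bins.column(s).astype(float)
        i = input_bins.column(t).astype(float)
        mask = i > 0
        if not mask.any():
            raise ValueError(f"pair ({s!r}, {t!r}): no background bin with input > 0")
        ratios = (c[mask] / samples.library_size(s)) / (i[mask] / samples.library_size(t))
        estimates.append(
            BackgroundEstimate(
                sample_id=s,
                scale_factor=float(reduce(ratios)),
                n_bins_used=int(mask.sum()),
                bin_width=bin_width,
                region_span=region_span,
            )
        )
    return estimates


def quantify_bam_over_intervals(
    bam_path: str,
    intervals: Sequence[PeakRecord],
    sample_id: str | None = None,
) -> CountMatrix:
    """Sum of per-base read depth within each interval (samtools bedcov
    semantics), returned as a one-sample CountMatrix. Requires an indexed,
    coordinate-sorted BAM."""
    import pysam

    try:
        bam = pysam.AlignmentFile(bam_path, "rb", require_index=True)
    except (ValueError, FileNotFoundError) as exc:
        raise ValueError(f"{bam_path}: missing or unreadable BAM index") from exc
    with bam:
        contigs = set(bam.references)
        values = np.zeros(len(intervals), dtype=np.int64)
        for i, iv in enumerate(intervals):
            if iv.chrom not in contigs:
                raise ValueError(f"contig {iv.chrom!r} absent from BAM header")
            cov = bam.count_coverage(iv.chrom, iv.start, iv.end, quality_threshold=0)
            values[i] = int(np.asarray(cov).sum())
    name = sample_id or bam_path
    return CountMatrix([p.peak_id for p in intervals], [name], values[:, None], "peak")
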