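"""Peak-to-gene linking, peak-gene correlation and four-way classification.

A peak and a gene are linked when the gene's TSS lies within a configurable
window (default 1 Mb) of the peak's nearest edge, many-to-many. Linked pairs
are correlated across samples (ChIP signal vs expression), classified into
PP/NN/PN/NP quadrants by strict fold-change thresholds, and ranked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .differential_stats import DifferentialRow, pearson_corr
from .genomic_io import GeneRecord, PeakRecord
from .signal_quant import NormalizedSignalMatrix

__all__ = [
    "PeakGeneLink",
    "IntegrationConfig",
    "link_peaks_to_genes",
    "correlate_links",
    "attach_fold_changes",
    "classify_quadrants",
    "rank_top_peak_genes",
    "quadrant_summary",
]

QUADRANTS = ("PP", "NN", "PN", "NP")


@dataclass
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance_bp: int
    chip_log2fc: float | None = None
    rna_log2fc: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    correlated: bool = False
    quadrant: str = "NS"


@dataclass(frozen=True)
class IntegrationConfig:
    window_bp: int = 1_000_000
    r_min: float = 0.5
    p_max: float = 0.05
    chip_lfc_min: float = 1.0
    rna_lfc_min: float = 5.0
    signed_r: bool = False  # when True, require r >= r_min instead of |r| >= r_min

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must lie in (0, 1)")
        if self.r_min <= 0 or self.chip_lfc_min <= 0 or self.rna_lfc_min <= 0:
            raise ValueError("thresholds must be positive")


def tss_to_peak_distance(peak: PeakRecord, tss: int) -> int:
    """Gap between a TSS and the nearest peak edge; 0 inside the peak."""
    return max(peak.start - tss, tss - peak.end, 0)


def link_peaks_to_genes(
    peaks: Sequence[PeakRecord],
    genes: Sequence[GeneRecord],
    window_bp: int = 1_000_000,
) -> list[PeakGeneLink]:
    """All (peak, gene) pairs on the same chromosome with TSS within
    ``window_bp`` of the peak (boundary inclusive), sorted by
    (peak_id, distance_bp, gene_id)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = [g for g in genes if g.chrom == chrom]
        by_chrom[chrom] = (np.array([g.tss for g in sub]), [g.gene_id for g in sub])
    links: list[PeakGeneLink] = []
    for peak in peaks:
        entry = by_chrom.get(peak.chrom)
        if entry is None:
            continue
        tss, gene_ids = entry
        dist = np.maximum(np.maximum(peak.start - tss, tss - peak.end), 0)
        for j in np.flatnonzero(dist <= window_bp):
            links.append(PeakGeneLink(peak.peak_id, gene_ids[j], int(dist[j])))
    links.sort(key=lambda ln: (ln.peak_id, ln.distance_bp, ln.gene_id))
    return links


def correlate_links(
    links: Sequence[PeakGeneLink],
    chip_signal: NormalizedSignalMatrix,
    expression: NormalizedSignalMatrix,
    chip_samples: Sequence[str],
    rna_samples: Sequence[str],
    config: IntegrationConfig = IntegrationConfig(),
    method: str = "pearson",
) -> list[PeakGeneLink]:
    """Fill pearson_r / pearson_p per link from paired sample columns.

    ``chip_samples[i]`` and ``rna_samples[i]`` must be the same biological
    sample; a zero-variance row keeps the link with r/p missing.
    """
    if len(chip_samples) != len(rna_samples):
        raise ValueError("chip and rna sample lists must pair one-to-one")
    if len(chip_samples) < 3:
        raise ValueError("correlation requires >= 3 paired samples")
    chip_idx = [chip_signal.sample_ids.index(s) for s in chip_samples]
    rna_idx = [expression.sample_ids.index(s) for s in rna_samples]
    chip_rows = {fid: i for i, fid in enumerate(chip_signal.feature_ids)}
    rna_rows = {fid: i for i, fid in enumerate(expression.feature_ids)}
    for ln in links:
        if ln.peak_id not in chip_rows:
            raise ValueError(f"link peak {ln.peak_id!r} missing from signal matrix")
        if ln.gene_id not in rna_rows:
            raise ValueError(f"link gene {ln.gene_id!r} missing from expression matrix")
        x = chip_signal.signal[chip_rows[ln.peak_id], chip_idx]
        y = expression.signal[rna_rows[ln.gene_id], rna_idx]
        try:
            res = pearson_corr(x, y, method=method)
        except ValueError:
            ln.pearson_r = None
            ln.pearson_p = None
            ln.correlated = False
            continue
        ln.pearson_r = res.r
        ln.pearson_p = res.p_value
        r_ok = res.r >= config.r_min if config.signed_r else abs(res.r) >= config.r_min
        ln.correlated = bool(r_ok and res.p_value < config.p_max)
    return list(links)


def attach_fold_changes(
    links: Sequence[PeakGeneLink],
    chip_diff: Sequence[DifferentialRow],
    rna_diff: Sequence[DifferentialRow],
) -> list[PeakGeneLink]:
    chip_fc = {r.feature_id: r.log2fc for r in chip_diff}
    rna_fc = {r.feature_id: r.log2fc for r in rna_diff}
    for ln in links:
        if ln.peak_id not in chip_fc:
            raise ValueError(f"link peak {ln.peak_id!r} missing from ChIP differential table")
        if ln.gene_id not in rna_fc:
            raise ValueError(f"link gene {ln.gene_id!r} missing from RNA differential table")
        ln.chip_log2fc = chip_fc[ln.peak_id]
        ln.rna_log2fc = rna_fc[ln.gene_id]
    return list(links)


def classify_quadrant(chip_lfc: float, rna_lfc: float, config: IntegrationConfig) -> str:
    """Strict-inequality four-way partition; anything else is NS."""
    c, r = config.chip_lfc_min, config.rna_lfc_min
    if chip_lfc > c and rna_lfc > r:
        return "PP"
    if chip_lfc < -c and rna_lfc < -r:
        return "NN"
    if chip_lfc > c and rna_lfc < -r:
        return "PN"
    if chip_lfc < -c and rna_lfc > r:
        return "NP"
    return "NS"


def classify_quadrants(
    links: Sequence[PeakGeneLink], config: IntegrationConfig = IntegrationConfig()
) -> list[PeakGeneLink]:
    for ln in links:
        if ln.chip_log2fc is None or ln.rna_log2fc is None:
            raise ValueError(f"link ({ln.peak_id}, {ln.gene_id}): fold changes not attached")
        ln.quadrant = classify_quadrant(ln.chip_log2fc, ln.rna_log2fc, config)
    return list(links)


def rank_top_peak_genes(links: Sequence[PeakGeneLink], k: int) -> list[PeakGeneLink]:
    """Top-k correlated PP/NN links by |chip_log2fc| * |rna_log2fc|, ties by
    larger |pearson_r|, then lexicographic (peak_id, gene_id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    eligible = [
        ln for ln in links if ln.quadrant in {"PP", "NN"} and ln.correlated
    ]

    def key(ln: PeakGeneLink):
        score = abs(ln.chip_log2fc) * abs(ln.rna_log2fc)
        r = abs(ln.pearson_r) if ln.pearson_r is not None else 0.0
        return (-score, -r, ln.peak_id, ln.gene_id)

    return sorted(eligible, key=key)[:k]


def quadrant_summary(links: Sequence[PeakGeneLink]) -> dict:
    """Counts per quadrant, classified total, NS count and unique-id tallies."""
    counts = Counter(ln.quadrant for ln in links)
    per_quadrant = {q: counts.get(q, 0) for q in QUADRANTS}
    total = sum(per_quadrant.values())
    assert total == sum(1 for ln in links if ln.quadrant != "NS")
    classified = [ln for ln in links if ln.quadrant != "NS"]
    return {
        **per_quadrant,
        "NS": counts.get("NS", 0),
        "total_classified": total,
        "unique_peaks_classified": len({ln.peak_id for ln in classified}),
        "unique_genes_classified": len({ln.gene_id for ln in classified}),
    }
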