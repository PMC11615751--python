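"""Readers and writers for the genomic and tabular formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals; GTF input
(1-based inclusive) is converted at the boundary. Malformed input is rejected
with an error naming the offending line, never silently repaired.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "GeneRecord",
    "CountMatrix",
    "SampleRecord",
    "SampleSheet",
    "read_peaks",
    "write_peaks",
    "read_gene_annotation",
    "write_gene_annotation_gtf",
    "read_count_matrix",
    "read_sample_sheet",
    "write_integration_table",
    "read_integration_table",
]

_INT_TOKEN = re.compile(r"[+-]?\d+")

_CONDITION_ALIASES = {
    "control": "control",
    "case": "case",
    "nd": "control",
    "masld": "case",
}

_ASSAYS = {"chip", "input", "rna"}


@dataclass(frozen=True)
class PeakRecord:
    """A peak interval in 0-based half-open coordinates."""

    peak_id: str
    chrom: str
    start: int
    end: int
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.peak_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a strand-aware TSS anchor.

    ``tss`` is ``start`` for + strand and ``end - 1`` (the 3' file coordinate
    in internal 0-based terms) for - strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.gene_length == 0:
            object.__setattr__(self, "gene_length", self.end - self.start)
        if self.gene_length < 1:
            raise ValueError(f"gene {self.gene_id!r}: gene_length must be >= 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(path: str | Path, format: str = "bed") -> list[PeakRecord]:
    """Read peak intervals from a BED or narrowPeak file.

    Only the first four columns are consulted; a missing or ``.`` name column
    yields a synthesized ``chrom:start-end`` identifier.
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unsupported peak format {format!r}")
    peaks: list[PeakRecord] = []
    seen: set[str] = set()
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if end <= start:
            raise ValueError(
                f"{path}: line {lineno}: empty or inverted interval [{start}, {end})"
            )
        name = cols[3] if len(cols) >= 4 and cols[3] not in {"", "."} else None
        peak_id = name if name is not None else f"{chrom}:{start}-{end}"
        if peak_id in seen:
            kind = "peak_id" if name else "synthesized peak_id"
            raise ValueError(f"{path}: line {lineno}: duplicate {kind} {peak_id!r}")
        seen.add(peak_id)
        peaks.append(PeakRecord(peak_id, chrom, start, end, source_line=lineno))
    return peaks


def write_peaks(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(
    path: str | Path,
    format: str = "gtf",
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Read gene records from a GTF (1-based inclusive, converted) or BED6 file."""
    if format not in {"gtf", "bed6"}:
        raise ValueError(f"unsupported annotation format {format!r}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, cols in _data_lines(path):
        if format == "gtf":
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            if cols[2] != feature_type:
                continue
            chrom, strand = cols[0], cols[6]
            try:
                start = int(cols[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            m = _GTF_GENE_ID.search(cols[8])
            if not m:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_id = m.group(1)
        else:
            if len(cols) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, strand, gene_id = cols[0], cols[5], cols[3]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
        if gene_id in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneRecord(gene_id, chrom, start, end, strand))
    return genes


def write_gene_annotation_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write genes as GTF ``gene`` features (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tacetylink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_kind: str = "peak"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.feature_kind not in {"peak", "gene", "bin"}:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"sample {sample_id!r} not in matrix") from exc
        return self.counts[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            list(self.feature_ids), list(sample_ids), self.counts[:, idx], self.feature_kind
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")


def read_count_matrix(path: str | Path, feature_kind: str = "peak") -> CountMatrix:
    """Read a TSV count matrix (header of sample ids, first column feature ids).

    Cells must be non-negative integer tokens; floats, negatives and ragged
    rows are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must name at least one sample")
        sample_ids = header[1:]
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: ragged row "
                    f"({len(cols)} columns, expected {len(header)})"
                )
            feature_ids.append(cols[0])
            row = []
            for cell in cols[1:]:
                if not _INT_TOKEN.fullmatch(cell):
                    raise ValueError(f"{path}: line {lineno}: non-integer cell {cell!r}")
                value = int(cell)
                if value < 0:
                    raise ValueError(f"{path}: line {lineno}: negative cell {cell!r}")
                row.append(value)
            rows.append(row)
    counts = np.array(rows, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    return CountMatrix(feature_ids, sample_ids, counts, feature_kind)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    condition: str  # control | case
    assay: str  # chip | input | rna
    library_size: int

    def __post_init__(self) -> None:
        if self.condition not in {"control", "case"}:
            raise ValueError(f"sample {self.sample_id!r}: condition must be control or case")
        if self.assay not in _ASSAYS:
            raise ValueError(f"sample {self.sample_id!r}: unknown assay {self.assay!r}")
        if self.library_size <= 0:
            raise ValueError(f"sample {self.sample_id!r}: library_size must be positive")


@dataclass
class SampleSheet:
    """Maps samples to condition, assay and total mapped read count."""

    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __getitem__(self, sample_id: str) -> SampleRecord:
        try:
            return self._by_id[sample_id]
        except KeyError as exc:
            raise KeyError(f"sample {sample_id!r} not in sample sheet") from exc

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def library_size(self, sample_id: str) -> int:
        return self[sample_id].library_size

    def select(self, assay: str | None = None, condition: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (assay is None or s.assay == assay)
            and (condition is None or s.condition == condition)
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tcondition\tassay\tlibrary_size\n")
            for s in self.samples:
                fh.write(f"{s.sample_id}\t{s.condition}\t{s.assay}\t{s.library_size}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet; ND/MASLD are accepted as control/case aliases."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "assay", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cond = _CONDITION_ALIASES.get(str(row["condition"]).strip().lower())
        if cond is None:
            raise ValueError(
                f"{path}: sample {row['sample_id']!r}: "
                f"unrecognized condition {row['condition']!r}"
            )
        try:
            libsize = int(row["library_size"])
        except ValueError as exc:
            raise ValueError(
                f"{path}: sample {row['sample_id']!r}: non-integer library_size"
            ) from exc
        records.append(
            SampleRecord(str(row["sample_id"]), cond, str(row["assay"]).strip().lower(), libsize)
        )
    return SampleSheet(records)


_INTEGRATION_COLUMNS = [
    "peak_id",
    "gene_id",
    "distance_bp",
    "chip_log2fc",
    "rna_log2fc",
    "pearson_r",
    "pearson_p",
    "quadrant",
]


def write_integration_table(links: Sequence, path: str | Path) -> None:
    """Serialize PeakGeneLink records as a TSV; missing r/p are written as NA."""
    with open(path, "w") as fh:
        fh.write("\t".join(_INTEGRATION_COLUMNS) + "\n")
        for ln in links:
            r = "NA" if ln.pearson_r is None else repr(float(ln.pearson_r))
            p = "NA" if ln.pearson_p is None else repr(float(ln.pearson_p))
            fh.write(
                f"{ln.peak_id}\t{ln.gene_id}\t{ln.distance_bp}\t"
                f"{ln.chip_log2fc!r}\t{ln.rna_log2fc!r}\t{r}\t{p}\t{ln.quadrant}\n"
            )


def read_integration_table(path: str | Path) -> list:
    from .integration import PeakGeneLink  # local import to avoid a cycle

    links: list[PeakGeneLink] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _INTEGRATION_COLUMNS:
            raise ValueError(f"{path}: unexpected integration table header")
        for lineno, raw in enumerate(fh, start=2):
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(_INTEGRATION_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: ragged row")
            links.append(
                PeakGeneLink(
                    peak_id=cols[0],
                    gene_id=cols[1],
                    distance_bp=int(cols[2]),
                    chip_log2fc=float(cols[3]),
                    rna_log2fc=float(cols[4]),
                    pearson_r=None if cols[5] == "NA" else float(cols[5]),
                    pearson_p=None if cols[6] == "NA" else float(cols[6]),
                    quadrant=cols[7],
                )
            )
    return links
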