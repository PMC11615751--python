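"""Self-contained statistics for the pipeline.

Negative-binomial two-group Wald test on count features (median-of-ratios
size factors, method-of-moments dispersion), Benjamini-Hochberg adjustment,
Pearson/Spearman correlation with a t-based p-value, and hypergeometric
over-representation against user-supplied gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_io import CountMatrix, SampleSheet

__all__ = [
    "DifferentialRow",
    "CorrelationResult",
    "EnrichmentResult",
    "size_factors",
    "nb_differential",
    "bh_adjust",
    "pearson_corr",
    "hypergeom_enrich",
    "enrich_gene_sets",
    "read_gmt",
    "write_differential_table",
    "read_differential_table",
]


@dataclass(frozen=True)
class DifferentialRow:
    feature_id: str
    base_mean: float
    log2fc: float  # case over control
    p_value: float
    p_adj: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adj: float = float("nan")


def size_factors(counts: CountMatrix | np.ndarray, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample scaling factors.

    The reference is the per-feature geometric mean across samples; features
    containing any zero are excluded unless ``pseudo_reference`` is set, in
    which case a 0.5 pseudocount is applied throughout.
    """
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    x = x.astype(float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("expected a features x samples matrix")
    if pseudo_reference:
        x = x + 0.5
        mask = np.ones(x.shape[0], dtype=bool)
    else:
        mask = (x > 0).all(axis=1)
        if not mask.any():
            raise ValueError(
                "no feature has all-positive counts; rerun with pseudo_reference=True "
                "(CLI: --pseudo-reference)"
            )
    logx = np.log(x[mask])
    ref = np.exp(logx.mean(axis=1))
    factors = np.median(x[mask] / ref[:, None], axis=0)
    return factors


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1, input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _moment_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray], floor: float) -> np.ndarray:
    """Per-feature NB dispersion alpha (var = mu + alpha*mu^2) pooled over conditions."""
    n_feat = norm.shape[0]
    alpha_sum = np.zeros(n_feat)
    alpha_n = np.zeros(n_feat)
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        a = np.zeros(n_feat)
        a[ok] = (v[ok] - m[ok]) / (m[ok] ** 2)
        alpha_sum[ok] += a[ok]
        alpha_n[ok] += 1
    alpha = np.full(n_feat, floor)
    has = alpha_n > 0
    alpha[has] = np.maximum(alpha_sum[has] / alpha_n[has], floor)
    return alpha


def nb_differential(
    counts: CountMatrix,
    samples: SampleSheet,
    assay: str | None = None,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    pseudo_reference: bool = False,
) -> list[DifferentialRow]:
    """Two-group negative-binomial Wald test (case over control).

    Counts are divided by median-of-ratios size factors; the log2 fold change
    is ``log2((mean_case + pc) / (mean_control + pc))``; the p-value comes from
    a normal approximation of the log-mean difference with NB variance using a
    per-feature method-of-moments dispersion floored at ``dispersion_floor``.
    """
    if assay is not None:
        wanted = set(samples.select(assay=assay))
        sample_ids = [s for s in counts.sample_ids if s in wanted]
    else:
        sample_ids = [s for s in counts.sample_ids if s in samples]
    ctrl = [s for s in sample_ids if samples[s].condition == "control"]
    case = [s for s in sample_ids if samples[s].condition == "case"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            f"need >= 2 samples per condition, got {len(ctrl)} control / {len(case)} case"
        )
    sub = counts.subset_samples(ctrl + case)
    sf = size_factors(sub, pseudo_reference=pseudo_reference)
    norm = sub.counts / sf[None, :]
    idx_ctrl = np.arange(len(ctrl))
    idx_case = np.arange(len(ctrl), len(ctrl) + len(case))

    m0 = norm[:, idx_ctrl].mean(axis=1)
    m1 = norm[:, idx_case].mean(axis=1)
    alpha = _moment_dispersion(norm, [idx_ctrl, idx_case], dispersion_floor)

    log2fc = np.log2((m1 + pseudocount) / (m0 + pseudocount))
    # delta method: Var(log(mean_g + pc)) ~= Var(mean_g) / (mean_g + pc)^2
    var0 = (m0 + alpha * m0**2) / len(ctrl) / (m0 + pseudocount) ** 2
    var1 = (m1 + alpha * m1**2) / len(case) / (m1 + pseudocount) ** 2
    se = np.sqrt(var0 + var1)
    d = np.log((m1 + pseudocount) / (m0 + pseudocount))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (sub.counts == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    base_mean = norm.mean(axis=1)
    return [
        DifferentialRow(fid, float(base_mean[i]), float(log2fc[i]), float(p[i]), float(padj[i]))
        for i, fid in enumerate(sub.feature_ids)
    ]


def pearson_corr(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Sample correlation with a two-sided t-test p-value on n - 2 df.

    ``method='spearman'`` rank-transforms both vectors first. Zero variance in
    either vector is an error; |r| = 1 maps to p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance in input vector")
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-14:  # exact collinearity up to rounding
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return CorrelationResult(r, 0.0, n)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, min(p, 1.0), n)


def hypergeom_enrich(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str], set_name: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation: P(overlap >= observed)."""
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes not in universe: {sorted(stray)[:10]}")
    annotated = set(gene_set) & universe
    overlap = len(query & annotated)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(annotated), len(query)))
    return EnrichmentResult(
        set_name=set_name,
        overlap=overlap,
        set_size=len(annotated),
        query_size=len(query),
        universe_size=len(universe),
        p_value=min(p, 1.0),
    )


def enrich_gene_sets(
    query: Iterable[str], gene_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> list[EnrichmentResult]:
    """Test each named gene set and attach BH-adjusted p-values."""
    query = set(query)
    universe = set(universe)
    results = [hypergeom_enrich(query, gs, universe, set_name=name) for name, gs in gene_sets.items()]
    padj = bh_adjust([r.p_value for r in results]) if results else []
    return [
        EnrichmentResult(
            r.set_name, r.overlap, r.set_size, r.query_size, r.universe_size, r.p_value, float(a)
        )
        for r, a in zip(results, padj)
    ]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need >= 3 columns")
            if cols[0] in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {cols[0]!r}")
            sets[cols[0]] = {g for g in cols[2:] if g}
    return sets


def write_differential_table(rows: Sequence[DifferentialRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tbase_mean\tlog2fc\tp_value\tp_adj\n")
        for r in rows:
            fh.write(
                f"{r.feature_id}\t{r.base_mean!r}\t{r.log2fc!r}\t{r.p_value!r}\t{r.p_adj!r}\n"
            )


def read_differential_table(path: str | Path) -> list[DifferentialRow]:
    rows: list[DifferentialRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["feature_id", "base_mean", "log2fc", "p_value", "p_adj"]:
            raise ValueError(f"{path}: unexpected differential table header")
        for raw in fh:
            cols = raw.rstrip("\n").split("\t")
            rows.append(
                DifferentialRow(cols[0], float(cols[1]), float(cols[2]), float(cols[3]), float(cols[4]))
            )
    return rows
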