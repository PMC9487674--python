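"""Normalization, pseudobulk aggregation and gene-filtering rules.

Pseudobulk aggregation collapses a genes x cells count matrix to a
genes x samples matrix, either by summing raw counts per sample (followed by
a bulk normalization such as TMM or median-of-ratios size factors) or by
averaging single-cell log-normalized values.  Gene filters reproduce the
per-method inclusion rules used by the compared test families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simgen import CellCountMatrix, ValidationError

__all__ = [
    "PseudobulkMatrix",
    "GeneFilterReport",
    "lognormalize",
    "aggregate_sum",
    "aggregate_mean",
    "tmm_factors",
    "median_of_ratios_factors",
    "cpm_log2",
    "apply_gene_filter",
    "FILTER_RULES",
]

#: prior count added before log2 in the CPM transform of the moderated-t path
CPM_PRIOR_COUNT = 0.5


@dataclass
class PseudobulkMatrix:
    """Genes x samples matrix from aggregating cells within samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_to_condition: dict[str, str]
    aggregation: str  # "sum" | "mean"
    normalization: str = "raw"
    cells_per_sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("pseudobulk shape does not match gene/sample ids")

    @property
    def conditions(self) -> np.ndarray:
        return np.asarray(
            [self.sample_to_condition[s] for s in self.sample_ids], dtype=object
        )

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass
class GeneFilterReport:
    rule: str
    genes_in: int
    genes_out: int
    removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genes_out > self.genes_in:
            raise ValidationError("filter cannot add genes")


def lognormalize(data: CellCountMatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size log normalization: ``ln(1 + count * scale / libsize)``."""
    lib = data.library_sizes().astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(
            f"cell {data.cell_ids[zero[0]]!r} has zero library size"
        )
    return np.log1p(data.counts * (scale / lib)[None, :])


def aggregate_sum(data: CellCountMatrix) -> PseudobulkMatrix:
    """Sum raw counts within each sample (genes x samples, raw scale)."""
    samples = data.samples
    values = np.empty((data.n_genes, len(samples)))
    n_cells = np.empty(len(samples), dtype=int)
    for j, s in enumerate(samples):
        idx = data.cells_of_sample(s)
        if idx.size == 0:
            raise ValidationError(f"sample {s!r} has no cells")
        values[:, j] = data.counts[:, idx].sum(axis=1)
        n_cells[j] = idx.size
    return PseudobulkMatrix(
        values=values,
        gene_ids=list(data.gene_ids),
        sample_ids=samples,
        sample_to_condition=dict(data.sample_to_condition),
        aggregation="sum",
        normalization="raw",
        cells_per_sample=n_cells,
    )


def aggregate_mean(normalized: np.ndarray, data: CellCountMatrix) -> PseudobulkMatrix:
    """Average single-cell-normalized values within each sample."""
    normalized = np.asarray(normalized)
    if normalized.shape != data.counts.shape:
        raise ValidationError(
            f"normalized matrix shape {normalized.shape} does not match "
            f"count matrix shape {data.counts.shape}"
        )
    samples = data.samples
    values = np.empty((data.n_genes, len(samples)))
    n_cells = np.empty(len(samples), dtype=int)
    for j, s in enumerate(samples):
        idx = data.cells_of_sample(s)
        if idx.size == 0:
            raise ValidationError(f"sample {s!r} has no cells")
        values[:, j] = normalized[:, idx].mean(axis=1)
        n_cells[j] = idx.size
    return PseudobulkMatrix(
        values=values,
        gene_ids=list(data.gene_ids),
        sample_ids=samples,
        sample_to_condition=dict(data.sample_to_condition),
        aggregation="mean",
        normalization="lognorm_mean",
        cells_per_sample=n_cells,
    )


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              logratio_trim: float = 0.30, abs_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one column against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not np.any(ok):
        return 1.0
    o, r = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # inverse asymptotic variance of M (delta method, binomial sampling)
    w = 1.0 / ((1 - o) / (obs[ok]) + (1 - r) / (ref[ok]))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - (np.floor(n * abs_trim) + 1)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0**f)


def tmm_factors(pb: PseudobulkMatrix,
                logratio_trim: float = 0.30, abs_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, product normalized to 1.

    The reference column is the sample whose 75th-percentile count fraction
    is closest to the mean 75th percentile across samples; each column's
    factor is a weighted trimmed mean of log2 count-fraction ratios to that
    reference (30% trim on log-ratios, 5% on average intensities).
    """
    if pb.aggregation != "sum":
        raise ValidationError("TMM expects sum-aggregated raw counts")
    v = pb.values
    if v.shape[1] < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = v.sum(axis=0)
    if np.any(lib == 0):
        bad = pb.sample_ids[int(np.argmin(lib))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    uq = np.array([np.percentile(v[:, j][v[:, j] > 0], 75) / lib[j]
                   if np.any(v[:, j] > 0) else 0.0 for j in range(v.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([
        _tmm_pair(v[:, j], v[:, ref], logratio_trim, abs_trim)
        for j in range(v.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))  # product -> 1
    return f


def median_of_ratios_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors over genes nonzero in every sample."""
    v = pb.values
    all_pos = np.all(v > 0, axis=1)
    if not np.any(all_pos):
        raise ValidationError("no gene with nonzero counts in all samples")
    sub = v[all_pos, :]
    log_geo = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return factors


def cpm_log2(pb: PseudobulkMatrix, factors: np.ndarray | None = None,
             prior_count: float = CPM_PRIOR_COUNT) -> np.ndarray:
    """log2 counts-per-million on factor-adjusted library sizes."""
    if factors is None:
        factors = np.ones(len(pb.sample_ids))
    eff_lib = pb.library_sizes() * np.asarray(factors)
    return np.log2((pb.values + prior_count) / (eff_lib + 2.0 * prior_count)[None, :] * 1e6)


def _filter_mask(data: CellCountMatrix, rule: str, params: dict) -> np.ndarray:
    counts = data.counts
    expressing = (counts > 0).sum(axis=1)
    if rule == "nonexpressed":
        return expressing > 0
    if rule == "min_cells_expressing":
        k = params.get("k", 3)
        return expressing >= k
    if rule == "counts_per_cell":
        t = params.get("t", 0.005)
        return counts.sum(axis=1) / counts.shape[1] >= t
    if rule == "min_cells_expressing_and_min_cells_per_sample":
        k = params.get("k", 20)
        return expressing >= k
    if rule == "expressing_lt_n_subjects":
        n_subjects = len(data.samples)
        return expressing >= n_subjects
    raise ValidationError(f"unknown filter rule {rule!r}")


FILTER_RULES = (
    "nonexpressed",
    "min_cells_expressing",
    "counts_per_cell",
    "min_cells_expressing_and_min_cells_per_sample",
    "expressing_lt_n_subjects",
)


def apply_gene_filter(
    data: CellCountMatrix, rule: str, **params
) -> tuple[CellCountMatrix, GeneFilterReport]:
    """Restrict to genes (and, for the per-sample rule, samples) passing ``rule``.

    Rules: ``nonexpressed`` (drop all-zero genes), ``min_cells_expressing``
    (k, default 3), ``counts_per_cell`` (threshold t, default 0.005),
    ``min_cells_expressing_and_min_cells_per_sample`` (k=20, m=10 — samples
    with fewer than m cells are dropped first), ``expressing_lt_n_subjects``
    (gene must be expressed in at least as many cells as there are samples).
    """
    if rule == "min_cells_expressing_and_min_cells_per_sample":
        m = params.get("m", 10)
        keep_samples = [
            s for s in data.samples if data.cells_of_sample(s).size >= m
        ]
        if len(keep_samples) < len(data.samples):
            data = data.subset_samples(keep_samples)
    mask = _filter_mask(data, rule, params)
    removed = [g for g, keep in zip(data.gene_ids, mask) if not keep]
    report = GeneFilterReport(
        rule=rule,
        genes_in=data.n_genes,
        genes_out=int(mask.sum()),
        removed=removed,
    )
    return data.subset_genes(mask), report
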