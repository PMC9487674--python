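"""Hierarchical negative-binomial simulation of multi-subject scRNA-seq counts.

The generative model produces UMI-like counts for a two-condition,
multi-subject design with two nested sources of overdispersion:

* **cell level** — for a cell c in sample s, the count of gene g follows a
  negative binomial with mean ``mu`` and variance ``mu * (1 + phi_c * mu)``
  (quadratic NB; ``phi_c`` is the cell overdispersion);
* **sample level** — each (gene, sample) pair carries a multiplicative
  subject effect ``u ~ Gamma(shape=theta_s, scale=1/theta_s)`` with mean 1
  and variance ``1/theta_s``, so small ``theta_s`` means strong
  between-subject variation and large ``theta_s`` makes subjects
  exchangeable.

The mean for gene g, cell c in sample s under condition x in {0, 1} is

    mu = exp(beta0_g) * u_gs * 2 ** (x * logfc_g)

with the baseline ``beta0_g`` drawn uniformly on a natural-log interval and
``logfc_g`` a signed log2 fold change (zero for null genes).

Two generators are provided: :func:`simulate_dataset` draws pure mean-shift
(DE vs non-DE) data over a parameter grid, and
:func:`simulate_category_dataset` extends the model with two-component
mixtures on the log-mean scale to emulate the richer differential-state
taxonomy (EE, EP, DE, DP, DM, DB).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CategoryConfig",
    "CellCountMatrix",
    "DS_CATEGORIES",
    "make_grid",
    "simulate_dataset",
    "simulate_category_dataset",
    "subsample_imbalance",
    "GRID_SAMPLES",
    "GRID_AVG_CELLS",
    "GRID_DISTRIBUTIONS",
    "GRID_CELL_OD",
    "GRID_SAMPLE_OD",
]

# Parameter lists of the full factorial benchmark grid (10*4*2*4*4 = 1280).
GRID_SAMPLES = (6, 8, 10, 12, 14, 16, 18, 20, 30, 40)
GRID_AVG_CELLS = (100, 500, 1000, 2000)
GRID_DISTRIBUTIONS = ("poisson", "negbinomial")
GRID_CELL_OD = (0.05, 0.10, 0.20, 0.50)
GRID_SAMPLE_OD = (0.1, 1.0, 10.0, 100.0)

#: categories counted as a true differential state
DS_CATEGORIES = frozenset({"DE", "DP", "DM", "DB"})

# dispersion (size) of the NB used to draw per-sample cell numbers when
# cell_count_distribution == "negbinomial"; small size -> skewed allocation
_CELLCOUNT_NB_SIZE = 2.0


class ValidationError(ValueError):
    """Raised when a configuration or input violates a documented invariant."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one reference-free DE / non-DE simulation."""

    n_samples_total: int = 10
    avg_cells_per_sample: int = 200
    cell_count_distribution: str = "poisson"
    cell_overdispersion: float = 0.2
    sample_overdispersion: float = 1.0
    n_genes: int = 2000
    n_de_genes: int = 100
    logfc_magnitude_range: tuple[float, float] = (0.5, 2.0)
    baseline_log_mean_range: tuple[float, float] = (-4.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_total < 4 or self.n_samples_total % 2 != 0:
            raise ValidationError(
                f"n_samples_total must be an even integer >= 4, got {self.n_samples_total}"
            )
        if self.avg_cells_per_sample <= 0:
            raise ValidationError("avg_cells_per_sample must be positive")
        if self.cell_count_distribution not in ("poisson", "negbinomial"):
            raise ValidationError(
                f"unknown cell_count_distribution {self.cell_count_distribution!r}"
            )
        if self.cell_overdispersion <= 0 or self.sample_overdispersion <= 0:
            raise ValidationError("overdispersion parameters must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValidationError(
                f"n_de_genes must be in [0, n_genes], got {self.n_de_genes}"
            )
        lo, hi = self.logfc_magnitude_range
        if lo < 0 or hi < lo:
            raise ValidationError("logfc_magnitude_range must satisfy 0 <= lo <= hi")
        b_lo, b_hi = self.baseline_log_mean_range
        if b_hi < b_lo:
            raise ValidationError("baseline_log_mean_range must be a closed interval")


@dataclass(frozen=True)
class CategoryConfig:
    """Configuration of a differential-state category simulation.

    Genes are assigned to six categories and simulated with a two-component
    scheme on the log-mean scale: a low component at ``beta0`` and a high
    component at ``beta0 + mixture_gap`` (log2).  ``cluster_logfc`` is the
    magnitude of the mean shift for DE genes; by default the gap between the
    mixture components is three times that magnitude.
    """

    n_genes: int = 2000
    n_samples_total: int = 8
    avg_cells_per_sample: int = 200
    category_fractions: dict = field(
        default_factory=lambda: {
            "EE": 0.85, "EP": 0.05, "DE": 0.025, "DP": 0.025, "DM": 0.025, "DB": 0.025,
        }
    )
    cluster_logfc: float = 1.0
    sample_overdispersion: float = 1.0
    cell_overdispersion: float = 0.2
    mixture_gap: float | None = None  # default: 3 * cluster_logfc (log2)
    dp_proportions: tuple[float, float] = (0.3, 0.7)
    baseline_log_mean_range: tuple[float, float] = (-4.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"EE", "EP", "DE", "DP", "DM", "DB"}
        unknown = set(self.category_fractions) - known
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"category fractions sum to {total}, expected 1")
        if self.n_samples_total < 4 or self.n_samples_total % 2 != 0:
            raise ValidationError("n_samples_total must be an even integer >= 4")
        if self.cluster_logfc <= 0:
            raise ValidationError("cluster_logfc must be positive")
        lo, hi = self.dp_proportions
        if not (0 < lo < 1 and 0 < hi < 1) or abs(lo + hi - 1.0) > 1e-12:
            raise ValidationError("dp_proportions must be mixing fractions summing to 1")
        if self.cell_overdispersion <= 0 or self.sample_overdispersion <= 0:
            raise ValidationError("overdispersion parameters must be positive")

    @property
    def gap(self) -> float:
        return 3.0 * self.cluster_logfc if self.mixture_gap is None else self.mixture_gap


@dataclass
class CellCountMatrix:
    """Genes x cells integer count matrix with sample / condition metadata.

    ``counts[g, c]`` is the UMI count of gene ``gene_ids[g]`` in cell
    ``cell_ids[c]``; ``cell_to_sample[c]`` names that cell's sample and
    ``sample_to_condition`` maps each sample to one of two condition labels.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_to_sample: np.ndarray  # sample id per cell, aligned with cell_ids
    sample_to_condition: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_to_sample = np.asarray(self.cell_to_sample, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.cell_to_sample) != len(self.cell_ids):
            raise ValidationError("cell_to_sample must assign every cell a sample")
        missing = set(self.cell_to_sample) - set(self.sample_to_condition)
        if missing:
            raise ValidationError(f"samples without condition: {sorted(missing)}")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integral")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_condition)

    def cells_of_sample(self, sample: str) -> np.ndarray:
        """Column indices of cells belonging to ``sample``."""
        return np.flatnonzero(self.cell_to_sample == sample)

    def condition_of_cells(self) -> np.ndarray:
        """Condition label per cell (aligned with ``cell_ids``)."""
        return np.asarray(
            [self.sample_to_condition[s] for s in self.cell_to_sample], dtype=object
        )

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, idx: np.ndarray) -> "CellCountMatrix":
        idx = np.asarray(idx)
        kept_samples = set(self.cell_to_sample[idx])
        return CellCountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_to_sample=self.cell_to_sample[idx],
            sample_to_condition={
                s: c for s, c in self.sample_to_condition.items() if s in kept_samples
            },
        )

    def subset_samples(self, samples: list[str]) -> "CellCountMatrix":
        keep = set(samples)
        idx = np.flatnonzero([s in keep for s in self.cell_to_sample])
        return self.subset_cells(idx)

    def subset_genes(self, mask: np.ndarray) -> "CellCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCountMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_to_sample=self.cell_to_sample,
            sample_to_condition=dict(self.sample_to_condition),
        )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-item seed below 2**31 from a master seed and index."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_grid(
    samples=GRID_SAMPLES,
    avg_cells=GRID_AVG_CELLS,
    distributions=GRID_DISTRIBUTIONS,
    cell_od=GRID_CELL_OD,
    sample_od=GRID_SAMPLE_OD,
    *,
    master_seed: int = 0,
    n_genes: int = 2000,
    n_de_genes: int = 100,
    avg_cells_key=None,
) -> list[SimConfig]:
    """Cartesian product of the five parameter lists, one :class:`SimConfig` each.

    Each configuration receives a distinct deterministic seed derived from
    ``master_seed`` and its index in the product, so the grid is reproducible
    as a whole and any single dataset can be regenerated in isolation.
    """
    lists = [samples, avg_cells, distributions, cell_od, sample_od]
    names = ["samples", "avg_cells", "distributions", "cell_od", "sample_od"]
    for name, lst in zip(names, lists):
        if len(lst) == 0:
            raise ValidationError(f"parameter list {name!r} is empty")
    configs = []
    for i, (n_s, n_c, dist, phi, theta) in enumerate(
        itertools.product(samples, avg_cells, distributions, cell_od, sample_od)
    ):
        configs.append(
            SimConfig(
                n_samples_total=int(n_s),
                avg_cells_per_sample=int(n_c),
                cell_count_distribution=str(dist),
                cell_overdispersion=float(phi),
                sample_overdispersion=float(theta),
                n_genes=n_genes,
                n_de_genes=n_de_genes,
                seed=derive_seed(master_seed, i),
            )
        )
    return configs


def _draw_cell_numbers(rng, n_samples, avg, distribution) -> np.ndarray:
    """Per-sample cell numbers; at least one cell per sample."""
    if distribution == "poisson":
        n = rng.poisson(avg, size=n_samples)
    else:  # negbinomial: mean avg, size r -> skewed allocations
        r = _CELLCOUNT_NB_SIZE
        p = r / (r + avg)
        n = rng.negative_binomial(r, p, size=n_samples)
    return np.maximum(n, 1)


def _sample_labels(n_samples: int) -> tuple[list[str], dict[str, str]]:
    samples = [f"s{i + 1}" for i in range(n_samples)]
    half = n_samples // 2
    cond = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    return samples, cond


def _nb_counts(rng, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, var mu*(1+phi*mu)) via the Gamma-Poisson mixture."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mu)
    return rng.poisson(lam)


def simulate_dataset(config: SimConfig) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Simulate one two-condition dataset with DE and non-DE genes.

    Returns the count matrix and a gene truth table with columns
    ``gene_id``, ``category`` (DE / nonDE), ``logfc`` (signed log2) and
    ``is_ds``.  Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    samples, sample_to_condition = _sample_labels(config.n_samples_total)
    x = np.array([1.0 if sample_to_condition[s] == "B" else 0.0 for s in samples])

    beta0 = rng.uniform(*config.baseline_log_mean_range, size=G)
    logfc = np.zeros(G)
    de_idx = rng.choice(G, size=config.n_de_genes, replace=False)
    mags = rng.uniform(*config.logfc_magnitude_range, size=config.n_de_genes)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    logfc[de_idx] = mags * signs

    n_cells = _draw_cell_numbers(
        rng, len(samples), config.avg_cells_per_sample, config.cell_count_distribution
    )
    # subject effect: genes x samples, mean 1, var 1/theta_s
    theta = config.sample_overdispersion
    u = rng.gamma(theta, 1.0 / theta, size=(G, len(samples)))

    base_mu = np.exp(beta0)  # per-cell mean at baseline
    blocks = []
    cell_to_sample = []
    for j, s in enumerate(samples):
        mu = (base_mu * np.exp2(x[j] * logfc) * u[:, j])[:, None]
        mu = np.broadcast_to(mu, (G, n_cells[j]))
        blocks.append(_nb_counts(rng, mu, config.cell_overdispersion))
        cell_to_sample.extend([s] * n_cells[j])
    counts = np.concatenate(blocks, axis=1).astype(np.int32)

    gene_ids = [f"g{i + 1}" for i in range(G)]
    cell_ids = [f"c{i + 1}" for i in range(counts.shape[1])]
    data = CellCountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_to_sample=np.array(cell_to_sample, dtype=object),
        sample_to_condition=sample_to_condition,
    )
    category = np.where(logfc != 0.0, "DE", "nonDE")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": category,
            "logfc": logfc,
            "is_ds": category == "DE",
        }
    )
    return data, truth


def _category_counts(fractions: dict, n_genes: int) -> dict[str, int]:
    """Exact integer allocation by largest remainder; order-stable."""
    order = ["EE", "EP", "DE", "DP", "DM", "DB"]
    cats = [c for c in order if c in fractions]
    raw = {c: fractions[c] * n_genes for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    short = n_genes - sum(counts.values())
    by_rem = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), order.index(c)))
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def simulate_category_dataset(config: CategoryConfig) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Simulate a dataset spanning the six differential-state categories.

    Per gene, a two-component scheme on the log2-mean scale with a low
    component at ``b`` and a high component at ``b + gap``:

    * EE — both conditions unimodal at the low component;
    * EP — both conditions an identical 50/50 low/high mixture;
    * DE — condition A unimodal low, condition B shifted by +-cluster_logfc;
    * DP — mixtures with ``dp_proportions`` (low, high) in A, reversed in B;
    * DM — A unimodal low, B unimodal high (shift of one full gap);
    * DB — A unimodal at the midpoint, B a 50/50 low/high mixture.

    Subject effects and cell-level NB noise are shared with
    :func:`simulate_dataset`.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gap = config.gap
    samples, sample_to_condition = _sample_labels(config.n_samples_total)
    is_b = np.array([sample_to_condition[s] == "B" for s in samples])

    counts_per_cat = _category_counts(config.category_fractions, G)
    category = np.concatenate(
        [np.repeat(c, k) for c, k in counts_per_cat.items()]
    )
    category = category[rng.permutation(G)]

    beta0 = rng.uniform(*config.baseline_log_mean_range, size=G)  # natural log
    low = np.exp(beta0)
    high = low * 2.0**gap
    mid = low * 2.0 ** (gap / 2.0)
    de_sign = rng.choice([-1.0, 1.0], size=G)

    logfc = np.zeros(G)
    de_mask = category == "DE"
    dm_mask = category == "DM"
    logfc[de_mask] = de_sign[de_mask] * config.cluster_logfc
    logfc[dm_mask] = de_sign[dm_mask] * gap

    n_cells = _draw_cell_numbers(rng, len(samples), config.avg_cells_per_sample, "poisson")
    theta = config.sample_overdispersion
    u = rng.gamma(theta, 1.0 / theta, size=(G, len(samples)))

    p_low_A, p_high_A = config.dp_proportions
    blocks = []
    cell_to_sample = []
    for j, s in enumerate(samples):
        nc = n_cells[j]
        cond_b = is_b[j]
        # probability that a cell sits in the HIGH component, per gene
        p_high = np.zeros(G)
        p_high[category == "EP"] = 0.5
        p_high[category == "DP"] = (p_low_A if cond_b else p_high_A)
        if cond_b:
            p_high[category == "DM"] = np.where(de_sign[dm_mask] > 0, 1.0, 0.0)
            p_high[category == "DB"] = 0.5
        comp_high = rng.random((G, nc)) < p_high[:, None]
        mu = np.where(comp_high, high[:, None], low[:, None]).copy()
        # DE: unimodal low in A, shifted in B
        if cond_b:
            mu[de_mask, :] = (low[de_mask] * np.exp2(logfc[de_mask]))[:, None]
            # DM down-shift genes: A low -> B stays low? handled via p_high;
            # for negative sign A starts HIGH instead (see below)
        db_mask = category == "DB"
        if not cond_b:
            mu[db_mask, :] = mid[db_mask][:, None]
            # DM negative sign: condition A at high component, B at low
            neg_dm = dm_mask & (de_sign < 0)
            mu[neg_dm, :] = high[neg_dm][:, None]
        mu *= u[:, j][:, None]
        blocks.append(_nb_counts(rng, mu, config.cell_overdispersion))
        cell_to_sample.extend([s] * nc)
    counts = np.concatenate(blocks, axis=1).astype(np.int32)

    gene_ids = [f"g{i + 1}" for i in range(G)]
    cell_ids = [f"c{i + 1}" for i in range(counts.shape[1])]
    data = CellCountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_to_sample=np.array(cell_to_sample, dtype=object),
        sample_to_condition=sample_to_condition,
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": category,
            "logfc": logfc,
            "is_ds": np.isin(category, sorted(DS_CATEGORIES)),
        }
    )
    return data, truth


def subsample_imbalance(
    data: CellCountMatrix, min_prop: float, max_prop: float, seed: int
) -> CellCountMatrix:
    """Impose an uneven cell allocation by per-sample downsampling.

    Retention proportions are evenly spaced between ``min_prop`` and
    ``max_prop`` (one per sample), randomly permuted across samples; each
    sample keeps ``floor(p * n_cells)`` cells (at least one), drawn without
    replacement.  The gene set is unchanged.
    """
    if not (0 < min_prop <= max_prop <= 1):
        raise ValidationError("need 0 < min_prop <= max_prop <= 1")
    rng = np.random.default_rng(seed)
    samples = data.samples
    props = np.linspace(min_prop, max_prop, len(samples))
    props = rng.permutation(props)
    keep: list[np.ndarray] = []
    for s, p in zip(samples, props):
        idx = data.cells_of_sample(s)
        k = max(int(np.floor(p * len(idx))), 1)
        if k == 0:
            raise ValidationError(f"sample {s!r} left with 0 cells")
        keep.append(rng.choice(idx, size=k, replace=False))
    order = np.sort(np.concatenate(keep))
    return data.subset_cells(order)
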