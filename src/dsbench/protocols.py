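"""Experimental protocols: grid benchmark, mock comparison, reproducibility,
and discordance profiling.

Each protocol is deterministic given its master seed: per-dataset and
per-repetition seeds are derived by stable hashing, so any row of the output
can be regenerated in isolation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import dstest, evalmetrics, normagg
from .simgen import (
    CellCountMatrix,
    SimConfig,
    ValidationError,
    derive_seed,
    simulate_dataset,
    subsample_imbalance,
)

logger = logging.getLogger("dsbench")

__all__ = [
    "run_benchmark_grid",
    "mock_comparison",
    "reproducibility",
    "discordance_profile",
]


def run_benchmark_grid(
    configs: list[SimConfig],
    methods: list[str],
    alpha: float = evalmetrics.ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Simulate each config, run each method, and score them jointly.

    Per dataset, all methods run on the same simulated counts, genes are
    intersected across methods, BH adjustment and the confusion metrics are
    computed on the shared set.  A method failing on one dataset is logged
    and yields NaN metrics for that dataset, not a fatal error.
    """
    if not configs or not methods:
        raise ValidationError("configs and methods must be non-empty")
    rows = []
    failures: dict[str, int] = {m: 0 for m in methods}
    for i, config in enumerate(configs):
        data, truth = simulate_dataset(config)
        dataset_id = f"ds{i}"
        results = {}
        for m in methods:
            try:
                results[m] = dstest.run_method(data, m, seed=derive_seed(config.seed, 1))
            except Exception:
                logger.warning("method %s failed on dataset %s", m, dataset_id)
                failures[m] += 1
        if not results:
            continue
        genes = evalmetrics.common_genes(list(results.values()))
        for m, res in results.items():
            summary = evalmetrics.evaluate_result(
                res, truth, genes=genes, dataset_id=dataset_id, alpha=alpha
            )
            rows.append(summary.as_dict())
        for m in methods:
            if m not in results:
                rows.append({"method": m, "dataset_id": dataset_id,
                             "auroc": np.nan, "sensitivity": np.nan,
                             "specificity": np.nan, "precision": np.nan,
                             "f1": np.nan, "mcc": np.nan,
                             "n_genes_evaluated": 0, "n_significant": 0})
    for m, k in failures.items():
        if k == len(configs) and k > 0:
            logger.error("method %s failed on every dataset", m)
    return pd.DataFrame(rows)


def _mock_split(samples: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Random balanced split into two mock groups (larger group gets the
    extra sample when the count is odd)."""
    if len(samples) < 4:
        raise ValidationError("mock comparison needs >= 4 samples")
    perm = rng.permutation(len(samples))
    half = len(samples) // 2
    assign = {}
    for j, idx in enumerate(perm):
        assign[samples[idx]] = "mockA" if j < half else "mockB"
    if sum(v == "mockA" for v in assign.values()) < 2:
        raise ValidationError("fewer than 2 samples per mock group")
    return assign


def mock_comparison(
    data: CellCountMatrix,
    methods: list[str],
    n_rep: int = 30,
    master_seed: int = 0,
    alpha: float = evalmetrics.ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Null-calibration protocol: random mock splits of one-condition data.

    ``data`` must contain samples from a single condition (no true signal);
    per repetition, samples are split into two balanced mock groups at
    random, every method runs, and the proportion of common genes with BH
    q <= alpha is recorded.  Any significant gene is a false positive.
    """
    conditions = set(data.sample_to_condition.values())
    if len(conditions) != 1:
        raise ValidationError(
            f"mock comparison expects one condition, got {sorted(conditions)}"
        )
    samples = data.samples
    rows = []
    for rep in range(n_rep):
        seed = derive_seed(master_seed, rep)
        rng = np.random.default_rng(seed)
        assign = _mock_split(samples, rng)
        mock = CellCountMatrix(
            counts=data.counts,
            gene_ids=list(data.gene_ids),
            cell_ids=list(data.cell_ids),
            cell_to_sample=data.cell_to_sample,
            sample_to_condition=assign,
        )
        results = {}
        for m in methods:
            try:
                results[m] = dstest.run_method(mock, m, seed=derive_seed(seed, 1))
            except Exception:
                logger.warning("mock rep %d: method %s failed", rep, m)
        if not results:
            continue
        genes = evalmetrics.common_genes(list(results.values()))
        for m, res in results.items():
            frame = res.as_frame().set_index("gene_id")
            p = frame.loc[genes, "p_value"].to_numpy()
            q = evalmetrics.bh_adjust(p)
            ok = ~np.isnan(q)
            prop = float(np.sum(q[ok] <= alpha)) / max(int(ok.sum()), 1)
            rows.append({
                "repetition": rep, "seed": seed, "method": m,
                "proportion_significant": prop,
                "n_genes": int(ok.sum()),
            })
    return pd.DataFrame(rows)


def reproducibility(
    data: CellCountMatrix,
    methods: list[str],
    n_rep_per_arm: int = 50,
    min_reps: int = 4,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Stability of p-value rankings under replicate resampling.

    Generates ``n_rep_per_arm`` balanced subsets (random replicate subsets,
    at least ``min_reps`` per condition) and as many imbalanced subsets
    (the same construction followed by even-interval 0.20-1 cell
    subsampling), runs every method on each, and returns Spearman's rank
    correlation of nominal p-values over shared genes for every unordered
    pair of datasets.  Methods with constant p-values on a dataset yield
    missing correlations for its pairs.
    """
    by_cond: dict[str, list[str]] = {}
    for s, c in data.sample_to_condition.items():
        by_cond.setdefault(c, []).append(s)
    if len(by_cond) != 2:
        raise ValidationError("reproducibility expects two conditions")
    for c, ss in by_cond.items():
        if len(ss) < min_reps + 1:
            raise ValidationError(
                f"condition {c!r} has {len(ss)} replicates; need >= {min_reps + 1}"
            )

    datasets = []  # (dataset_index, imbalanced_flag, CellCountMatrix)
    idx = 0
    for arm, imbalanced in (("balanced", False), ("imbalanced", True)):
        for rep in range(n_rep_per_arm):
            seed = derive_seed(master_seed, idx)
            rng = np.random.default_rng(seed)
            chosen = []
            for c, ss in sorted(by_cond.items()):
                k = int(rng.integers(min_reps, len(ss)))  # min_reps .. available-1
                chosen.extend(rng.choice(ss, size=k, replace=False))
            sub = data.subset_samples(chosen)
            if imbalanced:
                sub = subsample_imbalance(sub, 0.20, 1.0, seed=derive_seed(seed, 7))
            datasets.append((idx, imbalanced, sub))
            idx += 1

    # p-value vectors per method per dataset, aligned to the full gene list
    pmat: dict[str, np.ndarray] = {
        m: np.full((len(datasets), data.n_genes), np.nan) for m in methods
    }
    for di, _, sub in datasets:
        for m in methods:
            try:
                res = dstest.run_method(sub, m, seed=derive_seed(master_seed, 10_000 + di))
                pmat[m][di] = res.p_value
            except Exception:
                logger.warning("reproducibility dataset %d: method %s failed", di, m)

    rows = []
    flags = {di: imb for di, imb, _ in datasets}
    for m in methods:
        P = pmat[m]
        for i in range(len(datasets)):
            for j in range(i + 1, len(datasets)):
                shared = ~np.isnan(P[i]) & ~np.isnan(P[j])
                rho = np.nan
                if shared.sum() >= 3:
                    with np.errstate(invalid="ignore"):
                        r = stats.spearmanr(P[i, shared], P[j, shared]).statistic
                    rho = float(r) if np.isfinite(r) else np.nan
                rows.append({
                    "method": m, "dataset_i": i, "dataset_j": j,
                    "imbalanced_i": flags[i], "imbalanced_j": flags[j],
                    "spearman_rho": rho,
                })
    return pd.DataFrame(rows)


def discordance_profile(
    results: dict[str, "dstest.TestResult"],
    truth: pd.DataFrame,
    pb: "normagg.PseudobulkMatrix",
    normalized: np.ndarray,
    data: CellCountMatrix,
    alpha: float = evalmetrics.ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Per-gene diagnostics stratified by confusion class per method.

    For every method, genes are partitioned into TP/FP/TN/FN at BH ``alpha``
    over the common gene set, and each gene carries four descriptors: the
    average overlap of its pseudobulk values between conditions, the
    absolute pseudocount log2 fold change of pseudobulk group means, the
    mean pseudobulk expression and the mean single-cell-normalized
    expression.
    """
    genes = evalmetrics.common_genes(list(results.values()))
    is_ds = truth.set_index("gene_id")["is_ds"]
    pb_vals = dstest._pb_log_values(pb)
    pb_index = {g: i for i, g in enumerate(pb.gene_ids)}
    cond = pb.conditions
    mask_a = cond == sorted(set(cond))[0]
    sc_mean = np.asarray(normalized).mean(axis=1)
    sc_index = {g: i for i, g in enumerate(data.gene_ids)}

    per_gene = {}
    for g in genes:
        i = pb_index[g]
        xa, xb = pb_vals[i, mask_a], pb_vals[i, ~mask_a]
        per_gene[g] = {
            "avg_overlap": evalmetrics.average_overlap(xa, xb),
            "abs_log2fc_pc1": abs(np.log2((xa.mean() + 1.0) / (xb.mean() + 1.0))),
            "mean_pb_expr": float(pb_vals[i].mean()),
            "mean_sc_expr": float(sc_mean[sc_index[g]]),
        }

    rows = []
    for m, res in results.items():
        frame = res.as_frame().set_index("gene_id")
        p = frame.loc[genes, "p_value"].to_numpy()
        q = evalmetrics.bh_adjust(p)
        for g, qv in zip(genes, q):
            if np.isnan(qv):
                continue
            called = qv <= alpha
            true = bool(is_ds.loc[g])
            cls = ("TP" if called and true else
                   "FP" if called else
                   "FN" if true else "TN")
            rows.append({"method": m, "gene_id": g, "class": cls, **per_gene[g]})
    out = pd.DataFrame(rows)
    if not out.empty:
        present = out.groupby("method")["class"].unique()
        for m, classes in present.items():
            missing = set(("TP", "FP", "TN", "FN")) - set(classes)
            if missing:
                logger.info("discordance: method %s has empty classes %s",
                            m, sorted(missing))
    return out
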