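"""Performance evaluation: AUROC, confusion metrics at BH-FDR 0.05,
common-gene reconciliation and the average-overlap statistic.

Because the compared methods filter genes differently, evaluation is always
restricted to the intersection of tested genes before multiple-testing
adjustment — so every method is scored on the same gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simgen import ValidationError
from .dstest import TestResult

__all__ = [
    "EvalSummary",
    "common_genes",
    "bh_adjust",
    "auroc",
    "confusion_metrics",
    "average_overlap",
    "evaluate_result",
]

ALPHA_DEFAULT = 0.05


@dataclass
class EvalSummary:
    """Per-method, per-dataset performance record."""

    method: str
    dataset_id: str
    auroc: float
    sensitivity: float
    specificity: float
    precision: float  # NaN when no positives called
    f1: float
    mcc: float
    n_genes_evaluated: int
    n_significant: int

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "dataset_id": self.dataset_id,
            "auroc": self.auroc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "n_genes_evaluated": self.n_genes_evaluated,
            "n_significant": self.n_significant,
        }


def common_genes(results: list[TestResult]) -> list[str]:
    """Intersection of the tested-gene masks, in the first result's order."""
    if not results:
        raise ValidationError("need at least one result")
    keep = None
    for res in results:
        tested = {g for g, t in zip(res.gene_ids, res.tested) if t}
        keep = tested if keep is None else keep & tested
    if not keep:
        raise ValidationError("no gene tested by all methods")
    return [g for g in results[0].gene_ids if g in keep]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are ignored and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q = np.empty(m)
    q[order] = adj
    out[ok] = q
    return out


def auroc(p: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUROC with score ``-p`` and midranks for ties.

    Equals the Mann-Whitney probability that a randomly chosen positive gene
    receives a smaller p-value than a randomly chosen negative one.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(-p)  # higher score (= smaller p) -> higher rank
    r_pos = ranks[truth].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(
    q: np.ndarray, truth: np.ndarray, alpha: float = ALPHA_DEFAULT
) -> dict:
    """Confusion-matrix metrics calling positives at adjusted p <= alpha.

    Precision and F1 are NaN (undefined, not zero) when no positives are
    called; MCC is NaN when its denominator vanishes.
    """
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if q.shape != truth.shape:
        raise ValidationError("q and truth must align")
    called = q <= alpha
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0 else np.nan)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom > 0 else np.nan
    return {
        "sensitivity": sens, "specificity": spec, "precision": prec,
        "f1": f1, "mcc": mcc, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "n_significant": tp + fp,
    }


def average_overlap(x_a, x_b) -> float:
    """Average overlap O = 0.5 * (m'/m + n'/n) of two replicate vectors.

    m' counts values of group A within [min(B), max(B)] and n' conversely;
    O near 1 means the groups are indistinguishable, near 0 well separated.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size == 0 or x_b.size == 0:
        raise ValidationError("both groups need at least one replicate")
    m_prime = int(np.sum((x_a >= x_b.min()) & (x_a <= x_b.max())))
    n_prime = int(np.sum((x_b >= x_a.min()) & (x_b <= x_a.max())))
    return 0.5 * (m_prime / x_a.size + n_prime / x_b.size)


def evaluate_result(
    result: TestResult,
    truth: pd.DataFrame,
    genes: list[str] | None = None,
    dataset_id: str = "",
    alpha: float = ALPHA_DEFAULT,
) -> EvalSummary:
    """Score one method on one dataset over a shared gene universe.

    ``genes`` (typically the common-gene intersection across methods)
    restricts evaluation; BH adjustment is applied to this restricted set.
    """
    frame = result.as_frame().set_index("gene_id")
    is_ds = truth.set_index("gene_id")["is_ds"]
    if genes is None:
        genes = [g for g, t in zip(result.gene_ids, result.tested) if t]
    p = frame.loc[genes, "p_value"].to_numpy()
    y = is_ds.loc[genes].to_numpy(dtype=bool)
    q = bh_adjust(p)
    ok = ~np.isnan(q)
    cm = confusion_metrics(q[ok], y[ok], alpha=alpha)
    auc = auroc(p[ok], y[ok]) if (y[ok].any() and not y[ok].all()) else np.nan
    return EvalSummary(
        method=result.method,
        dataset_id=dataset_id,
        auroc=auc,
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        precision=cm["precision"],
        f1=cm["f1"],
        mcc=cm["mcc"],
        n_genes_evaluated=int(ok.sum()),
        n_significant=cm["n_significant"],
    )
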