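"""On-disk formats, run configuration and provenance.

Count data lives as a directory of plain-text files: ``matrix.mtx``
(Matrix Market coordinate triplets, 1-based), ``genes.tsv``, ``cells.tsv``
(cell id, sample id, condition) and optionally ``truth.tsv`` (gene id,
category, logfc, is_ds).  Tabular results are TSV with '.' decimals and
missing p-values serialized as "NA"; every run directory carries a manifest
with the seed and a config hash so artifacts are reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .simgen import CellCountMatrix, ValidationError

__all__ = [
    "read_count_data",
    "write_count_data",
    "write_truth",
    "read_truth",
    "write_results",
    "config_hash",
]

NA = "NA"


def write_count_data(data: CellCountMatrix, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + cells.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.coo_matrix(data.counts))
    pd.DataFrame({"gene_id": data.gene_ids}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cell_id": data.cell_ids,
            "sample_id": list(data.cell_to_sample),
            "condition": [
                data.sample_to_condition[s] for s in data.cell_to_sample
            ],
        }
    ).to_csv(out / "cells.tsv", sep="\t", index=False)


def read_count_data(path) -> CellCountMatrix:
    """Read the matrix.mtx + genes.tsv + cells.tsv layout back into memory."""
    path = Path(path)
    for fname in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (path / fname).exists():
            raise ValidationError(f"missing file {fname} in {path}")
    mat = scipy.io.mmread(path / "matrix.mtx")
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.all(counts == np.round(counts)):
        raise ValidationError("matrix.mtx contains non-integer values")
    counts = counts.astype(np.int64)
    genes = pd.read_csv(path / "genes.tsv", sep="\t")["gene_id"].tolist()
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    if counts.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {counts.shape} does not match metadata "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    sample_to_condition = {}
    for s, c in zip(cells["sample_id"], cells["condition"]):
        prev = sample_to_condition.setdefault(s, c)
        if prev != c:
            raise ValidationError(f"sample {s!r} maps to two conditions")
    return CellCountMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells["cell_id"].tolist(),
        cell_to_sample=cells["sample_id"].to_numpy(dtype=object),
        sample_to_condition=sample_to_condition,
    )


def write_truth(truth: pd.DataFrame, out_dir) -> None:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    truth.to_csv(Path(out_dir) / "truth.tsv", sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "truth.tsv", sep="\t")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir, seed: int = 0,
                  config: dict | None = None) -> dict:
    """Write result tables as TSV plus a JSON manifest.

    Missing values are serialized as "NA"; the manifest records per-file row
    counts, the seed and a hash of the configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config_hash": config_hash(config or {}),
        "files": {},
    }
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(out / fname, sep="\t", index=False, na_rep=NA)
        manifest["files"][fname] = {"rows": int(len(table))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
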