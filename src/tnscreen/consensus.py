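"""Cutoff classification and four-replicate consensus calls.

A gene is classified per comparison from its logFC, p and q:

* susceptibility — insertions enriched under phage selection
  (logFC >= +2, q < 0.01, p < 0.05): the intact gene normally aids phage
  killing, so its mutants outgrow the pool;
* resistance — insertions depleted (logFC <= -2, same significance): the
  intact gene normally hinders phage, so its mutants are killed faster;
* none otherwise.

The consensus over the four replicate selections (two doses x two time
points) calls a gene only when all four comparisons agree on the same
non-none class; its effect size is the mean of the four logFC values.
Cutoffs are inclusive on |logFC| and strict on p and q.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutoffConfig",
    "SUSCEPTIBILITY",
    "RESISTANCE",
    "NONE",
    "classify_gene",
    "consensus_calls",
    "write_consensus",
    "write_gene_lists",
]

SUSCEPTIBILITY = "susceptibility"
RESISTANCE = "resistance"
NONE = "none"


@dataclass(frozen=True)
class CutoffConfig:
    logfc_cut: float = 2.0
    q_cut: float = 0.01
    p_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.logfc_cut <= 0:
            raise ValueError("logfc_cut must be > 0")
        for name in ("q_cut", "p_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def classify_gene(logfc: float, p: float, q: float, cuts: CutoffConfig = CutoffConfig()) -> str:
    """Class of one gene in one comparison; |logFC| cutoff is inclusive."""
    if not (np.isfinite(logfc) and np.isfinite(p) and np.isfinite(q)):
        raise ValueError("classify_gene requires finite inputs")
    significant = q < cuts.q_cut and p < cuts.p_cut
    if significant and logfc >= cuts.logfc_cut:
        return SUSCEPTIBILITY
    if significant and logfc <= -cuts.logfc_cut:
        return RESISTANCE
    return NONE


def consensus_calls(
    results: Sequence[pd.DataFrame], cuts: CutoffConfig = CutoffConfig()
) -> pd.DataFrame:
    """Intersect per-replicate classifications into final calls.

    ``results`` are comparison tables (gene_id, logFC, p, q) over the same
    gene set.  A gene is called iff every replicate assigns it the same
    non-none class; all genes are reported with their mean logFC and the
    number of replicates in which they passed any cutoff.
    """
    if not results:
        raise ValueError("no comparison results supplied")
    base = results[0]["gene_id"].to_numpy()
    aligned = []
    for r in results:
        if set(r["gene_id"]) != set(base):
            raise ValueError("comparison tables cover different gene sets")
        aligned.append(r.set_index("gene_id").loc[base])
    classes = np.array([
        [classify_gene(row.logFC, row.p, row.q, cuts) for row in r.itertuples()]
        for r in aligned
    ])  # shape (n_replicates, n_genes)
    logfcs = np.array([r["logFC"].to_numpy() for r in aligned])
    n_passing = (classes != NONE).sum(axis=0)
    unanimous = np.array([
        len(set(col)) == 1 and col[0] != NONE for col in classes.T
    ])
    call = np.where(unanimous, classes[0], NONE)
    return pd.DataFrame(
        {
            "gene_id": base,
            "class": call,
            "mean_logFC": logfcs.mean(axis=0),
            "n_passing": n_passing,
        }
    )


def write_consensus(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_gene_lists(
    calls: pd.DataFrame,
    susceptibility_path: str | Path,
    resistance_path: str | Path,
    annotations: dict[str, str] | None = None,
) -> None:
    """Write the two final gene lists (gene_id, annotation, mean logFC)."""
    ann = annotations or {}
    for cls, path in ((SUSCEPTIBILITY, susceptibility_path), (RESISTANCE, resistance_path)):
        sub = calls[calls["class"] == cls].copy()
        sub["annotation"] = [ann.get(g, "") for g in sub["gene_id"]]
        sub[["gene_id", "annotation", "mean_logFC"]].to_csv(path, sep="\t", index=False)
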