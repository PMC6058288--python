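"""Per-gene fitness statistics: log-CPM fold change, exact test, FDR.

For each selected-vs-control contrast the change in a gene's share of
mapped reads is summarised as a log2 fold change of counts per million
(with a pseudocount keeping it finite), an exact two-sided p-value, and a
Benjamini-Hochberg q-value across the assayable gene set.

The p-value is a conditional binomial exact test: given the total count
n = count_sel + count_ctrl for a gene, under the null of equal relative
abundance the selected count is Binomial(n, pi) with
pi = lib_sel / (lib_sel + lib_ctrl).  Two-sided tail probabilities use the
minimum-likelihood method (sum of all outcomes at most as probable as the
one observed, ties included with relative tolerance 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import GeneCountTable

__all__ = [
    "TestConfig",
    "cpm",
    "log_fold_change",
    "binomial_two_sided_p",
    "test_gene",
    "adjust_fdr",
    "compare",
    "write_comparison",
    "read_comparison",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class TestConfig:
    """Knobs of the per-gene statistical comparison."""

    pseudocount: float = 0.5
    test: str = "binomial-exact"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.test != "binomial-exact":
            raise ValueError(f"unknown test {self.test!r}")


def cpm(read_counts, library_size: float):
    """Counts per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(read_counts, dtype=np.float64) * 1e6 / library_size


def log_fold_change(
    count_sel,
    count_ctrl,
    lib_sel: float,
    lib_ctrl: float,
    pseudocount: float = 0.5,
):
    """log2 of the pseudocounted CPM ratio, selected over control.

    Antisymmetric under swapping the two samples; finite for zero counts.
    """
    sel = cpm(count_sel, lib_sel) + pseudocount
    ctrl = cpm(count_ctrl, lib_ctrl) + pseudocount
    return np.log2(sel / ctrl)


def binomial_two_sided_p(k: int, n: int, pi: float, tol: float = _TIE_TOL) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood method.

    p = sum of Binomial(n, pi) probabilities over all outcomes whose pmf is
    <= pmf(k) (within relative tolerance ``tol``).  p = 1 when n = 0.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, pi)
    p_obs = pmf[k]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + tol)].sum()))


def test_gene(count_sel: int, count_ctrl: int, lib_sel: float, lib_ctrl: float) -> float:
    """Exact conditional test of one gene's selected-vs-control counts."""
    if count_sel < 0 or count_ctrl < 0:
        raise ValueError("counts must be non-negative")
    if lib_sel <= 0 or lib_ctrl <= 0:
        raise ValueError("library sizes must be > 0")
    n = count_sel + count_ctrl
    pi = lib_sel / (lib_sel + lib_ctrl)
    return binomial_two_sided_p(count_sel, n, pi)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare(
    table: GeneCountTable,
    selected_sample: str,
    control_sample: str,
    config: TestConfig = TestConfig(),
) -> pd.DataFrame:
    """One selected-vs-control contrast over the assayable gene set.

    Returns a DataFrame (gene_id, logFC, p, q); q-values are adjusted across
    the genes tested in this comparison.
    """
    for s in (selected_sample, control_sample):
        if s not in table.samples:
            raise ValueError(f"sample {s!r} absent from count table")
    data = table.data
    if "assayable" in data.columns:
        data = data[data["assayable"]]
    if data.empty:
        raise ValueError("no assayable genes to compare")
    lib_sel = table.library_sizes[selected_sample]
    lib_ctrl = table.library_sizes[control_sample]
    counts_sel = data[f"reads_{selected_sample}"].to_numpy()
    counts_ctrl = data[f"reads_{control_sample}"].to_numpy()
    logfc = log_fold_change(counts_sel, counts_ctrl, lib_sel, lib_ctrl,
                            pseudocount=config.pseudocount)
    p = np.array([
        test_gene(int(s), int(c), lib_sel, lib_ctrl)
        for s, c in zip(counts_sel, counts_ctrl)
    ])
    return pd.DataFrame(
        {
            "gene_id": data["gene_id"].to_numpy(),
            "logFC": logfc,
            "p": p,
            "q": adjust_fdr(p),
        }
    )


def write_comparison(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False)


def read_comparison(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
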