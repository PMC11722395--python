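"""Cross-experiment differential-expression convergence.

Two crispant experiments with independent guide sets should perturb the
same genes if a phenotype is on-target.  The analysis: restrict to genes
expressed in BOTH experiments (baseMean ≥ a floor, 100 by default), apply
Benjamini–Hochberg FDR within each experiment (significant at adjusted
p < alpha, 0.1 by default), intersect the significant lists, classify the
overlap by direction of fold change, and score it with a one-sided
hypergeometric (Fisher exact) upper-tail test against the expressed-gene
universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConvergenceResult",
    "filter_basemean",
    "bh_fdr",
    "concordant_overlap",
    "overlap_fisher",
    "convergence",
]

REQUIRED_COLUMNS = ("gene", "baseMean", "log2FoldChange", "pvalue")


def _check_table(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{name}: duplicate gene id {dup!r}")


def filter_basemean(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    min_basemean: float = 100.0) -> pd.Index:
    """Gene universe: ids with baseMean ≥ ``min_basemean`` in BOTH tables
    (a gene below the floor in either experiment is excluded)."""
    _check_table(table_a, "table A")
    _check_table(table_b, "table B")
    a = table_a.set_index("gene")["baseMean"]
    b = table_b.set_index("gene")["baseMean"]
    common = a.index.intersection(b.index)
    keep = common[(a.loc[common] >= min_basemean) & (b.loc[common] >= min_basemean)]
    if len(keep) == 0:
        raise ValueError("expression filter left an empty gene universe")
    return keep


def bh_fdr(pvalues, alpha: float = 0.1):
    """Benjamini–Hochberg step-up adjustment.

    Returns (adjusted p-values, boolean significant array); significance
    is adjusted p strictly below ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    padj = np.empty(m)
    padj[order] = adj_sorted
    return padj, padj < alpha


def concordant_overlap(sig_a: pd.DataFrame, sig_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two significant-gene tables and classify by direction.

    Inputs need columns ``gene`` and ``log2FoldChange``.  The result has
    one row per overlapping gene with both fold changes and a
    ``concordant`` flag; genes with a fold change of exactly 0 are flagged
    (``sign_undefined``) and excluded from the concordance classification.
    """
    for df, name in ((sig_a, "sig A"), (sig_b, "sig B")):
        for c in ("gene", "log2FoldChange"):
            if c not in df.columns:
                raise ValueError(f"{name}: missing column {c!r}")
    merged = sig_a.merge(sig_b, on="gene", suffixes=("_a", "_b"))
    sa = np.sign(merged["log2FoldChange_a"])
    sb = np.sign(merged["log2FoldChange_b"])
    undefined = (sa == 0) | (sb == 0)
    merged["sign_undefined"] = undefined
    merged["concordant"] = (sa == sb) & ~undefined
    return merged


def overlap_fisher(n_a: int, n_b: int, k: int, n_universe: int) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) overlap p-value.

    P(X ≥ k) for X ~ Hypergeom(N, n_a, n_b): the chance of drawing at
    least k of the n_a list-A genes when sampling n_b genes from a
    universe of N.  Evaluated via the survival function, which scipy
    computes stably in log space.
    """
    if not (0 <= k <= min(n_a, n_b) and max(n_a, n_b) <= n_universe):
        raise ValueError(
            f"inconsistent counts: k={k}, nA={n_a}, nB={n_b}, N={n_universe}"
        )
    return float(stats.hypergeom.sf(k - 1, n_universe, n_a, n_b))


@dataclass
class ConvergenceResult:
    n_universe: int
    n_sig_a: int
    n_sig_b: int
    n_overlap: int
    n_concordant: int
    fisher_p: float
    overlap_table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(universe=self.n_universe, sig_a=self.n_sig_a,
                  sig_b=self.n_sig_b, overlap=self.n_overlap,
                  concordant=self.n_concordant, fisher_p=self.fisher_p)]
        )


def convergence(table_a: pd.DataFrame, table_b: pd.DataFrame,
                min_basemean: float = 100.0, fdr_alpha: float = 0.1,
                sign_stratified: bool = False) -> ConvergenceResult:
    """End-to-end convergence analysis of two DE result tables.

    The Fisher test scores the total overlap against the expression-
    filtered universe; with ``sign_stratified`` only sign-concordant
    overlap genes count as successes.
    """
    universe = filter_basemean(table_a, table_b, min_basemean)
    fa = table_a.set_index("gene").loc[universe].reset_index()
    fb = table_b.set_index("gene").loc[universe].reset_index()
    for df in (fa, fb):
        padj, sig = bh_fdr(df["pvalue"].to_numpy(), fdr_alpha)
        df["padj"] = padj
        df["significant"] = sig
    sig_a = fa[fa["significant"]]
    sig_b = fb[fb["significant"]]
    overlap = concordant_overlap(sig_a, sig_b)
    k = int(overlap["concordant"].sum()) if sign_stratified else len(overlap)
    p = overlap_fisher(len(sig_a), len(sig_b), k, len(universe))
    return ConvergenceResult(
        len(universe), len(sig_a), len(sig_b), len(overlap),
        int(overlap["concordant"].sum()), p, overlap,
    )
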