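"""Immune-feature comparison between comut+ and comut− patient groups.

Signature scores on a log2(value+1) expression matrix — mean-expression
scores (CYT over GZMA/PRF1, MHC class I core genes) and single-sample GSEA
(ssGSEA) for the T-cell-inflamed GEP signature — plus per-gene differential
testing of an immune panel (Wilcoxon + BH-FDR) and preranked GSEA on the
t-score-ranked gene list with a gene-permutation null.

The general immune-infiltration score here is a user-supplied signature
scored by ssGSEA; it is not the ESTIMATE algorithm and does not ship
ESTIMATE's gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSet
from .survival_stats import bh_fdr

__all__ = [
    "CYT_GENES",
    "MHC1_CORE_GENES",
    "IMMUNE_PANEL_47",
    "mean_signature_score",
    "ssgsea_score",
    "differential_panel",
    "preranked_gsea",
    "GseaResult",
]

#: Cytolytic-activity signature: granzyme A and perforin 1.
CYT_GENES = ["GZMA", "PRF1"]

#: MHC class I core genes (antigen presentation machinery). Editable fixture;
#: replace with your preferred curation.
MHC1_CORE_GENES = ["HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "NLRC5"]

#: 47-gene immune response panel (checkpoints, T-cell receptor, TME,
#: IFN-gamma / T-effector genes). Editable fixture: a representative curation
#: of the published immune-response gene families, user-replaceable.
IMMUNE_PANEL_47 = [
    # immune checkpoints
    "PDCD1", "CD274", "PDCD1LG2", "CTLA4", "LAG3",
    # tumour microenvironment
    "IL6", "IL1B", "IL18", "IL15RA", "IL2RB",
    # T-cell receptor / costimulation
    "CD3D", "CD3E", "CD3G", "CD247", "TRAC", "TRBC1", "TRGC1", "CD28",
    "ICOS", "TNFRSF9", "CD27",
    # T-effector and IFN-gamma pathway
    "IFNG", "GZMA", "GZMB", "GZMK", "PRF1", "CXCL9", "CXCL10", "CXCL11",
    "STAT1", "IRF1", "IDO1", "HLA-DRA", "HLA-DRB1", "HLA-E", "TBX21",
    "CD8A", "CD8B", "EOMES", "NKG7", "KLRD1",
    # antigen presentation / other
    "B2M", "TAP1", "TAP2", "PSMB9", "PSMB10", "CIITA",
]

#: T-cell-inflamed gene expression profile (GEP) signature genes.
GEP_GENES = [
    "CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9", "CXCR6",
    "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3", "NKG7", "PDCD1LG2",
    "PSMB10", "STAT1", "TIGIT",
]


def _check_expr(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    return expr


def mean_signature_score(expr: pd.DataFrame, gene_list: Sequence[str]) -> pd.Series:
    """Per-sample arithmetic mean of the signature genes present in ``expr``.

    Missing signature genes are skipped with a warning; an all-missing
    signature is an error.
    """
    expr = _check_expr(expr)
    present = [g for g in gene_list if g in expr.index]
    missing = [g for g in gene_list if g not in expr.index]
    if not present:
        raise ValueError("no signature gene present in expression matrix")
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=2)
    return expr.loc[present].mean(axis=0)


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Per sample, genes are ranked by expression (descending; ties get average
    ranks). Walking down the ranked list, the in-set empirical CDF weighted
    by rank^alpha (normalized over set genes) is compared with the
    unweighted out-of-set ECDF; the score is the sum of the differences over
    all positions. ``normalize=True`` divides by (number of genes − set
    size), bounding the score magnitude.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    expr = _check_expr(expr)
    in_set = expr.index.isin(genes)
    n_genes = len(expr.index)
    n_in = int(in_set.sum())
    if n_in < 2:
        raise ValueError("need >= 2 set genes present in the matrix")
    if n_genes - n_in < 2:
        raise ValueError("need >= 2 genes outside the set")
    X = expr.to_numpy(dtype=float)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        # average ranks, descending: rank 1 = highest expression
        r = stats.rankdata(-X[:, j], method="average")
        order = np.argsort(r, kind="stable")
        sorted_in = in_set[order]
        sorted_rank = r[order]
        # weight by rank from the bottom so the top gene carries N^alpha
        w = np.where(sorted_in, (n_genes - sorted_rank + 1.0) ** alpha, 0.0)
        cdf_in = np.cumsum(w) / w.sum()
        cdf_out = np.cumsum(~sorted_in) / (n_genes - n_in)
        scores[j] = float(np.sum(cdf_in - cdf_out))
    if normalize:
        scores = scores / (n_genes - n_in)
    return pd.Series(scores, index=expr.columns)


def differential_panel(
    expr: pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    panel: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon differential expression of a gene panel between groups.

    ``labels`` marks the comut+ group (True). Returns per tested gene the
    group means, mean difference (comut+ − comut−), Wilcoxon p, BH-FDR over
    the tested panel only, and a significance flag. Absent panel genes are
    reported with NaN statistics and excluded from the FDR family.
    """
    expr = _check_expr(expr)
    lab = np.asarray(labels, dtype=bool)
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    present = [g for g in panel if g in expr.index]
    absent = [g for g in panel if g not in expr.index]
    rows = []
    for g in present:
        x = expr.loc[g].to_numpy(dtype=float)
        a, b = x[lab], x[~lab]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((g, a.mean(), b.mean(), a.mean() - b.mean(), p))
    table = pd.DataFrame(
        rows, columns=["gene", "mean_pos", "mean_neg", "mean_diff", "p_value"]
    ).set_index("gene")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    for g in absent:
        table.loc[g] = [np.nan] * 5 + [False]
    return table


@dataclass
class GseaResult:
    """Preranked GSEA output per gene set."""

    table: pd.DataFrame  # index = set; es, nes, p_value, fdr, size
    ranking: pd.Series  # gene -> t score, descending
    n_perm: int
    seed: int


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic of a (pos) vs b (neg)."""
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    denom = np.sqrt(va / a.shape[1] + vb / b.shape[1])
    denom[denom == 0] = np.finfo(float).tiny
    return (ma - mb) / denom


def _es_from_ranking(t_sorted: np.ndarray, in_set_sorted: np.ndarray) -> float:
    """Weighted Kolmogorov–Smirnov running-sum enrichment score (weight |t|)."""
    w = np.abs(t_sorted) * in_set_sorted
    total = w.sum()
    n = len(t_sorted)
    n_in = int(in_set_sorted.sum())
    if total == 0:
        # degenerate: all set genes have t == 0; fall back to unweighted
        w = in_set_sorted.astype(float)
        total = w.sum()
    step_in = np.cumsum(w) / total
    step_out = np.cumsum(~in_set_sorted.astype(bool)) / (n - n_in)
    running = step_in - step_out
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    expr: pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> GseaResult:
    """GSEA on the Welch-t-ranked gene list with a gene-permutation null.

    Genes are ranked by the two-sample Welch t statistic comut+ vs comut−.
    Per set, the enrichment score is the extremum of the weighted KS running
    sum (weight |t|). The null redistributes set membership uniformly over
    genes (``n_perm`` draws from a seeded generator); the permutation p is
    the fraction of same-sign null scores at least as extreme, and NES is
    the score divided by the mean |null score| of matching sign. BH-FDR
    across the scored sets.
    """
    expr = _check_expr(expr)
    lab = np.asarray(labels, dtype=bool)
    if lab.sum() < 3 or (~lab).sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    X = expr.to_numpy(dtype=float)
    t = _welch_t(X[:, lab], X[:, ~lab])
    order = np.argsort(-t, kind="stable")
    t_sorted = t[order]
    genes_sorted = expr.index.to_numpy()[order]
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    rng = np.random.default_rng(seed)
    rows = []
    for gs in gene_sets:
        idx = np.array([gene_pos[g] for g in gs.genes if g in gene_pos], dtype=int)
        size = len(idx)
        if size < min_size or size > max_size:
            rows.append((gs.name, np.nan, np.nan, np.nan, size, "size out of bounds"))
            continue
        in_set = np.zeros(len(genes_sorted), dtype=bool)
        in_set[idx] = True
        es = _es_from_ranking(t_sorted, in_set)
        null = np.empty(n_perm)
        for k in range(n_perm):
            perm = np.zeros(len(genes_sorted), dtype=bool)
            perm[rng.choice(len(genes_sorted), size=size, replace=False)] = True
            null[k] = _es_from_ranking(t_sorted, perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.mean(np.abs(same_sign))
        rows.append((gs.name, es, nes, p, size, ""))
    table = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p_value", "size", "note"]
    ).set_index("set")
    scored = table["p_value"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if scored.any():
        fdr[scored] = bh_fdr(table.loc[scored, "p_value"].to_numpy())
    table["fdr"] = fdr
    ranking = pd.Series(t_sorted, index=genes_sorted)
    return GseaResult(table=table, ranking=ranking, n_perm=n_perm, seed=seed)
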