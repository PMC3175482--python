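"""Post-processing of selected gene sets across phenotypes.

Given the per-phenotype gene sets chosen by the sparse models, this module
summarises where the associations fall: which genes influence many
phenotypes (pleiotropy), whether functional or structural gene categories
(essentiality, paralogy, frameshifts, stop-codon variants, copy-number
variation, GO terms) are over- or under-represented among influential genes
(one-sided Fisher exact tests with Benjamini-Hochberg adjustment), whether
influential genes evolve faster (Welch t-test on per-gene
non-synonymous/synonymous rate ratios), and coordinate exports for
correlation biplots and chromosome maps.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_features import read_blast_tabular
from .stpls_core import STPLSModel

logger = logging.getLogger("stpls")

#: Raw-p significance ladder and its marks (10% *, 5% **, 1% ***).
ALPHA_MARKS = ((0.01, "***"), (0.05, "**"), (0.10, "*"))
#: Marks for FDR-adjusted p at the same levels.
ADJ_MARKS = ((0.01, "•••"), (0.05, "••"), (0.10, "•"))


def significance_mark(p: float, marks=ALPHA_MARKS) -> str:
    for alpha, mark in marks:
        if p < alpha:
            return mark
    return ""


def classify_paralogs(
    blastp_rows,
    lengths: pd.Series,
    *,
    e_max: float = 1e-10,
    min_cov: float = 0.5,
) -> pd.Series:
    """Flag reference genes with a within-genome homolog (paralog).

    A gene is a paralog iff it has a blastp hit against a *different*
    reference gene with E-value below ``e_max`` whose alignment covers at
    least ``min_cov`` of the query's length.  ``blastp_rows`` is a path,
    stream or DataFrame of 12-column tabular alignment rows among the
    reference genes; ``lengths`` maps gene id to length in residues.
    Returns a boolean Series over ``lengths``' index.
    """
    if isinstance(blastp_rows, pd.DataFrame):
        raw = blastp_rows
    else:
        raw = read_blast_tabular(blastp_rows)
    flags = pd.Series(False, index=lengths.index)
    if raw.empty:
        return flags
    hits = raw[raw["qseqid"] != raw["sseqid"]]
    hits = hits[hits["evalue"] < e_max]
    if hits.empty:
        return flags
    qlen = hits["qseqid"].map(lengths)
    if qlen.isna().any():
        unknown = sorted(hits.loc[qlen.isna(), "qseqid"].unique())
        raise ValueError(f"blastp queries not in reference set: {unknown[:5]}")
    covered = hits[hits["length"] >= min_cov * qlen]
    flags.loc[flags.index.intersection(covered["qseqid"].unique())] = True
    return flags


@dataclass
class EnrichmentResult:
    """One category's over/under-representation among selected genes.

    ``fold`` is the observed/expected ratio (x/n_sel)/(K/N); ``p`` the
    one-sided Fisher exact (hypergeometric tail) probability of an overlap
    at least as large, ``p_under`` the complementary one-sided test for
    depletion.  ``p_adj`` is filled when the result is part of a corrected
    family (see :func:`enrichment_table`).
    """

    category: str
    N: int
    n_sel: int
    K: int
    x: int
    fold: float
    p: float
    p_under: float
    p_adj: float = math.nan

    @property
    def marks(self) -> str:
        return significance_mark(self.p)

    @property
    def adj_marks(self) -> str:
        return "" if math.isnan(self.p_adj) else significance_mark(self.p_adj, ADJ_MARKS)


def fisher_greater_sf(x, N, K, n_sel):
    """P(X >= x) for X ~ Hypergeometric(N, K, n_sel), vectorized.

    This is the one-sided (enrichment) Fisher exact p for the 2x2 table
    [[x, n_sel - x], [K - x, N - n_sel - K + x]].
    """
    return stats.hypergeom.sf(np.asarray(x) - 1, N, K, n_sel)


def enrich(selected, category, universe, *, label: str = "") -> EnrichmentResult:
    """Fisher exact enrichment of ``category`` within ``selected`` genes.

    All three arguments are gene-id collections with ``selected`` and
    ``category`` subsets of ``universe``.
    """
    universe = set(universe)
    selected = set(selected)
    category = set(category)
    if not universe:
        raise ValueError("empty gene universe")
    if not selected <= universe or not category <= universe:
        raise ValueError("selected and category must be subsets of the universe")
    N, n_sel, K = len(universe), len(selected), len(category)
    x = len(selected & category)
    fold = (x / n_sel) / (K / N) if (n_sel and K) else 0.0
    p = float(fisher_greater_sf(x, N, K, n_sel))
    p_under = float(stats.hypergeom.cdf(x, N, K, n_sel))
    return EnrichmentResult(
        category=label, N=N, n_sel=n_sel, K=K, x=x, fold=fold, p=p, p_under=p_under
    )


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def enrichment_table(
    selected, categories: dict, universe
) -> pd.DataFrame:
    """Enrichment of every category against one selected set, FDR-corrected.

    ``categories`` maps category label to its gene set.  Returns one row per
    category with counts, fold ratio, raw and BH-adjusted p (over the
    category family), and the study's significance marks: '*'/'**'/'***' at
    raw p < 10/5/1% and bullet marks at the same levels for adjusted p.
    """
    results = [
        enrich(selected, genes, universe, label=label)
        for label, genes in categories.items()
    ]
    if results:
        for r, adj in zip(results, adjust_fdr([r.p for r in results])):
            r.p_adj = float(adj)
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "N": [r.N for r in results],
            "n_selected": [r.n_sel for r in results],
            "category_size": [r.K for r in results],
            "overlap": [r.x for r in results],
            "fold": [r.fold for r in results],
            "p": [r.p for r in results],
            "p_under": [r.p_under for r in results],
            "p_adj": [r.p_adj for r in results],
            "marks": [r.marks for r in results],
            "adj_marks": [r.adj_marks for r in results],
        }
    )


@dataclass
class PleiotropySet:
    """Genes selected in at least a given fraction of the phenotypes."""

    genes: list
    counts: pd.Series  # selection count per gene, all genes ever selected
    fraction: float
    min_count: int


def pleiotropy_set(selections: dict, fraction: float = 0.25) -> PleiotropySet:
    """Overall trait-influencing genes: selected in >= ``fraction`` of the
    phenotypes (ceiling convention: 25% of 20 phenotypes means >= 5).

    ``selections`` maps phenotype label to its selected gene set.
    """
    if not selections:
        raise ValueError("need at least one phenotype selection")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    v = len(selections)
    min_count = max(1, math.ceil(fraction * v))
    counts: dict = {}
    for genes in selections.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    counts_s = pd.Series(counts, dtype=int).sort_values(ascending=False)
    members = sorted(g for g, c in counts_s.items() if c >= min_count)
    return PleiotropySet(
        genes=members, counts=counts_s, fraction=fraction, min_count=min_count
    )


@dataclass
class RateComparison:
    mean_selected: float
    mean_other: float
    ratio: float
    t: float
    p: float


def compare_rates(rates: pd.Series, selected) -> RateComparison:
    """Do influential genes evolve faster?  Welch one-sided t-test.

    ``rates`` holds per-gene non-synonymous/synonymous frequency ratios;
    ``selected`` the influential gene set.  Tests mean(selected) >
    mean(other) with unequal variances.
    """
    rates = rates.dropna()
    selected = set(selected)
    sel = rates[rates.index.isin(selected)]
    other = rates[~rates.index.isin(selected)]
    if len(sel) < 2 or len(other) < 2:
        raise ValueError(
            f"need >= 2 genes with rates in each group "
            f"(selected={len(sel)}, other={len(other)})"
        )
    res = stats.ttest_ind(sel, other, equal_var=False, alternative="greater")
    mean_sel, mean_other = float(sel.mean()), float(other.mean())
    return RateComparison(
        mean_selected=mean_sel,
        mean_other=mean_other,
        ratio=mean_sel / mean_other if mean_other else math.inf,
        t=float(res.statistic),
        p=float(res.pvalue),
    )


def biplot_coords(
    model: STPLSModel, X, components: tuple[int, int] = (1, 2)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation-biplot coordinates over two latent components.

    Strain scores are the corresponding columns of T; gene loadings are the
    Pearson correlations of each standardized gene column with each score
    column, so loadings live in [-1, 1] and show each gene's contribution
    to the two underlying dimensions.  ``X`` is the training matrix on the
    original scale (standardized internally with the model's parameters).
    Constant gene columns get loading 0 with a warning.
    """
    c1, c2 = components
    if model.k < max(c1, c2):
        raise ValueError(
            f"model has {model.k} components; requested {components}"
        )
    if isinstance(X, pd.DataFrame):
        Xn = X.loc[:, model.columns].to_numpy(dtype=float)
        index = X.index
    else:
        Xn = np.asarray(X, dtype=float)
        index = pd.RangeIndex(Xn.shape[0])
    Xs = (Xn - model.x_params.mean.to_numpy()) / model.x_params.sd.to_numpy()
    T2 = model.T[:, [c1 - 1, c2 - 1]]
    cols = [f"comp{c1}", f"comp{c2}"]
    scores = pd.DataFrame(T2, index=index, columns=cols)

    Xc = Xs - Xs.mean(axis=0)
    Tc = T2 - T2.mean(axis=0)
    xn = np.sqrt((Xc**2).sum(axis=0))
    tn = np.sqrt((Tc**2).sum(axis=0))
    const = xn == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene columns; loadings set to 0",
            stacklevel=2,
        )
    xn_safe = np.where(const, 1.0, xn)
    load = (Xc.T @ Tc) / np.outer(xn_safe, tn)
    load[const] = 0.0
    load = np.clip(load, -1.0, 1.0)
    loadings = pd.DataFrame(load, index=model.columns, columns=cols)
    return scores, loadings


def chromosome_positions(selected, ann: pd.DataFrame) -> pd.DataFrame:
    """Positions of selected genes for a chromosome-map export.

    ``ann`` is indexed by gene id with columns ``chromosome``, ``strand``,
    ``start``, ``end``.  Rows are sorted by chromosome then start; genes
    with missing coordinates are flagged (``has_coords`` False) and sorted
    last rather than dropped.
    """
    rows = []
    for g in sorted(set(selected)):
        if g in ann.index and pd.notna(ann.at[g, "chromosome"]):
            rows.append(
                (
                    g,
                    ann.at[g, "chromosome"],
                    ann.at[g, "strand"],
                    ann.at[g, "start"],
                    ann.at[g, "end"],
                    True,
                )
            )
        else:
            rows.append((g, "", "", np.nan, np.nan, False))
    out = pd.DataFrame(
        rows, columns=["gene", "chromosome", "strand", "start", "end", "has_coords"]
    )
    out = out.sort_values(
        ["has_coords", "chromosome", "start"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out
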