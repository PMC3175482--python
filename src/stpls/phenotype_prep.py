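"""Phenotype table loading, K-nearest-neighbour imputation, standardization.

Phenotypes are real-valued strain x trait tables (e.g. growth Rate and
Efficiency under environmental stresses) with occasional missing entries.
Missing cells are imputed from the K strains with the most similar overall
phenotype pattern; all model fitting downstream operates on columns centred
to mean 0 and scaled to standard deviation 1 (sample, n-1 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class StandardizationParams:
    """Per-column means and standard deviations of the training data."""

    mean: pd.Series
    sd: pd.Series


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a strain x phenotype table (TSV or CSV by extension).

    First column holds strain labels; empty fields and "NA" are missing.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate strain or phenotype labels")
    return df.astype(float)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index_label="strain", na_rep="NA")


def knn_impute(t: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing phenotype cells from the K most similar strains.

    For a missing cell (i, j): candidate neighbours are the other rows with
    column j observed; similarity is Euclidean distance over the columns
    observed in both rows, computed on per-column standardized values; the
    imputed value is the unweighted mean of the K nearest neighbours' values
    in column j (on the original scale).  Observed cells are never changed.

    The default K = 5 suits tables of a few dozen strains.

    Raises if a column is entirely missing, if any row is entirely missing,
    or if a cell has fewer than K usable neighbours.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    values = t.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    if (~obs).sum() == 0:
        return t.copy()
    if not obs.any(axis=0).all():
        bad = [c for c, ok in zip(t.columns, obs.any(axis=0)) if not ok]
        raise ValueError(f"columns entirely missing: {bad}")
    if not obs.any(axis=1).all():
        bad = [r for r, ok in zip(t.index, obs.any(axis=1)) if not ok]
        raise ValueError(f"rows entirely missing: {bad}")

    # standardize on observed values only (distances only; output stays raw)
    col_mean = np.nanmean(values, axis=0)
    col_sd = np.nanstd(values, axis=0, ddof=1)
    col_sd = np.where((col_sd == 0) | np.isnan(col_sd), 1.0, col_sd)
    z = (values - col_mean) / col_sd

    out = values.copy()
    n = values.shape[0]
    for i, j in zip(*np.nonzero(~obs)):
        dists = np.full(n, np.inf)
        for r in range(n):
            if r == i or not obs[r, j]:
                continue
            shared = obs[i] & obs[r]
            shared[j] = False
            if not shared.any():
                continue
            diff = z[i, shared] - z[r, shared]
            dists[r] = float(np.sqrt(np.dot(diff, diff)))
        usable = np.isfinite(dists)
        if usable.sum() < k:
            raise ValueError(
                f"cell ({t.index[i]!r}, {t.columns[j]!r}): only "
                f"{int(usable.sum())} usable neighbours for K={k}"
            )
        order = np.argsort(dists, kind="stable")[:k]
        out[i, j] = float(np.mean(values[order, j]))
    return pd.DataFrame(out, index=t.index, columns=t.columns)


def standardize(m: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Centre each column to mean 0 and scale to sd 1 (sample, ddof=1)."""
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero) or sd.isna().any():
        raise ValueError(f"zero-variance columns: {list(zero.index)}")
    return (m - mean) / sd, StandardizationParams(mean=mean, sd=sd)


def apply_standardization(m: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Standardize new rows with stored (training) parameters."""
    return (m - params.mean) / params.sd


def destandardize(m: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    return m * params.sd + params.mean
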