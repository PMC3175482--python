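"""Cross-validated choice of component count and shrinkage; permutation nulls.

Model complexity is selected on a grid of component counts (default 1..10)
by shrinkage levels (default 0.70 ... 0.97) with random leave-3-out
cross-validation.  The minimum CVRMSE is itself noisy, so any cell whose
CVRMSE lies within two standard errors of the minimum is an acceptable
model, and among acceptable cells the sparsest is preferred (largest
shrinkage, then fewest components), subject to keeping at least
``min_genes`` selected so that downstream enrichment has comparable gene
lists to work with.

Model quality is summarised by Willmott's index of agreement (d-index) on
the pooled cross-validated predictions, and significance of a fit is judged
against a null distribution obtained by refitting the whole pipeline on
row-shuffled copies of X, which preserves the genotype correlation
structure while severing the genotype-phenotype link.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stpls_core
from .stpls_core import STPLSModel, st_pls_path

logger = logging.getLogger("stpls")

#: The study's shrinkage grid.
DELTA_GRID = (0.70, 0.73, 0.76, 0.79, 0.82, 0.85, 0.88, 0.91, 0.94, 0.97)

#: The study's component grid.
K_GRID = tuple(range(1, 11))


def d_index(obs, pred) -> float:
    """Willmott's index of agreement between observed and predicted vectors.

    d = 1 - sum (p_i - o_i)^2 / sum (|p_i - obar| + |o_i - obar|)^2,
    in [0, 1]; 1 iff the prediction is exact, 0 when the prediction carries
    no more information than the observed mean.  Undefined for a constant
    observed vector.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("obs and pred must be 1-d vectors of equal length")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(o) == 0.0:
        raise ValueError("constant observed vector: d-index undefined")
    obar = o.mean()
    denom = float(np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2))
    d = 1.0 - float(np.sum((p - o) ** 2)) / denom
    # the numerator never exceeds the denominator analytically; clamp the
    # ulp-level negatives that cancellation can produce
    return min(max(d, 0.0), 1.0)


def make_segments(
    n: int, segment_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random disjoint partition of range(n) into leave-``segment_size``-out
    segments.  The last segment absorbs any remainder, so with the default
    size 3 segments have 3 to 5 members."""
    if segment_size < 1 or segment_size > n:
        raise ValueError("segment_size must be in [1, n]")
    perm = rng.permutation(n)
    n_seg = max(1, n // segment_size)
    bounds = [i * segment_size for i in range(n_seg)] + [n]
    return [np.sort(perm[bounds[i]:bounds[i + 1]]) for i in range(n_seg)]


@dataclass
class CVGrid:
    """Cross-validation results over the (components x shrinkage) grid."""

    k_grid: np.ndarray
    delta_grid: np.ndarray
    cvrmse: np.ndarray  # (len(k_grid), len(delta_grid)), NaN where invalid
    se: np.ndarray  # standard error of CVRMSE across segments
    mean_ngenes: np.ndarray  # mean selected-gene count across folds
    valid: np.ndarray  # bool mask; False when any fold over-shrank
    cv_pred: np.ndarray  # (k, delta, n) pooled held-out predictions
    segments: list = field(default_factory=list)
    seed: int | None = None

    def min_cell(self) -> tuple[int, int]:
        """(k index, delta index) of the smallest valid CVRMSE."""
        masked = np.where(self.valid, self.cvrmse, np.inf)
        if not np.isfinite(masked).any():
            raise ValueError("no valid cell in the CV grid")
        return tuple(np.unravel_index(np.argmin(masked), masked.shape))


def cross_validate(
    X,
    y,
    *,
    k_grid=K_GRID,
    delta_grid=DELTA_GRID,
    segment_size: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CVGrid:
    """Leave-``segment_size``-out CV of ST-PLS over the model grid.

    For every random segment, models at every (k, delta) cell are fitted on
    the remaining strains (standardization refitted inside the fold) and the
    held-out strains predicted; squared errors are pooled into a CVRMSE per
    cell, with its standard error taken across segment-level RMSEs.  One
    path fit per (segment, delta) yields all component counts at once.
    A cell is invalid if any fold over-shrank before reaching its k.
    """
    Xf = stpls_core._as_frame(X)
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    n, p = Xf.shape
    if yv.shape != (n,):
        raise ValueError("X and y have mismatched lengths")
    k_grid = np.asarray(sorted(k_grid), dtype=int)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if k_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("empty model grid")
    k_max = int(k_grid.max())
    if k_max > n - segment_size - 1:
        raise ValueError(
            f"largest k={k_max} infeasible with n={n} and "
            f"segment_size={segment_size}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    segments = make_segments(n, segment_size, rng)
    n_seg = len(segments)
    Xv = Xf.to_numpy(dtype=float)

    nk, nd = k_grid.size, delta_grid.size
    sq_err = np.zeros((nk, nd))
    seg_rmse = np.full((n_seg, nk, nd), np.nan)
    ngenes = np.full((n_seg, nk, nd), np.nan)
    reached = np.zeros((n_seg, nd), dtype=int)  # components achieved per fold
    cv_pred = np.full((nk, nd, n), np.nan)

    for s, test_idx in enumerate(segments):
        train = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Xte = Xv[train], Xv[test_idx]
        ytr, yte = yv[train], yv[test_idx]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (Xte - mu) / sd
        ymu, ysd = ytr.mean(), ytr.std(ddof=1)
        if ysd == 0:
            raise ValueError("constant phenotype within a training fold")
        ytr_s = (ytr - ymu) / ysd
        for d, delta in enumerate(delta_grid):
            _, _, _, _, betas, k_valid = st_pls_path(Xtr_s, ytr_s, k_max, delta)
            reached[s, d] = k_valid
            if k_valid == 0:
                continue
            preds = Xte_s @ betas.T * ysd + ymu  # (n_test, k_valid)
            counts = np.count_nonzero(betas, axis=1)
            for ki, k in enumerate(k_grid):
                if k > k_valid:
                    break
                resid = preds[:, k - 1] - yte
                sq_err[ki, d] += float(resid @ resid)
                seg_rmse[s, ki, d] = float(np.sqrt(np.mean(resid**2)))
                ngenes[s, ki, d] = counts[k - 1]
                cv_pred[ki, d, test_idx] = preds[:, k - 1]

    valid = np.ones((nk, nd), dtype=bool)
    for ki, k in enumerate(k_grid):
        valid[ki] = (reached >= k).all(axis=0)
    cvrmse = np.where(valid, np.sqrt(sq_err / n), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.where(
            valid, np.nanstd(seg_rmse, axis=0, ddof=1) / np.sqrt(n_seg), np.nan
        )
        mean_ngenes = np.where(valid, np.nanmean(ngenes, axis=0), np.nan)
    cv_pred[~valid] = np.nan
    return CVGrid(
        k_grid=k_grid,
        delta_grid=delta_grid,
        cvrmse=cvrmse,
        se=se,
        mean_ngenes=mean_ngenes,
        valid=valid,
        cv_pred=cv_pred,
        segments=segments,
        seed=seed,
    )


@dataclass
class ModelChoice:
    """Outcome of the two-standard-error slack selection."""

    k: int
    delta: float
    cvrmse: float
    cvrmse_min: float
    slack_bound: float
    cv_d_index: float
    cv_pred: np.ndarray
    model: STPLSModel
    min_genes_relaxed: bool = False


def select_model(
    grid: CVGrid,
    X,
    y,
    *,
    slack_se: float = 2.0,
    min_genes: int = 25,
    prefer: str = "delta",
) -> ModelChoice:
    """Apply the slack rule to a CV grid and refit the chosen cell on all data.

    Candidates are valid cells whose CVRMSE is at most the grid minimum plus
    ``slack_se`` standard errors (SE of the minimum cell) and whose mean
    selected-gene count across folds is at least ``min_genes``.  Among
    candidates the largest shrinkage wins, ties broken by fewest components
    (``prefer="k"`` swaps that order).  If no candidate meets ``min_genes``,
    the constraint is dropped with a warning and the slack rule alone
    decides.  The d-index is computed from the pooled cross-validated
    predictions of the chosen cell.
    """
    ki_min, di_min = grid.min_cell()
    cvrmse_min = float(grid.cvrmse[ki_min, di_min])
    se_min = float(grid.se[ki_min, di_min])
    bound = cvrmse_min + slack_se * se_min

    ok = grid.valid & (grid.cvrmse <= bound)
    with_genes = ok & (grid.mean_ngenes >= min_genes)
    relaxed = False
    if not with_genes.any():
        warnings.warn(
            f"no candidate cell reaches min_genes={min_genes}; "
            "dropping the gene-count constraint",
            stacklevel=2,
        )
        relaxed = True
        with_genes = ok

    cells = np.argwhere(with_genes)
    if prefer == "delta":
        # max delta, then min k
        order = sorted(cells, key=lambda c: (-grid.delta_grid[c[1]], grid.k_grid[c[0]]))
    elif prefer == "k":
        order = sorted(cells, key=lambda c: (grid.k_grid[c[0]], -grid.delta_grid[c[1]]))
    else:
        raise ValueError("prefer must be 'delta' or 'k'")
    ki, di = order[0]
    k = int(grid.k_grid[ki])
    delta = float(grid.delta_grid[di])

    model = stpls_core.fit(X, y, k=k, delta=delta)
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    pred = grid.cv_pred[ki, di]
    return ModelChoice(
        k=k,
        delta=delta,
        cvrmse=float(grid.cvrmse[ki, di]),
        cvrmse_min=cvrmse_min,
        slack_bound=bound,
        cv_d_index=d_index(yv, pred),
        cv_pred=pred,
        model=model,
        min_genes_relaxed=relaxed,
    )


def run_selection(
    X,
    y,
    *,
    k_grid=K_GRID,
    delta_grid=DELTA_GRID,
    segment_size: int = 3,
    slack_se: float = 2.0,
    min_genes: int = 25,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ModelChoice:
    """CV + slack selection + final refit in one call (one phenotype)."""
    grid = cross_validate(
        X,
        y,
        k_grid=k_grid,
        delta_grid=delta_grid,
        segment_size=segment_size,
        seed=seed,
        rng=rng,
    )
    return select_model(grid, X, y, slack_se=slack_se, min_genes=min_genes)


def null_substreams(seed: int, n_perm: int):
    """Named random substreams for the permutation null: one stream drawing
    the row permutations and one independent CV stream per replicate."""
    perm_ss, cv_ss = np.random.SeedSequence(seed).spawn(2)
    return perm_ss, cv_ss.spawn(n_perm)


def permutation_null(
    X,
    y,
    *,
    n_perm: int,
    seed: int = 0,
    k_grid=K_GRID,
    delta_grid=DELTA_GRID,
    segment_size: int = 3,
    slack_se: float = 2.0,
    min_genes: int = 25,
    permutations=None,
) -> pd.DataFrame:
    """Null distribution of the d-index and selected-gene count.

    Each replicate permutes the rows of X (severing the link to y while
    keeping the gene-gene correlation structure), reruns cross-validation,
    slack selection and the final refit, and records the cross-validated
    d-index and the refit's selected-gene count.  All randomness (row
    permutations and CV partitions) derives from ``seed`` through named
    substreams.  ``permutations`` may inject explicit row orders (e.g. the
    identity) for testing.  Failed replicates are recorded with NaN.

    Returns a DataFrame with columns ``perm``, ``d_index``, ``n_selected``,
    ``failed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xf = stpls_core._as_frame(X)
    n = Xf.shape[0]
    perm_ss, cv_streams = null_substreams(seed, n_perm)
    perm_rng = np.random.default_rng(perm_ss)

    records = []
    for i in range(n_perm):
        if permutations is not None:
            order = np.asarray(permutations[i])
        else:
            order = perm_rng.permutation(n)
        Xp = pd.DataFrame(
            Xf.to_numpy()[order], index=Xf.index, columns=Xf.columns
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                choice = run_selection(
                    Xp,
                    y,
                    k_grid=k_grid,
                    delta_grid=delta_grid,
                    segment_size=segment_size,
                    slack_se=slack_se,
                    min_genes=min_genes,
                    rng=np.random.default_rng(cv_streams[i]),
                )
            records.append((i, choice.cv_d_index, choice.model.n_selected, False))
        except Exception as exc:  # noqa: BLE001 - failures recorded, not fatal
            logger.warning("permutation %d failed: %s", i, exc)
            records.append((i, np.nan, np.nan, True))
    return pd.DataFrame(records, columns=["perm", "d_index", "n_selected", "failed"])
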