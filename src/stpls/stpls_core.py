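"""Soft-Thresholding PLS (ST-PLS) regression for one phenotype.

Univariate-response PLS with orthogonal scores (NIPALS PLS1) in which every
loading-weight vector is sparsified before use.  At component a the raw
weight w = X_a' y_a is

  i)   scaled by its largest absolute entry,
  ii)  soft-thresholded: w_j <- sign(w_j) (|w_j| - delta)_+,
  iii) orthogonalized against previously accepted weight vectors, and
  iv)  normalized to unit length,

after which scores, loadings and deflation proceed as in standard PLS1.
The shrinkage delta in [0, 1) controls sparsity: larger delta zeroes more
genes.  Regression coefficients on the standardized scale are
beta = W (P'W)^{-1} q; the genes with nonzero beta form the selected set,
so fitting and variable selection happen simultaneously.  With delta = 0
the procedure reduces exactly to standard PLS1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype_prep import StandardizationParams

#: Squared-norm floor below which a score or weight vector counts as null.
_TINY = 1e-24


class OverShrunkError(RuntimeError):
    """Soft-thresholding at this delta zeroed the entire weight vector."""

    def __init__(self, delta: float, component: int = 1):
        super().__init__(
            f"all loading weights zero after soft-thresholding at "
            f"delta={delta} (component {component})"
        )
        self.delta = delta
        self.component = component


def st_weight_update(
    w: np.ndarray, delta: float, W_prev: np.ndarray | None = None
) -> np.ndarray:
    """Scale, soft-threshold, orthogonalize and normalize a weight vector.

    ``W_prev`` holds the previously accepted weight vectors as orthonormal
    columns (empty or None for the first component, where orthogonalization
    is a no-op).  Returns a unit vector orthogonal to the columns of
    ``W_prev``.  Raises :class:`OverShrunkError` if thresholding (or the
    subsequent orthogonalization) annihilates the vector.
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    w = np.asarray(w, dtype=float)
    amax = np.max(np.abs(w))
    if amax <= 0.0:
        raise ValueError("weight vector is identically zero")
    w = w / amax
    w = np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)
    if not np.any(w):
        raise OverShrunkError(delta)
    if W_prev is not None and W_prev.size:
        w = w - W_prev @ (W_prev.T @ w)
    nrm = float(np.linalg.norm(w))
    if nrm * nrm <= _TINY:
        raise OverShrunkError(delta)
    return w / nrm


@dataclass
class STPLSModel:
    """A fitted ST-PLS model for a single phenotype.

    All matrices are on the standardized scale.  ``selected`` is the set of
    gene labels with a nonzero regression coefficient.  If the requested
    number of components could not be extracted (over-shrinkage), ``k`` is
    the achieved count and ``truncated`` is True.
    """

    delta: float
    k: int
    k_requested: int
    W: np.ndarray  # p x k loading weights, orthonormal columns
    P: np.ndarray  # p x k X-loadings
    q: np.ndarray  # k y-loadings
    T: np.ndarray  # n x k component scores
    beta: np.ndarray  # p regression coefficients, standardized scale
    columns: pd.Index
    x_params: StandardizationParams
    y_params: StandardizationParams  # scalar series named after the phenotype
    truncated: bool = False
    selected: set = field(init=False)

    def __post_init__(self):
        self.selected = {
            label for label, b in zip(self.columns, self.beta) if b != 0.0
        }

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=pd.RangeIndex(X.shape[1]))


def st_pls_path(
    Xs: np.ndarray, ys: np.ndarray, k_max: int, delta: float
):
    """NIPALS ST-PLS recursion on pre-standardized arrays.

    Returns ``(W, P, q, T, betas, k_valid)`` where ``betas`` stacks the
    coefficient vector for every truncation 1..k_valid (row a-1 is the
    k = a model) — the whole component path in one pass, which is what
    cross-validation consumes.  ``k_valid`` < ``k_max`` means component
    ``k_valid + 1`` over-shrank or the residual was exhausted.
    """
    Xa = np.array(Xs, dtype=float)
    ya = np.array(ys, dtype=float)
    n, p = Xa.shape
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    T = np.zeros((n, k_max))
    betas = np.zeros((k_max, p))
    k_valid = 0
    for a in range(k_max):
        w = Xa.T @ ya
        if float(np.max(np.abs(w))) ** 2 <= _TINY:
            break  # residual covariance exhausted
        try:
            w = st_weight_update(w, delta, W[:, :a])
        except OverShrunkError:
            break
        t = Xa @ w
        tt = float(t @ t)
        if tt <= _TINY:
            break
        P[:, a] = Xa.T @ t / tt
        q[a] = float(ya @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xa -= np.outer(t, P[:, a])
        ya = ya - t * q[a]
        k = a + 1
        # Eq-style coefficients beta = W (P'W)^{-1} q at this truncation
        PtW = P[:, :k].T @ W[:, :k]
        try:
            betas[a] = W[:, :k] @ np.linalg.solve(PtW, q[:k])
        except np.linalg.LinAlgError as exc:  # guarded; W orthonormal
            raise np.linalg.LinAlgError(
                f"singular P'W at component {k}: {exc}"
            ) from exc
        k_valid = k
    return (
        W[:, :k_valid],
        P[:, :k_valid],
        q[:k_valid],
        T[:, :k_valid],
        betas[:k_valid],
        k_valid,
    )


def fit(X, y, k: int, delta: float) -> STPLSModel:
    """Fit an ST-PLS model with ``k`` components at shrinkage ``delta``.

    ``X`` is an n x p matrix (DataFrame with gene columns, or array) and
    ``y`` the length-n phenotype vector; both are standardized internally
    (columns centred, sd 1, sample convention).  Requires n >= 3 and
    k <= n - 1.  If a component beyond the first over-shrinks, the model is
    truncated at the last successful component and flagged; if the *first*
    component over-shrinks no model exists and :class:`OverShrunkError`
    propagates.
    """
    Xf = _as_frame(X)
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    n, p = Xf.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if yv.shape != (n,):
        raise ValueError("X and y have mismatched lengths")
    if isinstance(y, pd.Series) and isinstance(X, pd.DataFrame):
        if not X.index.equals(y.index):
            raise ValueError("X and y row labels are not aligned")
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, n-1] = [1, {n - 1}], got {k}")

    from .phenotype_prep import standardize

    # X standardization is lenient: a column constant across the training
    # rows carries no information, so it is mapped to zeros (sd treated as 1)
    # and can never be selected, instead of aborting the fit.
    mean = Xf.mean(axis=0)
    sd = Xf.std(axis=0, ddof=1)
    sd = sd.mask(sd == 0, 1.0)
    Xs_df = (Xf - mean) / sd
    x_params = StandardizationParams(mean=mean, sd=sd)
    y_name = y.name if isinstance(y, pd.Series) and y.name is not None else "y"
    y_series = pd.DataFrame({y_name: yv})
    ys_df, y_params_df = standardize(y_series)
    y_params = StandardizationParams(mean=y_params_df.mean, sd=y_params_df.sd)

    Xs = Xs_df.to_numpy()
    ys = ys_df[y_name].to_numpy()
    try:
        W, P, q, T, betas, k_valid = st_pls_path(Xs, ys, k, delta)
    except OverShrunkError:
        raise
    if k_valid == 0:
        raise OverShrunkError(delta, component=1)
    return STPLSModel(
        delta=delta,
        k=k_valid,
        k_requested=k,
        W=W,
        P=P,
        q=q,
        T=T,
        beta=betas[k_valid - 1],
        columns=Xf.columns,
        x_params=x_params,
        y_params=y_params,
        truncated=(k_valid < k),
    )


def predict(model: STPLSModel, X_new) -> np.ndarray:
    """Predict phenotype values for new strains on the original y scale.

    Columns of ``X_new`` are matched to the training columns by label (a
    bare array must already be in training column order); the new rows are
    standardized with the *training* parameters, projected through beta, and
    back-transformed with the training y mean and sd.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.columns if c not in X_new.columns]
        extra = [c for c in X_new.columns if c not in set(model.columns)]
        if missing or extra:
            raise ValueError(
                f"column mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        Xn = X_new.loc[:, model.columns].to_numpy(dtype=float)
    else:
        Xn = np.asarray(X_new, dtype=float)
        if Xn.ndim == 1:
            Xn = Xn[None, :]
        if Xn.shape[1] != len(model.columns):
            raise ValueError(
                f"expected {len(model.columns)} columns, got {Xn.shape[1]}"
            )
    mean = model.x_params.mean.to_numpy(dtype=float)
    sd = model.x_params.sd.to_numpy(dtype=float)
    Xs = (Xn - mean) / sd
    yhat_std = Xs @ model.beta
    y_mean = float(model.y_params.mean.iloc[0])
    y_sd = float(model.y_params.sd.iloc[0])
    return yhat_std * y_sd + y_mean
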