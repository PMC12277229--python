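"""Association statistics: Pearson matrix, depth regressions, PCA.

The Pearson matrix uses pairwise-complete observations.  The depth
regressions are ordinary least squares of analyte concentration (mg/L) on
tubewell depth (feet); in the study area both iron and arsenic decline with
depth (shallow aquifers are more contaminated), so the slope and r are
expected negative.  PCA runs on log10-transformed, standardized indicators
via the eigendecomposition of their correlation matrix, with a deterministic
sign convention so loadings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset

__all__ = ["LinearFit", "PcaResult", "pearson_matrix", "fit_depth_regression", "run_pca"]


@dataclass(frozen=True)
class LinearFit:
    w0: float                 # intercept
    w: tuple[float, ...]      # coefficients
    r2: float
    r: float
    n: int


@dataclass
class PcaResult:
    loadings: pd.DataFrame       # components x variables
    explained_pct: np.ndarray    # % of total variance, non-increasing
    scores: np.ndarray           # samples x components
    preprocessing: str


def pearson_matrix(dataset: Dataset, variables: Sequence[str]) -> pd.DataFrame:
    """Symmetric pairwise-complete Pearson matrix with unit diagonal.

    Zero-variance variables yield NaN off-diagonal entries with a warning.
    """
    df = dataset.df[list(variables)]
    n_complete = df.notna().sum()
    if (n_complete < 3).any():
        raise ValueError("pearson_matrix needs >= 3 observations per variable")
    corr = df.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    degenerate = [v for v in variables if df[v].nunique(dropna=True) <= 1]
    if degenerate:
        import warnings
        warnings.warn(f"zero-variance variables, correlations undefined: {degenerate}")
        for v in degenerate:
            corr.loc[v, corr.columns != v] = np.nan
            corr.loc[corr.index != v, v] = np.nan
    return corr


def fit_depth_regression(dataset: Dataset, analyte: str) -> LinearFit:
    """OLS of analyte concentration on depth (simple linear regression)."""
    if analyte not in ("fe", "as"):
        raise ValueError("analyte must be 'fe' or 'as'")
    sub = dataset.df[["depth", analyte]].dropna()
    if len(sub) < 3:
        raise ValueError("fit_depth_regression needs n >= 3")
    x, y = sub["depth"].to_numpy(), sub[analyte].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("depth is constant; regression undefined")
    res = stats.linregress(x, y)
    return LinearFit(w0=float(res.intercept), w=(float(res.slope),),
                     r2=float(res.rvalue) ** 2, r=float(res.rvalue), n=len(sub))


def run_pca(dataset: Dataset, variables: Sequence[str]) -> PcaResult:
    """Correlation-matrix PCA of log10-scaled indicators.

    Zero handling: each variable is shifted by epsilon = half its smallest
    positive observed value before the log, so legitimate zero concentrations
    (non-detects) stay in the analysis.  Components come from ``eigh`` on the
    correlation matrix of the transformed data; each loading row is oriented
    so its largest-magnitude entry is positive.
    """
    df = dataset.df[list(variables)].dropna()
    n, p = df.shape
    if n <= p:
        raise ValueError(f"run_pca needs n > {p} complete rows, got {n}")
    X = df.to_numpy(dtype=float)
    for j, v in enumerate(variables):
        col = X[:, j]
        if (col == 0).all():
            raise ValueError(f"variable {v!r} is all zero; cannot log-scale")
        positive = col[col > 0]
        eps = 0.5 * positive.min()
        X[:, j] = np.log10(col + eps)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variables after transform: {bad}")
    Z = (X - mean) / sd

    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    loadings = eigvec.T  # rows = components
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = Z @ loadings.T
    explained = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{i + 1}" for i in range(p)]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=comp_names, columns=list(variables)),
        explained_pct=explained,
        scores=scores,
        preprocessing="log10(x + 0.5*min positive), centered, unit-scaled; "
                      "correlation-matrix eigendecomposition",
    )
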