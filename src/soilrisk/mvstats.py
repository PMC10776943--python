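"""Multivariate screening statistics: Spearman, KMO, Bartlett, PCA.

These gate and complement the receptor modelling: the Spearman rank
correlation matrix (the survey data are non-normal), the Kaiser-Meyer-Olkin
sampling-adequacy measure, Bartlett's test of sphericity, and a PCA on the
correlation matrix of standardised concentrations with the eigenvalue > 1
retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConcentrationTable, ValidationError

__all__ = ["spearman_matrix", "kmo", "bartlett_sphericity", "pca",
           "PcaResult", "varimax"]


def _frame(table) -> pd.DataFrame:
    return table.df if isinstance(table, ConcentrationTable) else pd.DataFrame(table)


def spearman_matrix(table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metal x metal Spearman rank correlations with p-values.

    Ties are mid-ranked.  Constant columns yield NaN rows/columns (flagged,
    not silently dropped).
    """
    df = _frame(table)
    if len(df) < 3:
        raise ValidationError("need at least 3 sites")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(df.to_numpy())
    rho, p = res.statistic, res.pvalue
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    np.fill_diagonal(rho, 1.0)
    cols = df.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def kmo(corr: pd.DataFrame | np.ndarray) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, with q
    the partial correlations obtained from the inverse correlation matrix.
    Returns the overall measure and the per-variable MSA.  An identity
    correlation matrix has no off-diagonal signal: the result is NaN
    (undefined), not an error.
    """
    R = np.asarray(corr, dtype=float)
    names = (list(corr.columns) if isinstance(corr, pd.DataFrame)
             else list(range(R.shape[0])))
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValidationError("singular correlation matrix") from None
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    mask = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[mask] ** 2).sum()
    q2 = (partial[mask] ** 2).sum()
    if r2 + q2 == 0:
        return float("nan"), pd.Series(np.nan, index=names)
    overall = r2 / (r2 + q2)
    r2_i = (R**2 * mask).sum(axis=1)
    q2_i = (partial**2 * mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        msa = r2_i / (r2_i + q2_i)
    return float(overall), pd.Series(msa, index=names)


def bartlett_sphericity(corr: pd.DataFrame | np.ndarray,
                        n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) ln|R| with df = p(p-1)/2.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValidationError("need n > number of variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValidationError("nonpositive determinant of correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


@dataclass
class PcaResult:
    eigenvalues: pd.Series          # descending
    percent_variance: pd.Series
    cumulative_percent: pd.Series
    loadings: pd.DataFrame          # metal x component, eigvec * sqrt(eigval)
    n_retained: int                 # eigenvalue > 1 rule
    rotated: bool = False


def pca(table, rotate: bool = False) -> PcaResult:
    """PCA on the correlation matrix of standardised concentrations.

    Loadings are eigenvector * sqrt(eigenvalue); each loading column is
    sign-flipped so its largest-magnitude entry is positive (deterministic
    output).  ``rotate=True`` applies a varimax rotation to the retained
    loadings (off by default; eigenvalues reported are the unrotated ones).
    """
    df = _frame(table)
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValidationError("need at least 2 metals and 3 sites")
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[df.std(ddof=1) == 0].tolist()
        raise ValidationError(f"zero-variance column(s): {bad}")
    R = np.corrcoef(df.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]

    load = vecs * np.sqrt(vals)
    # sign convention: largest-|.| entry of each column positive
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    flip[flip == 0] = 1.0
    load = load * flip

    comps = [f"PC{i+1}" for i in range(len(vals))]
    eig = pd.Series(vals, index=comps)
    pct = 100.0 * eig / len(df.columns)
    res = PcaResult(
        eigenvalues=eig,
        percent_variance=pct,
        cumulative_percent=pct.cumsum(),
        loadings=pd.DataFrame(load, index=df.columns, columns=comps),
        n_retained=int((eig > 1.0).sum()),
    )
    if rotate:
        k = max(res.n_retained, 1)
        rotated = varimax(res.loadings.iloc[:, :k].to_numpy())
        res.loadings.iloc[:, :k] = rotated
        res.rotated = True
    return res


def varimax(loadings: np.ndarray, max_iter: int = 500,
            tol: float = 1e-8) -> np.ndarray:
    """Raw varimax rotation of a loading matrix."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p))
        R = u @ vt
        new = s.sum()
        if new <= var * (1 + tol):
            break
        var = new
    return L @ R
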