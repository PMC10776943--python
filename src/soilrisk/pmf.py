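"""Weighted positive matrix factorization (PMF) receptor model.

Approximates a nonnegative sites x metals matrix X as G F with G (sites x
factors) and F (factors x metals) both nonnegative, minimising the
uncertainty-weighted objective

    Q = sum_ij ((x_ij - (G F)_ij) / u_ij)^2 .

The per-cell uncertainty follows the EPA convention: u = (5/6) MDL where
the value is at or below the detection limit, and
u = sqrt((error_fraction * c)^2 + MDL^2) above it.

The optimizer is alternating weighted nonnegative least squares: each sweep
solves every row of G (given F) and every column of F (given G) exactly
with :func:`scipy.optimize.nnls`, so Q is non-increasing sweep to sweep.
Multi-restart: ``n_runs`` random initialisations seeded deterministically
from the master seed; the lowest-Q run is returned.  The scale ambiguity is
resolved by normalising each factor profile row to unit sum, with the
contributions absorbing the scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import ConcentrationTable, ValidationError

__all__ = ["build_uncertainty", "q_value", "fit", "diagnostics",
           "PmfSolution", "UncertaintyMatrix"]


# ---------------------------------------------------------------------------
# Uncertainty model
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyMatrix:
    """Per-cell measurement uncertainties u_ij > 0."""

    values: pd.DataFrame
    error_fraction: float
    mdl: dict[str, float]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValidationError("uncertainties must be strictly positive")


def build_uncertainty(table, mdl: dict[str, float] | float = 0.001,
                      error_fraction: float = 0.1) -> UncertaintyMatrix:
    """EPA-style uncertainty matrix for a concentration table.

    ``mdl`` is the minimum detection limit, a scalar or per-metal map
    (default 0.001 mg/kg for every metal(oid)); ``error_fraction`` the
    relative measurement error (default 0.1).
    """
    df = table.df if isinstance(table, ConcentrationTable) else pd.DataFrame(table)
    if not 0 < error_fraction < 1:
        raise ValidationError("error_fraction must lie in (0, 1)")
    if np.isscalar(mdl):
        mdl = {m: float(mdl) for m in df.columns}
    for m in df.columns:
        if not mdl.get(m, 0) > 0:
            raise ValidationError(f"nonpositive MDL for {m}")
    mdl_row = np.array([mdl[m] for m in df.columns])
    c = df.to_numpy()
    above = np.sqrt((error_fraction * c) ** 2 + mdl_row**2)
    below = (5.0 / 6.0) * mdl_row
    u = np.where(c <= mdl_row, below, above)
    return UncertaintyMatrix(values=pd.DataFrame(u, index=df.index,
                                                 columns=df.columns),
                             error_fraction=error_fraction, mdl=dict(mdl))


def q_value(X: np.ndarray, U: np.ndarray, G: np.ndarray,
            F: np.ndarray) -> float:
    """The weighted objective Q = sum(((X - G F) / U)^2)."""
    X, U, G, F = (np.asarray(a, dtype=float) for a in (X, U, G, F))
    if (U == 0).any():
        raise ValidationError("zero uncertainty cell")
    r = (X - G @ F) / U
    return float(np.sum(r * r))


# ---------------------------------------------------------------------------
# Alternating weighted NNLS
# ---------------------------------------------------------------------------

def _update_g(X, W, F):
    """Row-wise weighted NNLS for G given F; W = 1/U."""
    n, p = X.shape[0], F.shape[0]
    G = np.empty((n, p))
    for i in range(n):
        A = (F * W[i]).T          # metals x factors
        G[i], _ = nnls(A, X[i] * W[i])
    return G


def _update_f(X, W, G):
    m, p = X.shape[1], G.shape[1]
    F = np.empty((p, m))
    for j in range(m):
        A = G * W[:, j][:, None]  # sites x factors
        F[:, j], _ = nnls(A, X[:, j] * W[:, j])
    return F


def _nndsvd(X: np.ndarray, p: int, eps: float = 1e-12):
    """Nonnegative double SVD initialisation (Boutsidis & Gallopoulos).

    Deterministic; used for the first restart.  Each SVD component is split
    into its positive and negative parts and the dominant pair is kept.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    G = np.zeros((n, p))
    F = np.zeros((p, m))
    G[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    F[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for k in range(1, min(p, len(S))):
        u, v = U[:, k], Vt[k]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            scale = np.sqrt(S[k] * n_up * n_vp)
            gu, fv = up / max(n_up, eps), vp / max(n_vp, eps)
        else:
            scale = np.sqrt(S[k] * n_un * n_vn)
            gu, fv = un / max(n_un, eps), vn / max(n_vn, eps)
        G[:, k] = scale * gu
        F[k] = scale * fv
    mean = X.mean() or 1.0
    G[G < eps] = eps * mean
    F[F < eps] = eps * mean
    return G, F


@dataclass
class PmfSolution:
    """Best-of-restarts factorization with bookkeeping."""

    G: pd.DataFrame
    F: pd.DataFrame
    Q: float
    scaled_residuals: pd.DataFrame
    q_history: list[float]
    n_runs: int
    best_run: int
    converged: bool
    run_q: list[float] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.F.shape[0]

    def q_per_dof(self, n_cells: int | None = None) -> float:
        n, m = self.G.shape[0], self.F.shape[1]
        p = self.n_factors
        dof = n * m - p * (n + m)
        return self.Q / max(dof, 1)


def fit(X, U, n_factors: int, n_runs: int = 20, seed: int = 0,
        max_sweeps: int = 2000, tol: float = 1e-8) -> PmfSolution:
    """Multi-restart weighted PMF.

    ``X`` is a ConcentrationTable/DataFrame/array, ``U`` an
    UncertaintyMatrix or matching array.  Convergence: relative Q change
    below ``tol`` over a full sweep; non-convergence of the best run is
    reported via ``converged`` and a warning, never silently.
    """
    if isinstance(X, ConcentrationTable):
        X = X.df
    sites = list(X.index) if isinstance(X, pd.DataFrame) else None
    metals = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    Ua = U.values.to_numpy() if isinstance(U, UncertaintyMatrix) else np.asarray(U, dtype=float)
    if Xa.shape != Ua.shape:
        raise ValidationError("X and U shapes differ")
    if (Xa < 0).any():
        raise ValidationError("X must be nonnegative")
    if (Ua <= 0).any():
        raise ValidationError("uncertainties must be strictly positive")
    n, m = Xa.shape
    if not 0 < n_factors < min(n, m):
        raise ValidationError("n_factors must satisfy 0 < p < min(sites, metals)")

    W = 1.0 / Ua
    scale = Xa.mean() or 1.0
    master = np.random.SeedSequence(seed)
    best = None
    run_q = []
    for run, child in enumerate(master.spawn(n_runs)):
        if run == 0:
            # deterministic SVD-based start; remaining runs explore randomly
            G, F = _nndsvd(Xa, n_factors)
        else:
            rng = np.random.default_rng(child)
            G = rng.uniform(0.1, 1.0, (n, n_factors))
            F = rng.uniform(0.1, 1.0, (n_factors, m)) * scale
        q_prev = q_value(Xa, Ua, G, F)
        history = [q_prev]
        converged = False
        for _ in range(max_sweeps):
            G = _update_g(Xa, W, F)
            F = _update_f(Xa, W, G)
            q = q_value(Xa, Ua, G, F)
            history.append(q)
            if q_prev - q <= tol * max(q_prev, 1e-300):
                converged = True
                q_prev = q
                break
            q_prev = q
        run_q.append(q_prev)
        if best is None or q_prev < best[0]:
            best = (q_prev, G, F, history, run, converged)

    q, G, F, history, run, converged = best
    if not converged:
        warnings.warn(f"PMF best run did not converge in {max_sweeps} sweeps; "
                      f"achieved Q = {q:.6g}", RuntimeWarning)

    # resolve scale: unit-sum profile rows, contributions absorb the scale
    row_sum = F.sum(axis=1)
    keep = row_sum > 0
    row_sum[~keep] = 1.0
    F = F / row_sum[:, None]
    G = G * row_sum[None, :]

    factors = [f"F{k+1}" for k in range(n_factors)]
    sites = sites or list(range(n))
    metals = metals or list(range(m))
    resid = pd.DataFrame((Xa - G @ F) / Ua, index=sites, columns=metals)
    return PmfSolution(
        G=pd.DataFrame(G, index=sites, columns=factors),
        F=pd.DataFrame(F, index=factors, columns=metals),
        Q=q, scaled_residuals=resid, q_history=history,
        n_runs=n_runs, best_run=run, converged=converged, run_q=run_q)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def diagnostics(solution: PmfSolution, X) -> dict:
    """Per-metal fit quality and factor contribution shares.

    Returns per-metal r^2 between observed and reconstructed columns, the
    fraction of |scaled residuals| <= 3 (and <= 1), and the factor percent
    contribution per metal (column-normalised mass, rows sum to 100).
    """
    if isinstance(X, ConcentrationTable):
        X = X.df
    Xa = np.asarray(X, dtype=float)
    recon = solution.G.to_numpy() @ solution.F.to_numpy()
    metals = list(solution.F.columns)

    r2 = {}
    for j, mtl in enumerate(metals):
        obs, pred = Xa[:, j], recon[:, j]
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            r2[mtl] = 1.0 if np.allclose(obs, pred) else np.nan
        else:
            r2[mtl] = float(np.corrcoef(obs, pred)[0, 1] ** 2)

    sr = solution.scaled_residuals.to_numpy()
    # factor mass per metal: f_kj weighted by total factor contribution
    mass = solution.F.to_numpy() * solution.G.to_numpy().sum(axis=0)[:, None]
    total = mass.sum(axis=0)
    total[total == 0] = 1.0
    percent = pd.DataFrame(100.0 * mass / total,
                           index=solution.F.index, columns=metals)
    return {
        "r2": pd.Series(r2),
        "frac_abs_resid_le_1": float((np.abs(sr) <= 1).mean()),
        "frac_abs_resid_le_3": float((np.abs(sr) <= 3).mean()),
        "percent_contribution": percent,
    }
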