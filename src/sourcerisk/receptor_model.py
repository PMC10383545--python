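"""Uncertainty-weighted non-negative factorization of speciation matrices.

The receptor model approximates the data matrix X (samples x species)
by G @ F with G, F >= 0, minimizing the weighted objective

    Q = sum_ij ((x_ij - (GF)_ij) / u_ij)^2,

where u_ij are the per-cell measurement uncertainties.  Under a
correctly specified uncertainty model the expected value of Q is about
the number of data points minus the number of fitted parameters,

    Qexp = n*m - K*(n + m),

so Q/Qexp near 1 indicates a well-specified K-factor solution; the scan
over K uses the flattening of Q/Qexp to pick the factor number.

The solver uses multiplicative updates (Lee-Seung form with per-cell
weights 1/u^2), which keep G and F nonnegative and never increase Q.
Rotational ambiguity is not resolved; reproducibility comes from seeded
multi-start and the scale ambiguity is fixed by normalizing each profile
row to sum 1 over the mass species, folding the scale into G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

_EPS = 1e-12


def q_expected(n: int, m: int, K: int) -> float:
    """Degrees-of-freedom expectation of Q: n*m - K*(n+m)."""
    val = n * m - K * (n + m)
    if val <= 0:
        raise ValueError(f"over-parameterized: n*m - K*(n+m) = {val} <= 0 "
                         f"for n={n}, m={m}, K={K}")
    return float(val)


@dataclass
class FactorModel:
    """A fitted non-negative factorization with its diagnostics."""

    G: np.ndarray                  # n x K contributions (ng/m3 scale)
    F: np.ndarray                  # K x m profiles (rows sum to 1 over mass species)
    Q: float
    Qexp: float | None
    n_iter: int
    converged: bool
    seed: int
    start_index: int = 0
    columns: list[str] | None = None
    q_history: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.G.shape[1]

    @property
    def q_ratio(self) -> float | None:
        return None if self.Qexp is None else self.Q / self.Qexp

    def reconstruct(self) -> np.ndarray:
        return self.G @ self.F


def _as_array(x) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    return np.asarray(x, dtype=float), None


def _q_value(X: np.ndarray, W: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    R = X - G @ F
    return float(np.sum(W * R * R))


def fit(X, U, K: int, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6,
        tol_window: int = 10, mass_index: Sequence[int] | None = None,
        check_monotone: bool = False, track_history: bool = False) -> FactorModel:
    """Single-start weighted NMF.

    Deterministic given (X, U, K, seed).  Convergence is declared when
    the relative per-iteration decrease of Q stays below ``tol`` for
    ``tol_window`` consecutive iterations; otherwise the model is
    returned with ``converged=False`` and a warning.  With
    ``check_monotone`` the monotone-descent invariant of the update is
    asserted at every iteration.
    """
    X, columns = _as_array(X)
    Uarr, _ = _as_array(getattr(U, "values", U))
    if X.shape != Uarr.shape:
        raise ValueError(f"X {X.shape} and U {Uarr.shape} must have the same shape")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Uarr)):
        raise ValueError("X and U must be finite (apply the missing-data policy first)")
    if np.any(Uarr <= 0):
        raise ValueError("uncertainties must be strictly positive")
    n, m = X.shape
    if not 1 <= K <= min(n, m):
        raise ValueError(f"K={K} must be in [1, min(n,m)={min(n, m)}]")

    W = 1.0 / (Uarr * Uarr)
    WX = W * X
    rng = np.random.default_rng(seed)
    col_scale = np.maximum(X.mean(axis=0), _EPS)
    G = np.abs(rng.standard_normal((n, K))) + 0.1
    F = (np.abs(rng.standard_normal((K, m))) + 0.1) * (col_scale[None, :] / K)

    q_prev = _q_value(X, W, G, F)
    history = [q_prev] if track_history else None
    below = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        GF = G @ F
        G *= (WX @ F.T) / ((W * GF) @ F.T + _EPS)
        GF = G @ F
        F *= (G.T @ WX) / (G.T @ (W * GF) + _EPS)
        q = _q_value(X, W, G, F)
        if track_history:
            history.append(q)
        if check_monotone and q > q_prev * (1.0 + 1e-9) + 1e-12:
            raise AssertionError(f"Q increased at iteration {it}: {q_prev} -> {q}")
        rel = (q_prev - q) / max(q, _EPS)
        below = below + 1 if abs(rel) < tol else 0
        q_prev = q
        if below >= tol_window:
            converged = True
            break
    if not converged:
        warnings.warn(f"weighted NMF did not converge in {max_iter} iterations "
                      f"(K={K}, seed={seed})", RuntimeWarning, stacklevel=2)

    # fold scale into G: each profile row sums to 1 over the mass species
    midx = np.asarray(mass_index, dtype=int) if mass_index is not None else np.arange(m)
    scale = F[:, midx].sum(axis=1)
    ok = scale > 0
    F[ok] /= scale[ok, None]
    G[:, ok] *= scale[ok][None, :]

    try:
        qexp = q_expected(n, m, K)
    except ValueError:
        qexp = None
    return FactorModel(G=G, F=F, Q=q_prev, Qexp=qexp, n_iter=it,
                       converged=converged, seed=seed, columns=columns,
                       q_history=np.asarray(history) if track_history else None)


def best_fit(X, U, K: int, n_starts: int = 10, seed: int = 0,
             **fit_kwargs) -> FactorModel:
    """Best (lowest-Q) of ``n_starts`` seeded random starts.

    Converged starts are preferred; if none converged the overall best
    is returned.  Start seeds are sub-seeded from ``seed``.
    """
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n_starts)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        models = [fit(X, U, K, seed=int(s), **fit_kwargs) for s in seeds]
    for i, model in enumerate(models):
        model.start_index = i
        better = (best is None
                  or (model.converged and not best.converged)
                  or (model.converged == best.converged and model.Q < best.Q))
        if better:
            best = model
    if not best.converged:
        warnings.warn(f"no start converged for K={K}; returning lowest-Q model",
                      RuntimeWarning, stacklevel=2)
    best.n_converged = sum(m.converged for m in models)  # type: ignore[attr-defined]
    best.all_q = np.array([m.Q for m in models])          # type: ignore[attr-defined]
    return best


@dataclass
class FactorScan:
    """Q/Qexp trajectory of a factor-number scan."""

    table: pd.DataFrame                    # columns: K, Q, Qexp, q_ratio, n_converged
    models: dict[int, FactorModel] = field(default_factory=dict)

    def select_k(self, threshold: float = 0.10) -> int:
        """Smallest K whose Q/Qexp improvement to K+1 falls below
        ``threshold`` (relative drop); falls back to the largest K."""
        t = self.table.sort_values("K").reset_index(drop=True)
        r = t["q_ratio"].to_numpy()
        ks = t["K"].to_numpy()
        for i in range(len(ks) - 1):
            drop = (r[i] - r[i + 1]) / r[i]
            if drop < threshold:
                return int(ks[i])
        return int(ks[-1])


def scan_factors(X, U, k_min: int = 1, k_max: int = 10, n_starts: int = 10,
                 seed: int = 0, keep_models: bool = True, **fit_kwargs) -> FactorScan:
    """Best-of-starts fit for each K in [k_min, k_max]."""
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    rows = []
    models: dict[int, FactorModel] = {}
    for K in range(k_min, k_max + 1):
        model = best_fit(X, U, K, n_starts=n_starts, seed=seed + K, **fit_kwargs)
        rows.append({"K": K, "Q": model.Q, "Qexp": model.Qexp,
                     "q_ratio": model.q_ratio,
                     "n_converged": getattr(model, "n_converged", None)})
        if keep_models:
            models[K] = model
    return FactorScan(pd.DataFrame(rows), models)


def model_fit_stats(X, model: FactorModel) -> tuple[float, float]:
    """OLS slope and R^2 of reconstructed-vs-input over all modelled cells."""
    Xa, _ = _as_array(X)
    rec = model.reconstruct()
    x = Xa.ravel()
    y = rec.ravel()
    if np.std(x) == 0:
        raise ValueError("degenerate input: zero variance across cells")
    res = linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def match_factors(F_est: np.ndarray, F_true: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of estimated to true profiles.

    Returns ``(perm, similarities)`` where estimated factor i matches
    true factor ``perm[i]`` with cosine similarity ``similarities[i]``;
    the assignment maximizes the summed similarity.
    """
    A = np.asarray(F_est, dtype=float)
    B = np.asarray(F_true, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("match_factors requires the same number of factors")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    C = (A @ B.T) / np.outer(np.maximum(na, _EPS), np.maximum(nb, _EPS))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    return perm, C[rows, perm[rows]]
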