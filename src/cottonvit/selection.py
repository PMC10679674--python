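"""Feature-wavelength selection: SPA and CARS.

SPA (successive projections algorithm) is a greedy forward selector
that fights collinearity geometrically: starting from a candidate
column, it repeatedly adds the column with the largest norm after
projection onto the orthogonal complement of the columns already
chosen, then scores every chain prefix by multiple-linear-regression
RMSE on a validation split and keeps the (start, size) with minimal
RMSE.

CARS (competitive adaptive reweighted sampling) runs Monte-Carlo PLS
fits, ranks wavelengths by normalized absolute regression coefficient,
enforces an exponentially decreasing retention ratio (the "exponentially
decreasing function", endpoints r_1 = 1 and r_N = 2/p), resamples the
survivors by coefficient weight, and keeps the iteration whose retained
set minimizes the cross-validated RMSE (RMSECV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    method: str
    indices: np.ndarray                    # sorted unique band indices
    rmse_path: np.ndarray | None = None    # SPA: best RMSE per subset size
    rmsecv_path: np.ndarray | None = None  # CARS: RMSECV per iteration
    retained_path: np.ndarray | None = None  # CARS: enforced count per iteration
    coef_paths: np.ndarray | None = None   # CARS: (iterations, bands) coefficients
    chosen_iteration: int | None = None    # CARS: argmin of rmsecv_path
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("selected indices must be unique")


# ---------------------------------------------------------------------------
# SPA

def _mlr_prefix_rmse(X_tr, y_tr, X_va, y_va, chain):
    """Validation RMSE of intercept+prefix MLR models for every chain prefix.

    One QR factorization of the (intercept | chain) design serves all
    prefixes: the first j+1 columns of Q span the first j chain members.
    """
    n = X_tr.shape[0]
    A = np.column_stack([np.ones(n), X_tr[:, chain]])
    Q, R = np.linalg.qr(A)
    qty = Q.T @ y_tr
    rmses = np.full(len(chain), np.inf)
    for j in range(1, len(chain) + 1):
        Rj = R[: j + 1, : j + 1]
        if abs(Rj[j, j]) < 1e-10 * abs(Rj[0, 0]):
            break  # rank-deficient prefix; larger prefixes share the defect
        beta = np.linalg.solve(Rj, qty[: j + 1])
        pred = beta[0] + X_va[:, chain[:j]] @ beta[1:]
        rmses[j - 1] = np.sqrt(np.mean((pred - y_va) ** 2))
    return rmses


def _projection_chain(X: np.ndarray, start: int, k: int) -> list[int]:
    """Greedy chain of columns by maximal norm after orthogonal projection."""
    P = X.copy()
    chain = [start]
    u = P[:, start].copy()
    scale = float(np.sum(X * X, axis=0).max())
    for _ in range(k - 1):
        uu = u @ u
        if uu <= 1e-12 * scale:
            break
        P -= np.outer(u, (u @ P) / uu)
        norms = np.einsum("ij,ij->j", P, P)
        norms[chain] = -1.0
        if norms.max() <= 1e-12 * scale:
            break  # remaining columns are in the span of the chain
        nxt = int(np.flatnonzero(norms == norms.max()).min())
        chain.append(nxt)
        u = P[:, nxt].copy()
    return chain


def spa_select(X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray,
               max_vars: int = 30) -> SelectionResult:
    """Successive projections algorithm with validation-RMSE model sizing."""
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    n, p = X_train.shape
    max_vars = int(min(max_vars, n - 1, p))
    if max_vars < 1:
        raise ValueError("max_vars must allow at least one variable")
    col_norms = np.linalg.norm(X_train, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("all-zero column(s) in X_train")

    best = (np.inf, max_vars + 1, -1, None)  # rmse, size, start, chain
    rmse_path = np.full(max_vars, np.inf)
    for start in range(p):
        chain = _projection_chain(X_train, start, max_vars)
        rmses = _mlr_prefix_rmse(X_train, y_train, X_val, y_val, chain)
        m = len(chain)
        better = rmses[:m] < rmse_path[:m]
        rmse_path[:m][better] = rmses[:m][better]
        j = int(np.argmin(rmses))
        cand = (float(rmses[j]), j + 1, start, chain[: j + 1])
        if cand[:3] < best[:3]:  # ties: smaller size, then lower start index
            best = cand
    if best[3] is None:
        raise RuntimeError("SPA found no usable chain")
    rmse, size, start, chain = best
    return SelectionResult(method="SPA", indices=np.sort(chain),
                           rmse_path=rmse_path,
                           diagnostics={"start": start, "size": size,
                                        "val_rmse": rmse, "chain": list(chain)})


# ---------------------------------------------------------------------------
# CARS

def _pls_coef(X, y, n_components):
    ncomp = int(min(n_components, X.shape[1], X.shape[0] - 1))
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X, y)
    return np.asarray(pls.coef_).reshape(-1)


def _rmsecv(X, y, n_components, cv_folds):
    n = X.shape[0]
    kf = KFold(n_splits=cv_folds, shuffle=False)
    press = 0.0
    for tr, te in kf.split(X):
        ncomp = int(min(n_components, X.shape[1], len(tr) - 1))
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[tr], y[tr])
        press += float(np.sum((pls.predict(X[te]).ravel() - y[te]) ** 2))
    return np.sqrt(press / n)


def cars_select(X: np.ndarray, y: np.ndarray, n_mc: int = 100,
                cv_folds: int = 5, n_pls_components: int = 3,
                rng_seed: int = 0, mc_sample_ratio: float = 0.8) -> SelectionResult:
    """Competitive adaptive reweighted sampling wavelength selection."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < cv_folds:
        raise ValueError("need at least cv_folds rows")
    if n_pls_components >= n:
        raise ValueError("n_pls_components must be < rows")
    rng = np.random.default_rng(rng_seed)

    # exponentially decreasing retention ratio with r_1 = 1, r_N = 2/p
    N = n_mc
    k_edf = np.log(p / 2.0) / (N - 1)
    a_edf = (p / 2.0) ** (1.0 / (N - 1))
    ratios = a_edf * np.exp(-k_edf * np.arange(1, N + 1))

    retained = np.arange(p)          # working variable set
    rmsecv_path, retained_path, sets = [], [], []
    coef_paths = np.zeros((N, p))
    n_sub = max(int(round(mc_sample_ratio * n)), cv_folds)
    for i in range(N):
        rows = rng.choice(n, size=n_sub, replace=False)
        coef = _pls_coef(X[np.ix_(rows, retained)], y[rows], n_pls_components)
        coef_paths[i, retained] = coef
        w = np.abs(coef)
        if w.sum() == 0:
            w = np.ones_like(w)
        keep_n = int(min(len(retained), max(round(ratios[i] * p), 2)))
        retained_path.append(keep_n)
        # enforced retention: top keep_n by weight (stable sort -> lowest
        # band index wins ties), then adaptive reweighted sampling among them
        order = np.argsort(-w, kind="stable")
        pool = retained[order[:keep_n]]
        w_pool = w[order[:keep_n]]
        if keep_n < len(retained):  # ratio 1 at iteration 1 keeps everything
            draws = rng.choice(pool, size=keep_n, replace=True,
                               p=w_pool / w_pool.sum())
            retained = np.unique(draws)
        else:
            retained = np.sort(pool)
        if len(retained) < max(n_pls_components, 2):
            logger.info("CARS stopped at iteration %d: %d variables left",
                        i + 1, len(retained))
            break
        rmsecv_path.append(_rmsecv(X[:, retained], y, n_pls_components, cv_folds))
        sets.append(retained.copy())

    rmsecv_path = np.asarray(rmsecv_path)
    if rmsecv_path.size == 0:
        raise RuntimeError("CARS produced no evaluable iteration")
    chosen = int(np.argmin(rmsecv_path))
    return SelectionResult(method="CARS", indices=np.sort(sets[chosen]),
                           rmsecv_path=rmsecv_path,
                           retained_path=np.asarray(retained_path[: rmsecv_path.size]),
                           coef_paths=coef_paths[: rmsecv_path.size],
                           chosen_iteration=chosen,
                           diagnostics={"n_mc": n_mc, "cv_folds": cv_folds,
                                        "n_pls_components": n_pls_components,
                                        "rng_seed": rng_seed})
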