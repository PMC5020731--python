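"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles (explicit
normal equations, direct subset enumeration, naive weighting) and shares
no code with the implementation under test.
"""

from itertools import combinations

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients (intercept first) via explicit (X'X)^-1 X'y."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.inv(A.T @ A) @ A.T @ y


def brute_force_impute(values: np.ndarray, sigma_floor_scale: float = 1e-8):
    """Reference implementation of weighted all-subsets regression imputation.

    For every missing cell: enumerate every non-empty predictor subset of
    the other columns, fit by explicit normal equations on complete cases
    (rejecting subsets with fewer than k+2 cases or singular designs),
    weight applicable formulae by 1/residual_sd, and average predictions.
    Returns (completed, cell_sd) arrays.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    completed = values.copy()
    cell_sd = np.zeros_like(values)
    col_sd = np.nanstd(values, axis=0)

    for t in range(p):
        rows_missing = np.flatnonzero(np.isnan(values[:, t]))
        if rows_missing.size == 0:
            continue
        floor = sigma_floor_scale * (col_sd[t] if col_sd[t] > 0 else 1.0)
        others = [j for j in range(p) if j != t]
        fits = []  # (subset, intercept+coefs, sd)
        for k in range(1, len(others) + 1):
            for subset in combinations(others, k):
                cols = (t,) + subset
                ok = ~np.isnan(values[:, cols]).any(axis=1)
                m = int(ok.sum())
                if m < k + 2:
                    continue
                X = values[np.ix_(np.flatnonzero(ok), subset)]
                y = values[ok, t]
                A = np.column_stack([np.ones(m), X])
                if np.linalg.matrix_rank(A) < k + 1:
                    continue
                beta = np.linalg.inv(A.T @ A) @ A.T @ y
                resid = y - A @ beta
                sd = max(np.sqrt(resid @ resid / (m - k - 1)), floor)
                fits.append((subset, beta, sd))
        for i in rows_missing:
            preds, sds = [], []
            for subset, beta, sd in fits:
                x = values[i, list(subset)]
                if np.isnan(x).any():
                    continue
                preds.append(beta[0] + x @ beta[1:])
                sds.append(sd)
            if not preds:
                raise ValueError(f"no applicable formula for row {i}, col {t}")
            w = 1.0 / np.asarray(sds)
            w = w / w.sum()
            completed[i, t] = w @ np.asarray(preds)
            cell_sd[i, t] = w @ np.asarray(sds)
    return completed, cell_sd


def pca_eig_2x2(cov: np.ndarray):
    """Closed-form eigendecomposition of a symmetric 2x2 matrix."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    tr, det = a + c, a * c - b * b
    disc = np.sqrt(tr * tr / 4 - det)
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    if b == 0:
        v1 = np.array([1.0, 0.0]) if a >= c else np.array([0.0, 1.0])
    else:
        v1 = np.array([l1 - c, b])
        v1 = v1 / np.linalg.norm(v1)
    return (l1, l2), v1
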