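"""Independent brute-force oracles used to validate the fast implementations.

Everything here deliberately uses dense linear algebra and direct formulas
(explicit covariance inversion, grid search, naive estimators) so it shares
no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def dense_reml_loglik(delta: float, y: np.ndarray, X: np.ndarray,
                      K: np.ndarray) -> float:
    """Restricted log-likelihood at a fixed variance ratio, by dense algebra.

    Profiled over the genetic-variance scale:
    LL = 0.5 [ m ln(m / 2 pi) - m - m ln(y' P y) - ln|H| - ln|X' H^-1 X|
               + ln|X' X| ]
    with H = K + delta I, P = H^-1 - H^-1 X (X' H^-1 X)^-1 X' H^-1 and
    m = n - rank(X).
    """
    n, q = X.shape
    m = n - q
    H = K + delta * np.eye(n)
    Hinv = np.linalg.inv(H)
    XtHiX = X.T @ Hinv @ X
    P = Hinv - Hinv @ X @ np.linalg.inv(XtHiX) @ X.T @ Hinv
    ypy = float(y @ P @ y)
    sign, logdet_H = np.linalg.slogdet(H)
    assert sign > 0
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    assert sign > 0
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
    assert sign > 0
    return 0.5 * (
        m * np.log(m / (2.0 * np.pi)) - m - m * np.log(ypy)
        - logdet_H - logdet_XtHiX + logdet_XtX
    )


def dense_reml_grid_max(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                        n_points: int = 10_001) -> tuple[float, float]:
    """Max restricted log-likelihood over a dense ln(delta) grid in [-10, 10]."""
    grid = np.linspace(-10.0, 10.0, n_points)
    best_ll, best_delta = -np.inf, np.nan
    for ln_d in grid:
        ll = dense_reml_loglik(float(np.exp(ln_d)), y, X, K)
        if ll > best_ll:
            best_ll, best_delta = ll, float(np.exp(ln_d))
    return best_ll, best_delta


def ols_marker_f_test(y: np.ndarray, X: np.ndarray,
                      w: np.ndarray) -> tuple[float, float, float]:
    """Textbook added-regressor F test: full vs reduced residual sums of squares.

    Returns (effect, F, p) for the marker coefficient in [X | w] with
    1 and n - rank(X) - 1 degrees of freedom.
    """
    n = y.size
    Xf = np.column_stack([X, w])
    beta_f, _, _, _ = np.linalg.lstsq(Xf, y, rcond=None)
    rss_f = float(np.sum((y - Xf @ beta_f) ** 2))
    beta_r, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_r = float(np.sum((y - X @ beta_r) ** 2))
    df_den = n - X.shape[1] - 1
    f = (rss_r - rss_f) / (rss_f / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    return float(beta_f[-1]), float(f), p


def vanraden_kinship_naive(dosages: np.ndarray) -> np.ndarray:
    """Elementwise VanRaden kinship: explicit double loop over sample pairs."""
    n, m = dosages.shape
    p = dosages.mean(axis=0) / 2.0
    M = dosages - 2.0 * p
    poly = (p > 0) & (p < 1)
    c = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = float(np.sum(M[i, poly] * M[j, poly])) / c
    return K


def hudson_fst(dosages: np.ndarray, subpop: np.ndarray) -> float:
    """Hudson-type Fst averaged over markers for two subpopulations.

    Per marker: Fst = (between - within) / between with
    between = p1 (1 - p2) + p2 (1 - p1), within = p1 (1 - p1) n1/(n1 - 1)
    + p2 (1 - p2) n2/(n2 - 1) averaged; ratio-of-averages across markers.
    """
    groups = np.unique(subpop)
    assert groups.size == 2
    d1 = dosages[subpop == groups[0]]
    d2 = dosages[subpop == groups[1]]
    n1, n2 = d1.shape[0], d2.shape[0]
    p1 = d1.mean(axis=0) / 2.0
    p2 = d2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def adjacent_r2(dosages: np.ndarray) -> float:
    """Mean squared correlation of adjacent marker columns."""
    vals = []
    for j in range(dosages.shape[1] - 1):
        a = dosages[:, j] - dosages[:, j].mean()
        b = dosages[:, j + 1] - dosages[:, j + 1].mean()
        va, vb = float(a @ a), float(b @ b)
        if va == 0 or vb == 0:
            continue
        r = float(a @ b) / np.sqrt(va * vb)
        vals.append(r * r)
    return float(np.mean(vals))
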