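"""Mixed-linear-model machinery: spectral REML, P3D contexts, genome scans.

The model is ``y = X b + u + e`` with ``u ~ N(0, sigma_a^2 K)`` and
``e ~ N(0, sigma_e^2 I)``.  Variance components are estimated by restricted
maximum likelihood over the single ratio ``delta = sigma_e^2 / sigma_a^2``:
after projecting the model onto an orthonormal basis of the residual space of
``X`` and diagonalizing the projected kinship, the restricted log-likelihood
becomes a cheap one-dimensional function of ``delta``, maximized by a global
log-scale grid pass followed by bounded local refinement.

Marker tests follow the "population parameters previously determined" (P3D)
scheme: the variance ratio is estimated once without any marker, then frozen,
and each marker is tested by generalized least squares under the fixed
covariance ``V = sigma_a^2 K + sigma_e^2 I``.  A :class:`TestContext` caches
the spectral factorization of ``V`` so each marker costs one O(n) pass in the
rotated coordinates.  ``mlm_scan(..., p3d=False)`` instead re-estimates the
ratio for every marker with that marker in the fixed effects (the exact,
slow variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    DimensionError,
    ValidationError,
)
from .genotypes import GenotypeMatrix
from .kinship import KinshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MarkerTest",
    "ScanResult",
    "TestContext",
    "SpectralContext",
    "IdentityContext",
    "LowRankContext",
    "estimate_variance_components",
    "make_p3d_context",
    "make_lowrank_context",
    "identity_context",
    "test_marker_gls",
    "test_markers_batch",
    "glm_scan",
    "mlm_scan",
]

# search window for ln(delta); EMMA-style global grid then local refinement
_LN_DELTA_LO = -10.0
_LN_DELTA_HI = 10.0
_GRID_POINTS = 100
_EIG_FLOOR = -1e-8  # eigenvalues below this are an input error, above: clipped


@dataclass
class ModelSpec:
    """Fixed-effect design: intercept plus optional covariate columns.

    The random-effect incidence is the identity (one record per individual,
    no grouping), so only ``X`` needs to be carried around.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim != 2:
            raise DimensionError("X must be a 2-d design matrix")
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            raise ValidationError(
                f"design matrix is rank-deficient (rank {r} < {self.X.shape[1]} columns)"
            )

    @classmethod
    def from_covariates(
        cls, n: int, covariates: np.ndarray | pd.DataFrame | None = None
    ) -> "ModelSpec":
        """Intercept-only design, optionally augmented with covariates."""
        cols = [np.ones((n, 1))]
        if covariates is not None and np.size(covariates):
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != n:
                raise DimensionError("covariate rows do not match n")
            cols.append(C)
        return cls(X=np.hstack(cols))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]


@dataclass
class VarianceComponents:
    """REML estimates of the additive and residual variances and their ratio."""

    sigma_a2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_a2
    reml_loglik: float


@dataclass
class MarkerTest:
    """Result of a single 1-df marker F test.

    A collinear or monomorphic marker yields a *no-test sentinel*:
    ``p_value`` and ``f_stat`` are None and ``reason`` says why, so power
    bookkeeping can distinguish "untestable" from "not significant".
    """

    marker_id: str
    effect: float | None
    f_stat: float | None
    df_num: int
    df_den: int
    p_value: float | None
    n_excluded: int = 0
    reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.p_value is not None


@dataclass
class ScanResult:
    """Ordered per-marker tests plus provenance of the model that made them."""

    tests: list[MarkerTest]
    method: str
    kinship_fingerprint: str | None = None
    variance_components: VarianceComponents | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.method:
            raise ValidationError("scan provenance requires a method label")

    def pvalues(self, fill: float = np.nan) -> np.ndarray:
        return np.array(
            [t.p_value if t.p_value is not None else fill for t in self.tests]
        )

    def to_frame(self, G: GenotypeMatrix | None = None) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.tests):
            v = G.variants[i] if G is not None else None
            rows.append(
                {
                    "marker": t.marker_id,
                    "chromosome": v.chromosome if v else "",
                    "position": v.position if v else -1,
                    "effect": t.effect,
                    "f_stat": t.f_stat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p_value": t.p_value,
                    "n_excluded": t.n_excluded,
                    "method": self.method,
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path, G: GenotypeMatrix | None = None) -> None:
        self.to_frame(G).to_csv(path, sep="\t", index=False, na_rep="NA")


# ----------------------------------------------------------------------------
# restricted likelihood
# ----------------------------------------------------------------------------


def _residual_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q (n x (n-q)) of the orthocomplement of col(X)."""
    n, q = X.shape
    U, _, _ = np.linalg.svd(X, full_matrices=True)
    return U[:, q:]


def _project_kinship(K: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors of Q' K Q with the PSD repair policy applied."""
    A = Q.T @ K @ Q
    lam, W = np.linalg.eigh((A + A.T) / 2.0)
    if lam.min() < _EIG_FLOOR:
        raise ValidationError(
            f"kinship is not positive semidefinite (min projected eigenvalue "
            f"{lam.min():.3e} < {_EIG_FLOOR:g})"
        )
    lam = np.clip(lam, 0.0, None)
    return lam, W


def _reml_loglik(ln_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    """Restricted log-likelihood profiled over the variance scale.

    ``lam`` are the eigenvalues of the kinship projected to the residual
    space of X; ``eta2`` the squared rotated data.  Both have length n - q.
    """
    delta = np.exp(ln_delta)
    m = lam.size
    denom = lam + delta
    r = float(np.sum(eta2 / denom))
    return 0.5 * (
        m * np.log(m / (2.0 * np.pi)) - m - m * np.log(r) - float(np.log(denom).sum())
    )


def estimate_variance_components(
    y: np.ndarray, spec: ModelSpec, K: KinshipMatrix
) -> VarianceComponents:
    """REML estimates of (sigma_a^2, sigma_e^2) via spectral 1-d search.

    The restricted likelihood is evaluated on a uniform grid in ln(delta)
    over [-10, 10]; every local maximum is then refined by bounded scalar
    optimization (tolerance 1e-8 in ln delta) and the best refined point is
    returned with the profile variance estimates.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    n, q = spec.n, spec.rank
    if y.size != n:
        raise DimensionError(f"y has length {y.size}, design has {n} rows")
    if K.values.shape[0] != n:
        raise DimensionError("kinship dimension does not match y")
    if n <= q + 1:
        raise DegenerateFitError("need n > rank(X) + 1 observations")

    Q = _residual_basis(spec.X)
    eta = Q.T @ y
    ss_resid = float(eta @ eta)
    ss_total = float(y @ y)
    if ss_resid <= max(ss_total, 1.0) * 1e-12:
        raise DegenerateFitError(
            "trait is constant or perfectly explained by the fixed effects"
        )
    lam, W = _project_kinship(K.values, Q)
    eta2 = (W.T @ eta) ** 2

    grid = np.linspace(_LN_DELTA_LO, _LN_DELTA_HI, _GRID_POINTS)
    ll = np.array([_reml_loglik(g, lam, eta2) for g in grid])

    candidates: list[tuple[float, float]] = []  # (loglik, ln_delta)
    for i in range(_GRID_POINTS):
        left = ll[i - 1] if i > 0 else -np.inf
        right = ll[i + 1] if i < _GRID_POINTS - 1 else -np.inf
        if ll[i] >= left and ll[i] >= right:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, _GRID_POINTS - 1)]
            res = optimize.minimize_scalar(
                lambda x: -_reml_loglik(x, lam, eta2),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            candidates.append((-res.fun, float(res.x)))
    best_ll, best_ln_delta = max(candidates)
    delta = float(np.exp(best_ln_delta))
    m = lam.size
    sigma_a2 = float(np.sum(eta2 / (lam + delta)) / m)
    sigma_e2 = delta * sigma_a2
    return VarianceComponents(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=float(best_ll),
    )


# ----------------------------------------------------------------------------
# fixed-variance test contexts
# ----------------------------------------------------------------------------


class TestContext:
    """Reusable whitening of ``V = sigma_a^2 K + sigma_e^2 I`` for GLS tests.

    Subclasses implement ``_whiten``, a linear map ``A`` with ``A'A = V^{-1}``
    applied to n-vectors or (n, k) matrices.  The F statistic only involves
    inner products ``<a, V^{-1} b>``, so any such map (spectral, identity
    scaling, or low-rank Woodbury) yields identical tests.  The whitened
    design and its pseudo-inverse are cached at construction.
    """

    def __init__(self, spec: ModelSpec):
        self.rank_x = spec.rank
        self.Xw = self._whiten(spec.X)
        self._Xw_pinv = np.linalg.pinv(self.Xw)

    @property
    def n(self) -> int:
        return self.Xw.shape[0]

    def _whiten(self, A: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def transform(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).reshape(-1)
        if v.size != self.n:
            raise DimensionError(f"vector length {v.size} != n {self.n}")
        return self._whiten(v)

    def transform_matrix(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.shape[0] != self.n:
            raise DimensionError("matrix rows do not match context")
        return self._whiten(A)

    def residualize(self, vw: np.ndarray) -> np.ndarray:
        """Residual of an already-whitened array against the whitened design."""
        return vw - self.Xw @ (self._Xw_pinv @ vw)


class SpectralContext(TestContext):
    """Whitening through the full eigendecomposition of K."""

    def __init__(self, spec: ModelSpec, U: np.ndarray, inv_sqrt_d: np.ndarray):
        self._U = U
        self._inv_sqrt_d = inv_sqrt_d
        super().__init__(spec)

    def _whiten(self, A: np.ndarray) -> np.ndarray:
        R = self._U.T @ A
        if R.ndim == 1:
            return R * self._inv_sqrt_d
        return R * self._inv_sqrt_d[:, None]


class IdentityContext(TestContext):
    """V proportional to the identity: ordinary least squares."""

    def __init__(self, spec: ModelSpec, scale: float = 1.0):
        self._inv_sqrt = 1.0 / np.sqrt(scale)
        super().__init__(spec)

    def _whiten(self, A: np.ndarray) -> np.ndarray:
        return A * self._inv_sqrt


class LowRankContext(TestContext):
    """Woodbury whitening for ``V = sigma_e^2 I + (sigma_a^2 / c) M M'``.

    ``M`` (n x r, r typically << n) holds centered marker columns; the left
    singular vectors of M give the r directions where V deviates from
    sigma_e^2 I, so whitening costs O(n r) per vector instead of O(n^2).
    """

    def __init__(
        self,
        spec: ModelSpec,
        M: np.ndarray,
        normalizer: float,
        sigma_a2: float,
        sigma_e2: float,
    ):
        if sigma_e2 <= 0.0:
            raise ValidationError(
                "low-rank whitening requires a positive residual variance"
            )
        U, svals, _ = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
        d = sigma_a2 * (svals**2) / normalizer + sigma_e2
        keep = svals > svals.max(initial=0.0) * 1e-12 if svals.size else slice(0)
        self._Ur = U[:, keep]
        self._coef = np.sqrt(sigma_e2 / d[keep]) - 1.0
        self._inv_sqrt_e = 1.0 / np.sqrt(sigma_e2)
        super().__init__(spec)

    def _whiten(self, A: np.ndarray) -> np.ndarray:
        proj = self._Ur.T @ A
        if A.ndim == 1:
            out = A + self._Ur @ (self._coef * proj)
        else:
            out = A + self._Ur @ (self._coef[:, None] * proj)
        return out * self._inv_sqrt_e


def make_p3d_context(
    vc: VarianceComponents, K: KinshipMatrix, spec: ModelSpec
) -> TestContext:
    """Factor ``V = sigma_a^2 K + sigma_e^2 I`` once for repeated marker tests."""
    n = spec.n
    if K.values.shape[0] != n:
        raise DimensionError("kinship dimension does not match design")
    if vc.sigma_a2 == 0.0:
        return identity_context(spec, scale=vc.sigma_e2 or 1.0)
    lam, U = np.linalg.eigh((K.values + K.values.T) / 2.0)
    if lam.min() < _EIG_FLOOR:
        raise ValidationError(
            f"kinship is not positive semidefinite (min eigenvalue {lam.min():.3e})"
        )
    lam = np.clip(lam, 0.0, None)
    d = vc.sigma_a2 * lam + vc.sigma_e2
    # a zero d can only occur when sigma_e2 = 0 and K is rank-deficient;
    # floor it so the whitening stays finite
    floor = max(d.max(), 1.0) * 1e-12
    d = np.maximum(d, floor)
    return SpectralContext(spec, U=U, inv_sqrt_d=1.0 / np.sqrt(d))


def make_lowrank_context(
    vc: VarianceComponents,
    M: np.ndarray,
    normalizer: float,
    spec: ModelSpec,
) -> TestContext:
    """P3D context for a kinship given by its centered marker columns.

    Equivalent to ``make_p3d_context(vc, K, spec)`` with
    ``K = M M' / normalizer``, but O(n r^2) instead of O(n^3) to build.
    Falls back to the spectral route when sigma_e^2 is not positive.
    """
    if vc.sigma_a2 == 0.0:
        return identity_context(spec, scale=vc.sigma_e2 or 1.0)
    if vc.sigma_e2 <= 0.0:
        K = KinshipMatrix(
            values=(M @ M.T) / normalizer,
            normalizer=normalizer,
            marker_indices=tuple(range(M.shape[1])),
        )
        return make_p3d_context(vc, K, spec)
    return LowRankContext(
        spec, M=M, normalizer=normalizer,
        sigma_a2=vc.sigma_a2, sigma_e2=vc.sigma_e2,
    )


def identity_context(spec: ModelSpec, scale: float = 1.0) -> TestContext:
    """Context with ``V`` proportional to the identity (ordinary least squares)."""
    return IdentityContext(spec, scale=scale)


# relative tolerance below which a residualized marker counts as collinear
_COLLINEAR_TOL = 1e-10


def test_marker_gls(
    ctx: TestContext,
    y: np.ndarray,
    w: np.ndarray,
    marker_id: str = "",
    n_excluded: int = 0,
) -> MarkerTest:
    """1-df F test of the marker effect under the context's fixed covariance."""
    yw = ctx.transform(y)
    ww = ctx.transform(w)
    return _f_test_from_whitened(ctx, yw, ww, marker_id, n_excluded)


def _f_test_from_whitened(
    ctx: TestContext,
    yw: np.ndarray,
    ww: np.ndarray,
    marker_id: str,
    n_excluded: int,
) -> MarkerTest:
    df_den = ctx.n - ctx.rank_x - 1
    ry = ctx.residualize(yw)
    rw = ctx.residualize(ww)
    rw2 = float(rw @ rw)
    w2 = float(ww @ ww)
    if rw2 <= max(w2, 1.0) * _COLLINEAR_TOL:
        return MarkerTest(
            marker_id=marker_id,
            effect=None,
            f_stat=None,
            df_num=1,
            df_den=df_den,
            p_value=None,
            n_excluded=n_excluded,
            reason="marker collinear with fixed effects (or monomorphic)",
        )
    beta = float(rw @ ry) / rw2
    sse = float(ry @ ry) - beta * beta * rw2
    sse = max(sse, 0.0)
    if sse == 0.0 or df_den <= 0:
        f = np.inf
        p = 0.0
    else:
        f = beta * beta * rw2 / (sse / df_den)
        p = float(stats.f.sf(f, 1, df_den))
    p = max(p, np.nextafter(0.0, 1.0))  # keep p strictly positive
    return MarkerTest(
        marker_id=marker_id,
        effect=beta,
        f_stat=float(f),
        df_num=1,
        df_den=df_den,
        p_value=p,
        n_excluded=n_excluded,
    )


def test_markers_batch(
    ctx: TestContext,
    y: np.ndarray,
    W: np.ndarray,
    marker_ids: Sequence[str],
    n_excluded: int | Sequence[int] = 0,
) -> list[MarkerTest]:
    """Vectorized 1-df F tests of many markers sharing one context.

    ``W`` is n x m (one column per marker).  Identical to calling
    :func:`test_marker_gls` per column, but whitening, residualization and
    the F statistics are computed with matrix operations.
    """
    n, m = W.shape
    if n != ctx.n:
        raise DimensionError("marker matrix rows do not match context")
    yw = ctx.transform(y)
    Ww = ctx.transform_matrix(W)
    ry = ctx.residualize(yw)
    Rw = Ww - ctx.Xw @ (ctx._Xw_pinv @ Ww)
    rw2 = np.einsum("ij,ij->j", Rw, Rw)
    w2 = np.einsum("ij,ij->j", Ww, Ww)
    cross = ry @ Rw
    df_den = ctx.n - ctx.rank_x - 1
    ryy = float(ry @ ry)
    excl = (
        np.full(m, n_excluded, dtype=int)
        if np.isscalar(n_excluded)
        else np.asarray(n_excluded, dtype=int)
    )
    out: list[MarkerTest] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / rw2
        sse = np.maximum(ryy - beta * beta * rw2, 0.0)
        f = beta * beta * rw2 / (sse / df_den)
        pvals = stats.f.sf(f, 1, df_den)
    tiny = np.nextafter(0.0, 1.0)
    collinear = rw2 <= np.maximum(w2, 1.0) * _COLLINEAR_TOL
    for j in range(m):
        if collinear[j]:
            out.append(
                MarkerTest(
                    marker_id=marker_ids[j],
                    effect=None,
                    f_stat=None,
                    df_num=1,
                    df_den=df_den,
                    p_value=None,
                    n_excluded=int(excl[j]),
                    reason="marker collinear with fixed effects (or monomorphic)",
                )
            )
        else:
            fj = float(f[j]) if np.isfinite(f[j]) else np.inf
            pj = float(pvals[j]) if np.isfinite(pvals[j]) else 0.0
            out.append(
                MarkerTest(
                    marker_id=marker_ids[j],
                    effect=float(beta[j]),
                    f_stat=fj,
                    df_num=1,
                    df_den=df_den,
                    p_value=max(pj, tiny),
                    n_excluded=int(excl[j]),
                )
            )
    return out


# ----------------------------------------------------------------------------
# genome scans
# ----------------------------------------------------------------------------


def glm_scan(y: np.ndarray, spec: ModelSpec, G: GenotypeMatrix) -> ScanResult:
    """Fixed-effects-only scan: per-marker F tests with V proportional to I."""
    if G.has_missing():
        raise ValidationError("scan requires imputed genotypes")
    ctx = identity_context(spec)
    tests = test_markers_batch(ctx, y, G.dosages, G.marker_ids)
    return ScanResult(tests=tests, method="glm")


def mlm_scan(
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    p3d: bool = True,
) -> ScanResult:
    """Mixed-model scan with kinship ``K``.

    With ``p3d=True`` (default) variance components are estimated once from
    the marker-free model and fixed for every test.  With ``p3d=False`` the
    variance ratio is re-estimated for each marker with that marker included
    in the fixed effects before testing it (exact but ~m times slower).
    """
    if G.has_missing():
        raise ValidationError("scan requires imputed genotypes")
    y = np.asarray(y, dtype=float).reshape(-1)
    if p3d:
        vc = estimate_variance_components(y, spec, K)
        ctx = make_p3d_context(vc, K, spec)
        tests = test_markers_batch(ctx, y, G.dosages, G.marker_ids)
        return ScanResult(
            tests=tests,
            method="mlm-p3d",
            kinship_fingerprint=K.fingerprint,
            variance_components=vc,
        )
    tests: list[MarkerTest] = []
    vc0 = estimate_variance_components(y, spec, K)
    for j, mid in enumerate(G.marker_ids):
        w = G.dosages[:, j]
        Xm = np.column_stack([spec.X, w])
        if np.linalg.matrix_rank(Xm) <= spec.rank:
            tests.append(
                MarkerTest(
                    marker_id=mid,
                    effect=None,
                    f_stat=None,
                    df_num=1,
                    df_den=spec.n - spec.rank - 1,
                    p_value=None,
                    reason="marker collinear with fixed effects (or monomorphic)",
                )
            )
            continue
        try:
            vc_j = estimate_variance_components(y, ModelSpec(X=Xm), K)
        except DegenerateFitError:
            vc_j = vc0
        ctx_j = make_p3d_context(vc_j, K, spec)
        tests.append(test_marker_gls(ctx_j, y, w, marker_id=mid))
    return ScanResult(
        tests=tests,
        method="mlm-exact",
        kinship_fingerprint=K.fingerprint,
        variance_components=vc0,
    )
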