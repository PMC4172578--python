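"""The SUPER association scan: pseudo-QTN selection and complementary kinship.

SUPER (Settlement of MLM Under Progressively Exclusive Relationship) replaces
the all-marker kinship of a standard mixed-model scan with a kinship built
from a small set of *pseudo-QTNs* -- bin-representative markers chosen to
capture the trait's causal signal -- and, when testing each marker, excludes
from that kinship every pseudo-QTN in linkage disequilibrium with it.  This
"complementary trait-specific kinship" removes the confounding between the
random polygenic effect and the tested marker that otherwise erodes power.

The procedure:

1. a preliminary genome scan (GLM by default, MLM selectable) ranks markers;
2. the genome is cut into bins of ``b`` base pairs, each bin is represented
   by its most significant marker, and the ``s`` top-ranked representatives
   become the pseudo-QTN pool -- with ``(s, b)`` chosen to maximize the
   restricted likelihood of the marker-free mixed model whose kinship is
   built from the pool;
3. each marker is F-tested under the kinship from the pool minus the
   pseudo-QTNs whose squared dosage correlation with it reaches the LD
   threshold ``t`` (default 0.10).  Exclusion is genome-wide: LD from
   population structure counts the same as local linkage.

When every pseudo-QTN is excluded for some marker the kinship carries no
information and that marker falls back to a fixed-effects-only test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    DegenerateKinshipError,
    DimensionError,
    OptimizationError,
    ParameterError,
    SelectionError,
)
from .genotypes import GenotypeMatrix, VariantInfo
from .kinship import (
    KinshipMatrix,
    _centered_columns,
    compute_kinship,
    exclude_markers,
)
from .mlm import (
    ModelSpec,
    ScanResult,
    VarianceComponents,
    estimate_variance_components,
    glm_scan,
    identity_context,
    make_lowrank_context,
    make_p3d_context,
    mlm_scan,
    test_markers_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "PseudoQTNSet",
    "assign_bins",
    "choose_representatives",
    "optimize_pseudo_qtns",
    "ld_r2",
    "super_scan",
    "DEFAULT_S_GRID",
    "DEFAULT_B_GRID",
    "DEFAULT_LD_THRESHOLD",
]

# default optimization grids: bin sizes span sparse-to-dense marker maps,
# bin counts span small-to-moderate pseudo-QTN pools
DEFAULT_B_GRID: tuple[int, ...] = (500_000, 5_000_000, 50_000_000)
DEFAULT_S_GRID: tuple[int, ...] = (10, 20, 40, 80)
DEFAULT_LD_THRESHOLD: float = 0.10


@dataclass(frozen=True)
class Bin:
    """One genome segment of ``b`` bp and its most significant marker."""

    chromosome: str
    index: int  # ordinal floor((position - 1) / b) on the chromosome
    start: int  # 1-based inclusive start of the half-open span
    size: int
    representative: int | None = None  # marker column index
    rep_p: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        """Half-open base-pair interval [start, start + size)."""
        return (self.start, self.start + self.size)


@dataclass
class PseudoQTNSet:
    """Bin representatives selected to stand in for the unknown QTNs."""

    markers: tuple[int, ...]  # marker column indices, one per selected bin
    s: int
    b: int
    reml_loglik: float | None = None
    first_stage_p: tuple[float, ...] = ()
    bin_keys: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.markers) != len(set(self.markers)):
            raise ParameterError("pseudo-QTN markers must be distinct")

    def __len__(self) -> int:
        return len(self.markers)

    def to_frame(self, G: GenotypeMatrix) -> pd.DataFrame:
        rows = []
        for i, j in enumerate(self.markers):
            v: VariantInfo = G.variants[j]
            rows.append(
                {
                    "marker": v.id,
                    "chromosome": v.chromosome,
                    "position": v.position,
                    "first_stage_p": self.first_stage_p[i]
                    if self.first_stage_p
                    else np.nan,
                    "bin_index": self.bin_keys[i][1] if self.bin_keys else -1,
                }
            )
        return pd.DataFrame(rows)


def assign_bins(variants: list[VariantInfo], b: int) -> dict[tuple[str, int], list[int]]:
    """Partition markers into ``b``-bp bins per chromosome.

    A marker at 1-based position p maps to bin ``floor((p - 1) / b)`` on its
    chromosome; empty bins are simply absent from the mapping.
    """
    if b < 1:
        raise ParameterError(f"bin size must be >= 1 bp, got {b}")
    partition: dict[tuple[str, int], list[int]] = {}
    for j, v in enumerate(variants):
        key = (v.chromosome, (v.position - 1) // b)
        partition.setdefault(key, []).append(j)
    return partition


def choose_representatives(
    partition: dict[tuple[str, int], list[int]],
    first_stage: ScanResult,
    s: int,
    variants: list[VariantInfo],
    b: int = 0,
) -> PseudoQTNSet:
    """Pick each bin's lowest-p marker, then keep the ``s`` best bins.

    Ties on p within a bin break by smaller position, then lexicographic
    marker id; untestable (sentinel) markers are ineligible.  The returned
    markers are ordered by ascending representative p-value.
    """
    if s < 1:
        raise ParameterError(f"s must be >= 1, got {s}")
    reps: list[tuple[float, int, str, int, tuple[str, int]]] = []
    for key, members in partition.items():
        best = None
        for j in members:
            t = first_stage.tests[j]
            if not t.testable:
                continue
            cand = (t.p_value, variants[j].position, variants[j].id, j)
            if best is None or cand < best:
                best = cand
        if best is not None:
            reps.append((best[0], best[1], best[2], best[3], key))
    if not reps:
        raise SelectionError("no testable marker in any bin")
    reps.sort()
    chosen = reps[: min(s, len(reps))]
    return PseudoQTNSet(
        markers=tuple(r[3] for r in chosen),
        s=len(chosen),
        b=b,
        first_stage_p=tuple(r[0] for r in chosen),
        bin_keys=tuple(r[4] for r in chosen),
    )


def optimize_pseudo_qtns(
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    first_stage: ScanResult,
    s_grid: tuple[int, ...] = DEFAULT_S_GRID,
    b_grid: tuple[int, ...] = DEFAULT_B_GRID,
) -> tuple[PseudoQTNSet, pd.DataFrame]:
    """Choose (s, b) maximizing the restricted likelihood of the pool kinship.

    For every grid cell the bin representatives are selected, a kinship is
    built from them, and the marker-free mixed model's REML log-likelihood is
    recorded.  Ties break toward smaller s, then smaller b.  ``s`` is capped
    at ``n - rank(X) - 2`` so the variance-component fit stays identifiable,
    and at the number of non-empty bins.  Returns the winning set plus the
    full grid log (one row per cell: s, b, s_effective, reml_loglik).
    """
    if not s_grid or not b_grid:
        raise ParameterError("s_grid and b_grid must be non-empty")
    s_cap = spec.n - spec.rank - 2
    rows = []
    best: tuple[float, int, int, PseudoQTNSet] | None = None
    for b in sorted(set(int(x) for x in b_grid)):
        partition = assign_bins(G.variants, b)
        for s in sorted(set(int(x) for x in s_grid)):
            s_eff = min(s, s_cap)
            if s_eff < s:
                logger.info(
                    "optimize_pseudo_qtns: s=%d capped to %d (n - rank(X) - 2)",
                    s, s_eff,
                )
            if s_eff < 1:
                rows.append({"s": s, "b": b, "s_effective": 0,
                             "reml_loglik": np.nan})
                continue
            try:
                pset = choose_representatives(
                    partition, first_stage, s_eff, G.variants, b=b
                )
                if pset.s < s_eff:
                    logger.info(
                        "optimize_pseudo_qtns: s=%d exceeds %d non-empty bins "
                        "at b=%d; evaluated at s=%d", s_eff, pset.s, b, pset.s,
                    )
                K = compute_kinship(G, pset.markers)
                vc = estimate_variance_components(y, spec, K)
                ll = vc.reml_loglik
            except (DegenerateKinshipError, DegenerateFitError, SelectionError) as exc:
                logger.warning("grid cell s=%d b=%d degenerate: %s", s, b, exc)
                rows.append({"s": s, "b": b, "s_effective": np.nan,
                             "reml_loglik": np.nan})
                continue
            pset.reml_loglik = ll
            rows.append({"s": s, "b": b, "s_effective": pset.s,
                         "reml_loglik": ll})
            # maximize loglik; ties -> smaller s, then smaller b
            key = (-ll, pset.s, b)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (ll, pset.s, b, pset)
    grid_log = pd.DataFrame(rows)
    if best is None:
        raise OptimizationError("every (s, b) grid cell was degenerate")
    logger.info(
        "optimize_pseudo_qtns: selected s=%d, b=%d (reml_loglik=%.4f)",
        best[1], best[2], best[0],
    )
    return best[3], grid_log


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (0 if either is constant)."""
    g1 = np.asarray(g1, dtype=float).reshape(-1)
    g2 = np.asarray(g2, dtype=float).reshape(-1)
    if g1.size != g2.size:
        raise DimensionError("dosage vectors differ in length")
    if g1.size < 2:
        raise DimensionError("need at least 2 samples for LD")
    a = g1 - g1.mean()
    b = g2 - g2.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = float(a @ b) / np.sqrt(va * vb)
    return min(r * r, 1.0)


def _ld_r2_matrix(W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """r^2 between every column of W (markers) and every column of P (pool)."""
    Wc = W - W.mean(axis=0)
    Pc = P - P.mean(axis=0)
    sw = np.sqrt(np.einsum("ij,ij->j", Wc, Wc))
    sp = np.sqrt(np.einsum("ij,ij->j", Pc, Pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Wc.T @ Pc) / np.outer(sw, sp)
    R[~np.isfinite(R)] = 0.0  # constant columns: r^2 := 0 by convention
    return np.clip(R * R, 0.0, 1.0)


def super_scan(
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    pseudo: PseudoQTNSet,
    t: float = DEFAULT_LD_THRESHOLD,
    p3d: bool = True,
) -> ScanResult:
    """Genome scan under per-marker complementary pseudo-QTN kinship.

    Variance components are estimated once from the full pool kinship and
    reused for every exclusion set (P3D).  Markers sharing an exclusion set
    share one covariance factorization; a marker whose exclusion empties the
    pool is tested by GLM.  ``t > 1`` means "never exclude"; ``t = 0``
    excludes the whole pool for every marker.
    """
    if len(pseudo) == 0:
        raise ParameterError("pseudo-QTN set is empty")
    if t < 0.0:
        raise ParameterError(f"LD threshold must be >= 0, got {t}")
    if G.has_missing():
        raise ParameterError("scan requires imputed genotypes")
    y = np.asarray(y, dtype=float).reshape(-1)

    pool = list(pseudo.markers)
    K_full = compute_kinship(G, pool, keep_crossproduct=True)
    vc = estimate_variance_components(y, spec, K_full)
    if not p3d:
        # exact mode re-estimates the ratio per marker within each exclusion
        # set's kinship; retained for validation, ~m times slower
        return _super_scan_exact(y, spec, G, pseudo, t, K_full)

    P = G.dosages[:, pool]
    R2 = _ld_r2_matrix(G.dosages, P)  # m x s
    excl_mask = R2 >= t  # which pool members to drop per marker

    # group markers by exclusion set so each set is factorized once
    groups: dict[tuple[int, ...], list[int]] = {}
    for j in range(G.n_markers):
        key = tuple(np.flatnonzero(excl_mask[j]))
        groups.setdefault(key, []).append(j)

    # centered pool columns: each retained subset's kinship is the low-rank
    # M_R M_R' / c_R, whitened in O(n * s^2) instead of an n x n eigensolve
    M_pool, terms = _centered_columns(G, pool)

    tests_by_marker: dict[int, object] = {}
    glm_ctx = identity_context(spec)
    for key, members in groups.items():
        n_excluded = len(key)
        cols = G.dosages[:, members]
        ids = [G.marker_ids[j] for j in members]
        if n_excluded == len(pool):
            ctx = glm_ctx  # kinship emptied: fixed-effects-only fallback
        else:
            retained = np.setdiff1d(np.arange(len(pool)), np.asarray(key, int))
            c_r = float(terms[retained].sum())
            if c_r <= 0.0:
                ctx = glm_ctx  # only monomorphic pool members survive
            else:
                ctx = make_lowrank_context(
                    vc, M_pool[:, retained], c_r, spec
                )
        for j, test in zip(
            members, test_markers_batch(ctx, y, cols, ids, n_excluded=n_excluded)
        ):
            tests_by_marker[j] = test

    tests = [tests_by_marker[j] for j in range(G.n_markers)]
    return ScanResult(
        tests=tests,  # type: ignore[arg-type]
        method="super",
        kinship_fingerprint=K_full.fingerprint,
        variance_components=vc,
        extra={"t": t, "s": pseudo.s, "b": pseudo.b,
               "n_exclusion_sets": len(groups)},
    )


def _super_scan_exact(
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    pseudo: PseudoQTNSet,
    t: float,
    K_full: KinshipMatrix,
) -> ScanResult:
    """Per-marker variance re-estimation variant of :func:`super_scan`."""
    pool = list(pseudo.markers)
    P = G.dosages[:, pool]
    R2 = _ld_r2_matrix(G.dosages, P)
    excl_mask = R2 >= t
    glm_ctx = identity_context(spec)
    tests = []
    vc_cache: dict[tuple[int, ...], VarianceComponents] = {}
    for j in range(G.n_markers):
        key = tuple(np.flatnonzero(excl_mask[j]))
        n_excluded = len(key)
        w = G.dosages[:, j]
        if n_excluded == len(pool):
            ctx = glm_ctx
        else:
            K_sub = (
                K_full
                if n_excluded == 0
                else exclude_markers(K_full, G, [pool[i] for i in key])
            )
            if key not in vc_cache:
                vc_cache[key] = estimate_variance_components(y, spec, K_sub)
            ctx = make_p3d_context(vc_cache[key], K_sub, spec)
        tests.extend(
            test_markers_batch(
                ctx, y, w[:, None], [G.marker_ids[j]], n_excluded=n_excluded
            )
        )
    return ScanResult(
        tests=tests,
        method="super-exact",
        kinship_fingerprint=K_full.fingerprint,
        extra={"t": t, "s": pseudo.s, "b": pseudo.b},
    )


def run_super(
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    K_first: KinshipMatrix | None = None,
    first_stage: str = "glm",
    s_grid: tuple[int, ...] = DEFAULT_S_GRID,
    b_grid: tuple[int, ...] = DEFAULT_B_GRID,
    t: float = DEFAULT_LD_THRESHOLD,
    p3d: bool = True,
) -> tuple[ScanResult, PseudoQTNSet, pd.DataFrame]:
    """End-to-end SUPER: preliminary scan, (s, b) optimization, final scan.

    The preliminary scan is GLM by default (cheapest; the power cost relative
    to an MLM first stage is negligible) or MLM with ``K_first`` (built from
    all markers when not supplied).
    """
    if first_stage == "glm":
        stage1 = glm_scan(y, spec, G)
    elif first_stage == "mlm":
        Kf = K_first if K_first is not None else compute_kinship(G)
        stage1 = mlm_scan(y, spec, G, Kf, p3d=True)
    else:
        raise ParameterError(
            f"first_stage must be 'glm' or 'mlm', got {first_stage!r}"
        )
    pseudo, grid_log = optimize_pseudo_qtns(
        y, spec, G, stage1, s_grid=s_grid, b_grid=b_grid
    )
    result = super_scan(y, spec, G, pseudo, t=t, p3d=p3d)
    return result, pseudo, grid_log
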