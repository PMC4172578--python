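"""Power, calibration and multiple-testing tools, plus the power-study driver.

Power is estimated against an *empirical* null: the p-values of markers known
to be non-causal define the null distribution, the lower alpha-quantile of
that distribution is the per-replicate threshold, and power is the fraction
of causal markers whose p-value passes it.  Averaging over replicates gives
the study estimate with its standard error.  This sidesteps any reliance on
asymptotic test calibration when comparing methods.

:func:`run_power_study` wires the simulator and the scan methods together:
per replicate it simulates a trait on a (fixed or regenerated) structured
panel, runs every requested method, and scores power at the requested type-I
level.  Two null designs are supported: ``random`` (null = all non-QTN
markers) and ``held-out-chromosome`` (QTNs barred from the last chromosome,
whose markers form a linkage-free null).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SuperGwasError
from .genotypes import GenotypeMatrix
from .kinship import compute_kinship, exclude_markers
from .mlm import ModelSpec, ScanResult, glm_scan, mlm_scan
from .simulate import PopulationModel, simulate_genotypes, simulate_phenotype
from .superscan import (
    DEFAULT_B_GRID,
    DEFAULT_LD_THRESHOLD,
    DEFAULT_S_GRID,
    PseudoQTNSet,
    run_super,
    super_scan,
)

logger = logging.getLogger(__name__)

__all__ = [
    "empirical_threshold",
    "compute_power",
    "lambda_gc",
    "adjust_pvalues",
    "PowerStudyConfig",
    "PowerStudyResult",
    "run_power_study",
    "POWER_METHODS",
]

# median of a 1-df chi-square, the reference point for genomic control
_CHI2_1DF_MEDIAN = 0.4549364231195724


def empirical_threshold(null_pvalues: np.ndarray, alpha: float) -> float:
    """Lower alpha-quantile of the null p-values (ceil(alpha k)-th smallest).

    By construction the fraction of null p-values at or below the returned
    threshold is at least alpha, and no smaller order statistic achieves
    that.
    """
    p = np.asarray(null_pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ParameterError("empty null p-value set")
    if not (0.0 < alpha <= 1.0):
        raise ParameterError(f"alpha must lie in (0, 1], got {alpha}")
    if p.size < 1.0 / alpha:
        warnings.warn(
            f"only {p.size} null p-values for alpha={alpha}; the threshold "
            "is the smallest order statistic and will be coarse",
            stacklevel=2,
        )
    k = p.size
    i = int(np.ceil(alpha * k))
    return float(np.sort(p)[i - 1])


def compute_power(qtn_pvalues: np.ndarray, threshold: float) -> float:
    """Fraction of causal-marker p-values at or below the threshold.

    Untestable markers (NaN sentinels) count as misses, never as detections.
    """
    p = np.asarray(qtn_pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("empty QTN p-value set")
    with np.errstate(invalid="ignore"):
        hits = np.nansum(p <= threshold)
    return float(hits) / p.size


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor from 1-df chi-square quantiles."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ParameterError("empty p-value set")
    if (p <= 0.0).any():
        warnings.warn("p-values of 0 clamped for genomic control", stacklevel=2)
        p = np.maximum(p, np.nextafter(0.0, 1.0))
    if (p > 1.0).any():
        raise ParameterError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1DF_MEDIAN)


def adjust_pvalues(pvalues: np.ndarray, method: str, alpha: float = 0.05):
    """Multiple-testing adjustment.

    ``bonferroni-threshold`` returns the genome-wide p-value cutoff
    ``alpha / m`` (a float); ``bh-fdr`` returns Benjamini-Hochberg step-up
    q-values (an array aligned to the input order).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value set")
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if method == "bonferroni-threshold":
        return alpha / p.size
    if method == "bh-fdr":
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        return q
    raise ParameterError(
        f"method must be 'bonferroni-threshold' or 'bh-fdr', got {method!r}"
    )


# ----------------------------------------------------------------------------
# power study driver
# ----------------------------------------------------------------------------

POWER_METHODS = (
    "glm",
    "mlm-all-snps",
    "mlm-all-snps-excl-qtns",
    "mlm-qtn-only",
    "super-known-qtns",
    "super",
)


@dataclass
class PowerStudyConfig:
    """Everything a power study needs, in one reproducible snapshot."""

    model: PopulationModel = field(default_factory=PopulationModel)
    n_per_subpop: int = 100
    n_qtn: int = 20
    h2: float = 0.75
    alpha: float = 0.05
    reps: int = 100
    seed: int = 1
    methods: tuple[str, ...] = POWER_METHODS
    scenario: str = "random"  # or "held-out-chromosome"
    regenerate_genotypes: bool = False  # fresh panel per replicate
    ld_threshold: float = DEFAULT_LD_THRESHOLD
    s_grid: tuple[int, ...] = DEFAULT_S_GRID
    b_grid: tuple[int, ...] = DEFAULT_B_GRID
    first_stage: str = "glm"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(POWER_METHODS)
        if unknown:
            raise ParameterError(
                f"unknown methods {sorted(unknown)}; choose from {POWER_METHODS}"
            )
        if self.scenario not in ("random", "held-out-chromosome"):
            raise ParameterError(
                "scenario must be 'random' or 'held-out-chromosome', "
                f"got {self.scenario!r}"
            )
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")


@dataclass
class PowerStudyResult:
    """Per-replicate records plus the mean +/- SE summary per method."""

    records: pd.DataFrame  # columns: method, rep, power, threshold
    config: PowerStudyConfig
    failed_reps: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby("method")["power"]
        out = pd.DataFrame(
            {
                "power": g.mean(),
                "se": g.std(ddof=1) / np.sqrt(g.count()),
                "reps": g.count(),
            }
        )
        # preserve the configured method order
        return out.reindex([m for m in self.config.methods if m in out.index])

    def write(self, path, summary_path=None) -> None:
        self.records.to_csv(path, sep="\t", index=False)
        if summary_path is not None:
            self.summary().to_csv(summary_path, sep="\t")


def _scan_for_method(
    method: str,
    y: np.ndarray,
    spec: ModelSpec,
    G: GenotypeMatrix,
    qtn: np.ndarray,
    K_all,
    cfg: PowerStudyConfig,
) -> ScanResult:
    if method == "glm":
        return glm_scan(y, spec, G)
    if method == "mlm-all-snps":
        return mlm_scan(y, spec, G, K_all)
    if method == "mlm-all-snps-excl-qtns":
        K = exclude_markers(K_all, G, qtn.tolist())
        return mlm_scan(y, spec, G, K)
    if method == "mlm-qtn-only":
        K = compute_kinship(G, qtn.tolist())
        return mlm_scan(y, spec, G, K)
    if method == "super-known-qtns":
        pseudo = PseudoQTNSet(markers=tuple(int(j) for j in qtn),
                              s=len(qtn), b=0)
        return super_scan(y, spec, G, pseudo, t=cfg.ld_threshold)
    if method == "super":
        result, _, _ = run_super(
            y, spec, G,
            first_stage=cfg.first_stage,
            s_grid=cfg.s_grid, b_grid=cfg.b_grid, t=cfg.ld_threshold,
        )
        return result
    raise ParameterError(f"unknown method {method!r}")


def run_power_study(cfg: PowerStudyConfig) -> PowerStudyResult:
    """Simulate, scan and score every method over ``cfg.reps`` replicates."""
    ss = np.random.SeedSequence(cfg.seed)
    panel_seed, trait_root = ss.spawn(2)
    panel_seed_int = int(panel_seed.generate_state(1)[0] % (2**31))
    trait_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in trait_root.spawn(cfg.reps)
    ]

    excluded_chrom = (
        cfg.model.chromosomes[-1][0]
        if cfg.scenario == "held-out-chromosome"
        else None
    )

    G = None
    K_all = None
    records = []
    failed: list[int] = []
    for rep in range(cfg.reps):
        if G is None or cfg.regenerate_genotypes:
            geno_seed = (
                panel_seed_int if not cfg.regenerate_genotypes
                else (panel_seed_int + rep) % (2**31)
            )
            G = simulate_genotypes(cfg.model, cfg.n_per_subpop, seed=geno_seed)
            K_all = compute_kinship(G, keep_crossproduct=True)
        trait = simulate_phenotype(
            G, cfg.n_qtn, cfg.h2, seed=trait_seeds[rep],
            excluded_chromosome=excluded_chrom,
        )
        spec = ModelSpec.from_covariates(G.n_samples)
        qtn_set = set(trait.qtn_indices.tolist())
        if excluded_chrom is None:
            null_idx = [j for j in range(G.n_markers) if j not in qtn_set]
        else:
            null_idx = [
                j for j, v in enumerate(G.variants)
                if v.chromosome == excluded_chrom
            ]
        for method in cfg.methods:
            try:
                scan = _scan_for_method(
                    method, trait.y, spec, G, trait.qtn_indices, K_all, cfg
                )
            except SuperGwasError as exc:
                logger.warning("rep %d, method %s failed: %s", rep, method, exc)
                failed.append(rep)
                continue
            pvals = scan.pvalues()
            null_p = pvals[null_idx]
            null_p = null_p[np.isfinite(null_p)]
            threshold = empirical_threshold(null_p, cfg.alpha)
            power = compute_power(pvals[sorted(qtn_set)], threshold)
            records.append(
                {"method": method, "rep": rep, "power": power,
                 "threshold": threshold}
            )
    return PowerStudyResult(
        records=pd.DataFrame(records), config=cfg, failed_reps=failed
    )
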