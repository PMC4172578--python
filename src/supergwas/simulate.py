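"""Structured synthetic genotypes and additive traits.

The genotype generator follows a Balding-Nichols model with first-order
local linkage: each marker draws an ancestral allele frequency p uniformly
on [0.1, 0.9]; each subpopulation's frequency is a Beta(p(1-Fst)/Fst,
(1-p)(1-Fst)/Fst) deviate, giving expected differentiation Fst; and within a
haplotype each marker copies the previous marker's allele with probability
``ld_rho`` (resetting at chromosome starts), otherwise draws fresh from the
subpopulation frequency.  This produces the two confounders a mixed-model
GWAS must handle -- population stratification and local LD -- without
pretending to be a coalescent simulation.

Traits are strictly additive: ``n_qtn`` causal markers are drawn uniformly
(optionally avoiding one held-out chromosome), their effects are standard
normal, the genetic value is the effect-weighted dosage sum, and the residual
variance is set from the *realized* additive variance so the target
heritability holds by construction: ``Ve = Va (1 - h2) / h2``.

Genotype draws, QTN placement, effect sizes and residuals each use an
independently spawned random stream, so replicates differ only where
intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .genotypes import GenotypeMatrix, VariantInfo

__all__ = [
    "PopulationModel",
    "SimTrait",
    "simulate_genotypes",
    "simulate_phenotype",
    "QTN_COUNT_PRESETS",
]

# causal-marker counts of the four panel archetypes used throughout the
# power studies (maize-, arabidopsis-, rice- and dog-sized architectures)
QTN_COUNT_PRESETS: dict[str, int] = {
    "maize-like": 27,
    "arabidopsis-like": 20,
    "rice-like": 24,
    "dog-like": 20,
}


@dataclass
class PopulationModel:
    """Parameters of the structured-population genotype generator.

    ``chromosomes`` lists (label, n_markers, length_bp); markers are evenly
    spaced along each chromosome.  ``coding`` selects diploid 0/1/2 dosages
    (two haplotypes per individual) or inbred 0/2 (one doubled haplotype).
    """

    n_subpops: int = 2
    fst: float = 0.2
    ld_rho: float = 0.5
    coding: str = "diploid"
    chromosomes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [(str(c + 1), 300, 150_000_000) for c in range(10)]
    )

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ParameterError(f"n_subpops must be >= 1, got {self.n_subpops}")
        if not (0.0 <= self.fst < 1.0):
            raise ParameterError(f"fst must lie in [0, 1), got {self.fst}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ParameterError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.coding not in ("diploid", "inbred"):
            raise ParameterError(
                f"coding must be 'diploid' or 'inbred', got {self.coding!r}"
            )
        for label, m, length in self.chromosomes:
            if m < 1 or length < m:
                raise ParameterError(
                    f"chromosome {label!r}: need n_markers >= 1 and length >= n_markers"
                )

    @property
    def n_markers(self) -> int:
        return sum(m for _, m, _ in self.chromosomes)


@dataclass
class SimTrait:
    """A simulated additive trait plus its generating truth."""

    y: np.ndarray
    qtn_indices: np.ndarray  # marker column indices of the causal QTNs
    qtn_effects: np.ndarray  # N(0, 1) additive effects, one per QTN
    h2: float
    va: float  # realized variance of the additive values
    ve: float  # residual variance actually used


def _subpop_frequencies(
    p: np.ndarray, fst: float, n_subpops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, shape (n_subpops, m)."""
    if fst == 0.0:
        return np.tile(p, (n_subpops, 1))
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_subpops, p.size))


def simulate_genotypes(
    model: PopulationModel, n_per_subpop: int, seed: int
) -> GenotypeMatrix:
    """Draw a structured genotype panel; deterministic given ``seed``.

    Samples are named ``p<k>_i<j>`` so the subpopulation of origin stays
    recoverable from the identifier.
    """
    if n_per_subpop < 1:
        raise ParameterError(f"n_per_subpop must be >= 1, got {n_per_subpop}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = model.n_subpops * n_per_subpop
    n_hap = 1 if model.coding == "inbred" else 2
    subpop_of = np.repeat(np.arange(model.n_subpops), n_per_subpop)
    hap_subpop = np.repeat(subpop_of, n_hap)  # one row per haplotype

    variants: list[VariantInfo] = []
    blocks: list[np.ndarray] = []
    for label, m, length in model.chromosomes:
        p = rng.uniform(0.1, 0.9, size=m)
        q = _subpop_frequencies(p, model.fst, model.n_subpops, rng)  # (K, m)
        fresh = rng.random((n * n_hap, m)) < q[hap_subpop, :]
        copy = rng.random((n * n_hap, m)) < model.ld_rho
        copy[:, 0] = False  # LD chain restarts at each chromosome
        alleles = np.empty((n * n_hap, m), dtype=bool)
        alleles[:, 0] = fresh[:, 0]
        for j in range(1, m):
            alleles[:, j] = np.where(copy[:, j], alleles[:, j - 1], fresh[:, j])
        dos = alleles.reshape(n, n_hap, m).sum(axis=1).astype(float)
        if model.coding == "inbred":
            dos *= 2.0
        blocks.append(dos)
        spacing = length / (m + 1)
        positions = np.round(spacing * np.arange(1, m + 1)).astype(int)
        positions = np.maximum.accumulate(np.maximum(positions, 1))
        # evenly spaced, strictly increasing where spacing permits
        for k in range(m):
            variants.append(
                VariantInfo(id=f"{label}_{k + 1}", chromosome=label,
                            position=int(positions[k]))
            )
    samples = [
        f"p{subpop_of[i] + 1}_i{i % n_per_subpop + 1}" for i in range(n)
    ]
    return GenotypeMatrix(
        samples=samples, variants=variants, dosages=np.hstack(blocks)
    )


def subpopulation_labels(G: GenotypeMatrix) -> np.ndarray:
    """Recover the subpopulation index encoded in simulated sample names."""
    return np.array([int(s.split("_")[0][1:]) - 1 for s in G.samples])


def simulate_phenotype(
    G: GenotypeMatrix,
    n_qtn: int,
    h2: float,
    seed: int,
    excluded_chromosome: str | None = None,
) -> SimTrait:
    """Simulate an additive trait on an existing genotype panel.

    ``excluded_chromosome`` bars one chromosome from carrying QTNs so its
    markers form a clean empirical null.  ``h2 = 1`` returns the noiseless
    additive value; ``h2 = 0`` is defined as pure noise with variance equal
    to the realized additive variance (the scaling rule divides by zero
    there), with the sampled-but-unused QTNs still recorded.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ParameterError(f"h2 must lie in [0, 1], got {h2}")
    eligible = [
        j
        for j, v in enumerate(G.variants)
        if excluded_chromosome is None or v.chromosome != str(excluded_chromosome)
    ]
    if n_qtn < 1 or n_qtn > len(eligible):
        raise ParameterError(
            f"n_qtn must lie in [1, {len(eligible)}] eligible markers, got {n_qtn}"
        )
    ss = np.random.SeedSequence(seed)
    rng_qtn, rng_eff, rng_res = (np.random.default_rng(s) for s in ss.spawn(3))

    qtn = np.sort(rng_qtn.choice(eligible, size=n_qtn, replace=False))
    effects = rng_eff.normal(0.0, 1.0, size=n_qtn)
    additive = G.dosages[:, qtn] @ effects
    va = float(np.var(additive))
    if h2 == 1.0:
        ve = 0.0
        y = additive.copy()
    elif h2 == 0.0:
        ve = va
        y = rng_res.normal(0.0, np.sqrt(va), size=G.n_samples)
    else:
        ve = va * (1.0 - h2) / h2
        y = additive + rng_res.normal(0.0, np.sqrt(ve), size=G.n_samples)
    return SimTrait(
        y=y, qtn_indices=qtn, qtn_effects=effects, h2=h2, va=va, ve=ve
    )
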