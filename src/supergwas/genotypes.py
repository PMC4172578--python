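"""Genotype, phenotype and covariate containers and standard-format I/O.

Dosages are held on the 0-2 allele-count scale (fractional values are legal,
e.g. after mean imputation or when read from a VCF ``DS`` field).  Missing
genotypes are encoded as ``NaN`` until :func:`impute_missing` replaces them
with the per-marker mean.  Minor-allele frequency is always derived from the
stored dosages as ``min(p, 1 - p)`` with ``p = mean(dosage) / 2`` -- the sign
of the allele coding cancels in every downstream computation (kinship,
F-tests), so no reference/alternate bookkeeping is needed.

Two on-disk formats are supported:

* *numeric-tsv*: a header row ``taxa<TAB>m1<TAB>m2...`` followed by one row
  per sample, with a sidecar map file ``marker<TAB>chromosome<TAB>position``.
* *VCF* (v4.x, biallelic records only), via :mod:`cyvcf2`; ``GT`` is used
  when present, otherwise the ``DS`` dosage field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DimensionError,
    EmptyResultError,
    ParameterError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantInfo",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_variants",
    "impute_missing",
    "align_samples",
]


@dataclass(frozen=True)
class VariantInfo:
    """A single marker locus: identifier, map position and allele frequency.

    ``position`` is a 1-based base-pair coordinate; ``maf`` lives in
    [0, 0.5] and is computed from the dosage column, never read from a file.
    """

    id: str
    chromosome: str
    position: int
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"marker {self.id!r}: position must be >= 1, got {self.position}"
            )
        if not math.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(
                f"marker {self.id!r}: maf must lie in [0, 0.5], got {self.maf}"
            )


def _chromosome_sort_key(label: str):
    """Order chromosome labels numerically when possible, else lexically."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with its variant map.

    ``dosages`` has shape ``(n_samples, n_markers)``; entries are allele
    dosages in [0, 2] or NaN for missing.  Variants are kept sorted by
    (chromosome, position).
    """

    samples: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise DimensionError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} markers"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} outside [0, 2] at sample "
                f"{self.samples[i]!r}, marker {self.variants[j].id!r}"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = next(x for x in ids if ids.count(x) > 1)
            raise ValidationError(f"duplicate marker id {dup!r}")
        self._sort_variants()
        self._refresh_maf()

    # -- derived views ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.variants)

    @property
    def marker_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def allele_freqs(self) -> np.ndarray:
        """Per-marker allele frequency p = mean(dosage)/2 over non-missing.

        A fully missing marker gets NaN (silently; imputation rejects it).
        """
        counts = (~np.isnan(self.dosages)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sums = np.nansum(self.dosages, axis=0)
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dosages=self.dosages[idx, :].copy(),
        )

    # -- internal ----------------------------------------------------------

    def _sort_variants(self) -> None:
        order = sorted(
            range(len(self.variants)),
            key=lambda j: (
                _chromosome_sort_key(self.variants[j].chromosome),
                self.variants[j].position,
            ),
        )
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[j] for j in order]
            self.dosages = self.dosages[:, order]

    def _refresh_maf(self) -> None:
        p = self.allele_freqs()
        maf = np.minimum(p, 1.0 - p)
        self.variants = [
            replace(v, maf=float(m)) for v, m in zip(self.variants, maf)
        ]


@dataclass
class PhenotypeTable:
    """Trait values plus optional fixed-effect covariates, sample-indexed."""

    samples: list[str]
    trait: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        if self.trait.shape != (len(self.samples),):
            raise DimensionError(
                f"trait length {self.trait.shape} does not match "
                f"{len(self.samples)} samples"
            )
        if len(self.covariates) not in (0, len(self.samples)):
            raise DimensionError("covariate rows do not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, indices: Sequence[int]) -> "PhenotypeTable":
        idx = list(indices)
        cov = (
            self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates)
            else pd.DataFrame()
        )
        return PhenotypeTable(
            samples=[self.samples[i] for i in idx],
            trait=self.trait[idx].copy(),
            covariates=cov,
        )


# ----------------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------------


def _default_map_path(path: Path) -> Path:
    return path.with_suffix(".map")


def read_genotypes(
    path: str | Path,
    format: str = "numeric-tsv",
    map_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from ``numeric-tsv`` or ``vcf``.

    numeric-tsv needs a sidecar map file (``marker<TAB>chromosome<TAB>
    position``); by default it is looked up next to ``path`` with a ``.map``
    suffix.  Missing entries (``NA``, empty) stay NaN -- imputation is a
    separate, explicit step.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"genotype file not found: {path}")
    if format == "numeric-tsv":
        mp = Path(map_path) if map_path is not None else _default_map_path(path)
        return _read_numeric_tsv(path, mp)
    if format == "vcf":
        return _read_vcf(path)
    raise ParameterError(
        f"unknown genotype format {format!r}; use 'numeric-tsv' or 'vcf'"
    )


def _read_numeric_tsv(path: Path, map_path: Path) -> GenotypeMatrix:
    if not map_path.exists():
        raise ParseError(f"variant map sidecar not found: {map_path}")
    try:
        table = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "NaN", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if table.shape[1] < 2:
        raise ParseError(f"{path}: header must be 'taxa<TAB>marker1...'")
    samples = table.iloc[:, 0].astype(str).tolist()
    marker_ids = [str(c) for c in table.columns[1:]]
    try:
        dosages = table.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage entry ({exc})") from exc

    vmap = pd.read_csv(map_path, sep="\t", dtype=str)
    if vmap.shape[1] < 3:
        raise ParseError(
            f"{map_path}: expected columns marker<TAB>chromosome<TAB>position"
        )
    vmap.columns = ["marker", "chromosome", "position"] + list(vmap.columns[3:])
    lookup = {}
    for lineno, row in enumerate(vmap.itertuples(index=False), start=2):
        try:
            lookup[str(row.marker)] = (str(row.chromosome), int(row.position))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{map_path}, line {lineno}: bad position") from exc
    variants = []
    for mid in marker_ids:
        if mid not in lookup:
            raise DimensionError(
                f"marker {mid!r} present in {path.name} but absent from map "
                f"{map_path.name}"
            )
        chrom, pos = lookup[mid]
        variants.append(VariantInfo(id=mid, chromosome=chrom, position=pos))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {record.CHROM}:{record.POS} "
                f"({record.ID or '.'}); split or drop it first"
            )
        mid = record.ID if record.ID not in (None, ".") else (
            f"{record.CHROM}:{record.POS}"
        )
        gts = record.genotype.array() if record.gt_types is not None else None
        if gts is not None and gts.size:
            # columns: allele1, allele2, ..., phased flag last
            alleles = gts[:, :-1].astype(float)
            alleles[alleles < 0] = np.nan
            col = alleles.sum(axis=1)
        else:
            ds = record.format("DS")
            if ds is None:
                raise ParseError(
                    f"{path}: record {mid} has neither GT nor DS fields"
                )
            col = np.asarray(ds, dtype=float).reshape(-1)
        variants.append(
            VariantInfo(id=str(mid), chromosome=str(record.CHROM), position=int(record.POS))
        )
        columns.append(col)
    if not columns:
        raise ParseError(f"{path}: no variant records")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_genotypes(
    G: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None
) -> None:
    """Write numeric-tsv genotypes plus the variant-map sidecar."""
    path = Path(path)
    mp = Path(map_path) if map_path is not None else _default_map_path(path)
    frame = pd.DataFrame(G.dosages, columns=G.marker_ids)
    frame.insert(0, "taxa", G.samples)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    vmap = pd.DataFrame(
        {
            "marker": [v.id for v in G.variants],
            "chromosome": [v.chromosome for v in G.variants],
            "position": [v.position for v in G.variants],
        }
    )
    vmap.to_csv(mp, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read ``taxa<TAB>trait[<TAB>cov1...]`` with a header row."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"phenotype file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "NaN", ""])
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected at least taxa and trait columns")
    samples = table.iloc[:, 0].astype(str).tolist()
    trait = table.iloc[:, 1].to_numpy(dtype=float)
    cov = table.iloc[:, 2:].astype(float).reset_index(drop=True)
    return PhenotypeTable(samples=samples, trait=trait, covariates=cov)


def write_phenotypes(P: PhenotypeTable, path: str | Path) -> None:
    frame = pd.DataFrame({"taxa": P.samples, "trait": P.trait})
    for c in P.covariates.columns:
        frame[c] = P.covariates[c].to_numpy()
    frame.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------------
# filters / transforms
# ----------------------------------------------------------------------------


def filter_variants(
    G: GenotypeMatrix, min_maf: float = 0.0, max_missing: float = 1.0
) -> GenotypeMatrix:
    """Drop markers with MAF below ``min_maf`` or missingness above ``max_missing``.

    Boundary markers are kept: the rule is ``maf >= min_maf`` and
    ``missing_fraction <= max_missing``.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValidationError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    if not (0.0 <= max_missing <= 1.0):
        raise ValidationError(f"max_missing must lie in [0, 1], got {max_missing}")
    maf = np.array([v.maf for v in G.variants])
    miss = G.missing_fraction()
    keep_maf = maf >= min_maf
    keep_miss = miss <= max_missing
    keep = keep_maf & keep_miss
    if not keep.any():
        raise EmptyResultError(
            f"all {G.n_markers} markers removed "
            f"({int((~keep_maf).sum())} failed maf >= {min_maf}, "
            f"{int((~keep_miss).sum())} failed missing <= {max_missing})"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_variants: dropped %d/%d markers (maf<%g: %d, missing>%g: %d)",
            n_dropped, G.n_markers, min_maf, int((~keep_maf).sum()),
            max_missing, int((~keep_miss).sum()),
        )
    return G.subset_markers(np.flatnonzero(keep))


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-marker mean over typed samples."""
    if not G.has_missing():
        return G
    dosages = G.dosages.copy()
    miss = np.isnan(dosages)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        j = int(np.flatnonzero(fully_missing)[0])
        raise ValidationError(
            f"marker {G.variants[j].id!r} has no typed samples; cannot impute"
        )
    col_means = np.nanmean(dosages, axis=0)
    dosages[miss] = np.broadcast_to(col_means, dosages.shape)[miss]
    return GenotypeMatrix(
        samples=list(G.samples), variants=list(G.variants), dosages=dosages
    )


def align_samples(
    G: GenotypeMatrix, P: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both tables to their common samples, in genotype order."""
    pheno_index = {s: i for i, s in enumerate(P.samples)}
    g_idx = [i for i, s in enumerate(G.samples) if s in pheno_index]
    if not g_idx:
        raise AlignmentError(
            "no samples shared between genotype and phenotype tables"
        )
    p_idx = [pheno_index[G.samples[i]] for i in g_idx]
    dropped_g = len(G.samples) - len(g_idx)
    dropped_p = len(P.samples) - len(p_idx)
    if dropped_g or dropped_p:
        logger.info(
            "align_samples: dropped %d genotype-only and %d phenotype-only samples",
            dropped_g, dropped_p,
        )
    Pa = P.subset(p_idx)
    if np.isnan(Pa.trait).any():
        raise ValidationError("trait contains missing values after alignment")
    return G.subset_samples(g_idx), Pa
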