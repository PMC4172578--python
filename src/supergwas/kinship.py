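"""VanRaden genomic relationship matrices with exact marker-exclusion downdates.

The relationship matrix is ``K = M M' / c`` where column ``j`` of ``M`` is the
centered dosage ``d_j - 2 p_j`` (``p_j`` the observed allele frequency) and
``c = 2 * sum_j p_j (1 - p_j)`` over the included polymorphic markers.
Monomorphic markers contribute a zero column and a zero frequency-variance
term, so including them changes nothing.

Because the association scan repeatedly needs "this kinship minus a handful of
markers", :class:`KinshipMatrix` can retain the raw cross-product ``M M'`` and
the per-marker ``2 p_j (1 - p_j)`` terms, turning each exclusion into an
O(n^2) downdate that is numerically identical to recomputing from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateKinshipError, DimensionError, EmptyKinshipError
from .genotypes import GenotypeMatrix

__all__ = ["KinshipMatrix", "compute_kinship", "exclude_markers",
           "read_kinship", "write_kinship"]


@dataclass
class KinshipMatrix:
    """An n x n genomic relationship matrix plus downdate bookkeeping.

    ``marker_indices`` records which columns of the source genotype matrix
    went into the matrix; ``fingerprint`` is a stable hash of that subset so
    scan provenance can name the kinship it used.  When built with
    ``keep_crossproduct=True`` the object carries ``raw_crossproduct``
    (= M M'), per-marker centered columns are *not* stored -- the downdate
    recenters from the genotype matrix on demand.
    """

    values: np.ndarray
    normalizer: float
    marker_indices: tuple[int, ...]
    samples: list[str] = field(default_factory=list)
    raw_crossproduct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise DimensionError("kinship matrix must be square")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10:
            raise DimensionError(f"kinship asymmetric beyond tolerance ({asym:g})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)

    @property
    def fingerprint(self) -> str:
        import hashlib

        digest = hashlib.sha1(
            np.asarray(sorted(self.marker_indices), dtype=np.int64).tobytes()
        ).hexdigest()[:12]
        return f"k{self.n_markers}-{digest}"


def _centered_columns(
    G: GenotypeMatrix, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Centered dosage columns and their 2p(1-p) terms for a marker subset."""
    d = G.dosages[:, list(indices)]
    if np.isnan(d).any():
        raise DimensionError("kinship requires imputed dosages (no missing)")
    p = d.mean(axis=0) / 2.0
    M = d - 2.0 * p
    terms = 2.0 * p * (1.0 - p)
    # exactly zero out monomorphic columns (they are zero up to round-off)
    mono = terms == 0.0
    if mono.any():
        M[:, mono] = 0.0
    return M, terms


def compute_kinship(
    G: GenotypeMatrix,
    markers: Sequence[int] | None = None,
    keep_crossproduct: bool = False,
) -> KinshipMatrix:
    """VanRaden kinship from a marker subset (default: all markers).

    Allele frequencies are the observed frequencies in the current sample
    set.  Raises :class:`DegenerateKinshipError` if every included marker is
    monomorphic.
    """
    if markers is None:
        indices = tuple(range(G.n_markers))
    else:
        indices = tuple(int(j) for j in markers)
    if not indices:
        raise EmptyKinshipError("no markers supplied for kinship")
    M, terms = _centered_columns(G, indices)
    c = float(terms.sum())
    if c <= 0.0:
        raise DegenerateKinshipError(
            f"all {len(indices)} included markers are monomorphic"
        )
    raw = M @ M.T
    K = raw / c
    return KinshipMatrix(
        values=K,
        normalizer=c,
        marker_indices=indices,
        samples=list(G.samples),
        raw_crossproduct=raw if keep_crossproduct else None,
    )


def exclude_markers(
    K: KinshipMatrix, G: GenotypeMatrix, excluded: Sequence[int]
) -> KinshipMatrix:
    """Kinship over ``K.marker_indices`` minus ``excluded``, by O(n^2) downdate.

    Numerically equal (to ~1e-10 elementwise) to ``compute_kinship`` on the
    retained subset.  Raises :class:`EmptyKinshipError` when the exclusion
    empties the marker set (callers fall back to a fixed-effects-only test).
    """
    excl = set(int(j) for j in excluded)
    if not excl:
        return K
    unknown = excl - set(K.marker_indices)
    if unknown:
        raise DimensionError(
            f"markers {sorted(unknown)} are not part of this kinship"
        )
    retained = tuple(j for j in K.marker_indices if j not in excl)
    if not retained:
        raise EmptyKinshipError("exclusion removed every kinship marker")
    if K.raw_crossproduct is None:
        return compute_kinship(G, retained)
    M_ex, terms_ex = _centered_columns(G, sorted(excl))
    raw = K.raw_crossproduct - M_ex @ M_ex.T
    c = K.normalizer - float(terms_ex.sum())
    if c <= 0.0:
        raise DegenerateKinshipError("retained markers are all monomorphic")
    return KinshipMatrix(
        values=raw / c,
        normalizer=c,
        marker_indices=retained,
        samples=list(K.samples),
        raw_crossproduct=raw,
    )


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    """Export as a square tab-separated matrix with sample ids on both axes."""
    ids = K.samples or [f"s{i}" for i in range(K.n_samples)]
    pd.DataFrame(K.values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_kinship(path: str | Path) -> KinshipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    # an imported matrix carries no marker provenance or crossproduct
    return KinshipMatrix(
        values=values,
        normalizer=float("nan"),
        marker_indices=(),
        samples=[str(s) for s in frame.index],
    )
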