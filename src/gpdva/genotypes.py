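"""Genotype matrices, genetic maps, and the disequilibrium decomposition D = V + W + B.

A population sample of N fully homozygous lines scored at L biallelic loci is
held as an N x L matrix X with entries in {0, 2} (2 = homozygous for the
reference allele).  Centering with the sample allele frequencies gives
Z = X - 2*1p, and D = Z'Z/N is the variance-covariance matrix of genotypic
scores: d_ii = 4 p_i (1 - p_i) and d_ij = 4 (f_ij - p_i p_j), where
f_ij - p_i p_j is the gametic phase disequilibrium (GPD) between loci i and j.

D is partitioned entrywise into its diagonal V, the within-chromosome
off-diagonal part W and the between-chromosome part B.  W and B are kept as
full symmetric matrices, so sums over "pairs" count (i, j) and (j, i)
separately; the quadratic form a'Wa therefore already carries the factor 2
of the covariance component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodingError",
    "InvalidInputError",
    "GeneticMap",
    "GenotypeMatrix",
    "DisequilibriumDecomposition",
    "allele_frequencies",
    "center",
    "disequilibrium_matrix",
    "partition",
    "decomposition_from_matrix",
    "pairwise_r2",
    "ld_decay_distance",
]


class InvalidInputError(ValueError):
    """Raised for structurally invalid inputs (empty matrices, bad dimensions)."""


class CodingError(ValueError):
    """Raised when a genotype score is not in {0, 2}; names the offending cell."""


@dataclass(eq=False, frozen=True)
class GeneticMap:
    """Ordered loci on chromosomes with positions in centimorgan.

    Loci are sorted by (chromosome, position); positions are continuous cM
    in [0, chromosome length].  No physical (bp) coordinates exist anywhere.
    """

    chrom_ids: tuple
    chrom_lengths: np.ndarray  # cM, one per chromosome
    locus_ids: tuple
    locus_chrom: np.ndarray  # int codes indexing chrom_ids
    locus_pos: np.ndarray  # cM

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths", np.asarray(self.chrom_lengths, dtype=float))
        object.__setattr__(self, "locus_chrom", np.asarray(self.locus_chrom, dtype=np.int64))
        object.__setattr__(self, "locus_pos", np.asarray(self.locus_pos, dtype=float))
        if len(set(self.chrom_ids)) != len(self.chrom_ids):
            raise InvalidInputError("chromosome ids must be unique")
        if np.any(self.chrom_lengths <= 0):
            raise InvalidInputError("chromosome lengths must be positive")
        if len(self.locus_ids) != self.locus_pos.size or self.locus_chrom.size != self.locus_pos.size:
            raise InvalidInputError("locus id / chromosome / position lengths differ")
        if self.locus_chrom.size:
            if self.locus_chrom.min() < 0 or self.locus_chrom.max() >= len(self.chrom_ids):
                raise InvalidInputError("locus chromosome code out of range")
            lo = self.locus_pos < 0
            hi = self.locus_pos > self.chrom_lengths[self.locus_chrom]
            if np.any(lo | hi):
                bad = int(np.argmax(lo | hi))
                raise InvalidInputError(
                    f"locus {self.locus_ids[bad]!r} position {self.locus_pos[bad]} outside "
                    f"[0, chromosome length]"
                )
            key = self.locus_chrom * (self.locus_pos.max() + 1.0) + self.locus_pos
            if np.any(np.diff(key) < 0):
                raise InvalidInputError("loci must be sorted by (chromosome, position)")

    @classmethod
    def build(
        cls,
        chromosomes: Sequence[tuple],
        loci: Iterable[tuple],
    ) -> "GeneticMap":
        """Build a map from (chrom_id, length_cM) pairs and (locus_id, chrom_id, pos_cM)
        triples; loci are sorted by (chromosome, position)."""
        chrom_ids = tuple(c for c, _ in chromosomes)
        lengths = np.array([l for _, l in chromosomes], dtype=float)
        code = {c: k for k, c in enumerate(chrom_ids)}
        rows = []
        for lid, cid, pos in loci:
            if cid not in code:
                raise InvalidInputError(f"locus {lid!r} references unknown chromosome {cid!r}")
            rows.append((code[cid], float(pos), lid))
        rows.sort(key=lambda r: (r[0], r[1]))
        return cls(
            chrom_ids=chrom_ids,
            chrom_lengths=lengths,
            locus_ids=tuple(r[2] for r in rows),
            locus_chrom=np.array([r[0] for r in rows], dtype=np.int64),
            locus_pos=np.array([r[1] for r in rows], dtype=float),
        )

    @property
    def n_loci(self) -> int:
        return self.locus_pos.size

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_ids)

    def chrom_slices(self) -> list[slice]:
        """One contiguous slice of locus indices per chromosome (possibly empty)."""
        out = []
        bounds = np.searchsorted(self.locus_chrom, np.arange(self.n_chromosomes + 1))
        for k in range(self.n_chromosomes):
            out.append(slice(int(bounds[k]), int(bounds[k + 1])))
        return out

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        """Restrict the map to the loci at (sorted, unique) positional indices."""
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx.min() < 0 or idx.max() >= self.n_loci):
            raise InvalidInputError("subset indices must be sorted, unique and in range")
        return GeneticMap(
            chrom_ids=self.chrom_ids,
            chrom_lengths=self.chrom_lengths,
            locus_ids=tuple(self.locus_ids[i] for i in idx),
            locus_chrom=self.locus_chrom[idx],
            locus_pos=self.locus_pos[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": list(self.locus_ids),
                "chromosome": [self.chrom_ids[c] for c in self.locus_chrom],
                "position_cM": self.locus_pos,
            }
        )


@dataclass(eq=False)
class GenotypeMatrix:
    """N x L matrix of homozygous genotype scores in {0, 2} tied to a GeneticMap."""

    scores: np.ndarray
    gmap: GeneticMap
    individual_ids: tuple = field(default=())

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.size == 0:
            raise InvalidInputError("genotype matrix must be a nonempty 2-D array")
        bad = (self.scores != 0) & (self.scores != 2)
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise CodingError(
                f"genotype score {self.scores[r, c]!r} at individual {int(r)}, "
                f"locus {self.gmap.locus_ids[int(c)]!r} is not in {{0, 2}} "
                f"(only fully homozygous material is supported)"
            )
        if self.scores.shape[1] != self.gmap.n_loci:
            raise InvalidInputError(
                f"matrix has {self.scores.shape[1]} columns but map has {self.gmap.n_loci} loci"
            )
        if not self.individual_ids:
            self.individual_ids = tuple(f"ind{n}" for n in range(self.scores.shape[0]))
        if len(self.individual_ids) != self.scores.shape[0]:
            raise InvalidInputError("individual_ids length does not match row count")

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_loci(self) -> int:
        return self.scores.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return GenotypeMatrix(self.scores[:, idx], self.gmap.subset(idx), self.individual_ids)

    def haplotypes(self) -> np.ndarray:
        """0/1 allele codes, one haplotype per fully homozygous line."""
        return (self.scores // 2).astype(np.uint8)


def allele_frequencies(X: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Reference-allele frequencies p_i = sum_n x_ni / (2N)."""
    scores = X.scores if isinstance(X, GenotypeMatrix) else np.asarray(X)
    if scores.ndim != 2 or scores.size == 0:
        raise InvalidInputError("genotype matrix must be a nonempty 2-D array")
    bad = (scores != 0) & (scores != 2)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise CodingError(f"genotype score at row {int(r)}, column {int(c)} is not in {{0, 2}}")
    return scores.sum(axis=0) / (2.0 * scores.shape[0])


def center(X: GenotypeMatrix | np.ndarray, p: np.ndarray | None = None) -> np.ndarray:
    """Centered score matrix Z = X - 2*1p (columns sum to zero if p came from X)."""
    scores = X.scores if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    if p is None:
        p = allele_frequencies(X)
    p = np.asarray(p, dtype=float)
    if p.shape != (scores.shape[1],):
        raise InvalidInputError(
            f"allele frequency vector of length {p.size} does not match {scores.shape[1]} loci"
        )
    return scores - 2.0 * p[None, :]


def disequilibrium_matrix(Z: np.ndarray, N: int | None = None) -> np.ndarray:
    """Variance-covariance matrix of genotypic scores, D = Z'Z / N.

    The divisor is the sample size N (not N-1): this is what makes
    E[V_A | X] = trace(D) hold exactly for effects a ~ N(0, I).
    """
    Z = np.asarray(Z, dtype=float)
    if N is None:
        N = Z.shape[0]
    if N == 0:
        raise InvalidInputError("N must be positive")
    return (Z.T @ Z) / float(N)


@dataclass(eq=False)
class DisequilibriumDecomposition:
    """Entrywise partition D = V + W + B with allele frequencies and chromosome codes.

    V = diag(D); W holds off-diagonal entries for same-chromosome locus pairs;
    B holds entries for pairs on different chromosomes.  trace(W) = trace(B) = 0.
    """

    D: np.ndarray
    V: np.ndarray
    W: np.ndarray
    B: np.ndarray
    p: np.ndarray | None
    locus_chrom: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.D.shape[0]

    @classmethod
    def from_genotypes(
        cls, X: GenotypeMatrix, loci: np.ndarray | None = None
    ) -> "DisequilibriumDecomposition":
        if loci is not None:
            X = X.subset_loci(np.asarray(loci))
        p = allele_frequencies(X)
        D = disequilibrium_matrix(center(X, p))
        dec = partition(D, X.gmap)
        dec.p = p
        return dec

    def flip_alleles(self, idx: np.ndarray) -> "DisequilibriumDecomposition":
        """Decomposition after swapping reference/alternate alleles at the given loci.

        Flips the sign of the corresponding rows and columns of the off-diagonal
        parts; d_ii and all squared entries (hence every moment) are unchanged.
        """
        s = np.ones(self.n_loci)
        s[np.asarray(idx, dtype=np.int64)] = -1.0
        S = np.outer(s, s)
        p = None if self.p is None else np.where(s < 0, 1.0 - self.p, self.p)
        return DisequilibriumDecomposition(
            D=self.D * S, V=self.V.copy(), W=self.W * S, B=self.B * S,
            p=p, locus_chrom=self.locus_chrom,
        )


def partition(D: np.ndarray, gmap: GeneticMap, loci: np.ndarray | None = None) -> DisequilibriumDecomposition:
    """Split D into diagonal (V), within-chromosome (W) and between-chromosome (B) parts."""
    D = np.asarray(D, dtype=float)
    codes = gmap.locus_chrom if loci is None else gmap.locus_chrom[np.asarray(loci)]
    if D.shape != (codes.size, codes.size):
        raise InvalidInputError(
            f"D is {D.shape} but {codes.size} loci are mapped; every locus must be on the map"
        )
    same = codes[:, None] == codes[None, :]
    V = np.diag(np.diag(D))
    W = np.where(same, D, 0.0)
    np.fill_diagonal(W, 0.0)
    B = np.where(same, 0.0, D)
    return DisequilibriumDecomposition(D=D, V=V, W=W, B=B, p=None, locus_chrom=codes)


def decomposition_from_matrix(
    D: np.ndarray, chrom_codes: Sequence[int], p: np.ndarray | None = None
) -> DisequilibriumDecomposition:
    """Build a decomposition directly from a covariance matrix and chromosome codes
    (convenience for theoretical work without an explicit map)."""
    codes = np.asarray(chrom_codes, dtype=np.int64)
    D = np.asarray(D, dtype=float)
    if D.shape != (codes.size, codes.size):
        raise InvalidInputError("D shape does not match chromosome code length")
    same = codes[:, None] == codes[None, :]
    V = np.diag(np.diag(D))
    W = np.where(same, D, 0.0)
    np.fill_diagonal(W, 0.0)
    B = np.where(same, 0.0, D)
    return DisequilibriumDecomposition(D=D, V=V, W=W, B=B, p=p, locus_chrom=codes)


def pairwise_r2(X: GenotypeMatrix, loci: np.ndarray | None = None) -> tuple[pd.DataFrame, list]:
    """r^2 between all within-chromosome locus pairs, with map distances in cM.

    For fully homozygous lines the 0/2-score correlation equals the haplotype
    correlation, so r^2_ij = d_ij^2 / (d_ii d_jj).  Pairs with a monomorphic
    member are skipped; the skipped locus ids are returned alongside.
    """
    if loci is not None:
        X = X.subset_loci(np.asarray(loci))
    p = allele_frequencies(X)
    Z = center(X, p)
    D = disequilibrium_matrix(Z)
    gmap = X.gmap
    dii = np.diag(D)
    poly = dii > 0
    skipped = [gmap.locus_ids[i] for i in np.nonzero(~poly)[0]]
    rows = []
    for k, sl in enumerate(gmap.chrom_slices()):
        idx = np.arange(sl.start, sl.stop)
        idx = idx[poly[idx]]
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        denom = np.outer(dii[idx], dii[idx])
        r2 = sub * sub / denom
        pos = gmap.locus_pos[idx]
        iu, ju = np.triu_indices(idx.size, k=1)
        rows.append(
            pd.DataFrame(
                {
                    "locus_i": [gmap.locus_ids[i] for i in idx[iu]],
                    "locus_j": [gmap.locus_ids[j] for j in idx[ju]],
                    "chromosome": gmap.chrom_ids[k],
                    "dist_cM": np.abs(pos[ju] - pos[iu]),
                    "r2": r2[iu, ju],
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["locus_i", "locus_j", "chromosome", "dist_cM", "r2"])
    return df, skipped


def ld_decay_distance(
    r2_records: pd.DataFrame,
    threshold: float = 0.1,
    bin_width: float = 1.0,
) -> float:
    """Distance (cM) at which binned mean r^2 first falls below the threshold.

    Distances are binned in intervals of `bin_width` cM starting at zero; the
    midpoint of the first non-empty bin whose mean r^2 is below the threshold
    is returned.  If no bin crosses, returns ``math.inf`` ("beyond the map").
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must lie in (0, 1)")
    if len(r2_records) == 0:
        raise InvalidInputError("no r^2 records supplied")
    d = np.asarray(r2_records["dist_cM"], dtype=float)
    r2 = np.asarray(r2_records["r2"], dtype=float)
    nbins = int(math.floor(d.max() / bin_width)) + 1
    which = np.minimum((d / bin_width).astype(np.int64), nbins - 1)
    sums = np.bincount(which, weights=r2, minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    for k in range(nbins):
        if counts[k] == 0:
            continue
        if sums[k] / counts[k] < threshold:
            return (k + 0.5) * bin_width
    return math.inf
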