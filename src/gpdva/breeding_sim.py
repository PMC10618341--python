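"""In-silico meiosis, mating designs, doubled-haploid derivation and random mating.

Meiosis follows Haldane's mapping function with no crossover interference:
along each chromosome the gamete is a Markov walk over the ordered loci that
starts on a random parental haplotype and switches between haplotypes across
an interval of d cM with probability r = (1 - exp(-2d/100)) / 2.  This
per-interval chain is exactly equivalent to dropping a Poisson number of
crossovers on the genetic-distance scale, so no explicit crossover layer is
needed, and chromosomes assort independently.

Mating designs (with P parents):
  DC  disjoint crosses      - random order, consecutive pairs, P/2 crosses
  FC  factorial crosses     - random split into two sets, (P/2)^2 crosses
  HC  half-diallel          - all P(P-1)/2 unordered pairs, no selfs

A generation holds N diploid individuals; each F1 progeny assigns itself a
cross uniformly at random with replacement.  Random mating draws, for every
offspring independently, an unordered pair of two distinct parents.  One
doubled-haploid (DH) line is derived per individual by doubling a single
meiotic gamete.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GeneticMap, GenotypeMatrix, InvalidInputError

__all__ = [
    "DESIGNS",
    "haldane",
    "inverse_haldane",
    "Individual",
    "Population",
    "CrossPlan",
    "GenerationSet",
    "meiosis",
    "gametes",
    "make_dh",
    "dh_population",
    "design_crosses",
    "sample_progeny",
    "random_mate",
    "run_replication",
]

DESIGNS = ("DC", "FC", "HC")


def haldane(d_cM) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def inverse_haldane(r) -> np.ndarray | float:
    """Map distance in cM giving recombination fraction r (< 0.5)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass(eq=False)
class Individual:
    """Two haplotypes aligned to a GeneticMap; DH lines carry identical copies."""

    haplotypes: np.ndarray  # (2, L) uint8 allele codes, 1 = reference
    gmap: GeneticMap
    id: str = "ind"
    parents: tuple = (None, None)
    generation: str = ""

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2, self.gmap.n_loci):
            raise InvalidInputError("individual haplotypes must be (2, n_loci)")

    @property
    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.haplotypes[0], self.haplotypes[1]))


@dataclass(eq=False)
class Population:
    """N diploid individuals stored as an (N, 2, L) haplotype array."""

    haplotypes: np.ndarray
    gmap: GeneticMap
    generation: str = ""
    ids: tuple = ()
    mother_idx: np.ndarray | None = None  # pedigree: indices into the parent population
    father_idx: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise InvalidInputError("population haplotypes must be (N, 2, L)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise InvalidInputError("haplotype length does not match map")
        if not self.ids:
            self.ids = tuple(f"{self.generation or 'ind'}_{n}" for n in range(self.size))

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def individual(self, n: int) -> Individual:
        return Individual(self.haplotypes[n], self.gmap, id=self.ids[n], generation=self.generation)

    @classmethod
    def from_inbred_lines(cls, X: GenotypeMatrix, generation: str = "founders") -> "Population":
        hap = X.haplotypes()
        return cls(np.repeat(hap[:, None, :], 2, axis=1), X.gmap,
                   generation=generation, ids=tuple(X.individual_ids))

    def to_genotype_matrix(self) -> GenotypeMatrix:
        """0/2 score matrix; valid only for fully homozygous populations (e.g. DH)."""
        if not np.array_equal(self.haplotypes[:, 0, :], self.haplotypes[:, 1, :]):
            raise InvalidInputError("population is not fully homozygous")
        return GenotypeMatrix(self.haplotypes[:, 0, :].astype(np.int16) * 2, self.gmap, self.ids)


def _interval_recomb(gmap: GeneticMap) -> list[np.ndarray]:
    """Per chromosome, Haldane switch probabilities between adjacent loci."""
    out = []
    for sl in gmap.chrom_slices():
        pos = gmap.locus_pos[sl]
        out.append(haldane(np.diff(pos)) if pos.size > 1 else np.empty(0))
    return out


def gametes(haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Batch meiosis: one gamete per (2, L) parent in a (k, 2, L) stack."""
    haps = np.asarray(haps, dtype=np.uint8)
    k, _, L = haps.shape
    out = np.empty((k, L), dtype=np.uint8)
    for sl, r in zip(gmap.chrom_slices(), _interval_recomb(gmap)):
        m = sl.stop - sl.start
        if m == 0:
            continue
        start = rng.integers(0, 2, size=k, dtype=np.int64)
        if m > 1:
            switches = rng.random((k, m - 1)) < r[None, :]
            path = (start[:, None] + np.concatenate(
                [np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
        else:
            path = start[:, None]
        chrom = haps[:, :, sl]
        out[:, sl] = np.where(path == 0, chrom[:, 0, :], chrom[:, 1, :])
    return out


def meiosis(parent: Individual, gmap: GeneticMap | None = None, rng: np.random.Generator | None = None) -> np.ndarray:
    """One meiotic gamete (length-L allele vector) from a single parent."""
    gmap = gmap or parent.gmap
    if gmap.n_loci != parent.gmap.n_loci:
        raise InvalidInputError("parent haplotypes are not aligned to the map")
    rng = rng if rng is not None else np.random.default_rng()
    return gametes(parent.haplotypes[None, :, :], gmap, rng)[0]


def make_dh(parent: Individual, gmap: GeneticMap | None = None, rng: np.random.Generator | None = None) -> Individual:
    """Doubled haploid: a single gamete doubled into a fully homozygous individual."""
    g = meiosis(parent, gmap, rng)
    return Individual(np.stack([g, g]), gmap or parent.gmap, id=f"{parent.id}-DH",
                      parents=(parent.id, parent.id), generation=f"{parent.generation}-DH")


def dh_population(pop: Population, rng: np.random.Generator) -> Population:
    """One DH line from each individual of the population."""
    g = gametes(pop.haplotypes, pop.gmap, rng)
    idx = np.arange(pop.size)
    return Population(np.repeat(g[:, None, :], 2, axis=1), pop.gmap,
                      generation=f"{pop.generation}-DH",
                      ids=tuple(f"{i}-DH" for i in pop.ids),
                      mother_idx=idx, father_idx=idx)


@dataclass(frozen=True)
class CrossPlan:
    design: str
    parent_ids: tuple
    pairs: tuple  # tuples of parent ids

    @property
    def n_crosses(self) -> int:
        return len(self.pairs)


def design_crosses(parent_ids, design: str, rng: np.random.Generator) -> CrossPlan:
    """Build the list of parent pairs for a mating design.

    P = 2 yields the single biparental cross under every design.  DC and FC
    require an even number of parents.
    """
    parent_ids = tuple(parent_ids)
    P = len(parent_ids)
    if design not in DESIGNS:
        raise InvalidInputError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if P < 2:
        raise InvalidInputError("at least two parents are required")
    if P == 2:
        return CrossPlan(design, parent_ids, (tuple(parent_ids),))
    if design in ("DC", "FC") and P % 2:
        raise InvalidInputError(f"design {design} requires an even number of parents, got {P}")
    order = [parent_ids[i] for i in rng.permutation(P)]
    if design == "DC":
        pairs = tuple((order[2 * k], order[2 * k + 1]) for k in range(P // 2))
    elif design == "FC":
        half = P // 2
        pairs = tuple(itertools.product(order[:half], order[half:]))
    else:  # HC
        pairs = tuple(itertools.combinations(parent_ids, 2))
    return CrossPlan(design, parent_ids, pairs)


def sample_progeny(plan: CrossPlan, parents: Population, N: int, rng: np.random.Generator) -> Population:
    """Generation G1: each of N progenies draws its cross uniformly with replacement,
    then receives one meiotic gamete from each parent of that cross."""
    if plan.n_crosses == 0:
        raise InvalidInputError("empty cross plan")
    if N < 1:
        raise InvalidInputError("N must be at least 1")
    pos = {pid: n for n, pid in enumerate(parents.ids)}
    try:
        pair_idx = np.array([[pos[a], pos[b]] for a, b in plan.pairs], dtype=np.int64)
    except KeyError as err:
        raise InvalidInputError(f"cross plan references unknown parent {err}") from None
    cross = rng.integers(0, plan.n_crosses, size=N)
    mother = pair_idx[cross, 0]
    father = pair_idx[cross, 1]
    gm = gametes(parents.haplotypes[mother], parents.gmap, rng)
    gf = gametes(parents.haplotypes[father], parents.gmap, rng)
    return Population(np.stack([gm, gf], axis=1), parents.gmap, generation="G1",
                      mother_idx=mother, father_idx=father)


def random_mate(pop: Population, N: int, rng: np.random.Generator, generation: str = "") -> Population:
    """Next generation: N offspring, each from an independently drawn unordered
    pair of two distinct parents (monoecious, selfing excluded)."""
    n = pop.size
    if n < 2:
        raise InvalidInputError("random mating needs a population of at least 2")
    if N < 1:
        raise InvalidInputError("N must be at least 1")
    mother = rng.integers(0, n, size=N)
    father = rng.integers(0, n - 1, size=N)
    father += (father >= mother).astype(np.int64)  # shift past the mother: no selfing
    gm = gametes(pop.haplotypes[mother], pop.gmap, rng)
    gf = gametes(pop.haplotypes[father], pop.gmap, rng)
    return Population(np.stack([gm, gf], axis=1), pop.gmap, generation=generation,
                      mother_idx=mother, father_idx=father)


@dataclass(eq=False)
class GenerationSet:
    """Populations G1..Gk plus the 0/2 genotype matrices of their DH derivatives."""

    populations: dict = field(default_factory=dict)  # label -> Population
    dh_matrices: dict = field(default_factory=dict)  # label -> GenotypeMatrix
    parent_indices: np.ndarray | None = None
    plan: CrossPlan | None = None


def run_replication(
    founders: GenotypeMatrix,
    design: str,
    P: int,
    N: int,
    n_generations: int = 4,
    rng: np.random.Generator | int | None = None,
    loci: np.ndarray | None = None,
    parent_indices: np.ndarray | None = None,
) -> GenerationSet:
    """One full replication: sample P parents, cross, then intermate to G{n}.

    Parents are drawn without replacement from the founder panel.  G1 comes
    from the design's cross plan; G2..Gk from chained random mating of N
    individuals.  A DH population is derived from every intermating
    generation, and its genotype matrix is emitted at ``loci`` (default: all
    founder loci).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if P > founders.n_individuals:
        raise InvalidInputError(f"P={P} exceeds the founder panel size {founders.n_individuals}")
    if parent_indices is None:
        parent_indices = np.sort(rng.choice(founders.n_individuals, size=P, replace=False))
    else:
        parent_indices = np.asarray(parent_indices, dtype=np.int64)
    panel = founders if loci is None else founders.subset_loci(np.asarray(loci))
    parents = Population.from_inbred_lines(
        GenotypeMatrix(panel.scores[parent_indices], panel.gmap,
                       tuple(panel.individual_ids[i] for i in parent_indices)),
        generation="parents",
    )
    plan = design_crosses(parents.ids, design, rng)
    out = GenerationSet(parent_indices=parent_indices, plan=plan)
    pop = sample_progeny(plan, parents, N, rng)
    for k in range(1, n_generations + 1):
        pop.generation = f"G{k}"
        out.populations[f"G{k}"] = pop
        dh = dh_population(pop, rng)
        out.dh_matrices[f"G{k}-DH"] = dh.to_genotype_matrix()
        if k < n_generations:
            pop = random_mate(pop, N, rng, generation=f"G{k + 1}")
    return out
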