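"""Gamete, cross, and selfing simulation on a genetic map.

Each individual carries two haplotypes with allele codes +1 (major) and -1
(minor) per SNP, aligned to map order; the marker score is (h1 + h2) / 2,
recovering the {-1, 0, 1} coding. A gamete is formed by a Markov walk along
each chromosome: the starting haplotype is chosen with probability 1/2 and
the source switches between the two parental haplotypes at each adjacent
interval with its Haldane recombination fraction — an independent Bernoulli
draw per interval, which is exactly a no-interference crossover process.
Chromosomes assort independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geno_io import MarkerMatrix
from .linkage_map import GeneticMap

__all__ = [
    "HaploIndividual",
    "HaploPopulation",
    "founder_from_scores",
    "founders_from_matrix",
    "sample_gamete",
    "cross",
    "cross_pairs",
    "self_progeny",
    "self_population",
    "population_scores",
]


@dataclass
class HaploIndividual:
    """One diploid individual: two +/-1 haplotype vectors plus pedigree tags."""

    h1: np.ndarray
    h2: np.ndarray
    id: str = ""
    generation: str = ""
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.int8)
        self.h2 = np.asarray(self.h2, dtype=np.int8)
        if self.h1.shape != self.h2.shape:
            raise ValueError("haplotype length mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.h1)

    def scores(self) -> np.ndarray:
        """Marker scores (h1 + h2) / 2, entries in {-1, 0, 1}."""
        return ((self.h1.astype(np.int16) + self.h2) // 2).astype(np.int8)


@dataclass
class HaploPopulation:
    """A generation of individuals stored as stacked haplotype arrays."""

    h1: np.ndarray  # (n, p) int8
    h2: np.ndarray
    generation: str = ""
    ids: list[str] = field(default_factory=list)
    parent1: list[str] = field(default_factory=list)
    parent2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.int8)
        self.h2 = np.asarray(self.h2, dtype=np.int8)
        if self.h1.shape != self.h2.shape:
            raise ValueError("haplotype array shape mismatch")
        if not self.ids:
            self.ids = [f"{self.generation}_{i}" for i in range(len(self.h1))]

    def __len__(self) -> int:
        return self.h1.shape[0]

    @property
    def n_snps(self) -> int:
        return self.h1.shape[1]

    def individual(self, i: int) -> HaploIndividual:
        par = (
            (self.parent1[i], self.parent2[i])
            if self.parent1 and self.parent2
            else None
        )
        return HaploIndividual(
            self.h1[i], self.h2[i], id=self.ids[i],
            generation=self.generation, parents=par,
        )

    def scores(self) -> np.ndarray:
        return ((self.h1.astype(np.int16) + self.h2) // 2).astype(np.int8)

    def subset(self, index) -> "HaploPopulation":
        index = np.asarray(index)
        return HaploPopulation(
            h1=self.h1[index], h2=self.h2[index], generation=self.generation,
            ids=[self.ids[i] for i in index],
            parent1=[self.parent1[i] for i in index] if self.parent1 else [],
            parent2=[self.parent2[i] for i in index] if self.parent2 else [],
        )


def founder_from_scores(
    scores: np.ndarray, rng: np.random.Generator, id: str = "", generation: str = "P"
) -> HaploIndividual:
    """Phase an inbred accession's {-1, 0, 1} scores into two haplotypes.

    Homozygous loci phase deterministically; residual heterozygous loci get
    a uniformly random phase per locus, independently.
    """
    s = np.asarray(scores)
    if np.isnan(np.asarray(s, dtype=float)).any():
        raise ValueError("missing scores; impute before phasing")
    s = s.astype(np.int8)
    h1 = s.copy()
    h2 = s.copy()
    het = s == 0
    flip = rng.random(int(het.sum())) < 0.5
    a = np.where(flip, -1, 1).astype(np.int8)
    h1[het] = a
    h2[het] = -a
    return HaploIndividual(h1, h2, id=id, generation=generation)


def founders_from_matrix(
    m: MarkerMatrix, rng: np.random.Generator, generation: str = "P"
) -> HaploPopulation:
    """Phase every accession of a complete marker matrix."""
    inds = [
        founder_from_scores(m.scores[i], rng, id=m.accession_ids[i], generation=generation)
        for i in range(m.n_accessions)
    ]
    return HaploPopulation(
        h1=np.stack([x.h1 for x in inds]), h2=np.stack([x.h2 for x in inds]),
        generation=generation, ids=list(m.accession_ids),
    )


def _gametes_from_stacks(
    h1: np.ndarray, h2: np.ndarray, switch_probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per row of the stacked parental haplotypes.

    ``switch_probs[0]`` of each chromosome is 0.5, so a single cumulative
    parity over the whole SNP axis is valid: the uniform restart at each
    chromosome head erases any carried-over parity.
    """
    switches = rng.random(h1.shape) < switch_probs
    source = np.cumsum(switches, axis=1) & 1
    return np.where(source == 0, h1, h2).astype(np.int8)


def sample_gamete(
    ind: HaploIndividual, gm: GeneticMap, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Sample ``n`` independent gametes from one individual; shape (n, p)."""
    if ind.n_snps != gm.n_snps:
        raise ValueError("individual not aligned to map")
    probs = gm.switch_probs()
    h1 = np.broadcast_to(ind.h1, (n, ind.n_snps))
    h2 = np.broadcast_to(ind.h2, (n, ind.n_snps))
    out = _gametes_from_stacks(h1, h2, probs, rng)
    return out[0] if n == 1 else out


def cross(
    p1: HaploIndividual, p2: HaploIndividual, gm: GeneticMap,
    rng: np.random.Generator, id: str = "", generation: str = "F1",
) -> HaploIndividual:
    """One offspring from two parents: one gamete from each."""
    if p1.n_snps != p2.n_snps:
        raise ValueError("parent SNP dimension mismatch")
    g1 = sample_gamete(p1, gm, rng)
    g2 = sample_gamete(p2, gm, rng)
    return HaploIndividual(
        g1, g2, id=id, generation=generation, parents=(p1.id, p2.id)
    )


def cross_pairs(
    pop: HaploPopulation, pairs: list[tuple[int, int]], gm: GeneticMap,
    rng: np.random.Generator, generation: str = "F1",
) -> HaploPopulation:
    """One offspring per (i, j) pair of individuals in ``pop``."""
    probs = gm.switch_probs()
    i_idx = np.array([i for i, _ in pairs])
    j_idx = np.array([j for _, j in pairs])
    g1 = _gametes_from_stacks(pop.h1[i_idx], pop.h2[i_idx], probs, rng)
    g2 = _gametes_from_stacks(pop.h1[j_idx], pop.h2[j_idx], probs, rng)
    return HaploPopulation(
        h1=g1, h2=g2, generation=generation,
        ids=[f"{generation}_{k}" for k in range(len(pairs))],
        parent1=[pop.ids[i] for i, _ in pairs],
        parent2=[pop.ids[j] for _, j in pairs],
    )


def self_progeny(
    ind: HaploIndividual, n: int, gm: GeneticMap, rng: np.random.Generator,
    generation: str = "",
) -> HaploPopulation:
    """``n`` self-pollinated offspring, each from two independent gametes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    g1 = sample_gamete(ind, gm, rng, n=n)
    g2 = sample_gamete(ind, gm, rng, n=n)
    g1 = np.atleast_2d(g1)
    g2 = np.atleast_2d(g2)
    return HaploPopulation(
        h1=g1, h2=g2, generation=generation,
        ids=[f"{generation}_{ind.id}_{k}" for k in range(n)],
        parent1=[ind.id] * n, parent2=[ind.id] * n,
    )


def self_population(
    pop: HaploPopulation, n_per_individual: int, gm: GeneticMap,
    rng: np.random.Generator, generation: str = "",
) -> HaploPopulation:
    """Self every individual ``n_per_individual`` times, fully vectorized."""
    probs = gm.switch_probs()
    rep = np.repeat(np.arange(len(pop)), n_per_individual)
    g1 = _gametes_from_stacks(pop.h1[rep], pop.h2[rep], probs, rng)
    g2 = _gametes_from_stacks(pop.h1[rep], pop.h2[rep], probs, rng)
    parents = [pop.ids[i] for i in rep]
    return HaploPopulation(
        h1=g1, h2=g2, generation=generation,
        ids=[f"{generation}_{k}" for k in range(len(rep))],
        parent1=parents, parent2=parents,
    )


def population_scores(pop: HaploPopulation) -> np.ndarray:
    """Marker score matrix of a population: row i = (h1_i + h2_i) / 2."""
    if len(pop) == 0:
        raise ValueError("empty population")
    return pop.scores()


def write_population(pop: HaploPopulation, geno_path, pedigree_path, sep="\t") -> None:
    """Serialize scores in the standard genotype format plus a pedigree sidecar."""
    import pandas as pd

    df = pd.DataFrame(pop.scores(), index=pop.ids)
    df.columns = [f"snp{j}" for j in range(pop.n_snps)]
    df.index.name = "accession"
    df.to_csv(geno_path, sep=sep)
    ped = pd.DataFrame({
        "id": pop.ids,
        "generation": pop.generation,
        "parent1": pop.parent1 if pop.parent1 else [""] * len(pop),
        "parent2": pop.parent2 if pop.parent2 else [""] * len(pop),
    })
    ped.to_csv(pedigree_path, sep=sep, index=False)
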