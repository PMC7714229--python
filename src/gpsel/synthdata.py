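"""Synthetic founder panels, genetic maps, and additive phenotypes.

Emulates the structure of a diversity panel of near-inbred accessions:
multiple chromosomes with a monotone genetic map, subpopulation structure
generated by Balding–Nichols-style allele-frequency divergence around
shared ancestral frequencies, a configurable residual heterozygosity rate
(real inbred panels retain roughly 1–10% heterozygous calls), and a
configurable missing-genotype rate. The trait is purely additive: a subset
of genotyped SNPs receives normal effects and the residual is scaled so the
realized narrow-sense heritability matches the target exactly, which keeps
parameter-recovery tests clean.

What this generator does NOT emulate: linkage-disequilibrium decay
calibrated to any real genome, dominance/epistasis, genotyping-error
structure correlated with MAF, or trait effects at untyped loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MarkerMatrix, PhenotypeTable
from .linkage_map import GeneticMap

__all__ = ["SynthConfig", "make_founders", "make_phenotype", "TraitTruth"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic panel.

    Defaults give a small structured panel in the style of a rice diversity
    collection: a few hundred near-inbred accessions in a handful of
    subpopulations, chromosomes of ~100 cM, ~2% residual heterozygosity and
    ~2% missing genotypes, and a moderately heritable polygenic trait.
    """

    n_accessions: int = 200
    n_chromosomes: int = 2
    snps_per_chromosome: int = 250
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 30_000_000
    n_subpopulations: int = 3
    fst: float = 0.15  # Balding–Nichols divergence parameter
    het_rate: float = 0.02
    missing_rate: float = 0.0
    n_qtl: int = 50
    h2: float = 0.5
    mu: float = 0.0
    trait: str = "trait"
    direction: str = "maximize"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst", "het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_qtl exceeds total SNP count")


@dataclass
class TraitTruth:
    """Ground truth of a simulated trait, for recovery tests."""

    qtl_indices: np.ndarray
    effects: np.ndarray
    genetic_values: np.ndarray  # per accession, without mu or noise
    h2_realized: float


def make_founders(
    cfg: SynthConfig, return_membership: bool = False
) -> tuple[MarkerMatrix, GeneticMap]:
    """Generate a structured near-inbred founder panel and its genetic map.

    Per SNP, an ancestral allele frequency is drawn from U(0.1, 0.9) and
    perturbed per subpopulation with a Beta distribution parameterized by
    the divergence ``fst``. Accessions are near-inbred: each locus is
    heterozygous with probability ``het_rate`` and otherwise homozygous for
    an allele drawn at its subpopulation frequency. Scores are oriented so
    +1 is the panel-wide major allele; missing entries are then inserted at
    ``missing_rate``. bp positions are uniform-random increasing and cM is
    proportional to bp with monotone jitter.
    """
    rng = np.random.default_rng(cfg.seed)
    p_total = cfg.n_chromosomes * cfg.snps_per_chromosome
    n = cfg.n_accessions

    # map: per chromosome, sorted uniform bp; cM proportional with jitter
    chrom, bp_all, cm_all, snp_ids = [], [], [], []
    for c in range(cfg.n_chromosomes):
        bp = np.sort(
            rng.choice(cfg.chrom_length_bp, size=cfg.snps_per_chromosome, replace=False)
        )
        cm = bp / cfg.chrom_length_bp * cfg.chrom_length_cm
        jitter = rng.normal(0, 0.05, size=cfg.snps_per_chromosome)
        cm = np.maximum.accumulate(np.maximum(cm + jitter, 0.0))
        chrom.extend([str(c + 1)] * cfg.snps_per_chromosome)
        bp_all.append(bp)
        cm_all.append(cm)
        snp_ids.extend(f"c{c + 1}_s{j}" for j in range(cfg.snps_per_chromosome))
    bp_arr = np.concatenate(bp_all)
    cm_arr = np.concatenate(cm_all)

    # Balding–Nichols subpopulation frequencies around ancestral frequencies
    p_anc = rng.uniform(0.1, 0.9, size=p_total)
    if cfg.fst > 0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(cfg.n_subpopulations, p_total))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpopulations, 1))
    p_sub = np.clip(p_sub, 1e-3, 1 - 1e-3)

    membership = rng.integers(cfg.n_subpopulations, size=n)
    freqs = p_sub[membership]  # (n, p) per-accession allele-1 frequency

    hom_allele = np.where(rng.random((n, p_total)) < freqs, 1, -1)
    het = rng.random((n, p_total)) < cfg.het_rate
    scores = np.where(het, 0, hom_allele).astype(float)

    # orient +1 toward the observed panel-wide major allele
    f_obs = (2 * (scores == 1).sum(0) + (scores == 0).sum(0)) / (2 * n)
    flip = f_obs < 0.5
    scores[:, flip] = -scores[:, flip]

    if cfg.missing_rate > 0:
        miss = rng.random((n, p_total)) < cfg.missing_rate
        scores[miss] = np.nan

    m = MarkerMatrix(
        accession_ids=[f"acc{i:04d}" for i in range(n)],
        scores=scores,
        snp_ids=snp_ids,
        chrom=np.array(chrom, dtype=object),
        bp=bp_arr,
        cm=cm_arr,
    )
    gm = GeneticMap(chrom=m.chrom, snp_ids=snp_ids, bp=bp_arr, cm=cm_arr)
    if return_membership:
        return m, gm, membership
    return m, gm


def make_phenotype(
    m: MarkerMatrix, cfg: SynthConfig
) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate an additive trait y = mu + sum_q beta_q s_q + e on the panel.

    ``n_qtl`` SNPs drawn among the genotyped markers receive N(0, 1)
    effects; the residual is rescaled so the realized heritability
    var(g) / var(y) equals ``cfg.h2`` exactly (up to a single scalar
    rescaling of the drawn residual vector).
    """
    if cfg.n_qtl == 0:
        raise ValueError("n_qtl must be positive")
    if np.isnan(m.scores).any():
        raise ValueError("marker matrix has missing entries; impute first")
    rng = np.random.default_rng(cfg.seed + 1)
    qtl = np.sort(rng.choice(m.n_snps, size=cfg.n_qtl, replace=False))
    beta = rng.normal(0, 1, size=cfg.n_qtl)
    g = m.scores[:, qtl] @ beta
    var_g = float(np.var(g))
    if var_g == 0:
        raise ValueError("monomorphic QTL set produced zero genetic variance")
    e = rng.normal(0, 1, size=m.n_accessions)
    e = e - e.mean()
    gc = g - g.mean()
    e = e - (e @ gc) / (gc @ gc) * gc  # decorrelate in-sample so h2 is exact
    target_var_e = var_g * (1 - cfg.h2) / cfg.h2
    e *= np.sqrt(target_var_e / np.var(e))
    y = cfg.mu + g + e
    h2_real = var_g / float(np.var(y))
    values = pd.DataFrame({cfg.trait: y}, index=pd.Index(m.accession_ids))
    pheno = PhenotypeTable(values=values, directions={cfg.trait: cfg.direction})
    return pheno, TraitTruth(
        qtl_indices=qtl, effects=beta, genetic_values=g, h2_realized=h2_real
    )
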