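"""Genotype and phenotype I/O, quality control, thinning, coding, imputation.

Marker scores use the breeder's coding for inbred panels: ``1`` homozygous
for the major allele, ``-1`` homozygous for the minor allele, ``0``
heterozygous. Missing entries are held as NaN until imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SCORES = (-1.0, 0.0, 1.0)


@dataclass
class MarkerMatrix:
    """Accessions x SNP score matrix with per-SNP map metadata.

    Attributes
    ----------
    accession_ids : list of str
        Unique row labels.
    scores : ndarray of float, shape (n_accessions, n_snps)
        Entries in {-1, 0, 1}; NaN marks a missing genotype.
    snp_ids : list of str
        Unique column labels.
    chrom : ndarray of str
        Chromosome label per SNP.
    bp : ndarray of int
        Physical position per SNP (base pairs).
    cm : ndarray of float or None
        Genetic position per SNP (centimorgans); may be absent before
        interpolation from an anchor map.
    """

    accession_ids: list[str]
    scores: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.cm is not None:
            self.cm = np.asarray(self.cm, dtype=float)
        n, p = self.scores.shape
        if n != len(self.accession_ids):
            raise ValueError("scores row count does not match accession_ids")
        if p != len(self.snp_ids):
            raise ValueError("scores column count does not match snp_ids")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicate SNP ids")
        finite = self.scores[~np.isnan(self.scores)]
        bad = ~np.isin(finite, VALID_SCORES)
        if bad.any():
            rows, cols = np.nonzero(
                ~np.isnan(self.scores) & ~np.isin(self.scores, VALID_SCORES)
            )
            raise ValueError(
                f"invalid score {self.scores[rows[0], cols[0]]!r} at accession "
                f"{self.accession_ids[rows[0]]!r}, SNP {self.snp_ids[cols[0]]!r}"
            )

    @property
    def n_accessions(self) -> int:
        return self.scores.shape[0]

    @property
    def n_snps(self) -> int:
        return self.scores.shape[1]

    @property
    def p(self) -> int:
        """SNP count p used in the relationship matrix K = M M^T / p."""
        return self.scores.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return np.isnan(self.scores).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from non-missing scores.

        With scores coded -1/0/1 the major-allele count over non-missing
        accessions is ``2 * count(1) + count(0)``, giving allele frequency
        f; MAF = min(f, 1 - f). SNPs with no observed genotypes get MAF 0.
        """
        s = self.scores
        obs = ~np.isnan(s)
        n_obs = obs.sum(axis=0)
        major = 2 * np.nansum(s == 1, axis=0) + np.nansum(s == 0, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_obs > 0, major / (2 * n_obs), 0.0)
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index: np.ndarray) -> "MarkerMatrix":
        index = np.asarray(index)
        return MarkerMatrix(
            accession_ids=list(self.accession_ids),
            scores=self.scores[:, index],
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index],
            bp=self.bp[index],
            cm=None if self.cm is None else self.cm[index],
        )

    def take_accessions(self, ids: Sequence[str]) -> "MarkerMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        index = np.array([pos[a] for a in ids])
        return MarkerMatrix(
            accession_ids=list(ids),
            scores=self.scores[index],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            bp=self.bp,
            cm=self.cm,
        )

    def sorted_by_position(self) -> "MarkerMatrix":
        order = np.lexsort((self.bp, self.chrom.astype(str)))
        return self.take_snps(order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.accession_ids, columns=self.snp_ids
        )

    def write_genotypes(self, path, missing_token: str = "NA", sep: str = "\t") -> None:
        df = self.to_frame()
        out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
        out.index.name = "accession"
        out.to_csv(path, sep=sep)

    def write_map(self, path) -> None:
        """Write a PLINK-style .map file (chrom, id, cM, bp), whitespace-delimited."""
        cm = self.cm if self.cm is not None else np.zeros(self.n_snps)
        with open(path, "w") as fh:
            for c, s, g, b in zip(self.chrom, self.snp_ids, cm, self.bp):
                fh.write(f"{c}\t{s}\t{g:g}\t{b}\n")


@dataclass
class PhenotypeTable:
    """Per-accession trait values with an explicit optimization direction.

    ``directions[trait]`` is ``"maximize"`` (larger is better) or
    ``"minimize"`` (smaller is better); every strategy and truncation step
    interprets "top" through this direction.
    """

    values: pd.DataFrame  # index = accession id, columns = traits
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, d in self.directions.items():
            if d not in ("maximize", "minimize"):
                raise ValueError(f"direction for {t!r} must be maximize|minimize")

    def trait(self, name: str) -> pd.Series:
        return self.values[name]

    def direction(self, name: str) -> str:
        if name not in self.directions:
            raise KeyError(f"no direction configured for trait {name!r}")
        return self.directions[name]

    def check_against(self, m: MarkerMatrix) -> None:
        missing = set(self.values.index) - set(m.accession_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped accessions absent from marker matrix: "
                f"{sorted(missing)[:5]}"
            )


def read_genotypes(
    path,
    map_path,
    missing_token: str = "NA",
    sep: str | None = None,
) -> MarkerMatrix:
    """Read a delimited genotype file plus a PLINK-style .map file.

    The genotype file has a header row of SNP ids and a first column of
    accession ids; values are -1/0/1 or the missing token. The .map file has
    four whitespace-separated columns: chromosome, SNP id, genetic position
    (cM), physical position (bp). Genotype columns without a .map row are
    dropped with a logged count; the result is sorted by (chromosome, bp).
    """
    df = pd.read_csv(
        path, sep=sep, engine="python" if sep is None else "c", index_col=0,
        na_values=[missing_token], keep_default_na=False, dtype=str,
    )
    scores = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp"], dtype={"chrom": str, "snp_id": str},
    )
    if mp["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in map file")
    map_idx = {s: i for i, s in enumerate(mp["snp_id"])}
    keep = [j for j, s in enumerate(df.columns) if s in map_idx]
    dropped = df.shape[1] - len(keep)
    if dropped:
        logger.warning("%d genotype SNPs absent from map file; dropped", dropped)
    if not keep:
        raise ValueError("no genotype SNPs matched the map file")
    rows = [map_idx[df.columns[j]] for j in keep]
    m = MarkerMatrix(
        accession_ids=[str(a) for a in df.index],
        scores=scores[:, keep],
        snp_ids=[str(df.columns[j]) for j in keep],
        chrom=mp["chrom"].to_numpy()[rows],
        bp=mp["bp"].to_numpy()[rows],
        cm=mp["cm"].to_numpy(dtype=float)[rows],
    )
    return m.sorted_by_position()


def read_phenotypes(
    path, directions: Mapping[str, str], sep: str | None = None
) -> PhenotypeTable:
    """Read a delimited phenotype table (first column = accession id)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(values=df, directions=dict(directions))


def filter_snps(
    m: MarkerMatrix, max_missing_rate: float = 0.05, min_maf: float = 0.05
) -> MarkerMatrix:
    """Retain SNPs with missing rate <= threshold and MAF >= threshold.

    Both statistics are computed on the raw input matrix and applied
    jointly; a SNP at exactly the MAF boundary is kept (removal uses the
    strict inequality MAF < min_maf).
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing_rate <= 1:
        raise ValueError("max_missing_rate must be in [0, 1]")
    keep = (m.missing_rate() <= max_missing_rate) & (m.maf() >= min_maf)
    if not keep.any():
        raise ValueError(
            "no SNPs pass QC; relax max_missing_rate and/or min_maf"
        )
    logger.info("filter_snps: kept %d of %d SNPs", int(keep.sum()), m.n_snps)
    return m.take_snps(np.nonzero(keep)[0])


def _thin_by_bins(m: MarkerMatrix, pos: np.ndarray, width: float, rng_seed: int) -> MarkerMatrix:
    """One uniformly random SNP per non-empty half-open, zero-anchored bin."""
    rng = np.random.default_rng(rng_seed)
    bins = np.floor(pos / width).astype(np.int64)
    keep: list[int] = []
    for c in pd.unique(m.chrom):
        idx = np.nonzero(m.chrom == c)[0]
        for b in np.unique(bins[idx]):
            members = idx[bins[idx] == b]
            keep.append(int(rng.choice(members)))
    keep_arr = np.sort(np.array(keep))
    return m.take_snps(keep_arr)


def thin_by_bp_bins(m: MarkerMatrix, bin_bp: int = 20000, rng_seed: int = 0) -> MarkerMatrix:
    """Per chromosome, keep one random SNP per bin of ``bin_bp`` base pairs.

    Bins are half-open and anchored at zero: [0, bin_bp), [bin_bp, 2*bin_bp), ...
    Deterministic for a given ``rng_seed``.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    return _thin_by_bins(m, m.bp.astype(float), float(bin_bp), rng_seed)


def thin_by_cm_interval(
    m: MarkerMatrix, interval_cm: float = 0.1, rng_seed: int = 0
) -> MarkerMatrix:
    """Per chromosome, keep one random SNP per ``interval_cm`` genetic-map bin."""
    if interval_cm <= 0:
        raise ValueError("interval_cm must be positive")
    if m.cm is None:
        raise ValueError("genetic positions (cM) required; interpolate first")
    return _thin_by_bins(m, m.cm, interval_cm, rng_seed)


def impute_missing_as_major(m: MarkerMatrix) -> MarkerMatrix:
    """Replace every missing genotype with 1 (major-allele homozygote)."""
    scores = m.scores.copy()
    scores[np.isnan(scores)] = 1.0
    return replace(m, scores=scores)


def recode_from_allele_counts(
    counts: np.ndarray, accession_ids: Sequence[str], snp_ids: Sequence[str],
    chrom: Iterable, bp: Iterable,
) -> MarkerMatrix:
    """Recode 0/1/2 counted-allele dosages to -1/0/1 by observed frequency.

    The counted allele is called major where its observed frequency exceeds
    0.5; at exactly 0.5 the orientation keeping +1 for the counted allele is
    used when that allele's column label sorts first, mirroring a
    lexicographic tie-break on allele identity.
    """
    counts = np.asarray(counts, dtype=float)
    obs = ~np.isnan(counts)
    with np.errstate(invalid="ignore"):
        f = np.nansum(counts, axis=0) / (2 * obs.sum(axis=0))
    scores = counts - 1.0
    flip = f < 0.5
    scores[:, flip] = -scores[:, flip]
    return MarkerMatrix(
        accession_ids=list(accession_ids), scores=scores, snp_ids=list(snp_ids),
        chrom=np.asarray(list(chrom)), bp=np.asarray(list(bp)),
    )
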