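"""Genetic maps: interpolation of cM positions and Haldane recombination fractions.

Map distance X between adjacent markers (in Morgans) is converted to a
recombination fraction with Haldane's mapping function, which assumes no
crossover interference:

    r = (1 - exp(-2 X)) / 2

``.map`` files carry centimorgans; the conversion X = cM / 100 is applied
internally wherever a recombination fraction is derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import MarkerMatrix

logger = logging.getLogger(__name__)


def haldane_r(X) -> np.ndarray | float:
    """Recombination fraction for map distance ``X`` in Morgans.

    Monotone increasing, bounded in [0, 0.5).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * X))
    return float(r) if r.ndim == 0 else r


def haldane_inverse(r) -> np.ndarray | float:
    """Map distance in Morgans recovering ``r`` under Haldane's function."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    X = -0.5 * np.log(1.0 - 2.0 * r)
    return float(X) if X.ndim == 0 else X


@dataclass
class GeneticMap:
    """Per-chromosome ordered SNP positions with derived recombination fractions."""

    chrom: np.ndarray
    snp_ids: list[str]
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if not (len(self.chrom) == len(self.snp_ids) == len(self.bp) == len(self.cm)):
            raise ValueError("field lengths differ")
        for c in self.chromosomes():
            cm_c = self.cm[self.chrom == c]
            if np.any(np.diff(cm_c) < 0):
                raise ValueError(f"cM positions decrease within chromosome {c!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def chromosomes(self) -> list:
        return list(pd.unique(self.chrom))

    def chrom_slices(self) -> dict:
        """Index array per chromosome, in map order."""
        return {c: np.nonzero(self.chrom == c)[0] for c in self.chromosomes()}

    def interval_r(self) -> dict:
        """Adjacent-interval recombination fractions, per chromosome.

        A chromosome with k SNPs yields k - 1 fractions; chromosomes
        contribute no cross-chromosome interval.
        """
        out = {}
        for c, idx in self.chrom_slices().items():
            X = np.diff(self.cm[idx]) / 100.0
            out[c] = haldane_r(X) if len(X) else np.array([])
        return out

    def switch_probs(self) -> np.ndarray:
        """Per-SNP haplotype-switch probabilities for the gamete sampler.

        Entry j is the probability that the transmitted haplotype source
        changes between SNP j-1 and SNP j: 0.5 at the first SNP of each
        chromosome (independent assortment / random start) and the Haldane
        fraction of the preceding interval elsewhere.
        """
        probs = np.empty(self.n_snps)
        for c, idx in self.chrom_slices().items():
            probs[idx[0]] = 0.5
            if len(idx) > 1:
                probs[idx[1:]] = haldane_r(np.diff(self.cm[idx]) / 100.0)
        return probs

    @classmethod
    def from_marker_matrix(cls, m: MarkerMatrix) -> "GeneticMap":
        if m.cm is None:
            raise ValueError("marker matrix has no cM positions; interpolate first")
        return cls(chrom=m.chrom, snp_ids=list(m.snp_ids), bp=m.bp, cm=m.cm)

    def write_map(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, g, b in zip(self.chrom, self.snp_ids, self.cm, self.bp):
                fh.write(f"{c}\t{s}\t{g:g}\t{b}\n")


def interpolate_genetic_positions(
    snps: MarkerMatrix, anchors: pd.DataFrame
) -> GeneticMap:
    """Assign cM to each SNP by linear interpolation from anchor markers.

    ``anchors`` needs columns ``chrom``, ``bp``, ``cm`` with >= 2 anchors per
    chromosome, strictly increasing bp and non-decreasing cM. SNPs between
    two anchors are interpolated; SNPs outside the anchored range are
    extrapolated linearly from the nearest two anchors, clamped at 0 cM, and
    the per-chromosome sequence is made non-decreasing.
    """
    cm = np.full(snps.n_snps, np.nan)
    anchors = anchors.copy()
    anchors["chrom"] = anchors["chrom"].astype(str)
    for c in pd.unique(snps.chrom):
        idx = np.nonzero(snps.chrom == c)[0]
        a = anchors[anchors["chrom"] == str(c)].sort_values("bp")
        if len(a) < 2:
            raise ValueError(f"chromosome {c!r} has fewer than 2 anchors")
        abp = a["bp"].to_numpy(dtype=float)
        acm = a["cm"].to_numpy(dtype=float)
        if np.any(np.diff(abp) <= 0):
            raise ValueError(f"anchor bp not strictly increasing on chromosome {c!r}")
        if np.any(np.diff(acm) < 0):
            raise ValueError(f"anchor cM decreasing in bp on chromosome {c!r}")
        x = snps.bp[idx].astype(float)
        # np.interp clamps outside the range; extrapolate from the end segments
        y = np.interp(x, abp, acm)
        lo = x < abp[0]
        hi = x > abp[-1]
        if lo.any():
            slope = (acm[1] - acm[0]) / (abp[1] - abp[0])
            y[lo] = acm[0] + slope * (x[lo] - abp[0])
            n_clamped = int((y[lo] < 0).sum())
            if n_clamped:
                logger.info(
                    "chromosome %s: %d SNPs extrapolated below 0 cM, clamped", c, n_clamped
                )
        if hi.any():
            slope = (acm[-1] - acm[-2]) / (abp[-1] - abp[-2])
            y[hi] = acm[-1] + slope * (x[hi] - abp[-1])
        y = np.maximum(y, 0.0)
        y = np.maximum.accumulate(y)  # bp-sorted within chromosome by contract
        cm[idx] = y
    return GeneticMap(chrom=snps.chrom, snp_ids=list(snps.snp_ids), bp=snps.bp, cm=cm)


def interval_recomb_fractions(gm: GeneticMap) -> dict:
    """Adjacent-interval Haldane recombination fractions per chromosome."""
    return gm.interval_r()
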