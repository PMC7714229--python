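"""D-score genomic-diversity index and maximal-D-score subset search.

For a candidate subset of n0 accessions with genotypic values g0, the GBLUP
model gives Var(g0) = sigma_g^2 K0, where K0 is the principal submatrix of
the genomic relationship matrix on the subset. Its determinant,
|Var(g0)| = (sigma_g^2)^n0 |K0|, measures the joint variability of the
subset, so up to the constant factor the diversity of a subset is

    D-score = det(K0).

Closely related accessions shrink det(K0) toward zero (duplicates force it
to exactly zero), so maximizing the D-score over subsets of fixed size
picks genomically diverse parents — a D-optimality criterion.

The search over subsets is combinatorial; small instances are solved
exhaustively, larger ones by a genetic algorithm over index subsets
followed by a deterministic single-swap (Fedorov-style) exchange polish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from .gblup import GebvVector

__all__ = [
    "d_score",
    "d_scores_batch",
    "SubsetSearchConfig",
    "SubsetSearchResult",
    "exhaustive_max_dscore",
    "ga_max_dscore",
    "build_strategy",
    "parse_strategy",
    "STRATEGY_NAMES",
]

_DET_CLAMP = 1e-14

STRATEGY_NAMES = (
    "GEBV-O",
    "GD-O-30", "GD-O-50", "GD-O-100",
    "GEBV-GD-30", "GEBV-GD-50", "GEBV-GD-100",
)


def d_score(K: np.ndarray, subset: Sequence[int]) -> float:
    """det of the principal submatrix of ``K`` on ``subset``.

    Values below 1e-14 (including tiny negatives from rounding of singular
    PSD submatrices) are clamped to 0.
    """
    subset = np.asarray(subset, dtype=int)
    if len(np.unique(subset)) != len(subset):
        raise ValueError("duplicate index in subset")
    K0 = np.asarray(K, dtype=float)[np.ix_(subset, subset)]
    det = float(np.linalg.det(K0))
    return 0.0 if det < _DET_CLAMP else det


def d_scores_batch(K: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """D-scores for many equal-size subsets at once (rows of ``subsets``)."""
    subsets = np.asarray(subsets, dtype=int)
    K = np.asarray(K, dtype=float)
    K0 = K[subsets[:, :, None], subsets[:, None, :]]
    dets = np.linalg.det(K0)
    return np.where(dets < _DET_CLAMP, 0.0, dets)


@dataclass
class SubsetSearchConfig:
    """Configuration of the maximal-D-score subset search.

    ``n_subset`` members are chosen from ``candidates``; any
    ``forced_include`` ids are always part of the subset (and are removed
    from ``candidates`` if listed there too). GA defaults follow a small,
    well-mixed design: population 50, 200 generations, crossover 0.9,
    mutation 0.1, elitism 2, 5 restarts; a restart stops early after
    ``stagnation`` generations without improvement.
    """

    n_subset: int
    candidates: Sequence[int] = ()
    forced_include: Sequence[int] = ()
    pop_size: int = 50
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism: int = 2
    restarts: int = 5
    stagnation: int = 60
    seed: int = 0
    exhaustive_threshold: int = 2_000_000

    def validate(self) -> tuple[list[int], list[int], int]:
        forced = list(dict.fromkeys(self.forced_include))
        cands = [c for c in dict.fromkeys(self.candidates) if c not in forced]
        n_free = self.n_subset - len(forced)
        if n_free < 0:
            raise ValueError("forced_include larger than subset size")
        if n_free > len(cands):
            raise ValueError(
                f"cannot choose {n_free} free members from {len(cands)} candidates"
            )
        return cands, forced, n_free


class SubsetSearchResult(NamedTuple):
    subset: tuple[int, ...]
    score: float
    history: list[float]  # best score after each GA generation (empty for exhaustive)


def exhaustive_max_dscore(
    K: np.ndarray,
    candidates: Sequence[int],
    n_subset: int,
    forced_include: Sequence[int] = (),
    exhaustive_threshold: int = 2_000_000,
) -> SubsetSearchResult:
    """Enumerate every admissible subset and return the argmax D-score.

    Ties are broken toward the lexicographically smallest index set. Serves
    as the brute-force oracle for the stochastic search; refuses instances
    whose subset count exceeds ``exhaustive_threshold``.
    """
    cfg = SubsetSearchConfig(
        n_subset=n_subset, candidates=candidates, forced_include=forced_include,
        exhaustive_threshold=exhaustive_threshold,
    )
    cands, forced, n_free = cfg.validate()
    n_comb = math.comb(len(cands), n_free)
    if n_comb > exhaustive_threshold:
        raise ValueError(
            f"{n_comb} subsets exceed the exhaustive budget "
            f"({exhaustive_threshold}); use ga_max_dscore"
        )
    cands_sorted = sorted(cands)
    best_subset: tuple[int, ...] | None = None
    best_score = -np.inf
    for free in combinations(cands_sorted, n_free):
        subset = tuple(sorted(forced + list(free)))
        score = d_score(K, subset)
        if score > best_score:
            best_score, best_subset = score, subset
    assert best_subset is not None
    return SubsetSearchResult(best_subset, best_score, [])


def _exchange_polish(
    K: np.ndarray, subset: set[int], pool: set[int], forced: set[int]
) -> tuple[set[int], float]:
    """Deterministic single-swap hill climb: accept the best improving swap."""
    score = d_score(K, sorted(subset))
    improved = True
    while improved:
        improved = False
        movable = sorted(subset - forced)
        outside = sorted(pool - subset)
        if not movable or not outside:
            break
        trials = []
        for i in movable:
            base = subset - {i}
            for j in outside:
                trials.append(tuple(sorted(base | {j})))
        scores = d_scores_batch(K, np.array(trials))
        k = int(np.argmax(scores))
        if scores[k] > score:
            subset = set(trials[k])
            score = float(scores[k])
            improved = True
    return subset, score


def ga_max_dscore(K: np.ndarray, cfg: SubsetSearchConfig) -> SubsetSearchResult:
    """Genetic-algorithm search for the maximal-D-score subset.

    Chromosomes are size-``n_subset`` index subsets always containing the
    forced ids; fitness is the D-score; crossover uniformly mixes two
    parents' free members and repairs to the target size; mutation swaps a
    free member with a random non-member; elitism preserves the best
    chromosomes. After the GA a deterministic exchange polish (best
    improving single swap, repeated to a local optimum) is applied.
    Deterministic given ``cfg.seed``; the returned score is always >= the
    best initial random subset.
    """
    K = np.asarray(K, dtype=float)
    cands, forced, n_free = cfg.validate()
    forced_set = set(forced)
    pool = set(cands) | forced_set
    rng = np.random.default_rng(cfg.seed)
    if n_free == 0:
        subset = tuple(sorted(forced))
        return SubsetSearchResult(subset, d_score(K, subset), [])
    cand_arr = np.array(sorted(cands))

    best_overall: set[int] | None = None
    best_score = -np.inf
    history: list[float] = []

    for _ in range(max(cfg.restarts, 1)):
        popn = [
            set(rng.choice(cand_arr, size=n_free, replace=False))
            for _ in range(cfg.pop_size)
        ]
        fits = d_scores_batch(
            K, np.array([sorted(forced_set | s) for s in popn])
        )
        stagnant = 0
        restart_best = float(fits.max())
        for _gen in range(cfg.generations):
            order = np.argsort(-fits)
            elite = [set(popn[i]) for i in order[: cfg.elitism]]
            children: list[set[int]] = list(elite)
            while len(children) < cfg.pop_size:
                # tournament selection, size 2
                a, b = rng.integers(cfg.pop_size, size=2)
                p1 = popn[a] if fits[a] >= fits[b] else popn[b]
                a, b = rng.integers(cfg.pop_size, size=2)
                p2 = popn[a] if fits[a] >= fits[b] else popn[b]
                if rng.random() < cfg.crossover_rate:
                    common = p1 & p2
                    diff = sorted((p1 | p2) - common)
                    need = n_free - len(common)
                    pick = rng.choice(len(diff), size=need, replace=False)
                    child = common | {diff[i] for i in pick}
                else:
                    child = set(p1)
                if rng.random() < cfg.mutation_rate:
                    out = [c for c in cand_arr if c not in child]
                    if out:
                        drop = sorted(child)[rng.integers(len(child))]
                        child = (child - {drop}) | {out[rng.integers(len(out))]}
                children.append(child)
            popn = children
            fits = d_scores_batch(
                K, np.array([sorted(forced_set | s) for s in popn])
            )
            gen_best = float(fits.max())
            if gen_best > restart_best + 1e-15:
                restart_best = gen_best
                stagnant = 0
            else:
                stagnant += 1
            history.append(max(restart_best, best_score))
            if stagnant >= cfg.stagnation:
                break
        i_best = int(np.argmax(fits))
        if fits[i_best] > best_score:
            best_score = float(fits[i_best])
            best_overall = forced_set | popn[i_best]

    assert best_overall is not None
    polished, polished_score = _exchange_polish(K, best_overall, pool, forced_set)
    if polished_score >= best_score:
        best_overall, best_score = polished, polished_score
    history.append(best_score)
    return SubsetSearchResult(
        tuple(int(i) for i in sorted(best_overall)), best_score, history
    )


def parse_strategy(name: str) -> tuple[str, int | None]:
    """Split a strategy name into (kind, top_k); kind in {GEBV-O, GD-O, GEBV-GD}."""
    if name == "GEBV-O":
        return "GEBV-O", None
    for prefix in ("GEBV-GD-", "GD-O-"):
        if name.startswith(prefix):
            try:
                k = int(name[len(prefix):])
            except ValueError:
                break
            return prefix[:-1], k
    raise ValueError(
        f"unknown strategy {name!r}; expected GEBV-O, GD-O-<k> or GEBV-GD-<k>"
    )


def build_strategy(
    strategy_name: str,
    gebvs: GebvVector,
    K: np.ndarray,
    n_parents: int = 10,
    n_top_fixed: int = 2,
    cfg: SubsetSearchConfig | None = None,
    seed: int = 0,
    exhaustive_if_small: bool = False,
) -> list[str]:
    """Select parental lines by one of the named strategies.

    GEBV-O takes the ``n_parents`` directed-best accessions by GEBV.
    GD-O-k searches the directed top-k candidates for the size-``n_parents``
    subset with maximal D-score. GEBV-GD-k fixes the directed top
    ``n_top_fixed`` accessions and searches the remaining top-k candidates
    for the rest, again maximizing the D-score of the full subset.

    ``K`` must be indexed like ``gebvs``; selected ids are returned in
    directed GEBV order. With ``exhaustive_if_small`` the enumeration oracle
    replaces the GA whenever the instance fits its budget.
    """
    kind, top_k = parse_strategy(strategy_name)
    order = gebvs.directed_order()
    if kind == "GEBV-O":
        idx = list(order[:n_parents])
    else:
        if top_k is None or top_k < n_parents:
            raise ValueError("top_k must be >= n_parents")
        cand = list(order[: min(top_k, len(gebvs))])
        if kind == "GD-O":
            forced: list[int] = []
        else:  # GEBV-GD
            forced = cand[:n_top_fixed]
            cand = cand[n_top_fixed:]
        base = cfg or SubsetSearchConfig(n_subset=n_parents)
        search_cfg = SubsetSearchConfig(
            n_subset=n_parents, candidates=cand, forced_include=forced,
            pop_size=base.pop_size, generations=base.generations,
            crossover_rate=base.crossover_rate, mutation_rate=base.mutation_rate,
            elitism=base.elitism, restarts=base.restarts,
            stagnation=base.stagnation, seed=seed,
            exhaustive_threshold=base.exhaustive_threshold,
        )
        n_free = n_parents - len(forced)
        if exhaustive_if_small and math.comb(len(cand), n_free) <= 50_000:
            res = exhaustive_max_dscore(K, cand, n_parents, forced)
        else:
            res = ga_max_dscore(K, search_cfg)
        idx = list(res.subset)
    pos = {i: r for r, i in enumerate(order)}
    idx.sort(key=lambda i: pos[i])
    return [gebvs.ids[i] for i in idx]
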