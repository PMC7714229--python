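"""Full parental-selection evaluation: select, cross, advance, compare.

The procedure evaluated here, per strategy and repetition:

1. Select ``n_parents`` parental lines from the genotyped panel using the
   fitted GBLUP model's GEBVs (strategy-dependent: GEBV rank, maximal
   D-score, or top-GEBV-plus-D-score).
2. Cross every pair of selected parents — C(10, 2) = 45 F1 hybrids by
   default — or only the reduced group of crosses involving a top parent.
3. Self each retained individual to produce ``progeny_per_selected``
   offspring (45 x 60 = 2,700 per generation by default), predict GEBVs of
   the whole progeny pool with the trained model, and retain the
   ``n_selected`` directed-best individuals globally across families
   (truncation selection). Repeat to the final generation (F10), whose full
   population is kept.
4. Record the best final-generation RIL's GEBV, the mean parental GEBV
   (GEBV-P), the mean GEBV of the final population (GEBV-F10), and the
   genetic gain GEBV-F10 - GEBV-P.

Strategies are compared over independent repetitions (30 by default) with
Fisher's LSD test at alpha = 0.01 on the per-repetition values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import SubsetSearchConfig, build_strategy
from .gblup import GBLUPResults, GebvVector
from .geno_io import MarkerMatrix
from .linkage_map import GeneticMap
from .meiosis import cross_pairs, founders_from_matrix, self_population

logger = logging.getLogger(__name__)

__all__ = [
    "AdvancementConfig",
    "StrategyOutcome",
    "truncate_select",
    "reduced_f1_group",
    "run_strategy",
    "evaluate_strategies",
    "lsd_test",
    "LSDResult",
    "genetic_gain",
]


@dataclass
class AdvancementConfig:
    """Breeding-scheme parameters for the Monte Carlo advancement."""

    n_parents: int = 10
    progeny_per_selected: int = 60
    n_selected: int = 45
    final_generation: int = 10
    repetitions: int = 30
    n_top_fixed: int = 2
    seed: int = 0
    reduced_top: int | None = None  # keep only crosses involving a top parent
    paired_seeds: bool = True  # share repetition seeds across strategies
    ga: SubsetSearchConfig = field(
        default_factory=lambda: SubsetSearchConfig(n_subset=10)
    )

    def __post_init__(self) -> None:
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")

    @property
    def n_f1(self) -> int:
        return self.n_parents * (self.n_parents - 1) // 2

    @property
    def generation_size(self) -> int:
        return self.n_selected * self.progeny_per_selected


@dataclass
class StrategyOutcome:
    """Per-repetition result of one strategy."""

    repetition: int
    strategy: str
    parent_ids: list[str]
    gebv_p: float  # mean parental GEBV
    best_trajectory: list[float]  # directed-best GEBV, P through final gen
    mean_trajectory: list[float]
    gebv_f10: float  # mean GEBV of the final population
    best_ril: float
    best_ril_id: str = ""

    @property
    def gain(self) -> float:
        return genetic_gain(self.gebv_f10, self.gebv_p)


def genetic_gain(gebv_f10_mean: float, gebv_p_mean: float) -> float:
    """Genetic gain = GEBV-F10 - GEBV-P (signed; larger magnitude = more change)."""
    return float(gebv_f10_mean) - float(gebv_p_mean)


def truncate_select(gebvs: GebvVector, k: int) -> np.ndarray:
    """Indices of the ``k`` directed-best individuals, globally across families.

    Ties are broken by stable input order.
    """
    if k > len(gebvs):
        raise ValueError("k exceeds population size")
    return gebvs.directed_order()[:k]


def reduced_f1_group(
    parent_ids: list[str], n_top: int = 2
) -> list[tuple[str, str]]:
    """Crosses involving at least one of the first ``n_top`` parents.

    ``parent_ids`` must already be in directed GEBV order (best first), as
    returned by the strategy builders. With 10 parents and n_top = 2 this
    yields 17 crosses of the 45.
    """
    if n_top >= len(parent_ids):
        return list(combinations(parent_ids, 2))
    top = set(parent_ids[:n_top])
    return [
        (a, b) for a, b in combinations(parent_ids, 2) if a in top or b in top
    ]


def _directed_best(values: np.ndarray, direction: str) -> int:
    return int(np.argmax(values) if direction == "maximize" else np.argmin(values))


def run_strategy(
    rep_seed: int,
    strategy: str,
    fit: GBLUPResults,
    gm: GeneticMap,
    founders: MarkerMatrix,
    cfg: AdvancementConfig,
    repetition: int = 0,
) -> StrategyOutcome:
    """One repetition of parental selection plus advancement to the final generation.

    All stochastic stages of the repetition (subset-search GA, founder
    phasing, gamete sampling) draw from a stream seeded by ``rep_seed``.
    """
    rng = np.random.default_rng(rep_seed)
    ga_seed = int(rng.integers(2**31 - 1))

    cand_gebvs = fit.predict(founders)
    parent_ids = _select_parents(strategy, cand_gebvs, founders, fit, cfg, ga_seed)

    by_id = {a: v for a, v in zip(cand_gebvs.ids, cand_gebvs.values)}
    parent_vals = np.array([by_id[a] for a in parent_ids])
    gebv_p = float(parent_vals.mean())
    direction = fit.direction

    parents = founders_from_matrix(
        founders.take_accessions(parent_ids), rng, generation="P"
    )
    if cfg.reduced_top is not None:
        pairs_ids = reduced_f1_group(parent_ids, cfg.reduced_top)
        pos = {a: i for i, a in enumerate(parent_ids)}
        pairs = [(pos[a], pos[b]) for a, b in pairs_ids]
    else:
        pairs = list(combinations(range(cfg.n_parents), 2))
    f1 = cross_pairs(parents, pairs, gm, rng, generation="F1")
    f1_gebvs = fit.predict(f1.scores(), ids=f1.ids)

    best_traj = [float(parent_vals[_directed_best(parent_vals, direction)])]
    mean_traj = [gebv_p]
    best_traj.append(float(f1_gebvs.values[_directed_best(f1_gebvs.values, direction)]))
    mean_traj.append(float(f1_gebvs.values.mean()))

    retained = f1
    pool = f1
    pool_gebvs = f1_gebvs
    for gen in range(2, cfg.final_generation + 1):
        label = f"F{gen}"
        pool = self_population(retained, cfg.progeny_per_selected, gm, rng, generation=label)
        pool_gebvs = fit.predict(pool.scores(), ids=pool.ids)
        i_best = _directed_best(pool_gebvs.values, direction)
        best_traj.append(float(pool_gebvs.values[i_best]))
        mean_traj.append(float(pool_gebvs.values.mean()))
        if gen < cfg.final_generation:
            keep = truncate_select(pool_gebvs, cfg.n_selected)
            retained = pool.subset(keep)

    i_best = _directed_best(pool_gebvs.values, direction)
    return StrategyOutcome(
        repetition=repetition,
        strategy=strategy,
        parent_ids=parent_ids,
        gebv_p=gebv_p,
        best_trajectory=best_traj,
        mean_trajectory=mean_traj,
        gebv_f10=float(pool_gebvs.values.mean()),
        best_ril=float(pool_gebvs.values[i_best]),
        best_ril_id=pool.ids[i_best],
    )


def _select_parents(
    strategy: str, gebvs: GebvVector, founders: MarkerMatrix,
    fit: GBLUPResults, cfg: AdvancementConfig, ga_seed: int,
) -> list[str]:
    """Strategy dispatch on the candidate panel's own relationship matrix."""
    from .gblup import grm

    K_cand = grm(founders.scores)
    search = replace(cfg.ga, n_subset=cfg.n_parents)
    return build_strategy(
        strategy, gebvs, K_cand, n_parents=cfg.n_parents,
        n_top_fixed=cfg.n_top_fixed, cfg=search, seed=ga_seed,
    )


def evaluate_strategies(
    strategies: list[str],
    fit: GBLUPResults,
    gm: GeneticMap,
    founders: MarkerMatrix,
    cfg: AdvancementConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every strategy for ``cfg.repetitions`` repetitions and summarize.

    Returns ``(per_rep, summary)``: one row per (strategy, repetition), and
    a per-strategy table of mean and SD for best-RIL GEBV, GEBV-P,
    GEBV-F10 and genetic gain, with ranks and LSD letter groups (alpha =
    0.01) on the best-RIL values and on the gains. Deterministic given
    ``cfg.seed``; by default repetition r reuses seed ``cfg.seed + r``
    across strategies (paired design).
    """
    rows = []
    for r in range(cfg.repetitions):
        for s_i, strat in enumerate(strategies):
            rep_seed = cfg.seed + r if cfg.paired_seeds else cfg.seed + r * len(strategies) + s_i
            out = run_strategy(rep_seed, strat, fit, gm, founders, cfg, repetition=r)
            rows.append({
                "strategy": strat, "repetition": r, "gebv_p": out.gebv_p,
                "gebv_f10": out.gebv_f10, "best_ril": out.best_ril,
                "gain": out.gain, "parents": ",".join(out.parent_ids),
                "best_trajectory": out.best_trajectory,
            })
            logger.info(
                "rep %d %s: GEBV-P=%.4g best-RIL=%.4g gain=%.4g",
                r, strat, out.gebv_p, out.best_ril, out.gain,
            )
    per_rep = pd.DataFrame(rows)

    def agg(col):
        g = per_rep.groupby("strategy")[col]
        return g.mean(), g.std(ddof=1)

    summary = pd.DataFrame(index=pd.Index(strategies, name="strategy"))
    for col in ("best_ril", "gebv_p", "gebv_f10", "gain"):
        mean, sd = agg(col)
        summary[f"{col}_mean"] = mean
        summary[f"{col}_sd"] = sd
    groups_bril = {s: per_rep.loc[per_rep.strategy == s, "best_ril"].to_numpy() for s in strategies}
    groups_gain = {s: per_rep.loc[per_rep.strategy == s, "gain"].to_numpy() for s in strategies}
    if cfg.repetitions >= 2 and len(strategies) >= 2:
        letters_dir = fit.direction
        lsd_b = lsd_test(groups_bril, alpha=0.01, direction=letters_dir)
        # gains are compared by magnitude of change; rank by |gain|
        lsd_g = lsd_test(groups_gain, alpha=0.01, direction=letters_dir)
        summary["best_ril_lsd"] = [lsd_b.letters[s] for s in strategies]
        summary["gain_lsd"] = [lsd_g.letters[s] for s in strategies]
    key = summary["best_ril_mean"]
    asc = fit.direction == "minimize"
    summary["rank"] = key.rank(ascending=asc).astype(int)
    return per_rep, summary


@dataclass
class LSDResult:
    """Fisher's LSD multiple-comparison outcome."""

    mse: float
    df_error: int
    t_crit: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, lsd, significant
    letters: dict[str, str]


def lsd_test(
    groups: dict[str, np.ndarray], alpha: float = 0.01, direction: str = "maximize"
) -> LSDResult:
    """Fisher's least-significant-difference test with letter groups.

    The pooled error mean square comes from the one-way ANOVA residual;
    groups i, j differ significantly when |mean_i - mean_j| exceeds
    LSD_ij = t(1 - alpha/2, df_error) * sqrt(MSE (1/n_i + 1/n_j)). Letters
    are assigned greedily from the best-ranked group (per ``direction``):
    groups not significantly different from a letter's anchor share it.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    ns = {k: len(v) for k, v in arrs.items()}
    if min(ns.values()) < 2:
        raise ValueError("need at least 2 observations per group")
    N = sum(ns.values())
    k = len(names)
    means = {g: float(v.mean()) for g, v in arrs.items()}
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in arrs.items())
    df_error = N - k
    mse = sse / df_error
    t_crit = float(stats.t.ppf(1 - alpha / 2, df_error))

    rows = []
    sig = {}
    for g1, g2 in combinations(names, 2):
        diff = abs(means[g1] - means[g2])
        if mse > 0:
            lsd = t_crit * np.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
            is_sig = diff > lsd
        else:  # degenerate: zero residual variance
            lsd = 0.0
            is_sig = diff > 0
        rows.append({"group1": g1, "group2": g2, "diff": diff, "lsd": lsd,
                     "significant": bool(is_sig)})
        sig[(g1, g2)] = sig[(g2, g1)] = bool(is_sig)
    pairwise = pd.DataFrame(rows)

    ordered = sorted(names, key=lambda g: means[g], reverse=(direction == "maximize"))
    letters = {g: "" for g in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    next_letter = 0
    for anchor in ordered:
        if letters[anchor]:
            continue
        letter = alphabet[next_letter % len(alphabet)]
        next_letter += 1
        letters[anchor] += letter
        for other in ordered:
            if other != anchor and not sig[(anchor, other)]:
                letters[other] += letter
    return LSDResult(mse=mse, df_error=df_error, t_crit=t_crit,
                     pairwise=pairwise, letters=letters)
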