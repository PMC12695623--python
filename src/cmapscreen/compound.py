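"""Compound-level statistics and the composite reliability ranking.

Instance connectivity scores are aggregated per compound into the
components of a reliability score:

* ``mean_score`` +- ``sd_score`` — mean and sample s.d. of the scaled
  connectivity scores over the compound's instances (nulls count as 0);
* ``p_value`` — two-sided permutation p from resampling instance scores
  (size = the compound's instance count) out of the whole run's score
  pool, with the +1 pseudo-count;
* ``fdr`` — Benjamini-Hochberg step-up adjustment across compounds;
* ``instance_count`` — number of experiments including the compound;
* ``non_null_ratio`` — replicate consistency: fraction of the compound's
  instances that score non-null with the majority sign;
* ``specificity`` — how unusual the compound's connectivity to the query
  is compared with its connectivity to background gene sets (MSigDB-style
  collections split into surrogate signed queries);
* ``reliability`` — a weighted mean of the six components rescaled to
  [0, 1], used to rank the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import EnrichmentResult, _ks_matrix, scale_raw
from .ranks import RankMatrix
from .signature import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundSummary",
    "ScreenReport",
    "summarize_compound",
    "non_null_ratio",
    "permutation_pvalue",
    "bh_fdr",
    "build_surrogate_queries",
    "specificity_score",
    "reliability_score",
    "rank_compounds",
]

REPORT_COLUMNS = [
    "compound",
    "mean_score",
    "sd_score",
    "instance_count",
    "p_value",
    "fdr",
    "non_null_ratio",
    "specificity",
    "reliability",
    "direction",
]

#: order of the reliability components
RELIABILITY_COMPONENTS = (
    "abs_mean_score",
    "one_minus_p",
    "one_minus_fdr",
    "instance_count_capped",
    "non_null_ratio",
    "specificity",
)
DEFAULT_N_CAP = 4


@dataclass
class CompoundSummary:
    compound: str
    mean_score: float
    sd_score: float
    instance_count: int
    p_value: float = np.nan
    fdr: float = np.nan
    non_null_ratio: float = np.nan
    specificity: float = np.nan
    reliability: float = np.nan

    @property
    def direction(self) -> int:
        return int(np.sign(self.mean_score))


@dataclass
class ScreenReport:
    """Ranked screen output: one row per compound, best reliability first."""

    table: pd.DataFrame
    query_name: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.table)


def summarize_compound(results: Sequence[EnrichmentResult]) -> CompoundSummary:
    """Mean +- sample s.d. of scaled scores and the instance count.

    Null instances contribute a scaled score of 0; the s.d. is the n-1
    sample standard deviation (0 for a single instance).
    """
    if not results:
        raise ValueError("no results for compound")
    compounds = {r.compound for r in results}
    if len(compounds) > 1:
        raise ValueError(f"results mix compounds: {sorted(compounds)}")
    scores = np.array([r.scaled_score for r in results], dtype=float)
    return CompoundSummary(
        compound=results[0].compound,
        mean_score=float(scores.mean()),
        sd_score=float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        instance_count=len(scores),
        non_null_ratio=non_null_ratio(results),
    )


def non_null_ratio(results: Sequence[EnrichmentResult]) -> float:
    """Fraction of instances scoring non-null with the majority sign.

    The majority direction is the sign of the summed non-null scaled
    scores (falling back to the sign of the mean on a tie); an all-null
    compound returns 0.  The denominator is all of the compound's
    instances, nulls included.
    """
    if not results:
        raise ValueError("no results for compound")
    scores = np.array([r.scaled_score for r in results], dtype=float)
    nonnull = np.array([not r.is_null for r in results], dtype=bool)
    if not nonnull.any():
        return 0.0
    total = scores[nonnull].sum()
    majority = np.sign(total) if total != 0 else np.sign(scores.mean())
    if majority == 0:
        return 0.0
    consistent = nonnull & (np.sign(scores) == majority)
    return float(consistent.sum() / len(results))


def permutation_pvalue(
    observed_mean: float,
    n_instances: int,
    pool: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided resampling p-value for a compound's mean scaled score.

    Draws ``B`` resamples of size ``n_instances`` without replacement from
    the pool of all instances' scaled scores, and reports the
    pseudo-counted exceedance ``p = (1 + #{|mean_b| >= |obs|}) / (B + 1)``.
    Resampling instance scores (rather than re-labelling genes) makes the
    null respect the empirical score distribution of the compendium.
    """
    pool = np.asarray(pool, dtype=float)
    if B < 100:
        raise ValueError("B must be >= 100")
    if n_instances > len(pool):
        raise ValueError("pool smaller than the compound's instance count")
    if rng is None:
        rng = np.random.default_rng(seed)
    # vectorised sampling without replacement: the n smallest of iid
    # uniforms index a uniform n-subset of the pool
    u = rng.random((B, len(pool)))
    idx = np.argpartition(u, n_instances - 1, axis=1)[:, :n_instances]
    means = pool[idx].mean(axis=1)
    exceed = int(np.sum(np.abs(means) >= abs(observed_mean)))
    return (1 + exceed) / (B + 1)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_surrogate_queries(
    background: GeneSetCollection,
    universe: Sequence[str],
    sig_sizes: tuple[int, int],
    rng: np.random.Generator,
    min_genes: int = 5,
    min_sets: int = 20,
) -> dict[str, tuple[list[str], list[str]]]:
    """Turn unsigned background gene sets into surrogate signed queries.

    Each set is matched to the universe (sets with fewer than
    ``min_genes`` matches dropped with a warning), shuffled, and split
    into pseudo-up / pseudo-down halves size-matched as closely as
    possible to the real query's ``(t_up, t_down)`` by subsampling when
    larger.  Built once per run from the seeded generator, so specificity
    is deterministic.
    """
    t_up, t_down = sig_sizes
    lookup = {g.strip().casefold(): g for g in universe}
    surrogates: dict[str, tuple[list[str], list[str]]] = {}
    for name, genes in background.sets.items():
        matched = [lookup[g.strip().casefold()] for g in genes if g.strip().casefold() in lookup]
        if len(matched) < min_genes:
            logger.warning("background set %s: only %d genes in universe, dropped", name, len(matched))
            continue
        matched = list(matched)
        rng.shuffle(matched)
        n_up = min(t_up, max(1, len(matched) // 2))
        n_down = min(t_down, len(matched) - n_up)
        surrogates[name] = (matched[:n_up], matched[n_up : n_up + n_down])
    if len(surrogates) < min_sets:
        raise ValueError(
            f"only {len(surrogates)} usable background sets after universe matching; need >= {min_sets}"
        )
    return surrogates


def _surrogate_raw_scores(
    matrix: RankMatrix,
    surrogates: dict[str, tuple[list[str], list[str]]],
) -> np.ndarray:
    """(n_sets, n_instances) raw connectivity of each surrogate query."""
    rows = []
    for up, down in surrogates.values():
        ks_up = _ks_matrix(matrix.ranks.loc[up].to_numpy(), matrix.n_genes)
        ks_down = _ks_matrix(matrix.ranks.loc[down].to_numpy(), matrix.n_genes)
        raw = np.where(np.sign(ks_up) == np.sign(ks_down), 0.0, ks_up - ks_down)
        rows.append(raw)
    return np.vstack(rows)


def specificity_score(
    compound_mean: float,
    sig_sizes: tuple[int, int],
    background: GeneSetCollection,
    matrix: RankMatrix,
    seed: int,
    surrogate_raw: np.ndarray | None = None,
) -> float:
    """Specificity of a compound's connectivity against background queries.

    ``matrix`` holds the compound's instances.  Each background set is
    scored as a surrogate signed query over those instances; the raw
    background scores are scaled jointly (one scaling across all sets x
    instances, so the background occupies the same [-1, 1] axis) and
    averaged per set.  Specificity is the fraction of background sets
    whose |mean| stays below |compound_mean|: 1 = maximally specific,
    0 = every background matches at least as well.
    """
    if surrogate_raw is None:
        rng = np.random.default_rng(seed)
        surrogates = build_surrogate_queries(background, matrix.universe, sig_sizes, rng)
        surrogate_raw = _surrogate_raw_scores(matrix, surrogates)
    scaled = scale_raw(surrogate_raw.ravel()).reshape(surrogate_raw.shape)
    set_means = scaled.mean(axis=1)
    exceed = int(np.sum(np.abs(set_means) >= abs(compound_mean)))
    return 1.0 - exceed / len(set_means)


def reliability_score(
    summary: CompoundSummary,
    weights: Sequence[float] | None = None,
    n_cap: int = DEFAULT_N_CAP,
) -> float:
    """Composite reliability: weighted mean of six rescaled components.

    Components, in order: |mean_score|, 1 - p, 1 - FDR,
    min(instance_count / n_cap, 1), non_null_ratio, specificity.  Equal
    weights by default; weights must be non-negative and sum to 1.  The
    instance-count cap encodes that evidence saturates after a few
    replicates.
    """
    components = np.array(
        [
            abs(summary.mean_score),
            1.0 - summary.p_value,
            1.0 - summary.fdr,
            min(summary.instance_count / n_cap, 1.0),
            summary.non_null_ratio,
            summary.specificity,
        ]
    )
    if weights is None:
        weights = np.full(6, 1 / 6)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (6,) or (weights < 0).any():
        raise ValueError("weights must be 6 non-negative reals")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    usable = ~np.isnan(components)
    if not usable.all():
        # a skipped stage (e.g. no background collection) drops its
        # component and renormalises the remaining weights
        if weights[usable].sum() == 0:
            raise ValueError("all weighted components are unavailable")
        weights = weights[usable] / weights[usable].sum()
        components = components[usable]
    return float(np.dot(weights, components))


def rank_compounds(
    summaries: Sequence[CompoundSummary],
    query_name: str = "",
    params: dict | None = None,
    seed: int | None = None,
) -> ScreenReport:
    """Assemble the ranked screen report (best reliability first).

    Ties in reliability break by |mean_score| descending, then compound
    name ascending, giving a total deterministic order.
    """
    if not summaries:
        raise ValueError("no compound summaries to rank")
    table = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "mean_score": s.mean_score,
                "sd_score": s.sd_score,
                "instance_count": s.instance_count,
                "p_value": s.p_value,
                "fdr": s.fdr,
                "non_null_ratio": s.non_null_ratio,
                "specificity": s.specificity,
                "reliability": s.reliability,
                "direction": s.direction,
            }
            for s in summaries
        ]
    )
    table["_abs_mean"] = table["mean_score"].abs()
    table = (
        table.sort_values(
            ["reliability", "_abs_mean", "compound"],
            ascending=[False, False, True],
            kind="stable",
        )
        .drop(columns="_abs_mean")
        .reset_index(drop=True)
    )
    return ScreenReport(table=table, query_name=query_name, params=params or {}, seed=seed)
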