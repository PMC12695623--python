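"""Connectivity scoring: two-sided KS enrichment of tag lists in rankings.

The statistic is the classic Connectivity Map form of the
Kolmogorov-Smirnov running-sum enrichment score.  For a tag list of size
``t`` in a ranking of ``N`` genes, let ``V(1) <= ... <= V(t)`` be the
ascending rank positions of the tags.  Define

    a = max_j ( j/t - V(j)/N )
    b = max_j ( V(j)/N - (j-1)/t )

The enrichment score is ``a`` if ``a > b`` else ``-b`` (ties resolve to
the negative branch; frozen here since the source methodology does not
discuss them).  Positive scores mean the tags concentrate near the top
(rank 1 = most up-regulated), negative near the bottom.

An instance's raw connectivity score combines the up- and down-tag
enrichment: ``s = ks_up - ks_down`` when the two have opposite signs,
otherwise the instance is *null* and ``s = 0``.  Raw scores are scaled
per query onto [-1, +1] by dividing positives by the run's maximum
positive score and negatives by the magnitude of the run's minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ranks import RankedInstance, RankMatrix
from .signature import SignedSignature

__all__ = [
    "EnrichmentResult",
    "ks_enrichment",
    "instance_score",
    "score_signature",
    "scale_scores",
    "write_instance_table",
]

INSTANCE_TABLE_COLUMNS = [
    "instance_id",
    "compound",
    "ks_up",
    "ks_down",
    "raw_score",
    "scaled_score",
    "is_null",
]


@dataclass
class EnrichmentResult:
    """Per-instance scoring record for one query."""

    instance_id: str
    ks_up: float
    ks_down: float
    raw_score: float
    scaled_score: float = np.nan
    is_null: bool = False
    compound: str = ""


def _ks_from_positions(positions: np.ndarray, n_genes: int) -> float:
    """ES from the ascending rank positions of the tags (1-based)."""
    v = np.sort(np.asarray(positions, dtype=np.float64))
    t = len(v)
    j = np.arange(1, t + 1, dtype=np.float64)
    a = np.max(j / t - v / n_genes)
    b = np.max(v / n_genes - (j - 1) / t)
    return float(a) if a > b else -float(b)


def ks_enrichment(tags: Sequence[str], instance: RankedInstance) -> float:
    """KS enrichment score of a tag list in one instance's ranking.

    Requires every tag present in the instance universe (universe
    matching happens upstream, in :meth:`SignedSignature.match_universe`).
    Deterministic; the result lies in [-1 + 1/N, 1 - t/N].
    """
    if len(tags) == 0:
        raise ValueError("empty tag list")
    if len(tags) > instance.n_genes:
        raise ValueError("more tags than genes in the universe")
    try:
        positions = instance.ranks.loc[list(tags)].to_numpy()
    except KeyError as err:
        raise ValueError(f"tag absent from instance universe: {err}") from None
    return _ks_from_positions(positions, instance.n_genes)


def instance_score(sig: SignedSignature, instance: RankedInstance) -> EnrichmentResult:
    """Raw connectivity score of one instance against a signed query.

    ``raw_score = ks_up - ks_down`` when the two enrichment scores have
    opposite signs; when they agree in sign the instance is null and
    scores 0 (the compound moved both tag lists the same way, which is
    evidence of neither mimicry nor reversal).
    """
    ks_up = ks_enrichment(sig.up_tags, instance)
    ks_down = ks_enrichment(sig.down_tags, instance)
    return _combine(instance.instance_id, instance.compound, ks_up, ks_down)


def _combine(instance_id: str, compound: str, ks_up: float, ks_down: float) -> EnrichmentResult:
    if np.sign(ks_up) == np.sign(ks_down):
        return EnrichmentResult(instance_id, ks_up, ks_down, 0.0, is_null=True, compound=compound)
    return EnrichmentResult(instance_id, ks_up, ks_down, ks_up - ks_down, compound=compound)


def _ks_matrix(tag_ranks: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorised ES for one tag list over many instances.

    ``tag_ranks`` is a (t, M) array of the tags' ranks in M instances.
    """
    v = np.sort(tag_ranks.astype(np.float64), axis=0)
    t = v.shape[0]
    j = np.arange(1, t + 1, dtype=np.float64)[:, None]
    a = np.max(j / t - v / n_genes, axis=0)
    b = np.max(v / n_genes - (j - 1) / t, axis=0)
    return np.where(a > b, a, -b)


def score_signature(
    matrix: RankMatrix,
    sig: SignedSignature,
    scale: bool = True,
) -> pd.DataFrame:
    """Score every instance of a compendium against a signed query.

    Returns the per-instance table (columns ``instance_id, compound,
    ks_up, ks_down, raw_score, scaled_score, is_null``) in compendium
    column order.  The signature must already be matched to the
    compendium universe.
    """
    sig = sig.match_universe(matrix.universe)
    up = matrix.ranks.loc[sig.up_tags].to_numpy()
    down = matrix.ranks.loc[sig.down_tags].to_numpy()
    ks_up = _ks_matrix(up, matrix.n_genes)
    ks_down = _ks_matrix(down, matrix.n_genes)
    is_null = np.sign(ks_up) == np.sign(ks_down)
    raw = np.where(is_null, 0.0, ks_up - ks_down)
    table = pd.DataFrame(
        {
            "instance_id": matrix.ranks.columns,
            "compound": matrix.meta["compound"].to_numpy(),
            "ks_up": ks_up,
            "ks_down": ks_down,
            "raw_score": raw,
            "scaled_score": np.nan,
            "is_null": is_null,
        }
    )
    if scale:
        table["scaled_score"] = scale_raw(table["raw_score"].to_numpy())
    return table


def scale_raw(raw: np.ndarray) -> np.ndarray:
    """Map raw connectivity scores onto [-1, +1].

    Positives are divided by the maximum positive raw score, negatives by
    the magnitude of the minimum negative; zeros stay zero.  A branch
    with no scores of that sign is skipped.  Scaling scope is the whole
    set passed in — per query across all instances of a run.
    """
    raw = np.asarray(raw, dtype=np.float64)
    scaled = np.zeros_like(raw)
    pos = raw > 0
    neg = raw < 0
    if pos.any():
        scaled[pos] = raw[pos] / raw[pos].max()
    if neg.any():
        scaled[neg] = -raw[neg] / raw[neg].min()
    return scaled


def scale_scores(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill ``scaled_score`` across a list of results (in place; returned)."""
    if not results:
        raise ValueError("no results to scale")
    scaled = scale_raw(np.array([r.raw_score for r in results]))
    for r, s in zip(results, scaled):
        r.scaled_score = float(s)
    return results


def write_instance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=INSTANCE_TABLE_COLUMNS)
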