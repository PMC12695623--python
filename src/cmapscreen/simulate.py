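"""Synthetic compendium generator with planted ground truth.

Generates CMap-like rank compendia in which most compounds are null
(uniform random permutations) and a configurable fraction are *mimics*
(their instances are enriched for the planted query's up-tags near the
top of the ranking and down-tags near the bottom) or *anti-mimics* (the
reverse).  Each instance draws latent gene scores g ~ N(0, 1) i.i.d.;
for a mimic the planted up-tags get +lambda and the down-tags -lambda
(anti-mimics reversed), and genes are ranked by descending latent score.
The additive shift on a standard-normal latent scale gives graded,
realistic enrichment with an analytic (probit-scale) handle on effect
size; a "hard" mode that forces tags into the extreme rank blocks is
available for extreme-case tests.

Everything is deterministic given the config seed, so generated datasets
double as reproducible fixtures for recovery-based testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .compound import ScreenReport
from .ranks import RankMatrix
from .signature import GeneSetCollection, SignedSignature

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_compendium", "truth_recovery_report"]

MIMIC, ANTIMIMIC, NULL = "mimic", "antimimic", "null"


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults emulate a mid-sized screen: a 1,000-gene universe, 200
    compounds with 3 replicate instances each, 10% planted mimics and 5%
    anti-mimics at effect size lambda = 3 (a strong but not saturating
    shift: roughly 85% of a 50-tag list lands in the top 5% of the
    ranking), a 50+50-tag query, and 30 random background sets of 100
    genes for specificity.
    """

    n_genes: int = 1000
    n_compounds: int = 200
    instances_per_compound: int | tuple[int, int] = 3
    effect_size: float = 3.0
    mimic_fraction: float = 0.1
    antimimic_fraction: float = 0.05
    signature_sizes: tuple[int, int] = (50, 50)
    n_background_sets: int = 30
    background_set_size: int = 100
    seed: int = 0
    mode: str = "latent"  # or "hard": tags forced into extreme rank blocks

    def validate(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be >= 10")
        ipc = self.instances_per_compound
        if isinstance(ipc, (tuple, list)):
            lo, hi = ipc
            if lo < 1 or hi < lo:
                raise ValueError("instances_per_compound range invalid")
        elif ipc < 1:
            raise ValueError("instances_per_compound must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.mimic_fraction <= 1 and 0 <= self.antimimic_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.mimic_fraction + self.antimimic_fraction > 1:
            raise ValueError("mimic_fraction + antimimic_fraction must be <= 1")
        t_up, t_down = self.signature_sizes
        if t_up < 1 or t_down < 1 or t_up + t_down > self.n_genes:
            raise ValueError("signature_sizes invalid for the gene universe")
        if self.background_set_size > self.n_genes:
            raise ValueError("background_set_size exceeds gene universe")
        if self.mode not in ("latent", "hard"):
            raise ValueError("mode must be 'latent' or 'hard'")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-compound labels, signature and config."""

    labels: dict[str, str]
    signature: SignedSignature
    config: SyntheticConfig

    def compounds_with(self, label: str) -> list[str]:
        return [c for c, l in self.labels.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound": list(self.labels), "label": list(self.labels.values())}
        )


def simulate_compendium(
    config: SyntheticConfig,
) -> tuple[RankMatrix, SignedSignature, GeneSetCollection, SyntheticTruth]:
    """Generate a compendium, planted query, background sets and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]

    t_up, t_down = config.signature_sizes
    tag_idx = rng.choice(n, size=t_up + t_down, replace=False)
    up_idx, down_idx = tag_idx[:t_up], tag_idx[t_up:]
    signature = SignedSignature(
        name="planted",
        up_tags=[genes[i] for i in up_idx],
        down_tags=[genes[i] for i in down_idx],
        provenance=f"synthetic, lambda={config.effect_size}, seed={config.seed}",
    )

    n_mimic = round(config.mimic_fraction * config.n_compounds)
    n_anti = round(config.antimimic_fraction * config.n_compounds)
    labels = [MIMIC] * n_mimic + [ANTIMIMIC] * n_anti
    labels += [NULL] * (config.n_compounds - len(labels))
    rng.shuffle(labels)
    compounds = [f"cmpd_{i:04d}" for i in range(1, config.n_compounds + 1)]
    truth = SyntheticTruth(dict(zip(compounds, labels)), signature, config)

    ipc = config.instances_per_compound
    if isinstance(ipc, (tuple, list)):
        counts = rng.integers(ipc[0], ipc[1] + 1, size=config.n_compounds)
    else:
        counts = np.full(config.n_compounds, ipc)

    cols, meta_rows = [], []
    lam = config.effect_size
    for compound, label, count in zip(compounds, labels, counts):
        for rep in range(1, int(count) + 1):
            g = rng.standard_normal(n)
            sign = {MIMIC: 1.0, ANTIMIMIC: -1.0, NULL: 0.0}[label]
            if config.mode == "latent":
                g[up_idx] += sign * lam
                g[down_idx] -= sign * lam
            elif sign != 0:
                # hard mode: force tags into the extreme rank blocks
                g[up_idx] = sign * (np.abs(g).max() + 1 + rng.random(t_up))
                g[down_idx] = -sign * (np.abs(g).max() + 1 + rng.random(t_down))
            order = np.argsort(-g, kind="stable")
            ranks = np.empty(n, dtype=np.int64)
            ranks[order] = np.arange(1, n + 1)
            iid = f"{compound}_r{rep}"
            cols.append(ranks)
            meta_rows.append(
                {"instance_id": iid, "compound": compound, "dose": "10uM", "cell_line": "MCF7"}
            )

    ranks_df = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=[m["instance_id"] for m in meta_rows]
    )
    matrix = RankMatrix(ranks_df, pd.DataFrame(meta_rows))

    bg_sets = {
        f"BG_{i:03d}": [genes[j] for j in rng.choice(n, size=config.background_set_size, replace=False)]
        for i in range(1, config.n_background_sets + 1)
    }
    background = GeneSetCollection(bg_sets, source="synthetic")
    logger.info(
        "simulated %d instances / %d compounds (%d mimics, %d anti-mimics), %d genes",
        matrix.n_instances, config.n_compounds, n_mimic, n_anti, n,
    )
    return matrix, signature, background, truth


def truth_recovery_report(report: ScreenReport, truth: SyntheticTruth, k: int) -> dict:
    """Recovery metrics for a screen run on a synthetic compendium.

    recall@k    — fraction of planted mimics among the top-k reliability
                  ranks; precision@k is the top-k fraction that are mimics.
    direction_accuracy — fraction of planted (non-null) compounds whose
                  reported direction matches their label (+1 mimic,
                  -1 anti-mimic).
    """
    if k > len(report.table):
        raise ValueError(f"k={k} exceeds report size {len(report.table)}")
    mimics = set(truth.compounds_with(MIMIC))
    top_k = list(report.table["compound"].head(k))
    hits = sum(1 for c in top_k if c in mimics)
    recall = hits / len(mimics) if mimics else float("nan")
    precision = hits / k

    expected = {MIMIC: 1, ANTIMIMIC: -1}
    directions = dict(zip(report.table["compound"], report.table["direction"]))
    planted = [c for c, l in truth.labels.items() if l in expected]
    correct = sum(1 for c in planted if directions.get(c) == expected[truth.labels[c]])
    accuracy = correct / len(planted) if planted else float("nan")
    return {
        "k": k,
        "recall_at_k": recall,
        "precision_at_k": precision,
        "direction_accuracy": accuracy,
        "n_mimics": len(mimics),
        "n_planted": len(planted),
    }
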