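"""The screen model: signature x compendium -> ranked compound report.

`ConnectivityScreen` is the model object: it holds the signed query, the
rank compendium, an optional background gene-set collection and the run
settings.  `fit(seed)` executes the full screen — per-instance KS
connectivity scores, query-wide scaling, per-compound aggregation,
permutation p-values, BH FDR, specificity and the composite reliability
— and returns a `ScreenResults` carrying the instance table, the ranked
compound table, run metadata, a text `summary()` and plotting/saving
helpers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compound import (
    DEFAULT_N_CAP,
    CompoundSummary,
    ScreenReport,
    REPORT_COLUMNS,
    _surrogate_raw_scores,
    bh_fdr,
    build_surrogate_queries,
    non_null_ratio,
    permutation_pvalue,
    rank_compounds,
    reliability_score,
    specificity_score,
)
from .enrichment import EnrichmentResult, score_signature, write_instance_table
from .ranks import RankMatrix
from .signature import GeneSetCollection, SignedSignature

logger = logging.getLogger(__name__)

__all__ = ["ConnectivityScreen", "ScreenResults"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds (below 2**31) from the run seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


class ConnectivityScreen:
    """In silico drug screen of a signed signature against a compendium.

    Parameters
    ----------
    signature : SignedSignature
        The signed query (up/down tag lists); matched to the compendium
        universe at fit time, with unmatched tags dropped and logged.
    compendium : RankMatrix
        Instances x genes rank compendium (rank 1 = most up-regulated).
    background : GeneSetCollection, optional
        Background gene sets for specificity.  When omitted the
        specificity stage is skipped and reliability is computed from the
        remaining five components with renormalised weights.
    b_permutations : int
        Resamples per compound for the permutation p-value (default 1000).
    weights : sequence of 6 floats, optional
        Reliability component weights (default equal).
    n_cap : int
        Instance-count saturation cap in the reliability composite.
    """

    def __init__(
        self,
        signature: SignedSignature,
        compendium: RankMatrix,
        background: GeneSetCollection | None = None,
        *,
        b_permutations: int = 1000,
        weights: Sequence[float] | None = None,
        n_cap: int = DEFAULT_N_CAP,
    ) -> None:
        self.signature = signature
        self.compendium = compendium
        self.background = background
        self.b_permutations = int(b_permutations)
        self.weights = None if weights is None else list(weights)
        self.n_cap = int(n_cap)

    @classmethod
    def from_files(
        cls,
        up_grp: str | Path,
        down_grp: str | Path,
        matrix_path: str | Path,
        meta_path: str | Path,
        background_gmt: str | Path | None = None,
        name: str = "query",
        invert_ranks: bool = False,
        **kwargs,
    ) -> "ConnectivityScreen":
        """Build a screen from GRP tag lists, a rank matrix and metadata."""
        from .ranks import read_rank_matrix
        from .signature import read_gmt, read_grp

        signature = SignedSignature(
            name=name,
            up_tags=read_grp(up_grp),
            down_tags=read_grp(down_grp),
            provenance=f"{up_grp} / {down_grp}",
        )
        compendium = read_rank_matrix(matrix_path, meta_path, invert_ranks=invert_ranks)
        background = read_gmt(background_gmt) if background_gmt else None
        return cls(signature, compendium, background, **kwargs)

    def fit(self, seed: int) -> "ScreenResults":
        """Run the screen.  ``seed`` governs the permutation null and the
        surrogate signing of background sets; identical inputs and seed
        reproduce byte-identical reports."""
        perm_seed, spec_seed = _child_seeds(seed, 2)
        matched = self.signature.match_universe(self.compendium.universe)

        logger.info(
            "scoring %d instances (%d genes) against query %s (%d up / %d down tags)",
            self.compendium.n_instances, self.compendium.n_genes,
            matched.name, *matched.sizes,
        )
        instance_table = score_signature(self.compendium, matched)
        n_null = int(instance_table["is_null"].sum())
        logger.info("instance scores: %d null of %d", n_null, len(instance_table))

        pool = instance_table["scaled_score"].to_numpy()
        groups = instance_table.groupby("compound", sort=True)

        summaries: list[CompoundSummary] = []
        results_by_compound: dict[str, list[EnrichmentResult]] = {}
        for compound, sub in groups:
            results = [
                EnrichmentResult(
                    instance_id=row.instance_id,
                    ks_up=row.ks_up,
                    ks_down=row.ks_down,
                    raw_score=row.raw_score,
                    scaled_score=row.scaled_score,
                    is_null=row.is_null,
                    compound=compound,
                )
                for row in sub.itertuples()
            ]
            results_by_compound[compound] = results
            summaries.append(self._summarize(results))

        perm_rng = np.random.default_rng(perm_seed)
        for s in summaries:
            s.p_value = permutation_pvalue(
                s.mean_score, s.instance_count, pool, B=self.b_permutations, rng=perm_rng
            )
        fdrs = bh_fdr([s.p_value for s in summaries])
        for s, q in zip(summaries, fdrs):
            s.fdr = float(q)

        if self.background is not None:
            self._add_specificity(summaries, results_by_compound, matched, spec_seed)
        for s in summaries:
            s.reliability = reliability_score(s, self.weights, self.n_cap)

        params = {
            "b_permutations": self.b_permutations,
            "n_cap": self.n_cap,
            "weights": self.weights or [1 / 6] * 6,
            "signature_sizes": matched.sizes,
            "n_background_sets": len(self.background) if self.background else 0,
        }
        report = rank_compounds(summaries, query_name=matched.name, params=params, seed=seed)
        return ScreenResults(self, report, instance_table, seed)

    def _summarize(self, results: list[EnrichmentResult]) -> CompoundSummary:
        from .compound import summarize_compound

        return summarize_compound(results)

    def _add_specificity(
        self,
        summaries: list[CompoundSummary],
        results_by_compound: dict[str, list[EnrichmentResult]],
        matched: SignedSignature,
        spec_seed: int,
    ) -> None:
        rng = np.random.default_rng(spec_seed)
        surrogates = build_surrogate_queries(
            self.background, self.compendium.universe, matched.sizes, rng
        )
        logger.info("specificity: %d surrogate background queries", len(surrogates))
        # raw surrogate scores over all instances, sliced per compound below
        surrogate_raw = _surrogate_raw_scores(self.compendium, surrogates)
        col_index = {iid: j for j, iid in enumerate(self.compendium.ranks.columns)}
        for s in summaries:
            cols = [col_index[r.instance_id] for r in results_by_compound[s.compound]]
            s.specificity = specificity_score(
                s.mean_score,
                matched.sizes,
                self.background,
                self.compendium,
                spec_seed,
                surrogate_raw=surrogate_raw[:, cols],
            )


class ScreenResults:
    """Fitted screen: ranked compound table plus per-instance scores.

    Attributes
    ----------
    report : ScreenReport
        Ranked compound summaries (best reliability first).
    compound_table : DataFrame
        The report's table, one row per compound.
    instance_table : DataFrame
        Per-instance ks_up/ks_down, raw and scaled connectivity scores.
    seed : int
        The run seed (all randomness derives from it).
    """

    def __init__(
        self,
        model: ConnectivityScreen,
        report: ScreenReport,
        instance_table: pd.DataFrame,
        seed: int,
    ) -> None:
        self.model = model
        self.report = report
        self.instance_table = instance_table
        self.seed = seed

    @property
    def compound_table(self) -> pd.DataFrame:
        return self.report.table

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.report.table.head(k)

    def summary(self, k: int = 10) -> str:
        """Human-readable run summary with the top-k ranked compounds."""
        t = self.report.table
        lines = [
            "Connectivity screen results",
            "=" * 60,
            f"query:            {self.report.query_name}",
            f"compounds:        {len(t)}",
            f"instances:        {len(self.instance_table)}"
            f" ({int(self.instance_table['is_null'].sum())} null)",
            f"permutations/cpd: {self.model.b_permutations}",
            f"seed:             {self.seed}",
            "",
            f"top {min(k, len(t))} compounds by reliability:",
        ]
        view = t.head(k).copy()
        view["mean+-sd"] = [
            f"{m:+.3f} +- {s:.3f}" for m, s in zip(view["mean_score"], view["sd_score"])
        ]
        cols = ["compound", "mean+-sd", "p_value", "fdr", "non_null_ratio", "specificity", "reliability"]
        cols = [c for c in cols if c in view.columns]
        lines.append(view[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write instance scores TSV, compound report TSV and metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "instance_scores": outdir / "instance_scores.tsv",
            "compound_report": outdir / "compound_report.tsv",
            "run_metadata": outdir / "run_metadata.json",
        }
        write_instance_table(self.instance_table, paths["instance_scores"])
        self.report.table.to_csv(
            paths["compound_report"], sep="\t", index=False,
            columns=REPORT_COLUMNS, float_format="%.10g",
        )
        meta = {
            "query": self.report.query_name,
            "seed": self.seed,
            "params": self.report.params,
            "n_compounds": len(self.report.table),
            "n_instances": len(self.instance_table),
            "compendium_checksum": self.model.compendium.checksum(),
            "cmapscreen_version": __version__,
        }
        paths["run_metadata"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
        return paths

    def plot_ranking(self, ax=None, k: int | None = None):
        """Ranked-compound figure: connectivity (bars) with specificity and
        reliability overlaid on a secondary [0, 1] axis."""
        import matplotlib.pyplot as plt

        t = self.report.table if k is None else self.report.table.head(k)
        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, len(t) * 0.05), 4))
        x = np.arange(len(t))
        ax.bar(x, t["mean_score"], color="0.6", width=1.0, label="connectivity (mean scaled)")
        ax.set_ylabel("connectivity score")
        ax.set_ylim(-1.05, 1.05)
        ax.set_xlabel("compound rank")
        ax2 = ax.twinx()
        ax2.plot(x, t["specificity"], color="tab:blue", lw=0.8, label="specificity")
        ax2.plot(x, t["reliability"], color="tab:green", lw=0.8, label="reliability")
        ax2.set_ylabel("specificity / reliability")
        ax2.set_ylim(0, 1.05)
        h1, l1 = ax.get_legend_handles_labels()
        h2, l2 = ax2.get_legend_handles_labels()
        ax.legend(h1 + h2, l1 + l2, loc="lower left", fontsize=8)
        return ax
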