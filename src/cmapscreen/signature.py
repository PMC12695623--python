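"""Signed query signatures and gene-set collections.

A signed signature is the pair of tag lists (up-regulated, down-regulated
genes) that defines a transcriptomic state to be matched against a
perturbation compendium.  Signatures can be built from a differential
expression table by fold-change/significance thresholding, or read from
GRP files; background collections for specificity scoring are carried in
GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignedSignature",
    "GeneSetCollection",
    "read_grp",
    "write_grp",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "build_signature",
]


def _norm(gene: str) -> str:
    """Canonical form used for universe matching: trimmed, case-folded."""
    return gene.strip().casefold()


@dataclass
class SignedSignature:
    """A signed query: ordered up- and down-regulated gene tag lists.

    Parameters
    ----------
    name : str
        Identifier for the query.
    up_tags, down_tags : list of str
        Duplicate-free, mutually disjoint gene identifier lists.  Order is
        meaningful (strongest change first by convention) and preserved.
    provenance : str
        Free-text note on where the signature came from.
    """

    name: str
    up_tags: list[str]
    down_tags: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for side, tags in (("up", self.up_tags), ("down", self.down_tags)):
            if len(set(tags)) != len(tags):
                raise ValueError(f"{side}_tags of signature {self.name!r} contain duplicates")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: up and down tags overlap: {sorted(overlap)[:5]}"
            )

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.up_tags), len(self.down_tags)

    def match_universe(self, universe: Sequence[str]) -> "SignedSignature":
        """Restrict tags to a compendium gene universe.

        Matching is exact string equality after whitespace trimming and
        case-folding.  Unmatched tags are dropped with a logged count; tags
        are rewritten to the universe's spelling.  An empty surviving list
        on either side is a hard error because the signature is unusable.
        """
        lookup = {}
        for g in universe:
            lookup.setdefault(_norm(g), g)
        matched: dict[str, list[str]] = {}
        for side, tags in (("up", self.up_tags), ("down", self.down_tags)):
            kept = [lookup[_norm(t)] for t in tags if _norm(t) in lookup]
            dropped = len(tags) - len(kept)
            if dropped:
                logger.warning(
                    "signature %s: dropped %d/%d %s-tags absent from universe",
                    self.name, dropped, len(tags), side,
                )
            if not kept:
                raise ValueError(
                    f"signature {self.name!r}: no {side}-tags match the compendium universe"
                )
            matched[side] = kept
        return SignedSignature(self.name, matched["up"], matched["down"], self.provenance)


@dataclass
class GeneSetCollection:
    """Named, duplicate-free gene sets (MSigDB-style background collection)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.sets)


def read_grp(path: str | Path) -> list[str]:
    """Read a GRP gene list: one identifier per line, ``#`` comments ignored.

    Duplicates are removed keeping the first occurrence.  An empty list
    after filtering is a hard error.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[str] = []
    for line in path.read_text().splitlines():
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok not in seen:
            seen.add(tok)
            out.append(tok)
    if not out:
        raise ValueError(f"GRP file {path} contains no gene identifiers")
    logger.info("read %d genes from %s", len(out), path)
    return out


def write_grp(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT collection: ``name<TAB>description<TAB>gene...`` per line.

    The description field is discarded; per-set duplicate genes are removed
    (first occurrence kept).  A line with fewer than three fields or a
    repeated set name is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in collection.sets.items()
    ]
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table (TSV/CSV) with columns
    ``gene, log2fc, adj_p``.  Gene ids must be unique; adj_p in [0, 1]."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    de = pd.read_csv(path, sep=sep)
    missing = {"gene", "log2fc", "adj_p"} - set(de.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return de


def build_signature(
    de: pd.DataFrame,
    lfc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    max_tags: int = 250,
    name: str = "query",
) -> SignedSignature:
    """Distill a signed signature from a differential-expression table.

    Up-tags are genes with ``log2fc >= +lfc_threshold`` and
    ``adj_p < p_threshold``, sorted by descending log2fc and truncated to
    ``max_tags``; down-tags analogously with ``log2fc <= -lfc_threshold``,
    sorted ascending.  Ties in log2fc are broken by input row order
    (stable sort) so results are reproducible.  The default 1.5 cutoff on
    the log2 scale mirrors the fold-change filter used for the
    regeneration-associated expression shifts this screen was designed
    around.
    """
    if de.empty:
        raise ValueError("DE table is empty")
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if max_tags < 1:
        raise ValueError("max_tags must be positive")
    if de["gene"].duplicated().any():
        raise ValueError("DE table gene ids are not unique")
    if ((de["adj_p"] < 0) | (de["adj_p"] > 1)).any():
        raise ValueError("adj_p values outside [0, 1]")

    sig = de[de["adj_p"] < p_threshold]
    up = sig[sig["log2fc"] >= lfc_threshold].sort_values(
        "log2fc", ascending=False, kind="stable"
    )
    # at lfc_threshold == 0 a zero-change gene would satisfy both filters;
    # keep the lists disjoint by assigning it to the up side only
    down = sig[(sig["log2fc"] <= -lfc_threshold) & ~sig["gene"].isin(up["gene"])]
    down = down.sort_values("log2fc", ascending=True, kind="stable")
    up_tags = up["gene"].tolist()[:max_tags]
    down_tags = down["gene"].tolist()[:max_tags]
    for side, tags in (("up", up_tags), ("down", down_tags)):
        if not tags:
            raise ValueError(
                f"no genes pass the {side} threshold (|log2fc| >= {lfc_threshold}, "
                f"adj_p < {p_threshold}); relax the thresholds"
            )
    logger.info(
        "signature %s: %d up / %d down tags at |log2fc|>=%g, adj_p<%g",
        name, len(up_tags), len(down_tags), lfc_threshold, p_threshold,
    )
    return SignedSignature(
        name=name,
        up_tags=up_tags,
        down_tags=down_tags,
        provenance=f"built from DE table (lfc>={lfc_threshold}, p<{p_threshold}, max {max_tags})",
    )
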