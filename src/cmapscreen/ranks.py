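"""Perturbation compendium data model: per-instance full gene rankings.

An *instance* is one treatment-vs-control experiment for a compound at a
particular dose and cell line.  Its data is a full ranking of the gene
universe: rank 1 = the gene most up-regulated by the treatment relative
to control (the original Connectivity Map orientation; all downstream
scoring assumes it).  A compendium is a genes x instances integer matrix
where every column is a permutation of 1..N, plus an instance metadata
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedInstance",
    "RankMatrix",
    "read_rank_matrix",
    "write_rank_matrix",
    "ranks_from_expression",
]

META_COLUMNS = ["instance_id", "compound", "dose", "cell_line"]


@dataclass
class RankedInstance:
    """One instance's metadata plus its gene -> rank permutation."""

    instance_id: str
    compound: str
    dose: str
    cell_line: str
    ranks: pd.Series  # index: gene ids, values: int ranks 1..N

    def __post_init__(self) -> None:
        n = len(self.ranks)
        if n < 2:
            raise ValueError(f"instance {self.instance_id!r}: universe must have >= 2 genes")
        _check_permutation(self.ranks.to_numpy(), self.instance_id)
        if not self.compound:
            raise ValueError(f"instance {self.instance_id!r} has an empty compound name")

    @property
    def n_genes(self) -> int:
        return len(self.ranks)


def _check_permutation(values: np.ndarray, instance_id: str) -> None:
    n = len(values)
    counts = np.bincount(values.astype(np.int64), minlength=n + 1)
    if counts[0] != 0 or not (counts[1:] == 1).all():
        raise ValueError(f"instance {instance_id!r}: ranks are not a permutation of 1..{n}")


class RankMatrix:
    """A compendium: shared gene universe, rank columns, instance metadata.

    Parameters
    ----------
    ranks : DataFrame, genes x instances, integer
        Every column must be a permutation of 1..N (1 = most up-regulated).
    meta : DataFrame with columns instance_id, compound, dose, cell_line
        One row per rank column.  Metadata rows without a matching column
        are dropped with a warning; columns without metadata are an error.
    """

    def __init__(self, ranks: pd.DataFrame, meta: pd.DataFrame) -> None:
        if ranks.columns.duplicated().any():
            raise ValueError("duplicate instance ids in rank matrix")
        if ranks.index.duplicated().any():
            raise ValueError("duplicate gene ids in rank matrix universe")
        missing = set(META_COLUMNS) - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns {sorted(missing)}")
        meta = meta.copy()
        meta["instance_id"] = meta["instance_id"].astype(str)
        if meta["instance_id"].duplicated().any():
            raise ValueError("duplicate instance ids in metadata")
        values = ranks.to_numpy()
        for j, inst in enumerate(ranks.columns):
            _check_permutation(values[:, j], str(inst))
        no_meta = set(map(str, ranks.columns)) - set(meta["instance_id"])
        if no_meta:
            raise ValueError(f"instances without metadata: {sorted(no_meta)[:5]}")
        extra = set(meta["instance_id"]) - set(map(str, ranks.columns))
        if extra:
            logger.warning("dropping %d metadata rows without rank columns", len(extra))
            meta = meta[~meta["instance_id"].isin(extra)]
        if (meta["compound"].astype(str) == "").any():
            raise ValueError("metadata contains empty compound names")
        # align metadata to column order
        meta = meta.set_index("instance_id").loc[list(map(str, ranks.columns))].reset_index()
        self.ranks = ranks.astype(np.int64)
        self.ranks.index.name = "gene"
        self.meta = meta

    @property
    def universe(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_instances(self) -> int:
        return self.ranks.shape[1]

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.meta["compound"]))

    def instance(self, instance_id: str) -> RankedInstance:
        row = self.meta[self.meta["instance_id"] == instance_id]
        if row.empty:
            raise KeyError(f"no instance {instance_id!r}")
        row = row.iloc[0]
        return RankedInstance(
            instance_id=instance_id,
            compound=row["compound"],
            dose=str(row["dose"]),
            cell_line=str(row["cell_line"]),
            ranks=self.ranks[instance_id],
        )

    def __iter__(self) -> Iterator[RankedInstance]:
        for iid in self.ranks.columns:
            yield self.instance(iid)

    def subset(self, instance_ids: list[str]) -> "RankMatrix":
        """Restrict to the given instances (shared universe unchanged)."""
        return RankMatrix(
            self.ranks[instance_ids],
            self.meta[self.meta["instance_id"].isin(instance_ids)],
        )

    def checksum(self) -> str:
        """Content hash of ranks + metadata, for run provenance records."""
        import hashlib

        h = hashlib.sha256()
        h.update("\x00".join(self.universe).encode())
        h.update("\x00".join(map(str, self.ranks.columns)).encode())
        h.update(np.ascontiguousarray(self.ranks.to_numpy()).tobytes())
        h.update(self.meta.to_csv(index=False).encode())
        return h.hexdigest()


def read_rank_matrix(
    matrix_path: str | Path,
    meta_path: str | Path,
    invert_ranks: bool = False,
) -> RankMatrix:
    """Load a compendium from a GCT 1.2 or headered-TSV rank matrix plus a
    metadata CSV (columns instance_id, compound, dose, cell_line).

    ``invert_ranks`` flips the orientation (rank r -> N+1-r) for compendia
    stored with 1 = most down-regulated.
    """
    matrix_path = Path(matrix_path)
    with open(matrix_path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#"):
        if first.strip() != "#1.2":
            raise ValueError(f"{matrix_path}: unrecognized dialect (expected '#1.2', got {first!r})")
        ranks = pd.read_csv(matrix_path, sep="\t", skiprows=2, index_col=0)
        ranks = ranks.drop(columns=["Description"], errors="ignore")
    else:
        ranks = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ranks.index = ranks.index.astype(str)
    ranks.columns = ranks.columns.astype(str)
    ranks = ranks.astype(np.int64)
    if invert_ranks:
        ranks = ranks.shape[0] + 1 - ranks
    meta = pd.read_csv(meta_path, dtype=str)
    return RankMatrix(ranks, meta)


def write_rank_matrix(
    matrix: RankMatrix,
    matrix_path: str | Path,
    meta_path: str | Path,
    dialect: str = "tsv",
) -> None:
    """Write a compendium as TSV (round-trips bit-identically) or GCT 1.2."""
    matrix_path = Path(matrix_path)
    if dialect == "tsv":
        matrix.ranks.to_csv(matrix_path, sep="\t")
    elif dialect == "gct":
        with open(matrix_path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_instances}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.ranks.columns)) + "\n")
            for gene, row in zip(matrix.universe, matrix.ranks.to_numpy()):
                fh.write(gene + "\tna\t" + "\t".join(map(str, row)) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    matrix.meta.to_csv(meta_path, index=False)


def ranks_from_expression(
    treatment: Mapping[str, float],
    control: Mapping[str, float],
    universe: list[str] | None = None,
) -> pd.Series:
    """Convert a treatment/control expression pair to a 1..N ranking.

    Genes are ordered by descending log2(treatment/control); ties are
    broken by universe order (stable), so the result is invariant to
    multiplying both profiles by a common positive constant.
    """
    if set(treatment) != set(control):
        raise ValueError("treatment and control gene sets differ")
    if universe is None:
        universe = list(treatment)
    t = np.array([treatment[g] for g in universe], dtype=float)
    c = np.array([control[g] for g in universe], dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(c).all()):
        raise ValueError("expression values must be finite")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("expression values must be positive")
    logratio = np.log2(t) - np.log2(c)
    order = np.argsort(-logratio, kind="stable")
    ranks = np.empty(len(universe), dtype=np.int64)
    ranks[order] = np.arange(1, len(universe) + 1)
    return pd.Series(ranks, index=universe)
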