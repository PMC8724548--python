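"""miRNA-MBS interaction tables: loading, validation, score-to-probability
mapping, and degree-preserving randomization.

An interaction table is the sparse map from (miRNA, gene) pairs to scored
binding sites on the gene's 3'-UTR. Two input dialects are supported:

* ``targetscan`` — context scores, real numbers <= 0; mapped to binding
  probabilities by ``p = 1 - 2**score``.
* ``mirsvr`` — regression/ranking scores (typically negative, more negative =
  stronger site); the dialect carries no published probability map, so |score|
  is min-max rescaled over the loaded table to [0, 0.999], a monotone mapping
  that preserves the dialect's ranking semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIALECTS = ("targetscan", "mirsvr")

#: TSV column order for interaction tables.
COLUMNS = ["mirna_id", "gene_id", "utr_position", "score"]

_MIRSVR_TOP = 0.999  # keeps probability strictly below 1


class BindingSite(NamedTuple):
    """One scored miRNA binding site on a gene's 3'-UTR (1-based position)."""

    mirna_id: str
    gene_id: str
    position: int
    score: float
    probability: float


def score_to_probability(
    score: float,
    dialect: str = "targetscan",
    score_range: tuple[float, float] | None = None,
) -> float:
    """Map an interaction score to a binding probability in [0, 1).

    For the ``targetscan`` dialect this is ``p = 1 - 2**score`` (score <= 0):
    a score of 0 means a site that never binds, and increasingly negative
    context scores approach probability 1. For ``mirsvr``, |score| is min-max
    rescaled over the loaded table, so ``score_range`` (min, max of |score|)
    is required.
    """
    if dialect == "targetscan":
        if score > 0:
            raise ValueError(
                f"targetscan context scores must be <= 0, got {score}"
            )
        return 1.0 - 2.0**score
    if dialect == "mirsvr":
        if score_range is None:
            raise ValueError("mirsvr mapping needs the table's |score| range")
        lo, hi = score_range
        if hi <= lo:
            return 0.0
        a = abs(score)
        return float(np.clip((a - lo) / (hi - lo), 0.0, 1.0)) * _MIRSVR_TOP
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


@dataclass
class InteractionTable:
    """Sparse miRNA-MBS interaction table with per-site binding probabilities.

    ``df`` holds one row per site (columns: mirna_id, gene_id, utr_position,
    score, probability). Indices are derived lazily and cached.
    """

    df: pd.DataFrame
    dialect: str = "targetscan"
    _mirna_index: dict | None = field(default=None, repr=False, compare=False)
    _gene_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        df = self.df.reset_index(drop=True)
        if len(df) and (df["utr_position"] < 1).any():
            bad = df.index[df["utr_position"] < 1][0]
            raise ValueError(f"row {bad}: utr_position must be >= 1")
        if "probability" not in df.columns:
            df = df.assign(
                probability=_probabilities(df["score"].to_numpy(), self.dialect)
            )
        dup = df.duplicated(["mirna_id", "gene_id", "utr_position"], keep=False)
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} duplicate (miRNA, gene, position) rows; "
                "keeping the best (most negative) score per triple",
                stacklevel=2,
            )
            df = (
                df.sort_values("score", kind="stable")
                .drop_duplicates(["mirna_id", "gene_id", "utr_position"])
                .sort_index()
                .reset_index(drop=True)
            )
        self.df = df

    # -- indices ----------------------------------------------------------
    @property
    def mirna_index(self) -> dict[str, set[str]]:
        """Map mirna_id -> set of gene_ids it has sites on."""
        if self._mirna_index is None:
            self._mirna_index = {
                m: set(g)
                for m, g in self.df.groupby("mirna_id", sort=False)["gene_id"]
            }
        return self._mirna_index

    @property
    def gene_index(self) -> dict[str, list[BindingSite]]:
        """Map gene_id -> list of its BindingSite records (all miRNAs)."""
        if self._gene_index is None:
            idx: dict[str, list[BindingSite]] = {}
            for row in self.df.itertuples(index=False):
                idx.setdefault(row.gene_id, []).append(
                    BindingSite(
                        row.mirna_id,
                        row.gene_id,
                        int(row.utr_position),
                        float(row.score),
                        float(row.probability),
                    )
                )
            self._gene_index = idx
        return self._gene_index

    @property
    def sites(self) -> list[BindingSite]:
        return [s for sites in self.gene_index.values() for s in sites]

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.df["mirna_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene_id"].unique())

    def __len__(self) -> int:
        return len(self.df)

    # -- queries ----------------------------------------------------------
    def mbs_count_per_gene(self, gene_id: str) -> int:
        """Number of binding-site records for a gene across all miRNAs."""
        return len(self.gene_index.get(gene_id, ()))

    def pair_sites(self, mirna_id: str, gene_id: str) -> pd.DataFrame:
        sub = self.df
        return sub[(sub["mirna_id"] == mirna_id) & (sub["gene_id"] == gene_id)]

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path, header_comment: str | None = None) -> None:
        """Write the table as TSV (input columns plus probability)."""
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.df.to_csv(fh, sep="\t", index=False)


def _probabilities(scores: np.ndarray, dialect: str) -> np.ndarray:
    if dialect == "targetscan":
        if len(scores) and scores.max() > 0:
            bad = int(np.argmax(scores > 0))
            raise ValueError(
                f"row {bad}: positive score {scores[bad]} under targetscan "
                "dialect (context scores are <= 0)"
            )
        return 1.0 - 2.0**scores
    a = np.abs(scores)
    if len(a) == 0:
        return a
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo) * _MIRSVR_TOP


def load_table(path, dialect: str = "targetscan") -> InteractionTable:
    """Load a tab-separated interaction table.

    Expected header: ``mirna_id  gene_id  utr_position  score`` (an existing
    ``probability`` column is ignored and recomputed). Rows with missing
    score/position are rejected with their line number; an empty table is an
    error.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[COLUMNS]
    bad = df["utr_position"].isna() | df["score"].isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed row at line {line}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty interaction table")
    df["utr_position"] = df["utr_position"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    table = InteractionTable(df, dialect=dialect)
    log.info(
        "loaded %d sites, %d genes, %d miRNAs from %s (%s dialect)",
        len(table), len(table.genes), len(table.mirnas), path, dialect,
    )
    return table


def randomize_table(table: InteractionTable, seed: int) -> InteractionTable:
    """Permute miRNA labels across (miRNA, gene) pairs.

    The per-miRNA pair count and the per-gene site count (positions, scores)
    are preserved; the specific miRNA-gene pairing — the biological signal —
    is destroyed. Used as a null control: final retentions under a randomized
    table should be uncorrelated with retentions under the true one.
    """
    if len(table) == 0:
        raise ValueError("cannot randomize an empty table")
    rng = np.random.default_rng(seed)
    pairs = list(
        table.df.groupby(["mirna_id", "gene_id"], sort=True).indices.items()
    )
    labels = [m for (m, _g), _ in pairs]
    genes = [g for (_m, g), _ in pairs]
    perm = [labels[i] for i in rng.permutation(len(labels))]
    _resolve_collisions(perm, genes, rng)
    new_df = table.df.copy()
    mirna_col = new_df["mirna_id"].to_numpy(dtype=object)
    for (label, (_pair, rows)) in zip(perm, pairs):
        mirna_col[rows] = label
    new_df["mirna_id"] = mirna_col
    return InteractionTable(new_df, dialect=table.dialect)


def _resolve_collisions(perm: list, genes: list, rng, max_sweeps: int = 100):
    """Swap permuted labels until no gene carries the same miRNA twice."""
    n = len(perm)
    for _ in range(max_sweeps):
        seen: dict[tuple, int] = {}
        conflicts = []
        for i in range(n):
            key = (perm[i], genes[i])
            if key in seen:
                conflicts.append(i)
            else:
                seen[key] = i
        if not conflicts:
            return
        for i in conflicts:
            for _try in range(50):
                j = int(rng.integers(n))
                if (
                    (perm[j], genes[i]) not in seen
                    and (perm[i], genes[j]) not in seen
                    and j != i
                ):
                    perm[i], perm[j] = perm[j], perm[i]
                    break
    raise RuntimeError("could not resolve label collisions; table too dense")


def mbs_count_per_gene(table: InteractionTable, gene_id: str) -> int:
    """Module-level convenience wrapper for ``table.mbs_count_per_gene``."""
    return table.mbs_count_per_gene(gene_id)


def make_table(
    sites: Iterable[tuple[str, str, int, float]], dialect: str = "targetscan"
) -> InteractionTable:
    """Build a table from (mirna_id, gene_id, position, score) tuples."""
    rows = list(sites)
    df = pd.DataFrame(rows, columns=COLUMNS)
    if len(df):
        df["utr_position"] = df["utr_position"].astype(np.int64)
        df["score"] = df["score"].astype(float)
    else:
        df = df.astype(
            {"mirna_id": object, "gene_id": object, "utr_position": np.int64,
             "score": float}
        )
    return InteractionTable(df, dialect=dialect)
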