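"""Normalized molecular pools for the model cell.

Raw expression measurements (e.g. RNA-seq quantifications) are converted to
fixed-size integer molecule pools: by default 50,000 miRNA molecules and
25,000 mRNA molecules per cell (a 2:1 miRNA:mRNA stoichiometry). Species
falling below a minimum molecule count after apportionment are dropped —
defaults of >=1 molecule for miRNAs and 5 molecules for mRNAs (5/25,000 =
0.02% of the pool) — and the pool is re-apportioned once over the survivors
so the total is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from ._util import largest_remainder

MIRNA_POOL = 50_000
MRNA_POOL = 25_000
MIN_MIRNA = 1
MIN_MRNA = 5
#: Spike-in fraction assigned to an undetected miRNA before overexpression
#: (0.02% of the miRNA pool = 10 molecules at the default 50k pool).
SPIKE_FRACTION = 0.0002

#: Overexpression multiplication-factor ladder used by the screens.
FACTOR_LADDER = (1, 3, 9, 18, 90, 300, 1000)


def normalize(
    raw: Mapping[str, float] | pd.Series, pool: int, min_molecules: int = 0
) -> pd.Series:
    """Convert raw abundances to integer molecule counts summing to ``pool``.

    Largest-remainder apportionment, then species with fewer than
    ``min_molecules`` molecules are dropped and the pool re-apportioned once
    over the survivors (no iteration: a survivor can in principle end just
    below the threshold after the second pass; determinism is preferred).
    """
    counts = largest_remainder(raw, pool)
    if min_molecules > 0:
        keep = counts[counts >= min_molecules]
        if keep.empty:
            raise ValueError(
                f"no species reaches {min_molecules} molecules at pool {pool}"
            )
        if len(keep) < len(counts):
            raw_s = pd.Series(raw, dtype=float)
            counts = largest_remainder(raw_s[keep.index], pool)
    return counts.sort_index()


@dataclass(frozen=True)
class CellProfile:
    """Integer molecule counts for one normalized model cell."""

    mirna_counts: pd.Series
    mrna_counts: pd.Series
    mirna_pool: int = MIRNA_POOL
    mrna_pool: int = MRNA_POOL

    def __post_init__(self) -> None:
        for name, counts in (("miRNA", self.mirna_counts),
                             ("mRNA", self.mrna_counts)):
            if (counts < 0).any():
                raise ValueError(f"negative {name} count")

    @classmethod
    def from_raw(
        cls,
        mirna_raw: Mapping[str, float] | pd.Series,
        mrna_raw: Mapping[str, float] | pd.Series,
        mirna_pool: int = MIRNA_POOL,
        mrna_pool: int = MRNA_POOL,
        min_mirna: int = MIN_MIRNA,
        min_mrna: int = MIN_MRNA,
    ) -> "CellProfile":
        """Normalize raw miRNA/mRNA abundances into a model cell."""
        return cls(
            mirna_counts=normalize(mirna_raw, mirna_pool, min_mirna),
            mrna_counts=normalize(mrna_raw, mrna_pool, min_mrna),
            mirna_pool=mirna_pool,
            mrna_pool=mrna_pool,
        )

    # -- io ---------------------------------------------------------------
    def to_tsv(self, mirna_path, mrna_path) -> None:
        self.mirna_counts.rename("count").to_csv(mirna_path, sep="\t",
                                                 index_label="id")
        self.mrna_counts.rename("count").to_csv(mrna_path, sep="\t",
                                                index_label="id")

    @classmethod
    def from_tsv(cls, mirna_path, mrna_path,
                 mirna_pool: int | None = None,
                 mrna_pool: int | None = None) -> "CellProfile":
        mir = load_profile(mirna_path)
        mr = load_profile(mrna_path)
        return cls(
            mirna_counts=mir.astype(int),
            mrna_counts=mr.astype(int),
            mirna_pool=int(mirna_pool if mirna_pool is not None else mir.sum()),
            mrna_pool=int(mrna_pool if mrna_pool is not None else mr.sum()),
        )


def load_profile(path) -> pd.Series:
    """Read a two-column TSV ``id<TAB>value`` into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, value)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="value")
    if s.isna().any():
        raise ValueError(f"{path}: missing values")
    return s.sort_index()


def apply_overexpression(
    profile: CellProfile,
    mirna_id: str,
    factor: float,
    spike_fraction: float = SPIKE_FRACTION,
    renormalize: bool = True,
) -> CellProfile:
    """Overexpress one miRNA by a multiplication factor.

    An undetected miRNA is first spiked in at ``round(spike_fraction *
    mirna_pool)`` molecules (10 at the default pool) — this is the x1
    baseline — then multiplied by ``factor``. With ``renormalize`` the miRNA
    pool is re-apportioned to its original total, modelling a cell whose
    overall miRNA content is fixed while its composition shifts.
    """
    if factor < 1:
        raise ValueError(f"overexpression factor must be >= 1, got {factor}")
    counts = profile.mirna_counts.astype(float).copy()
    if mirna_id not in counts.index or counts[mirna_id] == 0:
        counts[mirna_id] = round(spike_fraction * profile.mirna_pool)
    counts[mirna_id] *= factor
    if renormalize:
        new = largest_remainder(counts, profile.mirna_pool)
    else:
        new = counts.round().astype(int)
    return replace(profile, mirna_counts=new.sort_index())


def swap_mirna_profile(a: CellProfile, b: CellProfile) -> CellProfile:
    """Hybrid cell: ``a``'s transcriptome with ``b``'s miRNA repertoire."""
    if (a.mirna_pool, a.mrna_pool) != (b.mirna_pool, b.mrna_pool):
        raise ValueError(
            f"pool mismatch: {(a.mirna_pool, a.mrna_pool)} vs "
            f"{(b.mirna_pool, b.mrna_pool)}"
        )
    return replace(a, mirna_counts=b.mirna_counts.copy())
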