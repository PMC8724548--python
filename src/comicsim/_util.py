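"""Shared numeric helpers: integer apportionment and per-run seed derivation."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd


def largest_remainder(raw: Mapping[str, float] | pd.Series, pool: int) -> pd.Series:
    """Apportion ``pool`` integer molecules proportionally to ``raw`` weights.

    Hamilton (largest-remainder) apportionment: each id gets the floor of its
    exact quota; leftover molecules go to the largest fractional remainders,
    ties broken by id lexicographic order. The result always sums to ``pool``
    exactly, and the procedure is scale-invariant in the weights.

    Parameters
    ----------
    raw
        Non-negative weights keyed by id; at least one must be positive.
    pool
        Total number of molecules to distribute (> 0).
    """
    s = pd.Series(raw, dtype=float)
    if pool <= 0:
        raise ValueError(f"pool must be positive, got {pool}")
    if (s < 0).any():
        bad = s.index[s < 0][0]
        raise ValueError(f"negative weight for id {bad!r}")
    total = s.sum()
    if total <= 0:
        raise ValueError("all weights are zero; nothing to apportion")
    quota = s / total * pool
    base = np.floor(quota).astype(np.int64)
    leftover = int(pool - base.sum())
    if leftover > 0:
        frac = quota - base
        # sort by (-fractional part, id): stable, deterministic tie-break
        order = sorted(s.index, key=lambda i: (-frac[i], i))
        for i in order[:leftover]:
            base[i] += 1
    return base


def derive_seed(base_seed: int, *keys: int | str) -> int:
    """Deterministic child seed < 2**31 from a base seed and a tuple of keys.

    Strings are folded to integers so that (base, mirna_id, factor_index)
    always maps to the same per-run seed regardless of call order elsewhere.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(int.from_bytes(k.encode(), "little") % (2**32))
        else:
            ints.append(int(k) % (2**32))
    ss = np.random.SeedSequence([int(base_seed) % (2**32), *ints])
    return int(ss.generate_state(1)[0] % (2**31))


def check_ids(ids: Iterable[str]) -> list[str]:
    """Validate that ids are non-empty strings without tab characters."""
    out = []
    for i in ids:
        if not isinstance(i, str) or not i or "\t" in i:
            raise ValueError(f"invalid id {i!r}")
        out.append(i)
    return out
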