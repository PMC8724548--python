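"""Perturbation screens built on the simulator.

The exhaustive overexpression screen runs one full simulation per
(miRNA, factor) combination and assembles, for each factor f, the retention
matrix M_f whose entry M_f[i, j] is the final % retention of gene i when
miRNA j is overexpressed by factor f. Ratio matrices M_f / M_k between two
factors, discretized at >2 (up) and <0.5 (down), expose genes whose
degradation responds to miRNA dosage. The hybrid-cell comparison swaps one
cell's miRNA repertoire into another and correlates the two retention
trajectories over the run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CellProfile, FACTOR_LADDER, apply_overexpression, \
    swap_mirna_profile
from .interactions import InteractionTable
from .simulator import RetentionTrajectory, SimConfig, run
from ._util import derive_seed


@dataclass
class RetentionMatrix:
    """Final retention (genes x miRNAs) at one overexpression factor."""

    factor: float
    data: pd.DataFrame  # rows: gene_order, columns: mirna_order

    @property
    def gene_order(self) -> list[str]:
        return list(self.data.index)

    @property
    def mirna_order(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RatioMatrix:
    """Elementwise M_f / M_k with 3-level discretization.

    Labels: ``up`` if ratio > up_threshold (gene retained better at factor f),
    ``down`` if ratio < down_threshold (more prone to degradation at f),
    ``neutral`` otherwise. Zero handling: 0/0 -> ratio 1 (neutral),
    positive/0 -> +inf (up).
    """

    numerator_factor: float
    denominator_factor: float
    ratios: pd.DataFrame
    labels: pd.DataFrame
    up_threshold: float = 2.0
    down_threshold: float = 0.5


def overexpression_screen(
    profile: CellProfile,
    table: InteractionTable,
    factors: Sequence[float] = FACTOR_LADDER,
    mirnas: Sequence[str] | None = None,
    config: SimConfig | None = None,
    renormalize: bool = True,
) -> dict[float, RetentionMatrix]:
    """Run the full (miRNA x factor) screen.

    One simulation per matrix cell-column; per-run seeds are derived
    deterministically from ``config.seed``, the miRNA id, and the factor
    index, so the whole screen is reproducible from one base seed.
    """
    factors = [float(f) for f in factors]
    if sorted(factors) != factors:
        raise ValueError("factors must be sorted ascending")
    if not factors or factors[0] != 1.0:
        raise ValueError("the factor ladder must start at 1 (the x1 baseline)")
    if config is None:
        config = SimConfig()
    if mirnas is None:
        mirnas = [m for m in table.mirnas if m in profile.mirna_counts.index]
    gene_order = [g for g, c in profile.mrna_counts.items() if c > 0]
    out: dict[float, RetentionMatrix] = {}
    for fi, f in enumerate(factors):
        cols = {}
        for mirna in mirnas:
            seed = derive_seed(config.seed, mirna, fi)
            run_cfg = replace(config, seed=seed)
            perturbed = apply_overexpression(
                profile, mirna, f, renormalize=renormalize
            )
            try:
                traj = run(perturbed, table, run_cfg)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise RuntimeError(
                    f"screen run failed for miRNA {mirna!r} at factor x{f:g}"
                ) from exc
            cols[mirna] = traj.final().reindex(gene_order)
        out[f] = RetentionMatrix(
            factor=f, data=pd.DataFrame(cols, index=gene_order)[list(mirnas)]
        )
    return out


def consecutive_pairs(factors: Sequence[float]) -> list[tuple[float, float]]:
    """The (f_{t+1}, f_t) pairs along the ladder, numerator = higher factor."""
    fs = sorted(float(f) for f in factors)
    return [(fs[i + 1], fs[i]) for i in range(len(fs) - 1)]


def ratio_matrices(
    screens: Mapping[float, RetentionMatrix],
    pairs: Sequence[tuple[float, float]] | None = None,
    up: float = 2.0,
    down: float = 0.5,
) -> list[RatioMatrix]:
    """Compute M_f / M_k ratio matrices with up/neutral/down discretization.

    ``pairs`` defaults to the consecutive ladder pairs (6 pairs for the
    7-factor ladder; 21 unordered pairs exist in total).
    """
    if pairs is None:
        pairs = consecutive_pairs(list(screens))
    out = []
    for f, k in pairs:
        if f not in screens or k not in screens:
            raise KeyError(f"factor pair ({f:g}, {k:g}) not in screen results")
        num = screens[f].data
        den = screens[k].data
        if not num.index.equals(den.index) or not num.columns.equals(
            den.columns
        ):
            raise ValueError("retention matrices are not aligned")
        n = num.to_numpy(float)
        d = den.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = n / d
        r[(n == 0) & (d == 0)] = 1.0
        r[(n > 0) & (d == 0)] = np.inf
        ratios = pd.DataFrame(r, index=num.index, columns=num.columns)
        lab = np.full(r.shape, "neutral", dtype=object)
        lab[r > up] = "up"
        lab[r < down] = "down"
        labels = pd.DataFrame(lab, index=num.index, columns=num.columns)
        out.append(
            RatioMatrix(
                numerator_factor=f,
                denominator_factor=k,
                ratios=ratios,
                labels=labels,
                up_threshold=up,
                down_threshold=down,
            )
        )
    return out


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.array_equal(x, y):
        return 1.0
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def hybrid_correlation(
    profile_a: CellProfile,
    profile_b: CellProfile,
    table: InteractionTable,
    config: SimConfig | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate a cell with its miRNA-swapped hybrid along the run.

    Runs the simulator on ``profile_a`` and on the hybrid carrying
    ``profile_b``'s miRNA repertoire (same seed, paired runs) and computes
    the chosen rank/linear correlation between the two per-gene retention
    vectors, restricted to the shared gene universe, at every checkpoint.

    Returns a DataFrame with columns ``iteration`` and ``correlation``; the
    shared-gene count is stored in ``df.attrs["n_shared"]``.
    """
    if config is None:
        config = SimConfig()
    hybrid = swap_mirna_profile(profile_a, profile_b)
    traj_a = run(profile_a, table, config)
    traj_h = run(hybrid, table, config)
    shared = [g for g in traj_a.genes if g in set(traj_h.genes)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    rows = []
    for cp in traj_a.checkpoints:
        x = traj_a.data.loc[shared, cp].to_numpy(float)
        y = traj_h.data.loc[shared, cp].to_numpy(float)
        rows.append((cp, _correlate(x, y, method)))
    out = pd.DataFrame(rows, columns=["iteration", "correlation"])
    out.attrs["n_shared"] = len(shared)
    return out
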