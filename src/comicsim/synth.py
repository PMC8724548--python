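"""Synthetic model cells with known ground truth.

The generator emulates the structural features of real cellular miRNA/mRNA
data that drive the simulator's behavior — a handful of dominant miRNAs
carrying ~90% of the miRNA pool over a long low-expression tail, a skewed
mRNA abundance distribution, and tens of scored binding sites per gene
spaced realistically along a 3'-UTR — without any sequence-level realism.
Planted targets and decay archetypes provide ground truth for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CellProfile, MIRNA_POOL, MRNA_POOL, MIN_MIRNA, MIN_MRNA
from .interactions import InteractionTable, make_table
from .simulator import RetentionTrajectory
from ._util import largest_remainder


@dataclass
class SynthSpec:
    """Parameters of one synthetic cell.

    ``mirna_skew`` is the power-law exponent of the miRNA abundance ranks;
    the default 2.2 puts ~93% of the pool on the top 5 of 100 miRNAs,
    matching the "handful of miRNAs dominate" regime. Scores are drawn from
    a shifted negative exponential on (-inf, 0] tuned so typical site
    probabilities span roughly [0.05, 0.9].
    """

    n_genes: int = 100
    n_mirnas: int = 20
    mirna_skew: float = 2.2
    sites_per_gene_mean: float = 25.0
    utr_length: int = 2_000
    spacing_nt: int = 50
    score_offset: float = 0.074  # probability floor ~0.05
    score_scale: float = 0.9
    score_floor: float = -3.32  # probability ceiling ~0.9
    mrna_sigma: float = 1.0  # lognormal spread of raw mRNA abundance
    mirna_pool: int = MIRNA_POOL
    mrna_pool: int = MRNA_POOL
    min_mirna: int = MIN_MIRNA
    min_mrna: int = MIN_MRNA
    planted_targets: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("need at least one gene and one miRNA")
        max_sites = self.utr_length // self.spacing_nt
        if self.sites_per_gene_mean > max_sites:
            raise ValueError(
                f"sites_per_gene_mean {self.sites_per_gene_mean} incompatible "
                f"with utr_length {self.utr_length} at {self.spacing_nt}-nt "
                f"spacing (max {max_sites})"
            )


def gene_name(i: int) -> str:
    return f"gene-{i:04d}"


def mirna_name(i: int) -> str:
    return f"mir-{i:03d}"


def _spaced_positions(rng, n: int, utr_length: int, spacing: int) -> list[int]:
    """n sorted 1-based positions with pairwise gaps >= spacing."""
    if n == 0:
        return []
    span = utr_length - (n - 1) * spacing
    y = np.sort(rng.integers(1, span + 1, size=n))
    return [int(y[i] + i * spacing) for i in range(n)]


def make_cell(spec: SynthSpec) -> tuple[CellProfile, InteractionTable, dict]:
    """Generate a normalized cell, its interaction table, and ground truth.

    Returns ``(profile, table, ground_truth)`` where ground truth records the
    planted targets, the per-gene site counts, and the top-5 miRNA pool
    share. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mirna_ids = [mirna_name(i) for i in range(1, spec.n_mirnas + 1)]
    gene_ids = [gene_name(i) for i in range(1, spec.n_genes + 1)]

    # abundances: rank-ordered power law for miRNAs, lognormal for mRNAs
    mirna_raw = pd.Series(
        (np.arange(1, spec.n_mirnas + 1, dtype=float) ** -spec.mirna_skew),
        index=mirna_ids,
    )
    mrna_raw = pd.Series(
        np.exp(rng.normal(0.0, spec.mrna_sigma, size=spec.n_genes)),
        index=gene_ids,
    )
    profile = CellProfile.from_raw(
        mirna_raw, mrna_raw,
        mirna_pool=spec.mirna_pool, mrna_pool=spec.mrna_pool,
        min_mirna=spec.min_mirna, min_mrna=spec.min_mrna,
    )
    kept_genes = [g for g in gene_ids if g in profile.mrna_counts.index]
    kept_mirnas = [m for m in mirna_ids if m in profile.mirna_counts.index]

    planted_by_gene: dict[str, list[tuple[str, float]]] = {}
    for mirna, gene, score in spec.planted_targets:
        planted_by_gene.setdefault(gene, []).append((mirna, score))

    sites: list[tuple[str, str, int, float]] = []
    sites_per_gene: dict[str, int] = {}
    max_sites = spec.utr_length // spec.spacing_nt
    for gene in kept_genes:
        planted = planted_by_gene.get(gene, [])
        n_random = int(min(rng.poisson(spec.sites_per_gene_mean),
                           max_sites - len(planted)))
        n = n_random + len(planted)
        positions = _spaced_positions(rng, n, spec.utr_length, spec.spacing_nt)
        # planted sites take the first positions; the rest are random draws
        for (mirna, score), pos in zip(planted, positions[: len(planted)]):
            sites.append((mirna, gene, pos, float(score)))
        for pos in positions[len(planted):]:
            mirna = kept_mirnas[int(rng.integers(len(kept_mirnas)))]
            score = -(spec.score_offset + rng.exponential(spec.score_scale))
            sites.append((mirna, gene, pos, float(max(score, spec.score_floor))))
        sites_per_gene[gene] = n
    table = make_table(sites) if sites else make_table([])

    top5 = profile.mirna_counts.sort_values(ascending=False).iloc[:5].sum()
    ground_truth = {
        "planted_targets": [list(t) for t in spec.planted_targets],
        "sites_per_gene": sites_per_gene,
        "top5_mirna_share": float(top5 / profile.mirna_pool),
        "genes": kept_genes,
        "mirnas": kept_mirnas,
        "spec": {k: v for k, v in asdict(spec).items()},
    }
    return profile, table, ground_truth


#: Five decay archetypes on normalized time t in [0, 1]; shapes mimic a
#: stable bulk, three intermediate decay rates, and an immediate collapse
#: whose endpoint nearly coincides with the fast class.
ARCHETYPES = {
    1: lambda t: 100.0 - 3.0 * t,                 # stable
    2: lambda t: 100.0 * np.exp(-0.45 * t),       # slow
    3: lambda t: 100.0 * np.exp(-1.5 * t),        # medium
    4: lambda t: 100.0 * np.exp(-3.5 * t),        # fast
    5: lambda t: 100.0 * np.exp(-12.0 * t),       # immediate
}

DEFAULT_ARCHETYPE_FRACTIONS = (0.69, 0.12, 0.08, 0.07, 0.04)


def make_trajectory_archetypes(
    n_genes: int = 200,
    fractions: Sequence[float] = DEFAULT_ARCHETYPE_FRACTIONS,
    noise_sd: float = 1.0,
    checkpoints: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[RetentionTrajectory, dict[str, int]]:
    """Noisy retention trajectories drawn from 5 planted decay archetypes.

    Gene counts per archetype follow ``fractions`` exactly (largest-remainder
    split). Gaussian noise is added at every checkpoint after iteration 0
    (retention at 0 is exactly 100) and values are clipped to [0, 100].
    Returns the trajectory and the ground-truth archetype label per gene.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(fractions) != len(ARCHETYPES):
        raise ValueError(f"need {len(ARCHETYPES)} fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if checkpoints is None:
        checkpoints = list(range(0, 100_001, 5_000))
    rng = np.random.default_rng(seed)
    counts = largest_remainder(
        {str(a): f for a, f in zip(ARCHETYPES, fractions)}, n_genes
    )
    labels: dict[str, int] = {}
    rows = []
    gene_ids = []
    t = np.asarray(checkpoints, dtype=float)
    t = t / t.max() if t.max() > 0 else t
    i = 0
    for a, fn in ARCHETYPES.items():
        base = fn(t)
        for _ in range(int(counts[str(a)])):
            i += 1
            g = gene_name(i)
            curve = base.copy()
            if noise_sd > 0:
                curve = curve + rng.normal(0.0, noise_sd, size=len(t))
                curve = np.clip(curve, 0.0, 100.0)
            curve[0] = 100.0
            rows.append(curve)
            gene_ids.append(g)
            labels[g] = a
    data = pd.DataFrame(
        rows, index=pd.Index(gene_ids, name="gene_id"),
        columns=[int(c) for c in checkpoints],
    )
    return RetentionTrajectory(data), labels


def planted_regulator_cell(
    n_genes: int = 100,
    n_mirnas: int = 20,
    score: float = -2.0,
    seed: int = 0,
) -> tuple[CellProfile, InteractionTable, dict]:
    """Benchmark cell for the randomized-table null control.

    Every gene carries exactly one planted site with a common score, from a
    miRNA drawn uniformly at random. Degree and score are therefore uniform
    across genes, so a gene's fate is determined solely by the abundance of
    the miRNA that targets it — exactly the signal that label randomization
    destroys. Final retentions under the true table should decorrelate from
    those under a randomized table, while replicate runs stay correlated.
    """
    rng = np.random.default_rng(seed)
    planted = [
        (mirna_name(int(rng.integers(1, n_mirnas + 1))), gene_name(i), score)
        for i in range(1, n_genes + 1)
    ]
    spec = SynthSpec(
        n_genes=n_genes, n_mirnas=n_mirnas, sites_per_gene_mean=0.0,
        planted_targets=planted, seed=seed,
    )
    return make_cell(spec)


#: miRNA id used as the dose-response sentinel regulator (absent from the
#: naive cell, so the x1 baseline is the 0.02% spike-in).
SENTINEL_MIRNA = "mir-099"
SENTINEL_GENE = gene_name(5)


def sentinel_dose_response_cell(
    n_genes: int = 30,
    n_mirnas: int = 8,
    seed: int = 7,
) -> tuple[CellProfile, InteractionTable, dict]:
    """Benchmark cell for overexpression dose-response monotonicity.

    One sentinel gene carries a single strong site (score -6, binding
    probability ~0.98) for a miRNA that is not expressed in the naive cell;
    overexpression starts from the spike-in baseline, so the sentinel's
    retention should fall monotonically along the factor ladder. All other
    genes carry one planted background site from an expressed miRNA.
    """
    rng = np.random.default_rng(seed)
    planted = [
        (mirna_name(int(rng.integers(1, n_mirnas + 1))), gene_name(i), -2.0)
        for i in range(1, n_genes + 1)
        if gene_name(i) != SENTINEL_GENE
    ]
    planted.append((SENTINEL_MIRNA, SENTINEL_GENE, -6.0))
    spec = SynthSpec(
        n_genes=n_genes, n_mirnas=n_mirnas, sites_per_gene_mean=0.0,
        planted_targets=planted, seed=seed,
    )
    return make_cell(spec)


def write_bundle(path_dir, spec: SynthSpec) -> dict:
    """Emit a synthetic cell as TSV files plus a ground-truth JSON sidecar."""
    import os

    os.makedirs(path_dir, exist_ok=True)
    profile, table, truth = make_cell(spec)
    profile.to_tsv(
        os.path.join(path_dir, "mirna_profile.tsv"),
        os.path.join(path_dir, "mrna_profile.tsv"),
    )
    table.to_tsv(os.path.join(path_dir, "interactions.tsv"))
    with open(os.path.join(path_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
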