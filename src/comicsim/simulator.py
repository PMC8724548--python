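"""Iterative stochastic kernel for miRNA-mRNA binding and degradation.

Each iteration models one encounter in the cell:

1. a miRNA type is sampled with probability proportional to its free count;
2. among that miRNA's target genes, one gene is sampled with probability
   proportional to its count of *eligible* molecules (molecules carrying at
   least one site of that miRNA whose position is at least ``spacing_nt``
   away from every RISC already bound on that molecule);
3. a molecule is drawn uniformly among the gene's eligible molecules and a
   site uniformly among the molecule's eligible sites;
4. binding succeeds with the site's probability; a successful first binding
   marks the molecule for removal ``removal_delay`` iterations later
   (degradation with a delay that opens a cooperative-binding window);
5. molecules whose delay expires this iteration are degraded and their bound
   miRNAs return to the free pool (miRNAs recycle, they never degrade);
6. optional random decay removes unbound molecules at a fixed per-iteration
   rate, and optional transcription injects new unbound molecules.

A failed Bernoulli draw, or a sampled miRNA with no eligible target, still
consumes the iteration, so iteration counts are comparable across conditions.

Unbound molecules of a gene are statistically exchangeable, so the state
stores them as a per-gene integer count; only occupied molecules (at least
one bound miRNA) are materialized as :class:`MoleculeState` records. The
sampling distribution is identical to the one-record-per-molecule reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CellProfile
from .interactions import InteractionTable
from ._util import largest_remainder


@dataclass
class SimConfig:
    """Run parameters for the simulator.

    total_iterations
        Length of the run; the reference setting is 100,000 iterations.
    removal_delay
        Iterations between a molecule's first successful binding and its
        degradation (default 1,000).
    spacing_nt
        Minimal distance between two bound RISCs on one molecule, measured
        between site start positions (default 50 nt).
    decay_rate
        Per-iteration probability that an unbound molecule decays
        spontaneously (default 0 = off).
    transcription
        Optional ``(interval, count)``: every ``interval`` iterations,
        ``count`` new unbound molecules are added, apportioned proportionally
        to the initial gene distribution.
    checkpoints
        Iterations at which retention is recorded; defaults to ~50 evenly
        spaced points plus iteration 0.
    """

    total_iterations: int = 100_000
    removal_delay: int = 1_000
    spacing_nt: int = 50
    decay_rate: float = 0.0
    transcription: tuple[int, int] | None = None
    checkpoints: Sequence[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_iterations < 0:
            raise ValueError("total_iterations must be >= 0")
        if self.removal_delay < 1:
            raise ValueError("removal_delay must be >= 1")
        if self.spacing_nt < 1:
            raise ValueError("spacing_nt must be >= 1")
        if not 0.0 <= self.decay_rate < 1.0:
            raise ValueError("decay_rate must be in [0, 1)")
        if self.transcription is not None:
            interval, count = self.transcription
            if interval < 1 or count < 0:
                raise ValueError("transcription needs interval >= 1, count >= 0")

    def resolved_checkpoints(self) -> list[int]:
        if self.checkpoints is not None:
            cps = sorted(set(int(c) for c in self.checkpoints) | {0})
            if cps[0] < 0 or cps[-1] > self.total_iterations:
                raise ValueError("checkpoints outside [0, total_iterations]")
            return cps
        step = max(1, self.total_iterations // 50)
        cps = list(range(0, self.total_iterations + 1, step))
        if cps[-1] != self.total_iterations:
            cps.append(self.total_iterations)
        return cps


@dataclass
class MoleculeState:
    """An occupied mRNA molecule: bound RISC positions and their miRNAs."""

    gene_id: str
    occupied_positions: list[int]
    bound_mirnas: list[str]
    first_bind_iteration: int | None = None


class RetentionTrajectory:
    """Per-gene % of initial molecules still unbound, sampled at checkpoints."""

    def __init__(self, data: pd.DataFrame):
        #: genes x checkpoints matrix of retention percentages.
        self.data = data

    @property
    def checkpoints(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def retention(self) -> dict[str, list[float]]:
        return {g: list(self.data.loc[g]) for g in self.data.index}

    def final(self) -> pd.Series:
        """Retention at the last checkpoint."""
        return self.data.iloc[:, -1]

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "RetentionTrajectory":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        df.columns = [int(c) for c in df.columns]
        return cls(df)


class CellState:
    """Mutable simulator world: free miRNAs, molecules, removal queue, RNG."""

    def __init__(self, profile: CellProfile, seed: int):
        if len(profile.mrna_counts) == 0 or len(profile.mirna_counts) == 0:
            raise ValueError("profile has no expressed species")
        self.gene_ids: list[str] = list(profile.mrna_counts.index)
        self.mirna_ids: list[str] = list(profile.mirna_counts.index)
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self._mirna_pos = {m: i for i, m in enumerate(self.mirna_ids)}
        self.unbound = profile.mrna_counts.to_numpy(np.int64).copy()
        self.initial = self.unbound.copy()
        self.free_mirna_arr = profile.mirna_counts.to_numpy(np.int64).copy()
        self.bound_mirna_arr = np.zeros_like(self.free_mirna_arr)
        #: per-gene lists of occupied MoleculeState records
        self.occupied: list[list[MoleculeState]] = [[] for _ in self.gene_ids]
        self.removal_queue: dict[int, list[tuple[int, MoleculeState]]] = {}
        self.iteration = 0
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        # lazily bound per-table sampling index
        self._table_key: int | None = None
        self._targets: list[np.ndarray] = []
        self._pair_sites: dict = {}
        self._gene_mirnas: list[list[int]] = []
        # E[mi, gi] = number of occupied molecules of gene gi that still
        # carry an eligible site for miRNA mi; refreshed incrementally
        # whenever a gene's occupancy pattern changes
        self._E: np.ndarray = np.zeros(
            (len(self.mirna_ids), len(self.gene_ids)), dtype=np.int64
        )
        self._spacing: int | None = None

    # -- views -------------------------------------------------------------
    @property
    def free_mirna(self) -> dict[str, int]:
        return {m: int(c) for m, c in zip(self.mirna_ids, self.free_mirna_arr)}

    @property
    def molecules(self) -> list[MoleculeState]:
        """Explicit records for occupied molecules (unbound ones are counts)."""
        return [m for per_gene in self.occupied for m in per_gene]

    def unbound_counts(self) -> dict[str, int]:
        return {g: int(c) for g, c in zip(self.gene_ids, self.unbound)}

    def total_mirna(self) -> int:
        return int(self.free_mirna_arr.sum() + self.bound_mirna_arr.sum())

    def total_molecules(self) -> int:
        return int(self.unbound.sum()) + sum(len(o) for o in self.occupied)

    # -- table binding ------------------------------------------------------
    def _bind_table(self, table: InteractionTable) -> None:
        """Precompute, per miRNA, its in-cell target genes and site arrays."""
        if self._table_key == id(table):
            return
        per_mirna: dict[int, set[int]] = {}
        pair_sites: dict = {}
        df = table.df
        mirna_col = df["mirna_id"].to_numpy(object)
        gene_col = df["gene_id"].to_numpy(object)
        pos_col = df["utr_position"].to_numpy(np.int64)
        prob_col = df["probability"].to_numpy(float)
        for i in range(len(df)):
            mi = self._mirna_pos.get(mirna_col[i])
            gi = self._gene_pos.get(gene_col[i])
            if mi is None or gi is None:
                continue
            pos, prob = pair_sites.setdefault((mi, gi), ([], []))
            pos.append(int(pos_col[i]))
            prob.append(float(prob_col[i]))
            per_mirna.setdefault(mi, set()).add(gi)
        self._targets = [
            np.asarray(sorted(per_mirna.get(mi, ())), dtype=np.int64)
            for mi in range(len(self.mirna_ids))
        ]
        self._pair_sites = pair_sites
        gene_mirnas: list[list[int]] = [[] for _ in self.gene_ids]
        for (mi, gi) in pair_sites:
            gene_mirnas[gi].append(mi)
        self._gene_mirnas = gene_mirnas
        self._table_key = id(table)
        self._spacing = None  # forces a full eligibility refresh next step

    def _refresh_gene(self, gi: int, spacing: int) -> None:
        """Recount eligible occupied molecules of gene ``gi`` per miRNA."""
        per_gene = self.occupied[gi]
        for mi in self._gene_mirnas[gi]:
            if not per_gene:
                self._E[mi, gi] = 0
                continue
            positions, _ = self._pair_sites[(mi, gi)]
            n = 0
            for mol in per_gene:
                if _eligible_sites(positions, mol.occupied_positions,
                                   spacing):
                    n += 1
            self._E[mi, gi] = n

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "mirna_ids": self.mirna_ids,
            "unbound": self.unbound.tolist(),
            "initial": self.initial.tolist(),
            "free_mirna": self.free_mirna_arr.tolist(),
            "bound_mirna": self.bound_mirna_arr.tolist(),
            "occupied": [
                [
                    {
                        "positions": m.occupied_positions,
                        "mirnas": m.bound_mirnas,
                        "first_bind": m.first_bind_iteration,
                        "due": due,
                    }
                    for m, due in (
                        (m, _due_of(self.removal_queue, m)) for m in per_gene
                    )
                ]
                for per_gene in self.occupied
            ],
            "iteration": self.iteration,
            "seed": self.seed,
            "rng_state": json.loads(json.dumps(self.rng.bit_generator.state)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellState":
        profile = CellProfile(
            mirna_counts=pd.Series(d["free_mirna"], index=d["mirna_ids"]),
            mrna_counts=pd.Series(d["unbound"], index=d["gene_ids"]),
            mirna_pool=int(sum(d["free_mirna"]) + sum(d["bound_mirna"])),
            mrna_pool=int(sum(d["unbound"])),
        )
        state = cls(profile, d["seed"])
        state.initial = np.asarray(d["initial"], dtype=np.int64)
        state.bound_mirna_arr = np.asarray(d["bound_mirna"], dtype=np.int64)
        state.iteration = int(d["iteration"])
        for gi, per_gene in enumerate(d["occupied"]):
            for rec in per_gene:
                mol = MoleculeState(
                    gene_id=d["gene_ids"][gi],
                    occupied_positions=list(rec["positions"]),
                    bound_mirnas=list(rec["mirnas"]),
                    first_bind_iteration=rec["first_bind"],
                )
                state.occupied[gi].append(mol)
                if rec["due"] is not None:
                    state.removal_queue.setdefault(rec["due"], []).append(
                        (gi, mol)
                    )
        state.rng.bit_generator.state = d["rng_state"]
        return state


def _due_of(queue: dict, mol: MoleculeState) -> int | None:
    for due, entries in queue.items():
        for _gi, m in entries:
            if m is mol:
                return due
    return None


def init_state(profile: CellProfile, seed: int,
               table: InteractionTable | None = None) -> CellState:
    """Fresh simulator state: all molecules unbound, all miRNAs free."""
    state = CellState(profile, seed)
    if table is not None:
        state._bind_table(table)
    return state


def _eligible_sites(positions: list[int], occupied: list[int],
                    spacing: int) -> list[int]:
    """Indices of sites far enough (>= spacing) from every bound RISC."""
    out = []
    for k, p in enumerate(positions):
        ok = True
        for o in occupied:
            if abs(p - o) < spacing:
                ok = False
                break
        if ok:
            out.append(k)
    return out


def step(state: CellState, table: InteractionTable,
         config: SimConfig) -> CellState:
    """Advance the state by exactly one iteration (mutates and returns it)."""
    state._bind_table(table)
    rng = state.rng
    it = state.iteration + 1  # the iteration being executed (1-based)
    spacing = config.spacing_nt
    if state._spacing != spacing:
        state._E[:] = 0
        for gi in range(len(state.gene_ids)):
            if state.occupied[gi]:
                state._refresh_gene(gi, spacing)
        state._spacing = spacing

    # (1) sample a miRNA type proportionally to free counts
    total_free = int(state.free_mirna_arr.sum())
    if total_free > 0:
        cum = np.cumsum(state.free_mirna_arr)
        mi = int(np.searchsorted(cum, rng.integers(total_free), side="right"))
        targets = state._targets[mi]
        if targets.size:
            # (2) eligible-molecule counts per target gene: unbound count
            # plus the maintained eligible-occupied count E[mi, gene]
            elig = state.unbound[targets] + state._E[mi, targets]
            total_elig = int(elig.sum())
            if total_elig > 0:
                # (3) gene ~ eligible counts; molecule uniform; site uniform
                gcum = np.cumsum(elig)
                ti = int(np.searchsorted(gcum, rng.integers(total_elig),
                                         side="right"))
                gi = int(targets[ti])
                positions, probs = state._pair_sites[(mi, gi)]
                r = int(rng.integers(int(elig[ti])))
                n_unbound = int(state.unbound[gi])
                if r < n_unbound:
                    site_k = int(rng.integers(len(positions)))
                    mol = None
                else:
                    good = [
                        (m, ks) for m in state.occupied[gi]
                        if (ks := _eligible_sites(
                            positions, m.occupied_positions, spacing))
                    ]
                    mol, ks = good[r - n_unbound]
                    site_k = ks[int(rng.integers(len(ks)))]
                # (4) Bernoulli binding
                if rng.random() < probs[site_k]:
                    state.free_mirna_arr[mi] -= 1
                    state.bound_mirna_arr[mi] += 1
                    mirna = state.mirna_ids[mi]
                    if mol is None:
                        mol = MoleculeState(
                            gene_id=state.gene_ids[gi],
                            occupied_positions=[positions[site_k]],
                            bound_mirnas=[mirna],
                            first_bind_iteration=it,
                        )
                        state.unbound[gi] -= 1
                        state.occupied[gi].append(mol)
                        state.removal_queue.setdefault(
                            it + config.removal_delay, []
                        ).append((gi, mol))
                    else:
                        mol.occupied_positions.append(positions[site_k])
                        mol.bound_mirnas.append(mirna)
                    state._refresh_gene(gi, spacing)

    # (5) degrade molecules whose removal delay expires this iteration
    for gi, mol in state.removal_queue.pop(it, ()):  # type: ignore[arg-type]
        state.occupied[gi].remove(mol)
        state._refresh_gene(gi, spacing)
        for mirna in mol.bound_mirnas:
            pm = state._mirna_pos[mirna]
            state.free_mirna_arr[pm] += 1
            state.bound_mirna_arr[pm] -= 1

    # (6) spontaneous decay of unbound molecules
    if config.decay_rate > 0.0:
        losses = rng.binomial(state.unbound, config.decay_rate)
        state.unbound -= losses

    # (7) transcription
    if config.transcription is not None:
        interval, count = config.transcription
        if count > 0 and it % interval == 0:
            add = largest_remainder(
                pd.Series(state.initial, index=state.gene_ids), count
            )
            state.unbound += add.reindex(state.gene_ids).to_numpy(np.int64)

    # (8)
    state.iteration = it
    return state


def retention(state: CellState,
              initial: Mapping[str, int] | None = None) -> dict[str, float]:
    """Per-gene retention: 100 x unbound / initial molecules.

    Molecules that are bound but not yet degraded do not count as retained.
    Genes with zero initial molecules are excluded.
    """
    init = (
        dict(initial)
        if initial is not None
        else {g: int(c) for g, c in zip(state.gene_ids, state.initial)}
    )
    out = {}
    for g, n0 in init.items():
        if n0 <= 0:
            continue
        gi = state._gene_pos.get(g)
        n_unbound = int(state.unbound[gi]) if gi is not None else 0
        out[g] = 100.0 * n_unbound / n0
    return out


def run(
    profile: CellProfile,
    table: InteractionTable,
    config: SimConfig,
    state: CellState | None = None,
    return_state: bool = False,
):
    """Run the simulator and record the per-gene retention trajectory.

    ``state`` restarts from a serialized/previous state instead of iteration
    0; remaining iterations up to ``config.total_iterations`` are executed.
    With ``return_state`` the final :class:`CellState` is returned alongside
    the :class:`RetentionTrajectory`.
    """
    cps = config.resolved_checkpoints()
    if state is None:
        state = init_state(profile, config.seed, table)
    else:
        state._bind_table(table)
    expressed = [g for g, c in zip(state.gene_ids, state.initial) if c > 0]
    records: dict[int, dict[str, float]] = {}
    cpset = set(cps)
    if state.iteration in cpset:
        records[state.iteration] = retention(state)
    while state.iteration < config.total_iterations:
        step(state, table, config)
        if state.iteration in cpset:
            records[state.iteration] = retention(state)
    cols = sorted(records)
    data = pd.DataFrame(
        {c: [records[c].get(g, np.nan) for g in expressed] for c in cols},
        index=pd.Index(expressed, name="gene_id"),
    )
    traj = RetentionTrajectory(data)
    if return_state:
        return traj, state
    return traj
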