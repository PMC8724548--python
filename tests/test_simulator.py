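import numpy as np
import pandas as pd
import pytest

import comicsim as c
from comicsim.simulator import CellState

from conftest import single_site_cell


def enumerate_bound_distribution(n_molecules, n_mirna, p, n_steps):
    """Exact distribution of occupied-molecule count after n_steps.

    Independent enumeration of the per-iteration outcome tree for a one-gene,
    one-miRNA, one-site system: while free miRNAs and unbound molecules
    remain, each step binds one (exchangeable) molecule with probability p.
    """
    dist = {}

    def recurse(bound, free, steps_left, prob):
        if steps_left == 0:
            dist[bound] = dist.get(bound, 0.0) + prob
            return
        unbound = n_molecules - bound
        if free == 0 or unbound == 0:
            recurse(bound, free, steps_left - 1, prob)
            return
        recurse(bound + 1, free - 1, steps_left - 1, prob * p)
        recurse(bound, free, steps_left - 1, prob * (1 - p))

    recurse(0, n_mirna, n_steps, 1.0)
    return dist


class TestInitState:
    def test_initial_counts(self, toy_profile, toy_table):
        state = c.init_state(toy_profile, seed=0, table=toy_table)
        assert state.unbound_counts() == {"gene-1": 30, "gene-2": 20}
        assert state.free_mirna == {"mir-a": 60, "mir-b": 40}
        assert state.iteration == 0
        assert all(v == 100.0 for v in c.retention(state).values())

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            c.init_state(
                c.CellProfile(mirna_counts=pd.Series(dtype=int),
                              mrna_counts=pd.Series(dtype=int),
                              mirna_pool=1, mrna_pool=1),
                seed=0,
            )


class TestStep:
    def test_forced_binding_and_removal_schedule(self):
        profile, table = single_site_cell(prob=1.0)
        cfg = c.SimConfig(total_iterations=10, removal_delay=5, seed=1)
        state = c.init_state(profile, seed=1, table=table)
        c.step(state, table, cfg)
        assert state.unbound_counts()["gene-1"] == 0
        (mol,) = state.molecules
        assert mol.occupied_positions == [100]
        assert mol.first_bind_iteration == 1
        assert list(state.removal_queue) == [1 + 5]
        assert state.free_mirna["mir-x"] == 0
        # molecule survives until the delay expires, then degrades and
        # its miRNA returns to the free pool
        for _ in range(4):
            c.step(state, table, cfg)
            assert state.total_molecules() == 1
        c.step(state, table, cfg)  # iteration 6 processes the removal
        assert state.total_molecules() == 0
        assert state.free_mirna["mir-x"] == 1

    def test_zero_probability_site_only_consumes_iteration(self):
        profile, table = single_site_cell(prob=0.0)
        cfg = c.SimConfig(total_iterations=10, seed=1)
        state = c.init_state(profile, seed=1, table=table)
        for _ in range(5):
            c.step(state, table, cfg)
        assert state.iteration == 5
        assert state.unbound_counts()["gene-1"] == 1
        assert not state.molecules

    def test_spacing_blocks_close_sites(self):
        table = c.make_table([
            ("mir-x", "gene-1", 100, -60.0),
            ("mir-x", "gene-1", 130, -60.0),  # 30 nt apart: conflicts
        ])
        profile = c.CellProfile(
            mirna_counts=pd.Series({"mir-x": 50}),
            mrna_counts=pd.Series({"gene-1": 1}),
            mirna_pool=50, mrna_pool=1,
        )
        cfg = c.SimConfig(total_iterations=50, removal_delay=1000,
                          spacing_nt=50, seed=2)
        state = c.init_state(profile, seed=2, table=table)
        for _ in range(50):
            c.step(state, table, cfg)
        (mol,) = state.molecules
        assert len(mol.occupied_positions) == 1

    def test_spacing_allows_distant_sites(self):
        table = c.make_table([
            ("mir-x", "gene-1", 100, -60.0),
            ("mir-x", "gene-1", 150, -60.0),  # exactly 50 nt: legal
        ])
        profile = c.CellProfile(
            mirna_counts=pd.Series({"mir-x": 50}),
            mrna_counts=pd.Series({"gene-1": 1}),
            mirna_pool=50, mrna_pool=1,
        )
        cfg = c.SimConfig(total_iterations=50, removal_delay=1000,
                          spacing_nt=50, seed=2)
        state = c.init_state(profile, seed=2, table=table)
        for _ in range(50):
            c.step(state, table, cfg)
        (mol,) = state.molecules
        assert sorted(mol.occupied_positions) == [100, 150]

    def test_bound_distribution_matches_enumeration(self):
        """Empirical bound counts after 3 steps vs the exact outcome tree."""
        n_rep = 4000
        p = 0.5
        expected = enumerate_bound_distribution(
            n_molecules=2, n_mirna=2, p=p, n_steps=3
        )
        profile, table = single_site_cell(prob=p, n_molecules=2, n_mirna=2)
        cfg = c.SimConfig(total_iterations=3, removal_delay=100, seed=0)
        counts = {k: 0 for k in expected}
        for rep in range(n_rep):
            state = c.init_state(profile, seed=rep, table=table)
            for _ in range(3):
                c.step(state, table, cfg)
            counts[len(state.molecules)] += 1
        for k, prob in expected.items():
            se = np.sqrt(prob * (1 - prob) / n_rep)
            assert counts[k] / n_rep == pytest.approx(prob, abs=3 * se + 1e-9)


class TestInvariants:
    def test_conservation_monotonicity_spacing(self, small_cell):
        profile, table, _ = small_cell
        cfg = c.SimConfig(total_iterations=2000, removal_delay=200, seed=5)
        state = c.init_state(profile, seed=5, table=table)
        total_mirna0 = state.total_mirna()
        prev_molecules = state.total_molecules()
        for i in range(2000):
            c.step(state, table, cfg)
            if i % 100 == 0:
                assert state.total_mirna() == total_mirna0
                assert state.total_molecules() <= prev_molecules
                prev_molecules = state.total_molecules()
                for mol in state.molecules:
                    ps = sorted(mol.occupied_positions)
                    assert all(b - a >= cfg.spacing_nt
                               for a, b in zip(ps, ps[1:]))
                    assert len(mol.bound_mirnas) == len(ps)

    def test_seed_determinism_bitwise(self, small_cell):
        profile, table, _ = small_cell
        cfg = c.SimConfig(total_iterations=1500, seed=11)
        t1 = c.run(profile, table, cfg)
        t2 = c.run(profile, table, cfg)
        assert np.array_equal(t1.data.to_numpy(), t2.data.to_numpy())
        t3 = c.run(profile, table, c.SimConfig(total_iterations=1500, seed=12))
        assert not np.array_equal(t1.data.to_numpy(), t3.data.to_numpy())

    def test_retention_curves_non_increasing(self, small_cell):
        profile, table, _ = small_cell
        cfg = c.SimConfig(total_iterations=3000, removal_delay=300, seed=8)
        traj = c.run(profile, table, cfg)
        diffs = traj.data.to_numpy()[:, 1:] - traj.data.to_numpy()[:, :-1]
        assert (diffs <= 1e-9).all()


class TestRun:
    def test_untargeted_gene_keeps_full_retention(self):
        profile = c.CellProfile(
            mirna_counts=pd.Series({"mir-x": 100}),
            mrna_counts=pd.Series({"gene-hit": 20, "gene-free": 20}),
            mirna_pool=100, mrna_pool=40,
        )
        table = c.make_table([("mir-x", "gene-hit", 50, -60.0)])
        cfg = c.SimConfig(total_iterations=500, removal_delay=50, seed=3)
        traj = c.run(profile, table, cfg)
        assert traj.final()["gene-free"] == 100.0
        assert traj.final()["gene-hit"] < 100.0

    def test_saturating_toy_reaches_zero_retention(self):
        profile, table = single_site_cell(prob=1.0, n_molecules=5,
                                          n_mirna=100)
        cfg = c.SimConfig(total_iterations=200, removal_delay=1, seed=4)
        traj = c.run(profile, table, cfg)
        assert traj.final()["gene-1"] == 0.0

    def test_decay_matches_geometric_closed_form(self):
        """Empty table + decay rate d: retention ~ 100 (1-d)^n."""
        d, n, n0 = 0.002, 600, 400
        profile = c.CellProfile(
            mirna_counts=pd.Series({"mir-x": 10}),
            mrna_counts=pd.Series({"gene-1": n0}),
            mirna_pool=10, mrna_pool=n0,
        )
        table = c.make_table([])
        finals = []
        for seed in range(30):
            cfg = c.SimConfig(total_iterations=n, decay_rate=d, seed=seed,
                              checkpoints=[0, n])
            finals.append(c.run(profile, table, cfg).final()["gene-1"])
        expected = 100.0 * (1 - d) ** n
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert np.mean(finals) == pytest.approx(expected, abs=3 * se)

    def test_transcription_adds_molecules(self):
        profile = c.CellProfile(
            mirna_counts=pd.Series({"mir-x": 10}),
            mrna_counts=pd.Series({"gene-1": 30, "gene-2": 10}),
            mirna_pool=10, mrna_pool=40,
        )
        table = c.make_table([])
        cfg = c.SimConfig(total_iterations=100, transcription=(10, 4),
                          checkpoints=[0, 100], seed=0)
        state = c.init_state(profile, seed=0, table=table)
        for _ in range(100):
            c.step(state, table, cfg)
        # 10 transcription events x 4 molecules, split 3:1
        assert state.unbound_counts() == {"gene-1": 60, "gene-2": 20}


class TestRetention:
    def test_partial_binding_fraction(self):
        profile, table = single_site_cell(prob=1.0, n_molecules=4, n_mirna=1)
        cfg = c.SimConfig(total_iterations=3, removal_delay=100, seed=0)
        state = c.init_state(profile, seed=0, table=table)
        c.step(state, table, cfg)
        # 1 of 4 bound (not yet removed) -> 75% retained
        assert c.retention(state) == {"gene-1": 75.0}

    def test_matches_independent_recount(self, small_cell):
        profile, table, _ = small_cell
        cfg = c.SimConfig(total_iterations=800, removal_delay=100, seed=6)
        state = c.init_state(profile, seed=6, table=table)
        for _ in range(800):
            c.step(state, table, cfg)
        rec = c.retention(state)
        for gi, g in enumerate(state.gene_ids):
            n0 = int(state.initial[gi])
            if n0 == 0:
                assert g not in rec
                continue
            assert rec[g] == pytest.approx(100.0 * state.unbound[gi] / n0)

    def test_zero_initial_excluded(self, toy_profile, toy_table):
        state = c.init_state(toy_profile, seed=0, table=toy_table)
        out = c.retention(state, {"gene-1": 30, "ghost": 0})
        assert "ghost" not in out and out["gene-1"] == 100.0


class TestSerialization:
    def test_restart_reproduces_uninterrupted_run(self, small_cell):
        profile, table, _ = small_cell
        cfg = c.SimConfig(total_iterations=1000, removal_delay=100, seed=9)
        full = c.run(profile, table, cfg)

        half_cfg = c.SimConfig(total_iterations=500, removal_delay=100,
                               seed=9)
        _traj, state = c.run(profile, table, half_cfg, return_state=True)
        restored = CellState.from_dict(state.to_dict())
        resumed = c.run(profile, table, cfg, state=restored)
        pd.testing.assert_series_equal(full.final(), resumed.final())
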