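"""Resolution sweeps, the Louvain adapter, optima selection, convergence."""

import math

import networkx as nx
import numpy as np
import pytest

from versatility import (
    DetectorAdapter,
    Partition,
    SweepResult,
    accumulate,
    build_ncluster_graph,
    NClusterSpec,
    convergence_diagnostic,
    derive_seed,
    find_optima,
    louvain_adapter,
    louvain_gamma,
    mean_versatility,
    run_ensemble,
    sweep_resolution,
    versatility,
)


def brute_force_best_partition(G: nx.Graph, gamma: float):
    """Exhaustive gamma-modularity maximisation over all set partitions.

    Independent oracle for small graphs: enumerates every partition via
    restricted-growth strings and scores Q_gamma directly from the
    modularity matrix B = A - gamma * k k^T / (2m).
    """
    nodes = list(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - gamma * np.outer(k, k) / two_m
    n = len(nodes)
    best = (-np.inf, None)

    def recurse(i, blocks, q):
        nonlocal best
        if i == n:
            if q > best[0]:
                best = (q, [list(b) for b in blocks])
            return
        for b in blocks:
            dq = 2 * sum(B[i, j] for j in b) + B[i, i]
            b.append(i)
            recurse(i + 1, blocks, q + dq)
            b.pop()
        blocks.append([i])
        recurse(i + 1, blocks, q + B[i, i])
        blocks.pop()

    recurse(0, [], 0.0)
    q, blocks = best
    return q / two_m, [{nodes[i] for i in b} for b in blocks]


class TestLouvainGamma:
    def test_gamma_zero_merges_each_component(self, karate):
        part = louvain_gamma(karate, 0.0, seed=1)
        assert part.n_communities == 1

    def test_huge_gamma_gives_singletons(self, karate):
        part = louvain_gamma(karate, 1000.0, seed=1)
        assert part.n_communities == len(part)

    def test_two_disconnected_cliques_match_brute_force(self):
        """Louvain at gamma=1 recovers the partition an exhaustive
        modularity search finds: exactly the two 5-cliques."""
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        _, blocks = brute_force_best_partition(G, 1.0)
        assert sorted(sorted(b) for b in blocks) == [
            [0, 1, 2, 3, 4],
            [5, 6, 7, 8, 9],
        ]
        part = louvain_gamma(G, 1.0, seed=0)
        groups = {}
        for node, lab in zip(part.node_ids, part.labels):
            groups.setdefault(lab, set()).add(node)
        assert sorted(sorted(g) for g in groups.values()) == [
            [0, 1, 2, 3, 4],
            [5, 6, 7, 8, 9],
        ]

    def test_same_seed_same_partition(self, karate):
        a = louvain_gamma(karate, 1.0, seed=7)
        b = louvain_gamma(karate, 1.0, seed=7)
        assert a == b

    def test_negative_weight_rejected(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=-1.0)
        with pytest.raises(ValueError, match="negative weight"):
            louvain_gamma(G, 1.0, seed=0)

    def test_negative_gamma_and_empty_graph_rejected(self, karate):
        with pytest.raises(ValueError):
            louvain_gamma(karate, -0.1, seed=0)
        with pytest.raises(ValueError):
            louvain_gamma(nx.Graph(), 1.0, seed=0)

    def test_directed_graph_symmetrised(self):
        D = nx.DiGraph()
        D.add_weighted_edges_from([(0, 1, 2.0), (1, 0, 2.0), (1, 2, 1.0)])
        part = louvain_gamma(D, 1.0, seed=0)
        assert len(part) == 3


class TestRunEnsemble:
    def test_single_run(self, karate):
        ens = run_ensemble(karate, louvain_adapter(1.0), 1, base_seed=0)
        assert ens.run_count == 1

    def test_reproducible_for_same_base_seed(self, karate):
        a = run_ensemble(karate, louvain_adapter(1.0), 10, base_seed=3)
        b = run_ensemble(karate, louvain_adapter(1.0), 10, base_seed=3)
        assert a.partitions == b.partitions

    def test_distinct_seeds_produce_variation(self, karate):
        ens = run_ensemble(karate, louvain_adapter(1.0), 30, base_seed=0)
        assert len({p.labels for p in ens.partitions}) > 1

    def test_provenance_recorded(self, karate):
        ens = run_ensemble(karate, louvain_adapter(0.5), 2, base_seed=1)
        assert "louvain" in ens.provenance and "base_seed=1" in ens.provenance

    def test_detector_failure_carries_run_index(self, karate):
        def boom(graph, seed):
            raise RuntimeError("nope")

        bad = DetectorAdapter(name="bad", fn=boom)
        with pytest.raises(RuntimeError, match="run 0"):
            run_ensemble(karate, bad, 3, base_seed=0)

    def test_derived_seeds_below_2_31(self):
        seeds = [derive_seed(12345, g, k) for g in range(3) for k in range(5)]
        assert all(0 <= s < 2**31 for s in seeds)
        assert len(set(seeds)) == len(seeds)


class TestSweepResolution:
    def test_trivial_extremes_flagged_and_zero(self, karate):
        res = sweep_resolution(karate, [0.001, 1000.0], runs_per_gamma=20, base_seed=0)
        assert res.trivial_flags.all()
        assert np.all(res.mean_versatility == 0.0)

    def test_deterministic_optimum_gives_zero(self):
        """Two disconnected cliques at gamma=1: every run finds the
        cliques, so mean versatility is exactly zero."""
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        res = sweep_resolution(G, [1.0], runs_per_gamma=50, base_seed=0)
        assert res.mean_versatility[0] == 0.0
        assert res.sem[0] == 0.0
        assert not res.trivial_flags[0]
        assert res.mean_community_count[0] == 2.0

    def test_end_to_end_reproducibility(self, karate):
        kw = dict(gammas=[0.4, 0.8], runs_per_gamma=25, base_seed=9)
        a = sweep_resolution(karate, **kw)
        b = sweep_resolution(karate, **kw)
        assert np.array_equal(a.mean_versatility, b.mean_versatility)
        assert np.array_equal(a.sem, b.sem)
        assert np.array_equal(a.mean_community_count, b.mean_community_count)

    def test_community_count_nondecreasing_in_gamma(self):
        G = build_ncluster_graph(NClusterSpec(4, 6), inter_weight=0.3)
        res = sweep_resolution(G, [0.3, 1.0, 3.0, 8.0], runs_per_gamma=40, base_seed=2)
        counts = res.mean_community_count
        assert np.all(np.diff(counts) >= -1e-9)

    def test_invalid_grids_rejected(self, karate):
        with pytest.raises(ValueError):
            sweep_resolution(karate, [], runs_per_gamma=10)
        with pytest.raises(ValueError):
            sweep_resolution(karate, [1.0, 0.5], runs_per_gamma=10)
        with pytest.raises(ValueError):
            sweep_resolution(karate, [1.0], runs_per_gamma=1)

    def test_serialisation_roundtrips(self, tmp_path, karate):
        res = sweep_resolution(karate, [0.5, 1.0], runs_per_gamma=10, base_seed=0)
        res.to_tsv(tmp_path / "s.tsv")
        res.to_json(tmp_path / "s.json")
        header = (tmp_path / "s.tsv").read_text().splitlines()[0]
        assert header.split("\t") == [
            "gamma", "mean_versatility", "sem", "mean_n_communities", "trivial",
        ]
        res.plot(tmp_path / "s.png")
        assert (tmp_path / "s.png").stat().st_size > 0


def _mk_result(gammas, values, sem=None, trivial=None, counts=None):
    n = len(gammas)
    return SweepResult(
        gammas=np.asarray(gammas, float),
        mean_versatility=np.asarray(values, float),
        sem=np.zeros(n) if sem is None else np.asarray(sem, float),
        mean_community_count=np.full(n, 3.0) if counts is None else np.asarray(counts),
        trivial_flags=np.zeros(n, bool) if trivial is None else np.asarray(trivial),
        runs_per_gamma=100,
    )


class TestFindOptima:
    def test_v_shape_finds_middle(self):
        res = _mk_result([0.1, 0.2, 0.3, 0.4, 0.5], [3, 2, 1, 2, 3])
        optima = find_optima(res)
        assert (0.3, "minimum") in optima
        assert optima[0] == (0.3, "minimum")

    def test_monotone_decreasing_last_point(self):
        res = _mk_result([0.1, 0.2, 0.3], [3, 2, 1])
        assert [o for o in find_optima(res) if o[1] == "minimum"] == [(0.3, "minimum")]

    def test_tie_broken_toward_lower_gamma(self):
        res = _mk_result([0.1, 0.2, 0.3, 0.4], [2, 1, 1, 2])
        minima = [g for g, kind in find_optima(res) if kind == "minimum"]
        assert minima == [0.2]

    def test_trivial_points_excluded(self):
        res = _mk_result(
            [0.1, 0.2, 0.3], [0.0, 1.0, 2.0], trivial=[True, False, False]
        )
        minima = [g for g, kind in find_optima(res) if kind == "minimum"]
        assert minima == [0.2]

    def test_all_trivial_warns_and_empty(self):
        res = _mk_result([0.1, 0.2], [0.0, 0.0], trivial=[True, True])
        with pytest.warns(UserWarning):
            assert find_optima(res) == []

    def test_plateau_detection(self):
        res = _mk_result(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            [3.0, 1.02, 1.00, 1.01, 3.0, 4.0],
            sem=[0.05] * 6,
        )
        plateaus = [g for g, kind in find_optima(res) if kind == "plateau"]
        assert plateaus == [0.3]

    def test_no_plateau_when_too_short(self):
        res = _mk_result([0.1, 0.2, 0.3], [1.0, 1.0, 5.0], sem=[0.05] * 3)
        assert [g for g, k in find_optima(res) if k == "plateau"] == []


class TestConvergenceDiagnostic:
    def test_deterministic_detector_sd_zero(self, karate):
        fixed = louvain_gamma(karate, 1.0, seed=0)
        det = DetectorAdapter(name="fixed", fn=lambda g, s: fixed)
        table = convergence_diagnostic(karate, det, max_runs=40, n_replicates=3)
        assert np.all(table["sd_mean_versatility"].to_numpy() == 0.0)
        assert table["runs"].iloc[-1] == 40

    def test_sd_shrinks_roughly_root_n(self, karate):
        """Monte-Carlo scaling: sd at 20 runs vs 320 runs should shrink
        by about 1/4 (within a factor of 2)."""
        det = louvain_adapter(0.7)
        rows = []
        for li, runs in enumerate((20, 320)):
            vals = [
                mean_versatility(
                    versatility(accumulate(run_ensemble(
                        karate, det, runs, derive_seed(55, li, rep)
                    )))
                )
                for rep in range(16)
            ]
            rows.append(np.std(vals, ddof=1))
        ratio = rows[0] / rows[1]
        assert 2.0 < ratio < 8.0  # ideal 4, within a factor of 2

    def test_parameter_validation(self, karate):
        det = louvain_adapter(1.0)
        with pytest.raises(ValueError):
            convergence_diagnostic(karate, det, max_runs=5)
        with pytest.raises(ValueError):
            convergence_diagnostic(karate, det, max_runs=50, n_replicates=2)
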