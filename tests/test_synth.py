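"""Generator tests: graph validity, determinism, local-model semantics,
censoring, and the probe/spot emission layer."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from dhcnet import (
    GroundTruthNetwork,
    SimulationConfig,
    TrueEdge,
    aggregate_spots,
    emit_probe_level,
    generate_dag,
    simulate_samples,
)


class TestGenerateDag:
    def test_single_node_has_no_edges(self):
        net = generate_dag(SimulationConfig(n_nodes=1, seed=0))
        assert net.edges == []

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_same_seed_is_bit_identical(self, seed):
        cfg = SimulationConfig(n_nodes=12, edge_density=0.3, seed=seed)
        a, b = generate_dag(cfg), generate_dag(cfg)
        assert a.nodes == b.nodes
        assert a.edges == b.edges

    def test_generated_graphs_are_acyclic(self):
        for seed in range(25):
            cfg = SimulationConfig(n_nodes=15, edge_density=0.4, seed=seed)
            assert nx.is_directed_acyclic_graph(generate_dag(cfg).graph())

    def test_expected_edge_count(self):
        # density 0.1 over C(20,2)=190 pairs -> mean 19 over replicates
        counts = [
            len(generate_dag(SimulationConfig(n_nodes=20, edge_density=0.1,
                                              seed=s)).edges)
            for s in range(200)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 19) < 3 * se + 1e-9

    def test_conditional_fraction_declared(self):
        cfg = SimulationConfig(n_nodes=15, edge_density=0.4,
                               fraction_conditional=1.0, seed=2)
        net = generate_dag(cfg)
        assert net.edges, "fixture should have edges"
        assert all(e.edge_class in ("switched", "linear") for e in net.edges)
        assert all(e.modulator in net.modulators for e in net.edges)

    @pytest.mark.parametrize("bad", [
        dict(n_nodes=0), dict(edge_density=1.5), dict(censor_fraction=-0.1),
        dict(n_samples=0), dict(spots_per_probe=3),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, **bad).validate()

    def test_cyclic_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            GroundTruthNetwork(
                nodes=["a", "b"],
                edges=[TrueEdge("a", "b", 1.0), TrueEdge("b", "a", 1.0)],
                noise_scale={"a": 1.0, "b": 1.0},
            )


def _two_node_net(edge_class="plain", effect=2.0, noise=0.0, **kw):
    mods = {"m0": 2} if edge_class != "plain" else {}
    e = TrueEdge("v000", "v001", effect, edge_class,
                 "m0" if mods else None, 1 if mods else None, **kw)
    return GroundTruthNetwork(["v000", "v001"], [e],
                              {"v000": noise, "v001": noise}, mods)


class TestSimulateSamples:
    def test_noiseless_child_is_exact_linear_function(self):
        net = _two_node_net(effect=2.0, noise=0.0)
        cfg = SimulationConfig(n_nodes=2, n_samples=50, seed=5,
                               modulator_levels=())
        vt, _ = simulate_samples(net, cfg)
        np.testing.assert_allclose(
            vt.continuous["v001"], 2.0 * vt.continuous["v000"], rtol=0, atol=1e-12
        )

    def test_switched_edge_inactive_samples_uncorrelated(self):
        net = _two_node_net("switched", effect=2.0, noise=0.3)
        cfg = SimulationConfig(n_nodes=2, n_samples=500, seed=11,
                               modulator_levels=(2,))
        vt, mods = simulate_samples(net, cfg)
        off = mods["m0"] == 0
        x = vt.continuous.loc[off.values, "v000"]
        y = vt.continuous.loc[off.values, "v001"]
        r_off = np.corrcoef(x, y)[0, 1]
        assert abs(r_off) < 3 / np.sqrt(off.sum())  # null bound
        on = ~off
        r_on = np.corrcoef(vt.continuous.loc[on.values, "v000"],
                           vt.continuous.loc[on.values, "v001"])[0, 1]
        assert r_on > 0.8

    def test_modulators_balanced(self):
        cfg = SimulationConfig(n_nodes=3, n_samples=48, seed=1,
                               modulator_levels=(2, 4))
        net = generate_dag(cfg)
        _, mods = simulate_samples(net, cfg)
        assert sorted(mods["m0"].value_counts()) == [24, 24]
        assert sorted(mods["m1"].value_counts()) == [12, 12, 12, 12]

    def test_no_censoring_when_fraction_zero(self, small_config):
        vt, _ = simulate_samples(generate_dag(small_config), small_config)
        assert vt.switches == {}

    def test_censoring_flags_lowest_values(self):
        cfg = SimulationConfig(n_nodes=10, n_samples=40, edge_density=0.1,
                               censor_fraction=0.25, metabolite_fraction=0.3,
                               seed=4)
        vt, _ = simulate_samples(generate_dag(cfg), cfg)
        metab = [v for v, r in vt.roles.items() if r == "metabolite"]
        assert len(metab) == 3 and vt.switches
        for v in vt.switches:
            sw = vt.discrete[vt.switches[v]]
            censored = vt.continuous.loc[sw == 0, v]
            observed = vt.continuous.loc[sw == 1, v]
            assert censored.nunique() == 1  # pinned to the detection limit
            assert censored.max() <= observed.min()

    def test_determinism(self, small_config):
        net = generate_dag(small_config)
        a, _ = simulate_samples(net, small_config)
        b, _ = simulate_samples(net, small_config)
        pd.testing.assert_frame_equal(a.continuous, b.continuous)
        pd.testing.assert_frame_equal(a.discrete, b.discrete)


class TestEmitProbeLevel:
    def test_zero_noise_round_trips_latent_values(self):
        net = _two_node_net(effect=1.5, noise=0.0)
        cfg = SimulationConfig(
            n_nodes=2, n_samples=20, seed=9, modulator_levels=(),
            probes_per_node=1, n_lineages=1, signal_scale=1.0,
            background_mean=0.0, background_sd=0.0, probe_noise_sd=0.0,
        )
        vt, _ = simulate_samples(net, cfg)
        spots, ann = emit_probe_level(vt, cfg)
        m = aggregate_spots(spots, ann.table)
        recovered = np.log(m.values.loc["v000_p0"]).sort_index()
        truth = vt.continuous["v000"].sort_index()
        np.testing.assert_allclose(recovered.values, truth.values, atol=1e-9)

    def test_each_probe_replicated_at_least_four_spots(self, small_config):
        vt, _ = simulate_samples(generate_dag(small_config), small_config)
        spots, _ = emit_probe_level(vt, small_config)
        per = spots.groupby(["probe", "sample"]).size()
        assert (per >= 4).all()

    def test_identity_annotation_straddles_lineage_cutoff(self):
        cfg = SimulationConfig(n_nodes=5, n_samples=20, seed=3,
                               probes_per_node=4, n_lineages=2)
        vt, _ = simulate_samples(generate_dag(cfg), cfg)
        _, ann = emit_probe_level(vt, cfg)
        for probe, row in ann.table.iterrows():
            own = row[f"identity_{row['lineage']}"]
            others = [row[c] for c in ann.identity_columns()
                      if c != f"identity_{row['lineage']}"]
            assert own >= 95.0
            assert all(o <= 80.0 for o in others)

    def test_within_lineage_probes_correlate_more_than_between(self):
        cfg = SimulationConfig(
            n_nodes=30, n_samples=100, edge_density=0.05, seed=21,
            probes_per_node=4, n_lineages=2,
            background_mean=0.05, background_sd=0.01, probe_noise_sd=0.05,
        )
        vt, _ = simulate_samples(generate_dag(cfg), cfg)
        spots, ann = emit_probe_level(vt, cfg)
        m = aggregate_spots(spots, ann.table)
        logged = np.log(m.values)
        hits = 0
        bins = list(ann.table.groupby("bin"))
        for _, grp in bins:
            within, between = [], []
            probes = list(grp.index)
            for i, p in enumerate(probes):
                for q in probes[i + 1:]:
                    r = np.corrcoef(logged.loc[p], logged.loc[q])[0, 1]
                    if grp.loc[p, "lineage"] == grp.loc[q, "lineage"]:
                        within.append(r)
                    else:
                        between.append(r)
            if np.mean(within) > np.mean(between):
                hits += 1
        assert hits / len(bins) >= 0.95


def test_ground_truth_write_round_trip(tmp_path, small_config):
    net = generate_dag(small_config)
    path = tmp_path / "truth.graphml"
    net.write(path)
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(net.nodes)
    assert {(u, v) for u, v in back.edges} == net.edge_pairs()
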