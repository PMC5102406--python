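"""Preprocessing tests: geometric spot averaging, the 2-SD background
filter, correlated ortholog-probe collapsing, and censoring + eighth-root
transform — each checked against direct brute-force implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dhcnet import (
    SimulationConfig,
    aggregate_spots,
    censor_and_transform,
    collapse_orthologs,
    filter_background,
    generate_dag,
    emit_probe_level,
    simulate_samples,
)
from dhcnet.preprocess import DegenerateDataError, ProbeMatrix


def spot_frame(rows):
    return pd.DataFrame(rows, columns=["probe", "sample", "intensity",
                                       "bg_mean", "bg_sd"])


def matrix_from_values(values: pd.DataFrame, bg_mean=0.0, bg_sd=0.0,
                       annotation=None) -> ProbeMatrix:
    shape = pd.DataFrame(np.full(values.shape, bg_mean),
                         index=values.index, columns=values.columns)
    sd = pd.DataFrame(np.full(values.shape, bg_sd),
                      index=values.index, columns=values.columns)
    return ProbeMatrix(values, shape, sd, annotation)


class TestAggregateSpots:
    @pytest.mark.parametrize("spots,expected", [
        ([4.0], 4.0),
        ([4.0, 16.0], 8.0),
        ([1, 1, 1, 1, 1, 1, 1, 8], 8 ** 0.125),
    ])
    def test_geometric_mean(self, spots, expected):
        frame = spot_frame([("p1", "s1", v, 0.0, 0.0) for v in spots])
        m = aggregate_spots(frame)
        assert m.values.loc["p1", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_intensity_names_the_spot(self):
        frame = spot_frame([("p1", "s1", 2.0, 0, 0), ("p2", "s2", 0.0, 0, 0)])
        with pytest.raises(ValueError, match="p2"):
            aggregate_spots(frame)

    def test_background_statistics_are_worst_case(self):
        frame = spot_frame([
            ("p1", "s1", 5.0, 1.0, 0.5),
            ("p1", "s1", 5.0, 2.0, 0.1),
        ])
        m = aggregate_spots(frame)
        assert m.bg_mean.loc["p1", "s1"] == 2.0
        assert m.bg_sd.loc["p1", "s1"] == 0.5

    def test_order_invariance(self, rng):
        rows = [(f"p{i % 5}", f"s{j % 4}", float(rng.uniform(1, 10)), 1.0, 0.2)
                for i in range(20) for j in range(8)]
        frame = spot_frame(rows)
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, b = aggregate_spots(frame), aggregate_spots(shuffled)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestFilterBackground:
    def test_single_bright_sample_retains_probe(self):
        values = pd.DataFrame({"s1": [1.0 + 2.5 * 0.4], "s2": [0.5]}, index=["p1"])
        m = matrix_from_values(values, bg_mean=1.0, bg_sd=0.4)
        assert filter_background(m, k=2.0).probes == ["p1"]

    def test_all_dim_samples_removes_probe(self):
        values = pd.DataFrame({"s1": [1.7], "s2": [1.8]}, index=["p1"])
        m = matrix_from_values(values, bg_mean=1.0, bg_sd=0.4)  # threshold 1.8
        assert filter_background(m, k=2.0).probes == []

    def test_negative_k_rejected(self):
        values = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(ValueError):
            filter_background(matrix_from_values(values), k=-1)

    def test_planted_dark_probes_equal_brute_force(self):
        cfg = SimulationConfig(n_nodes=20, n_samples=30, edge_density=0.1,
                               seed=13, dark_probe_fraction=0.3,
                               background_mean=20.0, background_sd=4.0)
        vt, _ = simulate_samples(generate_dag(cfg), cfg)
        spots, ann = emit_probe_level(vt, cfg)
        m = aggregate_spots(spots, ann.table)
        kept = set(filter_background(m, k=2.0).probes)
        # independent brute force over the rule
        brute = {
            p for p in m.probes
            if any(m.values.loc[p, s] > m.bg_mean.loc[p, s] + 2 * m.bg_sd.loc[p, s]
                   for s in m.samples)
        }
        assert kept == brute
        # background-only probes are removed unless a rare background
        # fluctuation genuinely exceeds the rule in some sample
        dark = set(ann.table.index[ann.table["dark"]])
        assert len(dark & kept) <= max(1, 0.2 * len(dark))
        bright = set(m.probes) - dark
        assert bright <= kept


def correlated_bin_matrix(rng, n_samples=30):
    """Three probes in one bin: two tightly correlated, one distinct."""
    base = rng.normal(0, 1, n_samples)
    other = rng.normal(0, 1, n_samples)
    values = pd.DataFrame(
        {
            "pA": np.exp(base),                 # lower intensity twin
            "pB": np.exp(base + 0.5),           # brighter twin
            "pC": np.exp(other),
        },
        index=[f"s{i}" for i in range(n_samples)],
    ).T
    ann = pd.DataFrame({"bin": ["hupL"] * 3}, index=["pA", "pB", "pC"])
    return matrix_from_values(values, annotation=ann)


class TestCollapseOrthologs:
    def test_two_correlated_one_distinct_keeps_two(self, rng):
        m = correlated_bin_matrix(rng)
        collapsed, report = collapse_orthologs(m, r_min=0.9)
        assert sorted(collapsed.probes) == ["pB", "pC"]  # brighter twin wins
        assert report.loc["pA", "representative"] == "pB"
        assert report.loc["pC", "representative"] == "pC"

    def test_exact_duplicate_collapses(self, rng):
        vals = np.exp(rng.normal(size=(1, 20)))
        values = pd.DataFrame(np.vstack([vals, vals]), index=["pA", "pB"],
                              columns=[f"s{i}" for i in range(20)])
        ann = pd.DataFrame({"bin": ["g1", "g1"]}, index=values.index)
        collapsed, _ = collapse_orthologs(matrix_from_values(values, annotation=ann))
        assert len(collapsed.probes) == 1

    def test_two_lineage_clusters_give_two_representatives(self, rng):
        # six probes targeting one ortholog, three per lineage signal
        sig = {"L0": rng.normal(0, 1, 40), "L1": rng.normal(0, 1, 40)}
        cols = {}
        for g, lin in enumerate(["L0"] * 3 + ["L1"] * 3):
            cols[f"p{g}"] = np.exp(sig[lin] + rng.normal(0, 0.05, 40))
        values = pd.DataFrame(cols, index=[f"s{i}" for i in range(40)]).T
        ann = pd.DataFrame({"bin": ["hupL"] * 6}, index=values.index)
        collapsed, report = collapse_orthologs(matrix_from_values(values, annotation=ann))
        assert len(collapsed.probes) == 2
        assert report["representative"].nunique() == 2

    def test_idempotent_and_conserving(self, rng):
        cfg = SimulationConfig(n_nodes=15, n_samples=40, edge_density=0.1,
                               seed=8, probes_per_node=3, n_lineages=1,
                               background_mean=0.02, background_sd=0.005)
        vt, _ = simulate_samples(generate_dag(cfg), cfg)
        spots, ann = emit_probe_level(vt, cfg)
        m = aggregate_spots(spots, ann.table)
        once, report = collapse_orthologs(m)
        assert sorted(report.index) == sorted(m.probes)  # every probe mapped once
        twice, report2 = collapse_orthologs(once)
        assert once.probes == twice.probes
        assert (report2["representative"] == report2.index).all()

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(np.ones((2, 2)), index=["pA", "pB"],
                              columns=["s1", "s2"])
        ann = pd.DataFrame({"bin": ["g", "g"]}, index=values.index)
        with pytest.raises(DegenerateDataError):
            collapse_orthologs(matrix_from_values(values, annotation=ann))


class TestCensorAndTransform:
    def test_zero_without_limit_uses_default_substitute(self):
        cont = pd.DataFrame({"met": [0.0, 256.0]}, index=["s1", "s2"])
        vt = censor_and_transform(cont, censorable=["met"])
        assert vt.continuous.loc["s1", "met"] == pytest.approx(1e-4 ** 0.125)
        assert vt.continuous.loc["s1", "met"] == pytest.approx(0.31622776, rel=1e-6)
        assert vt.discrete.loc["s1", "met__switch"] == 0
        assert vt.continuous.loc["s2", "met"] == pytest.approx(2.0)
        assert vt.discrete.loc["s2", "met__switch"] == 1

    def test_value_at_detection_limit_is_censored(self):
        cont = pd.DataFrame({"met": [0.5, 0.51]}, index=["s1", "s2"])
        vt = censor_and_transform(cont, detection_limits={"met": 0.5})
        assert vt.discrete.loc["s1", "met__switch"] == 0
        assert vt.discrete.loc["s2", "met__switch"] == 1
        assert vt.continuous.loc["s1", "met"] == pytest.approx(0.5 ** 0.125)

    def test_negative_values_rejected(self):
        cont = pd.DataFrame({"x": [-1.0]})
        with pytest.raises(ValueError):
            censor_and_transform(cont)

    def test_discrete_passthrough_untouched(self):
        cont = pd.DataFrame({"x": [1.0, 16.0]}, index=["s1", "s2"])
        disc = pd.DataFrame({"acceptor": [2, 0]}, index=["s1", "s2"])
        vt = censor_and_transform(cont, discrete=disc)
        assert list(vt.discrete["acceptor"]) == [2, 0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=3,
                    max_size=12, unique=True))
    def test_eighth_root_preserves_ranking(self, values):
        cont = pd.DataFrame({"x": values})
        vt = censor_and_transform(cont)
        assert list(cont["x"].rank()) == list(vt.continuous["x"].rank())


def test_pipeline_count_law():
    """Retained probes after filter+collapse match an independent
    implementation of both rules on the same fixture."""
    cfg = SimulationConfig(n_nodes=12, n_samples=30, edge_density=0.1,
                           seed=31, probes_per_node=3, n_lineages=1,
                           dark_probe_fraction=0.25,
                           background_mean=20.0, background_sd=4.0)
    vt, _ = simulate_samples(generate_dag(cfg), cfg)
    spots, ann = emit_probe_level(vt, cfg)
    m = aggregate_spots(spots, ann.table)
    pipeline = collapse_orthologs(filter_background(m, k=2.0), r_min=0.9)[0]

    # brute force: the rules restated from scratch
    bright = [
        p for p in m.probes
        if ((m.values.loc[p] > m.bg_mean.loc[p] + 2 * m.bg_sd.loc[p]).any())
    ]
    kept = []
    for bin_id in sorted(ann.table.loc[bright, "bin"].unique()):
        probes = sorted(p for p in bright if ann.table.loc[p, "bin"] == bin_id)
        # single-linkage components under r > 0.9 on log values
        comp = {p: {p} for p in probes}
        for i, a in enumerate(probes):
            for b in probes[i + 1:]:
                r = np.corrcoef(np.log(m.values.loc[a]), np.log(m.values.loc[b]))[0, 1]
                if r > 0.9 and comp[a] is not comp[b]:
                    merged = comp[a] | comp[b]
                    for p in merged:
                        comp[p] = merged
        seen = set()
        for p in probes:
            key = frozenset(comp[p])
            if key in seen:
                continue
            seen.add(key)
            kept.append(min(key, key=lambda q: (-m.values.loc[q].mean(), q)))
    assert sorted(pipeline.probes) == sorted(kept)
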