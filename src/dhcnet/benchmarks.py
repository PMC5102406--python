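"""Self-contained validation benchmarks with known ground truth.

Each benchmark builds its own synthetic inputs, runs the relevant pipeline
stage, and measures how well the result matches the planted truth or an
independent oracle:

* :func:`oracle_benchmark` — sampled edge frequencies vs exhaustive
  enumeration posteriors on small instances;
* :func:`structure_recovery_benchmark` — precision/recall of the f >= 0.6
  consensus against a planted 20-node DAG at study-scale sample size;
* :func:`conditional_recovery_benchmark` — detection of a planted
  switched-conditional relationship as conditional rather than plain;
* :func:`cutoff_benchmark` — slope-minimum cutoff detection on a frequency
  mixture whose density minimum is known analytically;
* :func:`printed_count_network` — a network with prescribed node and edge
  counts, for bookkeeping checks on count-derived summaries.

Problem sizes are chosen so the whole battery runs on a desk machine in
minutes; the methods notes discuss what these scales do and do not probe.
"""

from __future__ import annotations

from math import lgamma

import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork, detect_cutoff, extract_consensus, frequency_curves
from .ensemble import EDGE_COLUMNS, build_ensemble, exact_edge_posterior
from .fragments import enumerate_fragments
from .synth import (
    GroundTruthNetwork,
    SimulationConfig,
    TrueEdge,
    generate_dag,
    simulate_samples,
)

_VARIANT_KEYS = ["node1", "node2", "modulator", "mod_class", "active_level"]


def oracle_benchmark(
    n_datasets: int = 20, M: int = 1000, seed: int = 0, n_samples: int = 30
) -> pd.DataFrame:
    """Compare ensemble frequencies with exact posteriors on 4-variable data.

    Each dataset comes from a fresh random 4-node DAG (edge density 0.3, so
    empty, single-edge, chain and collider structures all occur); the
    fragment library is exhaustive, so the enumeration oracle and the
    sampler target exactly the same posterior.  Returns one row per dataset
    with the worst absolute deviation across all relationships.
    """
    rows = []
    for i in range(n_datasets):
        cfg = SimulationConfig(
            n_nodes=4, n_samples=n_samples, edge_density=0.3,
            modulator_levels=(), seed=seed * 10_000 + i,
        )
        table, _ = simulate_samples(generate_dag(cfg), cfg)
        lib = enumerate_fragments(table, max_parents=3, top_fragments=None)
        post, n_dags = exact_edge_posterior(lib)
        summ = build_ensemble(lib, M=M, seed=seed * 10_000 + i + 1)
        merged = post.merge(summ.edges, on=_VARIANT_KEYS, how="outer")
        merged["posterior"] = merged["posterior"].fillna(0.0)
        merged["f"] = merged["f"].fillna(0.0)
        rows.append({
            "dataset": i,
            "n_dags": n_dags,
            "max_abs_deviation": float((merged["posterior"] - merged["f"]).abs().max()),
        })
    return pd.DataFrame(rows)


def structure_recovery_benchmark(
    n_seeds: int = 10,
    seed: int = 0,
    n_nodes: int = 20,
    n_samples: int = 48,
    cutoff: float = 0.6,
    M: int = 1000,
) -> pd.DataFrame:
    """Precision/recall of the consensus edge set against a planted DAG.

    Edges are compared as unordered node pairs: a linear-Gaussian
    likelihood cannot orient many edges, and the consensus network reports
    signed, not directed, relationships.
    """
    rows = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_nodes=n_nodes, n_samples=n_samples, edge_density=0.1,
            modulator_levels=(), seed=seed * 10_000 + i,
        )
        net = generate_dag(cfg)
        table, _ = simulate_samples(net, cfg)
        lib = enumerate_fragments(table, max_parents=3)
        summ = build_ensemble(lib, M=M, seed=seed * 10_000 + i + 1)
        cons = extract_consensus(summ, cutoff)
        pred = {tuple(sorted(p)) for p in zip(cons.edges["node1"], cons.edges["node2"])}
        true = {tuple(sorted(p)) for p in net.edge_pairs()}
        tp = len(pred & true)
        rows.append({
            "seed": i,
            "n_true": len(true), "n_predicted": len(pred), "n_correct": tp,
            "precision": tp / len(pred) if pred else 1.0,
            "recall": tp / len(true) if true else 1.0,
        })
    return pd.DataFrame(rows)


def conditional_recovery_benchmark(
    n_seeds: int = 10,
    seed: int = 0,
    n_samples: int = 48,
    effect: float = 1.0,
    cutoff: float = 0.6,
    M: int = 1000,
) -> pd.DataFrame:
    """Detection of a planted switched-conditional relationship.

    The true model links two variables only in samples where a balanced
    binary switch is on.  A run succeeds when the ensemble reports the
    relationship as conditional on the switch at f >= cutoff — mass on the
    switched-conditional variant plus its linearly-conditional form, which
    for a binary modulator nests the same on/off model — while the plain
    (unconditional) variant of the pair stays below the cutoff.
    """
    net = GroundTruthNetwork(
        nodes=["v000", "v001"],
        edges=[TrueEdge("v000", "v001", effect, "switched", "m0", active_level=1)],
        noise_scale={"v000": 0.5, "v001": 0.5},
        modulators={"m0": 2},
    )
    rows = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_nodes=2, n_samples=n_samples, modulator_levels=(2,),
            seed=seed * 10_000 + i,
        )
        table, _ = simulate_samples(net, cfg)
        lib = enumerate_fragments(table, max_parents=1, top_fragments=None)
        summ = build_ensemble(lib, M=M, seed=seed * 10_000 + i + 1)
        f_switched = summ.edge_f("v000", "v001", modulator="m0", mod_class="switched")
        f_linear = summ.edge_f("v000", "v001", modulator="m0", mod_class="linear")
        f_plain = summ.edge_f("v000", "v001")
        f_conditional = f_switched + f_linear
        rows.append({
            "seed": i, "f_switched": f_switched, "f_conditional": f_conditional,
            "f_plain": f_plain,
            "success": bool(f_conditional >= cutoff and f_plain < cutoff),
        })
    return pd.DataFrame(rows)


def _beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    logc = lgamma(a + b) - lgamma(a) - lgamma(b)
    return np.exp(logc + (a - 1) * np.log(x) + (b - 1) * np.log1p(-x))


def cutoff_benchmark(
    seed: int = 0,
    n_low: int = 1500,
    n_high: int = 450,
    low: tuple[float, float] = (1.5, 10.0),
    high: tuple[float, float] = (12.0, 1.8),
    window: tuple[float, float] = (0.2, 0.9),
) -> dict:
    """Cutoff detection on a two-component frequency mixture.

    Low-frequency mass (false-positive-like) follows one beta component and
    high-confidence mass another; |dE/df| at cutoff c is the mixture density
    there, so the planted answer is the analytic density minimum inside the
    search window.  Returns the detected cutoff, the planted one, and the
    curves' monotonicity flags.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
    freqs = np.concatenate([
        rng.beta(*low, size=n_low), rng.beta(*high, size=n_high)
    ])
    freqs = np.clip(freqs, 0.001, 1.0)
    edges = pd.DataFrame({
        "node1": [f"a{i:05d}" for i in range(len(freqs))],
        "node2": [f"b{i:05d}" for i in range(len(freqs))],
        "modulator": "", "mod_class": "plain", "active_level": -1,
        "count": np.round(freqs * 1000).astype(int),
        "f": freqs,
        "r": 1.0,
    })[EDGE_COLUMNS]
    curve = frequency_curves(edges)
    detected = detect_cutoff(curve, window=window)

    grid = np.linspace(window[0], window[1], 1401)
    density = n_low * _beta_pdf(grid, *low) + n_high * _beta_pdf(grid, *high)
    planted = float(grid[int(np.argmin(density))])
    return {
        "detected": detected,
        "planted": planted,
        "edges_nonincreasing": bool(np.all(np.diff(curve.n_edges) <= 0)),
        "nodes_nonincreasing": bool(np.all(np.diff(curve.n_nodes) <= 0)),
    }


def printed_count_network(
    n_nodes: int, n_edges: int, seed: int = 0
) -> ConsensusNetwork:
    """A consensus-shaped network with exactly the given node and edge counts.

    Useful for checking count-derived summaries such as edges-per-node: the
    first ~n/2 edges pair every node up so all nodes are edge endpoints, and
    the remainder are distinct random pairs among them.
    """
    if n_edges < (n_nodes + 1) // 2:
        raise ValueError("too few edges to touch every node")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    nodes = [f"g{i:05d}" for i in range(n_nodes)]
    pairs: list[tuple[str, str]] = [
        (nodes[2 * i], nodes[2 * i + 1]) for i in range(n_nodes // 2)
    ]
    if n_nodes % 2:
        pairs.append((nodes[-1], nodes[0]))
    seen = set(pairs)
    while len(pairs) < n_edges:
        i, j = rng.integers(n_nodes, size=2)
        if i == j:
            continue
        a, b = sorted((nodes[i], nodes[j]))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        pairs.append((a, b))
    edges = pd.DataFrame({
        "node1": [p[0] for p in pairs],
        "node2": [p[1] for p in pairs],
        "modulator": "", "mod_class": "plain", "active_level": -1,
        "count": 1000, "f": rng.uniform(0.6, 1.0, size=n_edges), "r": 1.0,
    })[EDGE_COLUMNS]
    return ConsensusNetwork(0.6, edges)
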