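"""Synthetic ground-truth networks and probe-level array data.

The generator produces everything the downstream stages consume, with known
truth: a sparse linear-Gaussian DAG over continuous variables, optional
conditional (modulated) edges, censored metabolite-like variables, and a
probe/spot layer that reintroduces the redundancy of a pangenome two-color
array — several probes per gene split across strain lineages, each probe
printed in replicate spots on top of background fluorescence.

Scales are chosen to mirror the study conditions the pipeline targets:
a few dozen samples (24-48), effect sizes of order one, and sparse graphs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import VariableTable

EDGE_CLASSES = ("plain", "switched", "linear")


@dataclass(frozen=True)
class TrueEdge:
    """One directed ground-truth edge.

    ``edge_class`` is ``plain`` (always active), ``switched`` (active only in
    samples where ``modulator == active_level``) or ``linear`` (slope differs
    by modulator level; the declared ``effect`` applies at ``active_level``).
    """

    parent: str
    child: str
    effect: float
    edge_class: str = "plain"
    modulator: str | None = None
    active_level: int | None = None
    # slope applied at non-active modulator levels of a "linear" edge
    alt_effect: float | None = None


@dataclass
class GroundTruthNetwork:
    nodes: list[str]
    edges: list[TrueEdge]
    noise_scale: dict[str, float]
    #: modulator name -> number of levels
    modulators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth network must be acyclic")
        for e in self.edges:
            if not np.isfinite(e.effect) or e.effect == 0:
                raise ValueError(f"edge {e.parent}->{e.child} has invalid effect {e.effect}")
            if e.edge_class not in EDGE_CLASSES:
                raise ValueError(f"unknown edge class {e.edge_class!r}")
            if e.edge_class != "plain" and e.modulator not in self.modulators:
                raise ValueError(
                    f"conditional edge {e.parent}->{e.child} references "
                    f"undeclared modulator {e.modulator!r}"
                )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.parent, e.child, effect=e.effect, edge_class=e.edge_class)
        return g

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.parent, e.child) for e in self.edges}

    # -- IO --------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """GraphML for the topology plus a JSON sidecar with edge classes."""
        path = Path(path)
        nx.write_graphml(self.graph(), path)
        side = {
            "modulators": self.modulators,
            "noise_scale": self.noise_scale,
            "edges": [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "effect": e.effect,
                    "edge_class": e.edge_class,
                    "modulator": e.modulator,
                    "active_level": e.active_level,
                    "alt_effect": e.alt_effect,
                }
                for e in self.edges
            ],
        }
        path.with_suffix(path.suffix + ".edges.json").write_text(json.dumps(side, indent=1))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the seed fully determines every output."""

    n_nodes: int = 20
    n_samples: int = 48
    edge_density: float = 0.1
    fraction_conditional: float = 0.0
    probes_per_node: int = 1
    n_lineages: int = 1
    background_mean: float = 50.0
    background_sd: float = 10.0
    censor_fraction: float = 0.0
    seed: int = 0
    # calibration choices, not study-reported values: effect magnitudes of
    # order one and moderate noise keep edges detectable at n ~ 24-48
    effect_range: tuple[float, float] = (0.5, 1.5)
    noise_scale: float = 0.5
    metabolite_fraction: float = 0.2
    #: number of levels of each available modulator (binary by default;
    #: append a >=3 entry for a tiered acceptor-type-like operator)
    modulator_levels: tuple[int, ...] = (2, 2)
    spots_per_probe: int = 4
    probe_noise_sd: float = 0.05
    #: multiplicative intensity scale of true signal over background units,
    #: so detected transcripts sit well above background fluorescence
    signal_scale: float = 200.0
    #: fraction of emitted probes carrying no signal, only background
    dark_probe_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must lie in [0, 1]")
        if not 0 <= self.fraction_conditional <= 1:
            raise ValueError("fraction_conditional must lie in [0, 1]")
        if not 0 <= self.censor_fraction <= 1:
            raise ValueError("censor_fraction must lie in [0, 1]")
        if self.probes_per_node < 1 or self.n_lineages < 1:
            raise ValueError("probes_per_node and n_lineages must be >= 1")
        if self.background_mean < 0 or self.background_sd < 0:
            raise ValueError("background statistics must be nonnegative")
        if self.spots_per_probe < 4:
            raise ValueError("probes are replicated in at least four spots")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_dag(config: SimulationConfig) -> GroundTruthNetwork:
    """Draw a random sparse DAG with a declared fraction of conditional edges.

    Nodes are ordered by a random permutation; each of the n(n-1)/2 ordered
    pairs becomes an edge independently with probability ``edge_density``, so
    the expected edge count is ``edge_density * n(n-1)/2``.
    """
    config.validate()
    rng = _rng(config, 0)
    nodes = [f"v{i:03d}" for i in range(config.n_nodes)]
    order = list(rng.permutation(config.n_nodes))
    modulators = {f"m{i}": lv for i, lv in enumerate(config.modulator_levels)}
    binary_mods = [m for m, lv in modulators.items() if lv == 2]

    lo, hi = config.effect_range
    edges: list[TrueEdge] = []
    for i, j in combinations(range(config.n_nodes), 2):
        if rng.random() >= config.edge_density:
            continue
        parent, child = nodes[order[i]], nodes[order[j]]
        effect = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        if modulators and rng.random() < config.fraction_conditional:
            if binary_mods and rng.random() < 0.5:
                mod = binary_mods[rng.integers(len(binary_mods))]
                edges.append(
                    TrueEdge(parent, child, effect, "switched", mod, active_level=1)
                )
            else:
                mod = list(modulators)[rng.integers(len(modulators))]
                alt = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                edges.append(
                    TrueEdge(parent, child, effect, "linear", mod, 1, alt_effect=alt)
                )
        else:
            edges.append(TrueEdge(parent, child, effect))

    noise = {n: config.noise_scale for n in nodes}
    return GroundTruthNetwork(nodes, edges, noise, modulators)


def _balanced_levels(n_samples: int, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    base = np.resize(np.arange(n_levels), n_samples)
    return rng.permutation(base)


def simulate_samples(
    network: GroundTruthNetwork, config: SimulationConfig
) -> tuple[VariableTable, pd.DataFrame]:
    """Draw samples from the linear-Gaussian local models in topological order.

    Root nodes are standard normal; each child is
    ``sum(slope * parent) + N(0, noise_scale)`` where the slope of a
    conditional edge depends on its modulator's level in that sample.
    A ``censor_fraction`` of each metabolite-like variable's entries (the
    lowest values, mimicking a detection limit) is replaced by the limit and
    flagged by a paired switch set to 0.

    Returns the table plus the true modulator assignments.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_samples
    samples = [f"s{i:02d}" for i in range(n)]

    mods = pd.DataFrame(
        {m: _balanced_levels(n, lv, rng) for m, lv in network.modulators.items()},
        index=samples,
        dtype=int,
    )

    g = network.graph()
    incoming: dict[str, list[TrueEdge]] = {v: [] for v in network.nodes}
    for e in network.edges:
        incoming[e.child].append(e)

    values: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        x = rng.normal(0.0, 1.0, n) if not incoming[node] else np.zeros(n)
        for e in incoming[node]:
            parent = values[e.parent]
            if e.edge_class == "plain":
                slope = np.full(n, e.effect)
            else:
                level = mods[e.modulator].to_numpy()
                if e.edge_class == "switched":
                    slope = np.where(level == e.active_level, e.effect, 0.0)
                else:  # linear: declared effect at the active level, alt elsewhere
                    slope = np.where(level == e.active_level, e.effect, e.alt_effect)
            x = x + slope * parent
        if incoming[node]:
            x = x + rng.normal(0.0, network.noise_scale[node], n)
        values[node] = x

    cont = pd.DataFrame(values, index=samples)[network.nodes]

    # role assignment: a fixed-seed draw designates metabolite-like variables
    n_metab = int(round(config.metabolite_fraction * config.n_nodes))
    metab = set(rng.choice(network.nodes, size=n_metab, replace=False)) if n_metab else set()
    roles = {v: ("metabolite" if v in metab else "transcript") for v in network.nodes}

    discrete = mods.copy()
    switches: dict[str, str] = {}
    if config.censor_fraction > 0:
        for v in sorted(metab):
            limit = float(np.quantile(cont[v], config.censor_fraction))
            censored = cont[v] <= limit
            cont.loc[censored, v] = limit
            sw = f"{v}__switch"
            discrete[sw] = (~censored).astype(int)
            switches[v] = sw

    table = VariableTable(cont, discrete, roles=roles, switches=switches)
    return table, mods


@dataclass
class ProbeAnnotation:
    """Probe metadata: ortholog bin and percent identity per lineage group."""

    table: pd.DataFrame  # index: probe; columns: bin, lineage, identity_<g>...

    def identity_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("identity_")]


def emit_probe_level(
    latent: VariableTable, config: SimulationConfig
) -> tuple[pd.DataFrame, ProbeAnnotation]:
    """Expand latent transcripts into replicated probe spots with background.

    Each transcript node spawns ``probes_per_node`` probes assigned
    round-robin to ``n_lineages`` lineage groups.  Lineage 0 reports the
    latent signal itself; other lineages report an independent latent series,
    standing in for a co-resident strain with its own expression program.
    A spot measures ``exp(signal + probe noise)`` plus a background
    fluorescence draw, replicated ``spots_per_probe`` times.

    Returns a spot table (probe, sample, intensity, bg_mean, bg_sd) and the
    probe annotation with per-lineage percent identities drawn to straddle
    the strain-assignment cutoff (target >= 95, off-target <= 80).
    """
    config.validate()
    rng = _rng(config, 2)
    transcripts = [v for v in latent.continuous_vars if latent.role_of(v) == "transcript"]
    samples = list(latent.continuous.index)
    n = len(samples)
    lineages = [f"L{g}" for g in range(config.n_lineages)]

    records = []
    ann_rows = []
    for node in transcripts:
        signals = {0: latent.continuous[node].to_numpy()}
        for g in range(1, config.n_lineages):
            signals[g] = rng.normal(0.0, 1.0, n)
        for p in range(config.probes_per_node):
            g = p % config.n_lineages
            probe = f"{node}_p{p}"
            dark = rng.random() < config.dark_probe_fraction
            probe_noise = rng.normal(0.0, config.probe_noise_sd, n)
            signal = (np.zeros(n) if dark
                      else config.signal_scale * np.exp(signals[g] + probe_noise))
            for s_idx, sample in enumerate(samples):
                for _ in range(config.spots_per_probe):
                    bg = 0.0
                    if config.background_sd > 0 or config.background_mean > 0:
                        bg = max(rng.normal(config.background_mean, config.background_sd), 0.0)
                    records.append(
                        (probe, sample, signal[s_idx] + bg,
                         config.background_mean, config.background_sd)
                    )
            idents = {}
            for gg, lin in enumerate(lineages):
                if gg == g:
                    idents[f"identity_{lin}"] = rng.uniform(95.0, 100.0)
                else:
                    idents[f"identity_{lin}"] = rng.uniform(60.0, 80.0)
            ann_rows.append({"probe": probe, "bin": node, "lineage": lineages[g],
                             "dark": dark, **idents})

    spots = pd.DataFrame(
        records, columns=["probe", "sample", "intensity", "bg_mean", "bg_sd"]
    )
    # a spot of exactly zero intensity cannot occur on a real scanned array;
    # clip to a tiny positive floor so ratios stay positive
    spots["intensity"] = spots["intensity"].clip(lower=1e-9)
    annotation = ProbeAnnotation(pd.DataFrame(ann_rows).set_index("probe"))
    return spots, annotation


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t")


def simulate_study(config: SimulationConfig):
    """Convenience: DAG -> samples -> probe level, all from one config."""
    net = generate_dag(config)
    table, mods = simulate_samples(net, config)
    spots, annotation = emit_probe_level(table, config)
    return net, table, mods, spots, annotation


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
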