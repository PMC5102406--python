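"""Ensemble construction: sample many acyclic networks from the fragment
library and summarise edge frequencies.

Each network assigns one fragment to every child; the assignment must be
jointly acyclic.  Networks are drawn by Gibbs-style structure MCMC: a sweep
visits the children in random order and resamples each child's fragment with
probability proportional to ``exp(score)`` among the fragments that keep the
union graph acyclic.  Each of the M ensemble members is the end state of an
independent chain started from the empty network, so members are exchangeable
and the whole ensemble is reproducible from one seed.

The edge frequency f of a relationship is the fraction of the M networks in
which it appears — f = 0.6 means 600 of 1,000 networks.  A conditional
relationship (edge + modulator + class) is tallied separately from its
unconditional counterpart.  An exhaustive enumeration oracle
(:func:`exact_edge_posterior`) provides the ground truth for small instances,
and :func:`simulate_from_ensemble` runs the fitted models forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from numba import njit

from .fragments import Fragment, FragmentLibrary

_DEFAULT_BURN_IN = 100     # full Gibbs sweeps per chain
_DEFAULT_PAIR_UPDATES = 6  # blocked two-child updates per sweep

_U0 = np.uint64(0)
_U1 = np.uint64(1)


@njit(cache=False)
def _ctz(x: np.uint64) -> int:
    i = 0
    while (x >> np.uint64(i)) & _U1 == _U0:
        i += 1
    return i


@njit(cache=False)
def _desc(out: np.ndarray, start: int) -> np.uint64:
    desc = _U0
    frontier = out[start]
    while frontier != _U0:
        new = frontier & ~desc
        if new == _U0:
            break
        desc |= new
        nxt = _U0
        m = new
        while m != _U0:
            nxt |= out[_ctz(m)]
            m &= m - _U1
        frontier = nxt
    return desc


@njit(cache=False)
def _set_frag(masks, state, out, c: int, idx: int) -> None:
    old = masks[c, state[c]]
    new = masks[c, idx]
    bit = _U1 << np.uint64(c)
    rem = old & ~new
    while rem != _U0:
        out[_ctz(rem)] &= ~bit
        rem &= rem - _U1
    add = new & ~old
    while add != _U0:
        out[_ctz(add)] |= bit
        add &= add - _U1
    state[c] = idx


@njit(cache=False)
def _child_update(masks, nfrag, weights, empty_idx, state, out, c: int) -> None:
    d = _desc(out, c)
    tot = 0.0
    for j in range(nfrag[c]):
        if masks[c, j] & d == _U0:
            tot += weights[c, j]
    if tot <= 0.0:
        idx = empty_idx[c]
    else:
        r = np.random.random() * tot
        idx = empty_idx[c]
        acc = 0.0
        for j in range(nfrag[c]):
            if masks[c, j] & d == _U0:
                acc += weights[c, j]
                if acc >= r:
                    idx = j
                    break
    _set_frag(masks, state, out, c, idx)


@njit(cache=False)
def _pair_update(masks, nfrag, weights, empty_idx, state, out, a: int, b: int) -> None:
    saved_a = state[a]
    saved_b = state[b]
    _set_frag(masks, state, out, a, empty_idx[a])
    _set_frag(masks, state, out, b, empty_idx[b])
    da = _desc(out, a)
    db = _desc(out, b)
    bit_a = _U1 << np.uint64(a)
    bit_b = _U1 << np.uint64(b)
    tot = 0.0
    for i in range(nfrag[a]):
        ma = masks[a, i]
        if ma & da != _U0:
            continue
        thru_b = ma & (db | bit_b) != _U0
        wa = weights[a, i]
        for j in range(nfrag[b]):
            mb = masks[b, j]
            if mb & db != _U0:
                continue
            if thru_b and (mb & (da | bit_a) != _U0):
                continue
            tot += wa * weights[b, j]
    if tot <= 0.0:
        _set_frag(masks, state, out, a, saved_a)
        _set_frag(masks, state, out, b, saved_b)
        return
    r = np.random.random() * tot
    acc = 0.0
    sel_a = saved_a
    sel_b = saved_b
    done = False
    for i in range(nfrag[a]):
        if done:
            break
        ma = masks[a, i]
        if ma & da != _U0:
            continue
        thru_b = ma & (db | bit_b) != _U0
        wa = weights[a, i]
        for j in range(nfrag[b]):
            mb = masks[b, j]
            if mb & db != _U0:
                continue
            if thru_b and (mb & (da | bit_a) != _U0):
                continue
            acc += wa * weights[b, j]
            if acc >= r:
                sel_a = i
                sel_b = j
                done = True
                break
    _set_frag(masks, state, out, a, sel_a)
    _set_frag(masks, state, out, b, sel_b)


@njit(cache=False)
def _gibbs_chains(masks, nfrag, weights, empty_idx, burn_in: int,
                  pair_updates: int, seeds) -> np.ndarray:
    M = seeds.shape[0]
    n = masks.shape[0]
    states = np.empty((M, n), np.int64)
    state = np.empty(n, np.int64)
    out = np.empty(n, np.uint64)
    order = np.empty(n, np.int64)
    for mi in range(M):
        np.random.seed(seeds[mi])
        for c in range(n):
            state[c] = empty_idx[c]
            out[c] = _U0
        for _ in range(burn_in):
            for i in range(n):
                order[i] = i
            for i in range(n - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                t = order[i]
                order[i] = order[j]
                order[j] = t
            for i in range(n):
                _child_update(masks, nfrag, weights, empty_idx, state, out, order[i])
            if n >= 2:
                for _ in range(pair_updates):
                    a = np.random.randint(0, n)
                    b = np.random.randint(0, n - 1)
                    if b >= a:
                        b += 1
                    _pair_update(masks, nfrag, weights, empty_idx, state, out, a, b)
        for c in range(n):
            states[mi, c] = state[c]
    return states


@dataclass
class DAGSample:
    """One sampled network: a fragment per child plus the derived edge set."""

    assignment: dict[str, int]  # child -> index into the library's fragment list
    fragments: dict[str, Fragment]

    def edges(self) -> list[tuple]:
        out = []
        for child, frag in self.fragments.items():
            for p in frag.parents:
                out.append(frag.edge_key(p))
        return out


class _Compiled:
    """Bitmask representation of a library for the fast Gibbs inner loop."""

    def __init__(self, lib: FragmentLibrary):
        self.lib = lib
        self.children = lib.children
        self.n = len(self.children)
        self.index = {v: i for i, v in enumerate(self.children)}
        self.small = self.n <= 63
        self.masks: list = []         # per child: parent masks per fragment
        self.weights: list = []       # per child: exp(score - max score)
        self.empty_idx: list[int] = []
        for child in self.children:
            frags = lib.fragments[child]
            masks = []
            for f in frags:
                m = 0
                for p in f.parents:
                    m |= 1 << self.index[p]
                masks.append(m)
            scores = np.array([f.score for f in frags], float)
            w = np.exp(scores - scores.max())
            if self.small:
                self.masks.append(np.array(masks, dtype=np.uint64))
            else:
                self.masks.append(masks)
            self.weights.append(w)
            self.empty_idx.append(next(i for i, f in enumerate(frags) if f.is_empty))
        if self.small:
            maxf = max(len(w) for w in self.weights)
            self.masks2d = np.zeros((self.n, maxf), np.uint64)
            self.weights2d = np.zeros((self.n, maxf), np.float64)
            self.nfrag = np.array([len(w) for w in self.weights], np.int64)
            self.empty_arr = np.array(self.empty_idx, np.int64)
            for c in range(self.n):
                k = self.nfrag[c]
                self.masks2d[c, :k] = self.masks[c]
                self.weights2d[c, :k] = self.weights[c]

    def run_chains_fast(self, seeds: np.ndarray, burn_in: int,
                        pair_updates: int) -> list[list[int]]:
        states = _gibbs_chains(self.masks2d, self.nfrag, self.weights2d,
                               self.empty_arr, burn_in, pair_updates,
                               seeds.astype(np.uint32))
        return [[int(x) for x in row] for row in states]

    # -- graph bookkeeping over python-int bitmasks ----------------------

    @staticmethod
    def _descendants(out: list[int], start: int) -> int:
        desc = 0
        frontier = out[start]
        while frontier:
            new = frontier & ~desc
            if not new:
                break
            desc |= new
            nxt = 0
            m = new
            while m:
                b = m & -m
                nxt |= out[b.bit_length() - 1]
                m ^= b
            frontier = nxt
        return desc

    def _allowed(self, c: int, desc: int) -> np.ndarray:
        masks = self.masks[c]
        if self.small:
            return (masks & np.uint64(desc)) == 0
        return np.array([m & desc == 0 for m in masks])

    def _set_fragment(self, state: list[int], out: list[int], c: int, idx: int) -> None:
        old = int(self.masks[c][state[c]])
        new = int(self.masks[c][idx])
        bit = 1 << c
        m = old & ~new
        while m:
            b = m & -m
            out[b.bit_length() - 1] &= ~bit
            m ^= b
        m = new & ~old
        while m:
            b = m & -m
            out[b.bit_length() - 1] |= bit
            m ^= b
        state[c] = idx

    def _update_child(self, state: list[int], out: list[int], c: int,
                      rng: np.random.Generator) -> None:
        w = self.weights[c] * self._allowed(c, self._descendants(out, c))
        tot = w.sum()
        if tot <= 0:
            idx = self.empty_idx[c]
        else:
            cum = np.cumsum(w)
            idx = int(np.searchsorted(cum, rng.random() * tot, side="right"))
            idx = min(idx, len(w) - 1)
        self._set_fragment(state, out, c, idx)

    def _update_pair(self, state: list[int], out: list[int], a: int, b: int,
                     rng: np.random.Generator) -> None:
        """Jointly resample the fragments of two children.

        Single-child updates cannot cross between structure modes that
        require coordinated changes (for example reversing an edge, or
        trading a collider for a covering edge); a blocked update over all
        acyclic fragment combinations of the pair can.
        """
        bit_a, bit_b = 1 << a, 1 << b
        # graph without the pair's incoming edges
        saved_a, saved_b = state[a], state[b]
        self._set_fragment(state, out, a, self.empty_idx[a])
        self._set_fragment(state, out, b, self.empty_idx[b])
        da = self._descendants(out, a)
        db = self._descendants(out, b)
        ok_a = self._allowed(a, da)
        ok_b = self._allowed(b, db)
        # a combined cycle needs a path a ~> x in Pb plus a path b ~> u in Pa
        masks_a, masks_b = self.masks[a], self.masks[b]
        if self.small:
            thru_a = (masks_b & np.uint64(da | bit_a)) != 0
            thru_b = (masks_a & np.uint64(db | bit_b)) != 0
        else:
            thru_a = np.array([m & (da | bit_a) != 0 for m in masks_b])
            thru_b = np.array([m & (db | bit_b) != 0 for m in masks_a])
        valid = (ok_a[:, None] & ok_b[None, :]
                 & ~(thru_b[:, None] & thru_a[None, :]))
        joint = (self.weights[a][:, None] * self.weights[b][None, :]) * valid
        tot = joint.sum()
        if tot <= 0:
            ia, ib = saved_a, saved_b
        else:
            flat = np.cumsum(joint.ravel())
            k = int(np.searchsorted(flat, rng.random() * tot, side="right"))
            k = min(k, joint.size - 1)
            ia, ib = divmod(k, joint.shape[1])
        self._set_fragment(state, out, a, int(ia))
        self._set_fragment(state, out, b, int(ib))

    def run_chain(self, rng: np.random.Generator, burn_in: int,
                  pair_updates: int = _DEFAULT_PAIR_UPDATES) -> list[int]:
        state = list(self.empty_idx)
        out = [0] * self.n  # out[u]: bitmask of children currently having parent u
        for _ in range(burn_in):
            for c in rng.permutation(self.n):
                self._update_child(state, out, int(c), rng)
            if self.n >= 2:
                for _ in range(pair_updates):
                    a, b = rng.choice(self.n, size=2, replace=False)
                    self._update_pair(state, out, int(a), int(b), rng)
        return state

    def to_sample(self, state: list[int]) -> DAGSample:
        assignment = {child: state[i] for i, child in enumerate(self.children)}
        frags = {
            child: self.lib.fragments[child][state[i]]
            for i, child in enumerate(self.children)
        }
        return DAGSample(assignment, frags)


def sample_network(
    lib: FragmentLibrary, seed: int = 0, burn_in: int = _DEFAULT_BURN_IN,
    pair_updates: int = _DEFAULT_PAIR_UPDATES,
) -> DAGSample:
    """Draw a single acyclic network; deterministic given the seed."""
    comp = _Compiled(lib)
    seq = np.random.SeedSequence([int(seed), 17])
    if comp.small:
        state = comp.run_chains_fast(seq.generate_state(1), burn_in, pair_updates)[0]
    else:
        state = comp.run_chain(np.random.default_rng(seq), burn_in, pair_updates)
    return comp.to_sample(state)


EDGE_COLUMNS = ["node1", "node2", "modulator", "mod_class", "active_level",
                "count", "f", "r"]


def _pair_key(edge_key: tuple) -> tuple:
    """Relationship identity ignoring orientation.

    A linear-Gaussian likelihood cannot distinguish the two orientations of
    many edges (Markov equivalence), so a relationship is reported per
    unordered node pair — the convention of the consensus-network tables,
    where edges carry a sign r rather than a direction.  Acyclicity still
    guarantees at most one orientation per network, so f stays in [0, 1].
    """
    parent, child, mod, cls, active = edge_key
    a, b = sorted((parent, child))
    return (a, b, mod or "", cls, -1 if active is None else active)


@dataclass
class EnsembleSummary:
    """Edge and fragment frequencies over an ensemble of M networks."""

    M: int
    edges: pd.DataFrame          # EDGE_COLUMNS
    fragment_freqs: pd.DataFrame  # child, fragment_index, count, f
    states: list[list[int]]       # per network: fragment index per child
    lib: FragmentLibrary

    def edge_f(self, a: str, b: str, modulator: str | None = None,
               mod_class: str = "plain") -> float:
        """Frequency of the (unordered) relationship a--b under one variant."""
        a, b = sorted((a, b))
        e = self.edges
        sel = (
            (e["node1"] == a) & (e["node2"] == b)
            & (e["mod_class"] == mod_class)
            & (e["modulator"] == (modulator or ""))
        )
        return float(e.loc[sel, "f"].sum())

    def pair_table(self) -> pd.DataFrame:
        """Edge frequencies aggregated over modulator variants.

        Within one network a node pair is linked by exactly one fragment, so
        the pair's frequency is the sum of its variant frequencies and still
        lies in [0, 1].  This is the accounting behind the node/edge-vs-cutoff
        curves and the consensus network; each pair keeps the annotation of
        its most frequent variant.
        """
        rows = []
        for (a, b), grp in self.edges.groupby(["node1", "node2"], sort=True):
            top = grp.loc[grp["count"].idxmax()]
            rows.append({
                "node1": a, "node2": b,
                "modulator": top["modulator"], "mod_class": top["mod_class"],
                "active_level": top["active_level"],
                "count": int(grp["count"].sum()),
                "f": float(grp["f"].sum()),
                "r": float(top["r"]),
            })
        return pd.DataFrame(rows, columns=EDGE_COLUMNS)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def _edge_sign(lib: FragmentLibrary, parent: str, child: str,
               cache: dict) -> float:
    key = (parent, child)
    if key not in cache:
        x = lib.data.continuous[parent].to_numpy(float)
        y = lib.data.continuous[child].to_numpy(float)
        sx, sy = x.std(), y.std()
        cache[key] = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else float("nan")
    return cache[key]


def build_ensemble(
    lib: FragmentLibrary,
    M: int = 1000,
    seed: int = 0,
    burn_in: int = _DEFAULT_BURN_IN,
    pair_updates: int = _DEFAULT_PAIR_UPDATES,
) -> EnsembleSummary:
    """Sample M networks with independent sub-seeds and tabulate frequencies.

    The sign r attached to every observed edge is the Pearson correlation of
    the two variables on the (transformed) data across all samples — it is a
    property of the data, not of the ensemble.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    comp = _Compiled(lib)
    root = np.random.SeedSequence(int(seed))
    if comp.small:
        states = comp.run_chains_fast(root.generate_state(M), burn_in, pair_updates)
    else:
        states = [
            comp.run_chain(np.random.default_rng(seq), burn_in, pair_updates)
            for seq in root.spawn(M)
        ]
    edge_counts: dict[tuple, int] = {}
    frag_counts: dict[tuple[str, int], int] = {}
    for state in states:
        for i, child in enumerate(comp.children):
            idx = state[i]
            frag_counts[(child, idx)] = frag_counts.get((child, idx), 0) + 1
            frag = lib.fragments[child][idx]
            for p in frag.parents:
                k = _pair_key(frag.edge_key(p))
                edge_counts[k] = edge_counts.get(k, 0) + 1

    sign_cache: dict = {}
    rows = []
    for (a, b, mod, cls, active), count in sorted(edge_counts.items()):
        rows.append({
            "node1": a, "node2": b,
            "modulator": mod, "mod_class": cls,
            "active_level": active,
            "count": count, "f": count / M,
            "r": _edge_sign(lib, a, b, sign_cache),
        })
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)

    frag_rows = [
        {"child": c, "fragment_index": i, "count": n, "f": n / M}
        for (c, i), n in sorted(frag_counts.items())
    ]
    fragment_freqs = pd.DataFrame(frag_rows,
                                  columns=["child", "fragment_index", "count", "f"])
    return EnsembleSummary(M, edges, fragment_freqs, states, lib)


# -- exhaustive oracle ----------------------------------------------------

_MAX_ORACLE_VARS = 5


def _assignment_acyclic(masks: tuple[int, ...]) -> bool:
    n = len(masks)
    remaining = (1 << n) - 1
    while remaining:
        progressed = False
        m = remaining
        while m:
            b = m & -m
            i = b.bit_length() - 1
            if masks[i] & remaining == 0:
                remaining ^= b
                progressed = True
            m ^= b
        if not progressed:
            return False
    return True


def exact_edge_posterior(lib: FragmentLibrary) -> tuple[pd.DataFrame, int]:
    """Exact per-relationship posterior by enumerating fragment assignments.

    Every joint assignment of one fragment per child is visited; acyclic
    assignments are weighted by the product of their fragments' exponentiated
    scores under a uniform structure prior.  Returns the normalized posterior
    inclusion probability per (edge, modulator, class) together with the
    number of acyclic assignments visited (for a modulator-free exhaustive
    library this equals the number of labeled DAGs under the in-degree cap).

    Refuses more than five continuous variables.
    """
    children = lib.children
    if len(children) > _MAX_ORACLE_VARS:
        raise ValueError(
            f"exact enumeration supports at most {_MAX_ORACLE_VARS} variables, "
            f"got {len(children)}"
        )
    index = {v: i for i, v in enumerate(children)}
    per_child_masks: list[list[int]] = []
    per_child_w: list[np.ndarray] = []
    for child in children:
        frags = lib.fragments[child]
        masks = []
        for f in frags:
            m = 0
            for p in f.parents:
                m |= 1 << index[p]
            masks.append(m)
        scores = np.array([f.score for f in frags])
        per_child_masks.append(masks)
        per_child_w.append(np.exp(scores - scores.max()))

    total = 0.0
    n_dags = 0
    edge_mass: dict[tuple, float] = {}
    for combo in product(*(range(len(m)) for m in per_child_masks)):
        masks = tuple(per_child_masks[c][i] for c, i in enumerate(combo))
        if not _assignment_acyclic(masks):
            continue
        n_dags += 1
        w = 1.0
        for c, i in enumerate(combo):
            w *= per_child_w[c][i]
        total += w
        for c, i in enumerate(combo):
            frag = lib.fragments[children[c]][i]
            for p in frag.parents:
                k = _pair_key(frag.edge_key(p))
                edge_mass[k] = edge_mass.get(k, 0.0) + w

    rows = [
        {"node1": a, "node2": b, "modulator": mod, "mod_class": cls,
         "active_level": active, "posterior": mass / total}
        for (a, b, mod, cls, active), mass in sorted(edge_mass.items())
    ]
    cols = ["node1", "node2", "modulator", "mod_class", "active_level", "posterior"]
    return pd.DataFrame(rows, columns=cols), n_dags


# -- forward simulation ---------------------------------------------------

def _topological_order(children: list[str], frags: dict[str, Fragment]) -> list[str]:
    parents = {c: set(frags[c].parents) for c in children}
    order: list[str] = []
    remaining = set(children)
    while remaining:
        free = sorted(v for v in remaining if not parents[v] & remaining)
        if not free:
            raise RuntimeError("sampled network is cyclic")  # pragma: no cover
        order.extend(free)
        remaining -= set(free)
    return order


def simulate_from_ensemble(
    summary: EnsembleSummary, n_draws: int, seed: int = 0
) -> pd.DataFrame:
    """Forward-simulate samples from the fitted networks of the ensemble.

    Networks are drawn uniformly from the ensemble members; discrete
    modulator patterns are bootstrapped from the observed data; continuous
    values are generated in topological order from each child's fitted
    linear-Gaussian fragment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    lib = summary.lib
    children = lib.children
    net_idx = rng.integers(len(summary.states), size=n_draws)
    disc = lib.data.discrete
    boot = rng.integers(len(disc), size=n_draws) if len(disc.columns) else None

    out = np.empty((n_draws, len(children)))
    col = {v: j for j, v in enumerate(children)}
    for net in np.unique(net_idx):
        sel = np.flatnonzero(net_idx == net)
        frags = {
            child: lib.fragments[child][summary.states[net][i]]
            for i, child in enumerate(children)
        }
        disc_rows = disc.iloc[boot[sel]] if boot is not None else None
        for child in _topological_order(children, frags):
            f = frags[child]
            mu = np.full(len(sel), f.intercept)
            if f.parents:
                if f.edge_class == "plain":
                    for slope, p in zip(f.slopes, f.parents):
                        mu += slope * out[sel, col[p]]
                elif f.edge_class == "switched":
                    ind = (disc_rows[f.modulator].to_numpy() == f.active_level)
                    for slope, p in zip(f.slopes, f.parents):
                        mu += slope * ind * out[sel, col[p]]
                else:  # linear: slopes ordered level-major, parents inner
                    levels = sorted(np.unique(disc[f.modulator]))
                    mvals = disc_rows[f.modulator].to_numpy()
                    k = 0
                    for lv in levels:
                        ind = (mvals == lv).astype(float)
                        for p in f.parents:
                            mu += f.slopes[k] * ind * out[sel, col[p]]
                            k += 1
            noise = rng.normal(0.0, np.sqrt(f.sigma2), len(sel))
            out[sel, col[child]] = mu + noise
    return pd.DataFrame(out, columns=children)
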