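"""Local-model ("fragment") enumeration and scoring.

A fragment is one child variable with a candidate parent set (continuous
variables only) and optionally a discrete modulator that makes the
relationship conditional:

* ``plain`` — child ~ intercept + sum(slope * parent) on all samples;
* ``switched`` — parent terms enter only in samples where the (binary)
  modulator equals its active level;
* ``linear`` — a separate slope per modulator level.

Fragments are fitted as linear-Gaussian models and scored; the default score
is the BIC-penalized maximum log-likelihood ``logL - (q/2) log n`` with ``q``
the parameter count (coefficients plus the noise variance).  A conjugate
Zellner g-prior marginal likelihood (g = n) is available as an alternative.
Scores are comparable within a child and feed the network sampler as
unnormalized log-probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, log, pi
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import VariableTable

log_ = logging.getLogger(__name__)

FRAGMENT_CLASSES = ("plain", "switched", "linear")

#: floor on the ML noise variance; keeps noiseless fixtures finite
_MIN_SIGMA2 = 1e-12


class DegenerateFitError(ValueError):
    """Singular design matrix (e.g. duplicated parent columns)."""


@dataclass(frozen=True)
class Fragment:
    child: str
    parents: tuple[str, ...]
    edge_class: str = "plain"
    modulator: str | None = None
    active_level: int | None = None
    score: float = float("nan")
    #: fitted intercept, slope per design column, and ML noise variance
    intercept: float = 0.0
    slopes: tuple[float, ...] = ()
    #: design column labels matching ``slopes``
    slope_labels: tuple[str, ...] = ()
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.child in self.parents:
            raise ValueError(f"child {self.child!r} cannot be its own parent")
        if self.edge_class not in FRAGMENT_CLASSES:
            raise ValueError(f"unknown fragment class {self.edge_class!r}")
        if self.edge_class != "plain" and self.modulator is None:
            raise ValueError("conditional fragment requires a modulator")

    @property
    def is_empty(self) -> bool:
        return not self.parents

    def edge_key(self, parent: str) -> tuple:
        """Identity of the (parent -> child, modulator, class) relationship."""
        if self.edge_class == "plain":
            return (parent, self.child, None, "plain", None)
        return (parent, self.child, self.modulator, self.edge_class, self.active_level)


def _design(
    data: VariableTable,
    child: str,
    parents: tuple[str, ...],
    edge_class: str,
    modulator: str | None,
    active_level: int | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = data.continuous[child].to_numpy(float)
    n = len(y)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]
    if edge_class == "plain" or not parents:
        for p in parents:
            cols.append(data.continuous[p].to_numpy(float))
            labels.append(p)
    elif edge_class == "switched":
        level = data.discrete[modulator].to_numpy()
        ind = (level == active_level).astype(float)
        for p in parents:
            cols.append(ind * data.continuous[p].to_numpy(float))
            labels.append(f"{p}|{modulator}=={active_level}")
    else:  # linear: one slope per observed modulator level
        level = data.discrete[modulator].to_numpy()
        for lv in sorted(np.unique(level)):
            ind = (level == lv).astype(float)
            for p in parents:
                cols.append(ind * data.continuous[p].to_numpy(float))
                labels.append(f"{p}|{modulator}=={lv}")
    return np.column_stack(cols), y, labels[1:]


def score_fragment(
    child: str,
    parents: tuple[str, ...] | list[str],
    data: VariableTable,
    modulator: str | None = None,
    edge_class: str = "plain",
    active_level: int | None = None,
    score: str = "bic",
) -> Fragment:
    """Fit one local linear-Gaussian model and score it.

    Requires ``n_samples > |parents| + 2``.  A rank-deficient design (for
    example a duplicated parent) raises :class:`DegenerateFitError`.
    """
    parents = tuple(parents)
    n = data.n_samples
    if n <= len(parents) + 2:
        raise ValueError(
            f"need n_samples > |parents| + 2 (got n={n}, |parents|={len(parents)})"
        )
    if len(set(parents)) != len(parents):
        raise DegenerateFitError(f"duplicated parents in {parents}")
    if edge_class == "switched":
        levels = np.unique(data.discrete[modulator])
        if len(levels) != 2:
            raise ValueError("switched-conditional fragments require a binary modulator")
        if active_level is None:
            active_level = int(levels.max())
    if edge_class == "linear" and active_level is None:
        active_level = int(data.discrete[modulator].max())

    X, y, labels = _design(data, child, parents, edge_class, modulator, active_level)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError(
            f"singular design for child {child!r}, parents {parents}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, _MIN_SIGMA2)
    loglik = -0.5 * n * (log(2 * pi * sigma2) + 1.0)

    if score == "bic":
        q = X.shape[1] + 1  # coefficients + noise variance
        value = loglik - 0.5 * q * log(n)
    elif score == "marginal":
        value = _g_prior_marginal(X, y, rss)
    else:
        raise ValueError(f"unknown score type {score!r}")

    return Fragment(
        child=child,
        parents=parents,
        edge_class=edge_class if parents else "plain",
        modulator=modulator if parents else None,
        active_level=active_level if (parents and edge_class != "plain") else None,
        score=value,
        intercept=float(beta[0]),
        slopes=tuple(float(b) for b in beta[1:]),
        slope_labels=tuple(labels),
        sigma2=sigma2,
    )


def _g_prior_marginal(X: np.ndarray, y: np.ndarray, rss: float) -> float:
    """Log marginal likelihood under a unit-information Zellner g-prior.

    Flat prior on the intercept and noise variance, ``N(0, g sigma^2 (X'X)^-1)``
    on the slopes with g = n.  Constant terms shared by all models of one
    child are dropped; only within-child comparability matters.
    """
    n, k = X.shape[0], X.shape[1] - 1
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= _MIN_SIGMA2:
        tss = _MIN_SIGMA2
    r2 = max(0.0, 1.0 - rss / tss)
    g = float(n)
    return 0.5 * (n - 1 - k) * log(1 + g) - 0.5 * (n - 1) * log(1 + g * (1 - r2))


@dataclass
class FragmentLibrary:
    """Scored fragments per child plus the data they were fitted on."""

    fragments: dict[str, list[Fragment]]
    data: VariableTable
    max_parents: int
    score_type: str = "bic"

    def __post_init__(self) -> None:
        for child, frags in self.fragments.items():
            if not any(f.is_empty for f in frags):
                raise ValueError(f"child {child!r} lacks the empty fragment")

    @property
    def children(self) -> list[str]:
        return list(self.fragments)

    def n_fragments(self, child: str) -> int:
        return len(self.fragments[child])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for child, frags in self.fragments.items():
            for f in frags:
                rows.append({
                    "child": child,
                    "parents": ";".join(f.parents),
                    "class": f.edge_class,
                    "modulator": f.modulator or "",
                    "active_level": "" if f.active_level is None else f.active_level,
                    "score": f.score,
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_parent_rule(parent_role: str, child_role: str) -> bool:
    """Causal-ordering prior: transcripts never drive setup parameters."""
    if parent_role == "transcript" and child_role == "setup":
        return False
    return True


def enumerate_fragments(
    data: VariableTable,
    max_parents: int = 3,
    score: str = "bic",
    top_fragments: int | None = 200,
    classes: tuple[str, ...] = ("switched", "linear"),
    parent_rule=default_parent_rule,
) -> FragmentLibrary:
    """Score every parent set of size <= ``max_parents`` for every child.

    Each non-empty parent set is additionally crossed with every discrete
    variable under each enabled conditional class (``switched`` only for
    binary modulators).  Per child, at most ``top_fragments`` fragments are
    retained by score — the empty fragment always survives, so the sampler
    can leave any child parentless.  Pass ``top_fragments=None`` for the
    exhaustive library used by the exact-enumeration oracle.
    """
    n = data.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    if max_parents >= n - 2:
        raise ValueError(
            f"max_parents={max_parents} too large for n={n} samples; "
            f"reduce to at most {n - 3} so every fragment stays identifiable"
        )
    variables = data.continuous_vars
    mod_variants: list[tuple[str, str, int]] = []  # (class, modulator, active)
    for d in data.discrete_vars:
        levels = np.unique(data.discrete[d])
        if "switched" in classes and len(levels) == 2:
            mod_variants.append(("switched", d, int(levels.max())))
        if "linear" in classes and len(levels) >= 2:
            mod_variants.append(("linear", d, int(levels.max())))

    lib: dict[str, list[Fragment]] = {}
    for child in variables:
        child_role = data.role_of(child)
        allowed = [
            p for p in variables
            if p != child and (parent_rule is None or parent_rule(data.role_of(p), child_role))
        ]
        frags: list[Fragment] = [score_fragment(child, (), data, score=score)]
        for size in range(1, max_parents + 1):
            for parents in combinations(allowed, size):
                try:
                    frags.append(score_fragment(child, parents, data, score=score))
                except DegenerateFitError:
                    continue
                for cls, mod, active in mod_variants:
                    try:
                        frags.append(score_fragment(
                            child, parents, data, modulator=mod,
                            edge_class=cls, active_level=active, score=score,
                        ))
                    except DegenerateFitError:
                        continue
        if top_fragments is not None and len(frags) > top_fragments:
            empty = frags[0]
            rest = sorted(frags[1:], key=lambda f: -f.score)[: top_fragments - 1]
            frags = [empty] + rest
        lib[child] = frags
    return FragmentLibrary(lib, data, max_parents, score)


def library_size(n_continuous: int, max_parents: int, n_mod_variants: int = 0) -> int:
    """Fragments per child before pruning: empty + parent sets x (1 + variants)."""
    nonempty = sum(comb(n_continuous - 1, j) for j in range(1, max_parents + 1))
    return 1 + nonempty * (1 + n_mod_variants)
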