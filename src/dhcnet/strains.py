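"""Strain-lineage analysis on pangenome-array probes.

A pangenome array carries probes designed against several strain genomes, so
a probe's percent identity to each lineage's representative genome tells
which lineage's transcript it actually reports.  Probes at or above the
identity cutoff (85% by default) for exactly one lineage are assigned to it;
probes qualifying for several lineages are ambiguous; probes qualifying for
none are unassigned.  Consensus edges are then classified as within- or
between-lineage, and lineage-ordered correlograms expose the block structure
that separates co-resident strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusNetwork
from .preprocess import DegenerateDataError, ProbeMatrix, _correlation_scale

AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclass
class LineageAssignment:
    """Per-probe lineage label plus the identities that justify it."""

    labels: pd.Series           # probe -> lineage | ambiguous | unassigned
    identities: pd.DataFrame    # probe x lineage percent identity
    cutoff: float

    def of(self, probe: str) -> str:
        return self.labels.get(probe, UNASSIGNED)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()


def assign_strain_groups(
    annotation: pd.DataFrame, cutoff: float = 85.0
) -> LineageAssignment:
    """Label each probe by the single lineage whose identity meets the cutoff.

    ``annotation`` must carry one ``identity_<lineage>`` column per lineage,
    indexed by probe, with identities in [0, 100].
    """
    ident_cols = [c for c in annotation.columns if c.startswith("identity_")]
    if not ident_cols:
        raise ValueError("annotation has no identity_<lineage> columns")
    idents = annotation[ident_cols].astype(float)
    idents.columns = [c.removeprefix("identity_") for c in ident_cols]
    if ((idents < 0) | (idents > 100)).any().any():
        bad = idents[((idents < 0) | (idents > 100)).any(axis=1)].index[0]
        raise ValueError(f"identity outside [0, 100] for probe {bad!r}")

    qualifies = idents >= cutoff
    n_hits = qualifies.sum(axis=1)
    labels = pd.Series(UNASSIGNED, index=idents.index, dtype=object)
    labels[n_hits >= 2] = AMBIGUOUS
    single = n_hits == 1
    labels[single] = qualifies[single].idxmax(axis=1)
    return LineageAssignment(labels, idents, cutoff)


def classify_edges(
    net: ConsensusNetwork, assignment: LineageAssignment
) -> pd.Series:
    """Count consensus edges within each lineage, between lineages, or excluded.

    An edge whose endpoints are both assigned to the same lineage counts as
    ``within_<lineage>``; endpoints in two different lineages count as
    ``between``; edges touching an ambiguous, unassigned or non-probe node
    (a condition or metabolite variable) are ``excluded``.  The categories
    partition the consensus edge set.
    """
    counts: dict[str, int] = {"between": 0, "excluded": 0}
    for row in net.edges.itertuples(index=False):
        a, b = assignment.of(row.node1), assignment.of(row.node2)
        if a in (AMBIGUOUS, UNASSIGNED) or b in (AMBIGUOUS, UNASSIGNED):
            counts["excluded"] += 1
        elif a == b:
            key = f"within_{a}"
            counts[key] = counts.get(key, 0) + 1
        else:
            counts["between"] += 1
    return pd.Series(counts, dtype=int).sort_index()


@dataclass
class Correlogram:
    """Symmetric probe-correlation matrix ordered by ortholog bin then lineage."""

    matrix: pd.DataFrame
    order: list[str]

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("correlogram must be symmetric")

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def correlogram(
    m: ProbeMatrix,
    probes: list[str] | None = None,
    assignment: LineageAssignment | None = None,
) -> Correlogram:
    """Pairwise probe correlations on the collapse scale (log intensities).

    Rows are ordered by ortholog bin, then lineage label (when an assignment
    is given), then probe id.  A constant probe has undefined correlations,
    reported as missing; its diagonal entry stays 1.
    """
    if len(m.samples) < 3:
        raise DegenerateDataError("at least 3 samples are needed for a correlogram")
    probes = list(probes) if probes is not None else m.probes

    def sort_key(p: str):
        bin_id = ""
        if m.annotation is not None and "bin" in m.annotation.columns and p in m.annotation.index:
            bin_id = str(m.annotation.loc[p, "bin"])
        lineage = assignment.of(p) if assignment is not None else ""
        return (bin_id, lineage, p)

    order = sorted(probes, key=sort_key)
    logged = _correlation_scale(m.values.loc[order])
    corr = logged.T.corr()  # pandas leaves zero-variance rows as NaN
    np.fill_diagonal(corr.values, 1.0)
    return Correlogram(corr, order)
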