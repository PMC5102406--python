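"""Spot-level array data to the mixed-type inference table.

Stages, in the order the pipeline applies them:

1. :func:`aggregate_spots` — geometric averaging of replicate spots into a
   probe x sample matrix, carrying background statistics forward.
2. :func:`filter_background` — drop probes never rising ``k`` standard
   deviations above background fluorescence in any sample.
3. :func:`collapse_orthologs` — within each ortholog bin, collapse probes
   whose expression is highly correlated (r > 0.9 by default) onto the
   highest-intensity representative, leaving distinct probes (typically
   targeting a different strain lineage) in place.
4. :func:`censor_and_transform` — substitute below-detection metabolite
   values by the detection limit (or 1e-4), pair them with a 0/1 censoring
   switch, and eighth-root transform every continuous variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import VariableTable

log = logging.getLogger(__name__)

SPOT_COLUMNS = ["probe", "sample", "intensity", "bg_mean", "bg_sd"]

#: substitute for a censored value when no detection limit is defined
DEFAULT_CENSOR_VALUE = 1e-4


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested operation."""


@dataclass
class ProbeMatrix:
    """Aggregated probe x sample intensities plus probe annotation.

    ``bg_mean``/``bg_sd`` carry, per (probe, sample), the worst-case
    background statistics of the replicate spots (the maxima), so the
    background filter errs toward removal.
    """

    values: pd.DataFrame
    bg_mean: pd.DataFrame
    bg_sd: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, frame in (("bg_mean", self.bg_mean), ("bg_sd", self.bg_sd)):
            if not frame.index.equals(self.values.index) or not frame.columns.equals(
                self.values.columns
            ):
                raise ValueError(f"{name} must be aligned with values")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def mean_intensity(self) -> pd.Series:
        return self.values.mean(axis=1)

    def subset(self, probes: Iterable[str]) -> "ProbeMatrix":
        probes = list(probes)
        ann = self.annotation.loc[probes] if self.annotation is not None else None
        return ProbeMatrix(
            self.values.loc[probes],
            self.bg_mean.loc[probes],
            self.bg_sd.loc[probes],
            ann,
        )


def read_spot_table(path: str | Path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return spots


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe")


def aggregate_spots(
    spots: pd.DataFrame, annotation: pd.DataFrame | None = None
) -> ProbeMatrix:
    """Geometrically average replicate spots into one value per (probe, sample)."""
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    bad = spots["intensity"] <= 0
    if bad.any():
        row = spots[bad].iloc[0]
        raise ValueError(
            f"nonpositive intensity {row['intensity']} at spot "
            f"(probe={row['probe']!r}, sample={row['sample']!r})"
        )
    grouped = spots.groupby(["probe", "sample"], sort=True)
    values = np.exp(grouped["intensity"].apply(lambda v: np.log(v).mean())).unstack()
    bg_mean = grouped["bg_mean"].max().unstack()
    bg_sd = grouped["bg_sd"].max().unstack()
    if annotation is not None:
        annotation = annotation.loc[values.index]
    return ProbeMatrix(values, bg_mean, bg_sd, annotation)


def filter_background(m: ProbeMatrix, k: float = 2.0) -> ProbeMatrix:
    """Keep probes exceeding ``bg_mean + k * bg_sd`` in at least one sample."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    above = m.values > (m.bg_mean + k * m.bg_sd)
    keep = above.any(axis=1)
    removed = list(m.values.index[~keep])
    if removed:
        log.info("background filter removed %d/%d probes: %s",
                 len(removed), len(keep), removed)
    return m.subset(m.values.index[keep])


def _correlation_scale(values: pd.DataFrame) -> pd.DataFrame:
    # correlations are computed on log intensities: ratio data are
    # multiplicative and the analysis-scale transform is monotone in the log
    return np.log(values)


def _single_linkage_clusters(corr: pd.DataFrame, r_min: float) -> list[list[str]]:
    probes = list(corr.index)
    parent = {p: p for p in probes}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, a in enumerate(probes):
        for b in probes[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_min:
                parent[find(a)] = find(b)
    clusters: dict[str, list[str]] = {}
    for p in probes:
        clusters.setdefault(find(p), []).append(p)
    return [sorted(c) for c in clusters.values()]


def collapse_orthologs(
    m: ProbeMatrix, r_min: float = 0.9
) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Collapse correlated probes within each ortholog bin.

    Probes in a bin are grouped by single linkage under the relation
    ``pearson r > r_min`` (on log intensities); each group is represented by
    its highest-mean-intensity probe (ties broken by the lexicographically
    smallest probe id).  Returns the reduced matrix and a report mapping
    every input probe to its representative.
    """
    if m.annotation is None or "bin" not in m.annotation.columns:
        raise ValueError("collapse_orthologs requires annotation with a 'bin' column")
    if len(m.samples) < 3:
        raise DegenerateDataError(
            "at least 3 samples are needed for correlation-based collapsing"
        )
    logged = _correlation_scale(m.values)
    means = m.mean_intensity()

    rows = []
    keep: list[str] = []
    for bin_id, ann in m.annotation.groupby("bin", sort=True):
        probes = sorted(set(ann.index) & set(m.values.index))
        if not probes:
            continue
        corr = logged.loc[probes].T.corr()
        for cluster in _single_linkage_clusters(corr, r_min):
            # representative: max mean intensity, then smallest id
            rep = min(cluster, key=lambda p: (-means[p], p))
            keep.append(rep)
            for p in cluster:
                rows.append({"probe": p, "bin": bin_id, "representative": rep,
                             "cluster_size": len(cluster)})
    report = pd.DataFrame(rows).set_index("probe").loc[
        [p for p in m.probes if p in {r["probe"] for r in rows}]
    ]
    keep = [p for p in m.probes if p in set(keep)]  # preserve input order
    return m.subset(keep), report


def probe_matrix_to_frame(m: ProbeMatrix) -> pd.DataFrame:
    """Transpose to the samples x probes orientation used for inference."""
    return m.values.T.copy()


def censor_and_transform(
    continuous: pd.DataFrame,
    detection_limits: Mapping[str, float] | None = None,
    censorable: Iterable[str] | None = None,
    discrete: pd.DataFrame | None = None,
    roles: Mapping[str, str] | None = None,
) -> VariableTable:
    """Apply detection-limit censoring and the eighth-root transform.

    A censorable value that is zero, or at or below its detection limit, is
    replaced by the limit (or ``1e-4`` when no limit is defined) and its
    paired censoring switch is set to 0; otherwise the switch is 1.  Values
    exactly at the limit count as censored.  All continuous values are then
    mapped through ``x -> x ** (1/8)``; discrete variables pass through
    untouched.
    """
    detection_limits = dict(detection_limits or {})
    for var, lim in detection_limits.items():
        if lim < 0:
            raise ValueError(f"negative detection limit for {var!r}")
    if (continuous < 0).any().any():
        bad = continuous.lt(0).any()
        raise ValueError(f"negative raw values in {list(bad[bad].index)}")
    censorable = set(censorable) if censorable is not None else set(detection_limits)

    cont = continuous.astype(float).copy()
    switch_frames = {}
    switches: dict[str, str] = {}
    for var in continuous.columns:
        if var not in censorable:
            continue
        limit = detection_limits.get(var, DEFAULT_CENSOR_VALUE)
        if limit <= 0:
            limit = DEFAULT_CENSOR_VALUE
        censored = (cont[var] == 0) | (cont[var] <= limit)
        cont.loc[censored, var] = limit
        sw = f"{var}__switch"
        switch_frames[sw] = (~censored).astype(int)
        switches[var] = sw

    if (cont <= 0).any().any():
        bad = cont.le(0).any()
        raise ValueError(
            f"nonpositive values in non-censorable variables {list(bad[bad].index)}"
        )
    cont = cont ** 0.125

    disc = pd.DataFrame(switch_frames, index=continuous.index, dtype=int)
    if discrete is not None:
        disc = pd.concat([discrete.astype(int), disc], axis=1)
    return VariableTable(cont, disc, roles=dict(roles or {}), switches=switches)


def build_variable_table(
    m: ProbeMatrix,
    metabolites: pd.DataFrame | None = None,
    setup: pd.DataFrame | None = None,
    detection_limits: Mapping[str, float] | None = None,
    discrete: pd.DataFrame | None = None,
) -> VariableTable:
    """Assemble transcripts + metabolites + setup parameters into one table.

    Transcript intensities are never censored (the background filter already
    removed undetected probes); metabolite columns are all censorable.
    """
    pieces = [probe_matrix_to_frame(m)]
    roles = {p: "transcript" for p in m.probes}
    censorable: set[str] = set()
    if metabolites is not None:
        pieces.append(metabolites)
        roles.update({c: "metabolite" for c in metabolites.columns})
        censorable |= set(metabolites.columns)
    if setup is not None:
        pieces.append(setup)
        roles.update({c: "setup" for c in setup.columns})
    continuous = pd.concat(pieces, axis=1)
    return censor_and_transform(
        continuous, detection_limits, censorable, discrete, roles
    )
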