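"""Mixed-type variable tables: the common currency of the pipeline.

A :class:`VariableTable` holds, per sample, the continuous variables that can
become network nodes (transcript intensities, metabolite concentrations,
respiration rates, experimental setup parameters — all on the eighth-root
analysis scale) together with the discrete variables (censoring switches,
binary culture-state operators, tiered electron-acceptor/donor codes) that
may act as modulators of node-node relationships but never as nodes
themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: recognised roles for continuous variables
ROLES = ("transcript", "metabolite", "rate", "setup")


@dataclass
class VariableTable:
    """Per-sample table of continuous network variables and discrete modulators.

    Parameters
    ----------
    continuous
        samples x variables frame of continuous values on the analysis
        (eighth-root) scale.
    discrete
        samples x variables frame of integer-coded discrete variables,
        including censoring switches.  May be empty.
    roles
        map variable name -> one of :data:`ROLES`; variables missing from
        the map are treated as transcripts.
    switches
        map censorable continuous variable -> name of its paired censoring
        switch column in ``discrete``.
    """

    continuous: pd.DataFrame
    discrete: pd.DataFrame = None
    roles: dict[str, str] = field(default_factory=dict)
    switches: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discrete is None:
            self.discrete = pd.DataFrame(index=self.continuous.index)
        if not self.continuous.index.equals(self.discrete.index):
            raise ValueError("continuous and discrete tables must share a sample index")
        for role in self.roles.values():
            if role not in ROLES:
                raise ValueError(f"unknown variable role {role!r}")
        for var, sw in self.switches.items():
            if var not in self.continuous.columns:
                raise ValueError(f"switch declared for unknown variable {var!r}")
            if sw not in self.discrete.columns:
                raise ValueError(f"missing switch column {sw!r} for variable {var!r}")
            levels = set(self.discrete[sw].unique())
            if not levels <= {0, 1}:
                raise ValueError(f"censoring switch {sw!r} must be binary 0/1, got {levels}")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.continuous.index)

    @property
    def continuous_vars(self) -> list[str]:
        return list(self.continuous.columns)

    @property
    def discrete_vars(self) -> list[str]:
        return list(self.discrete.columns)

    def role_of(self, var: str) -> str:
        return self.roles.get(var, "transcript")

    # -- IO --------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write one TSV of continuous + paired switch + other discrete columns.

        Roles and the variable/switch pairing go to a ``.meta.json`` sidecar
        so the table round-trips.
        """
        path = Path(path)
        table = pd.concat([self.continuous, self.discrete], axis=1)
        table.to_csv(path, sep="\t", index_label="sample")
        meta = {
            "roles": self.roles,
            "switches": self.switches,
            "continuous": list(self.continuous.columns),
            "discrete": list(self.discrete.columns),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariableTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        table = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(
            continuous=table[meta["continuous"]],
            discrete=table[meta["discrete"]].astype(int),
            roles=meta["roles"],
            switches=meta["switches"],
        )
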