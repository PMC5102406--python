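"""Minimal reader for GEO series-matrix text files.

A series matrix stores ``!``-prefixed metadata lines followed by a
tab-separated probe x sample block delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``.  Only the
value block and the sample titles are extracted — enough to feed already
normalized intensity matrices into the preprocessing stage.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd


def _open(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Return (probe x sample values, metadata dict of ``!Series/!Sample`` lines)."""
    path = Path(path)
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line.partition("\t")
                values = [v.strip('"') for v in rest.split("\t")] if rest else []
                meta.setdefault(key.lstrip("!"), []).extend(values)
    if not table_lines:
        raise ValueError(f"{path} contains no series-matrix table")
    header = [h.strip('"') for h in table_lines[0].split("\t")]
    rows = [ln.split("\t") for ln in table_lines[1:]]
    frame = pd.DataFrame(rows, columns=header)
    frame.iloc[:, 0] = frame.iloc[:, 0].str.strip('"')
    frame = frame.set_index(header[0])
    frame = frame.apply(pd.to_numeric, errors="coerce")
    return frame, meta
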