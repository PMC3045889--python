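"""Flat-file serialization of count matrices and result tables.

The count matrix travels as TSV with a ``#library`` metadata header block
(one line per library: id, organ, condition, total_tags), followed by
``unitag_id``, ``sequence`` and one integer column per library.  Normalized
values are rounded to two decimals at serialization only.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .tags import Library, TagCountMatrix


def write_counts(matrix: TagCountMatrix, path: str | Path) -> None:
    with open(path, "w") as handle:
        for lib in matrix.libraries:
            handle.write(
                f"#library\t{lib.id}\t{lib.organ}\t{lib.condition}\t{lib.total_tags}\n"
            )
        frame = matrix.counts.copy()
        frame.insert(0, "sequence", matrix.sequences)
        frame.index.name = "unitag_id"
        frame.to_csv(handle, sep="\t")


def read_counts(path: str | Path) -> TagCountMatrix:
    libraries: list[Library] = []
    body_lines: list[str] = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#library\t"):
                _, lib_id, organ, condition, total = line.rstrip("\n").split("\t")
                libraries.append(Library(lib_id, organ, condition, int(total)))
            else:
                body_lines.append(line)
    frame = pd.read_csv(_io.StringIO("".join(body_lines)), sep="\t", index_col="unitag_id")
    sequences = frame.pop("sequence")
    matrix = TagCountMatrix(frame, sequences, libraries)
    for declared, actual in zip(libraries, matrix.libraries):
        if declared.total_tags != actual.total_tags:
            raise ValueError(
                f"library {declared.id}: declared total {declared.total_tags} "
                f"!= column sum {actual.total_tags}"
            )
    return matrix


def write_table(frame: pd.DataFrame, path: str | Path, round_decimals: int | None = 2) -> None:
    """Write a result table as TSV, rounding float columns for display."""
    out = frame.copy()
    if round_decimals is not None:
        for col in out.columns:
            if out[col].dtype.kind == "f" and col not in ("p_value", "p", "evalue", "p_bh"):
                out[col] = out[col].round(round_decimals)
    out.to_csv(path, sep="\t")
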