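"""Tabular I/O: labeled TSV matrices, GMT gene sets, cohort tables.

All tabular exchange uses TSV with explicit headers; gene sets use the GMT
convention (set name, description, then tab-separated members, one set per
line); manifests and results are JSON.  Floating-point output uses a fixed
"%.10g" format so reruns are byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import GeneSet
from .synthetic.cohort import CohortTable

FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    pass


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "region") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix_tsv(path, orientation: str = "rows") -> pd.DataFrame:
    """Labeled numeric matrix from TSV (header row + label column).

    ``orientation="columns"`` transposes after reading.  Non-numeric cells
    raise a :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty input file")
    lines = text.splitlines()
    header = lines[0].split("\t")
    n_cols = len(header)
    rows, labels = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})"
            )
        labels.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    df = pd.DataFrame(rows, index=labels, columns=header[1:])
    df.index.name = header[0]
    return df.T if orientation == "columns" else df


def write_gmt(sets: list[GeneSet], path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = (descriptions or {}).get(s.name, s.provenance)
            fh.write("\t".join([s.name, desc, *s.members]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    """GMT gene sets; duplicate members are dropped with a warning."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, _desc, *members = parts
        unique = list(dict.fromkeys(members))
        if len(unique) < len(members):
            warnings.warn(f"{name}: duplicate members deduplicated", stacklevel=2)
        out.append(GeneSet(name=name, members=unique))
    return out


def write_cohort_tsv(cohort: CohortTable, features_path, covariates_path) -> None:
    long = cohort.to_long_frame()
    long.to_csv(features_path, sep="\t", index=False, float_format=FLOAT_FMT)
    cohort.covariates.to_csv(
        covariates_path, sep="\t", index_label="subject", float_format=FLOAT_FMT
    )


def read_cohort_tsv(features_path, covariates_path) -> CohortTable:
    long = pd.read_csv(features_path, sep="\t")
    cov = pd.read_csv(covariates_path, sep="\t", index_col="subject")
    cov.index = cov.index.astype(str)
    long["subject"] = long["subject"].astype(str)
    return CohortTable.from_long_frame(long, cov)
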