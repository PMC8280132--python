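"""Flat-file readers and writers shared across the pipeline.

All tabular artifacts are plain TSV. Lines starting with ``#`` are
comments; writers emit a single leading comment line naming the columns
so files remain self-describing while staying header-free for parsers.
Gene-set collections use the standard GMT layout (name, description,
then one gene per tab-separated field).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError


def read_tsv(path: os.PathLike | str, columns: list[str]) -> pd.DataFrame:
    """Read a comment-prefixed, header-free TSV into named columns."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=columns, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=columns)
    if df.shape[1] != len(columns):
        raise ParseError(f"{path}: expected {len(columns)} columns, got {df.shape[1]}")
    return df


def write_tsv(path: os.PathLike | str, df: pd.DataFrame, float_format: str = "%.10g") -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def read_gmt(path: os.PathLike | str) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into ``{name: (description, genes)}`` (insertion-ordered)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = (desc, frozenset(genes))
    return sets


def write_gmt(path: os.PathLike | str, sets: Mapping[str, tuple[str, Iterable[str]]]) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_interactions(path: os.PathLike | str) -> pd.DataFrame:
    """Read a scored interaction list (protein_a, protein_b, score).

    Scores must parse as floats in [0, 1]; the first offending line is
    reported by number. Pairs are canonicalized (a < b) and duplicate
    unordered pairs collapse to their maximum score. Self-loops are
    dropped: a protein's interaction with itself carries no edge in a
    simple interaction graph.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, raw_score = fields
            try:
                score = float(raw_score)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed score {raw_score!r}") from None
            if not 0.0 <= score <= 1.0:
                raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1]")
            if a == b:
                continue
            if b < a:
                a, b = b, a
            rows.append((a, b, score))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])
    if not df.empty:
        df = (
            df.groupby(["protein_a", "protein_b"], as_index=False)["score"]
            .max()
            .sort_values(["protein_a", "protein_b"], ignore_index=True)
        )
    return df


def read_gene_list(path: os.PathLike | str) -> frozenset[str]:
    """Read a one-identifier-per-line list (e.g. reference disease genes)."""
    genes = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return frozenset(genes)


def write_gene_list(path: os.PathLike | str, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
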