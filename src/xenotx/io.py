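"""Readers and writers for the pipeline's plain-text formats.

All formats are tab-separated text: count matrices (genes x samples,
first column ``gene``), two-column ortholog tables, GMT gene-set files
(plain and a signed dialect whose member tokens are ``GENE,+1`` /
``GENE,-1``), SIF-like signed graphs (``source TAB relation TAB target``)
and JSON ground truth.  Writers emit deterministic byte streams (fixed
column order, ``%.10g`` floats, ``\\n`` line endings) so that repeated
runs under one seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd

PathLike = Union[str, Path]

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_gmt",
    "write_gmt",
    "read_signed_gmt",
    "write_signed_gmt",
    "read_sif",
    "write_sif",
    "read_json",
    "write_json",
]


def _fmt(x) -> str:
    """Deterministic cell formatting: integers bare, floats at 10 sig figs."""
    if isinstance(x, float):
        if x == int(x) and abs(x) < 1e15:
            return str(int(x))
        return "%.10g" % x
    return str(x)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: PathLike) -> pd.DataFrame:
    """Read a genes x samples TSV whose first column is ``gene``.

    Raises ``ValueError`` on duplicate gene symbols or non-numeric cells.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    df.index = df.index.str.strip()
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene symbols: {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric cell: {e}") from e
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts are not allowed")
    return df


def write_count_matrix(df: pd.DataFrame, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in zip(df.index, df.values):
            fh.write(str(gene) + "\t" + "\t".join(_fmt(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# ortholog table


def read_ortholog_table(path: PathLike) -> pd.DataFrame:
    """Two-column TSV with header ``human TAB mouse``; must be one-to-one."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["human", "mouse"]:
        raise ValueError(f"{path}: expected header 'human\\tmouse', got {list(df.columns)}")
    df = df[["human", "mouse"]].apply(lambda c: c.str.strip())
    for col in ("human", "mouse"):
        if df[col].duplicated().any():
            dups = sorted(df[col][df[col].duplicated()].unique())
            raise ValueError(f"{path}: ortholog table not one-to-one; duplicate {col} symbols {dups[:5]}")
    return df.reset_index(drop=True)


def write_ortholog_table(df: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("human\tmouse\n")
        for h, m in zip(df["human"], df["mouse"]):
            fh.write(f"{h}\t{m}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    """Standard GMT: set name, description, then member genes."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"{path}:{lineno}: duplicate genes in set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: PathLike, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", newline="\n") as fh:
        for name in sets:
            desc = descriptions.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(sets[name]) + "\n")


def read_signed_gmt(path: PathLike) -> Dict[str, List[Tuple[str, int]]]:
    """Signed-GMT dialect: member tokens are ``GENE,+1`` / ``GENE,-1``."""
    db: Dict[str, List[Tuple[str, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: signed GMT line needs name, description, >=1 token")
            name = parts[0]
            members: List[Tuple[str, int]] = []
            for tok in parts[2:]:
                if not tok:
                    continue
                try:
                    gene, d = tok.rsplit(",", 1)
                    direction = int(d)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: bad token {tok!r} (want GENE,+1 or GENE,-1)") from e
                if direction not in (1, -1):
                    raise ValueError(f"{path}:{lineno}: direction must be +1 or -1, got {direction}")
                members.append((gene, direction))
            genes = [g for g, _ in members]
            if len(set(genes)) != len(genes):
                raise ValueError(f"{path}:{lineno}: duplicate gene in signature {name!r}")
            db[name] = members
    return db


def write_signed_gmt(db: Mapping[str, Sequence[Tuple[str, int]]], path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in db:
            toks = [f"{g},{'+1' if d > 0 else '-1'}" for g, d in db[name]]
            fh.write(name + "\tna\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# SIF-like signed graphs

RELATION_SIGNS = {"increases": 1, "decreases": -1}
SIGN_RELATIONS = {1: "increases", -1: "decreases"}

# BEL relation synonyms normalized onto the two supported relations.
RELATION_SYNONYMS = {
    "increases": "increases",
    "directlyIncreases": "increases",
    "->": "increases",
    "=>": "increases",
    "decreases": "decreases",
    "directlyDecreases": "decreases",
    "-|": "decreases",
    "=|": "decreases",
}


def read_sif(path: PathLike, synonyms: Mapping[str, str] | None = None) -> List[Tuple[str, int, str]]:
    """Read (source, sign, target) triples from a SIF-like TSV."""
    synonyms = dict(RELATION_SYNONYMS, **(synonyms or {}))
    edges: List[Tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'source\\trelation\\ttarget'")
            src, rel, dst = (p.strip() for p in parts)
            if rel not in synonyms:
                raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}")
            edges.append((src, RELATION_SIGNS[synonyms[rel]], dst))
    return edges


def write_sif(edges: Iterable[Tuple[str, int, str]], path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for src, sign, dst in edges:
            fh.write(f"{src}\t{SIGN_RELATIONS[sign]}\t{dst}\n")


# ---------------------------------------------------------------------------
# JSON


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
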