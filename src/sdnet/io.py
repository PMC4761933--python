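"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are UTF-8 TSV with Unix newlines, tolerate ``#``-comment
lines, and reject malformed rows with line-numbered errors.  Gene symbols
are uppercased on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .expression import ExpressionMatrix
from .network import InteractionTable, canonical_symbol
from .topology import MEASURES, TopologyProfile


class FormatError(ValueError):
    """Malformed input row, reported with its path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_seed_list(path) -> list[str]:
    """One gene symbol per line."""
    seeds = []
    for lineno, line in _data_lines(path):
        sym = canonical_symbol(line)
        if not sym or "\t" in sym:
            raise FormatError(path, lineno, f"invalid gene symbol {line!r}")
        seeds.append(sym)
    if not seeds:
        raise FormatError(path, 0, "seed list is empty")
    return seeds


def write_seed_list(seeds, path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in seeds), encoding="utf-8")


def read_interactions(path) -> InteractionTable:
    """3-column TSV: protein_a, protein_b, grade (header required)."""
    records, header_seen = [], False
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if not header_seen:
            if [p.strip().lower() for p in parts[:3]] != ["protein_a", "protein_b", "grade"]:
                raise FormatError(path, lineno,
                                  "expected header 'protein_a\\tprotein_b\\tgrade'")
            header_seen = True
            continue
        if len(parts) != 3:
            raise FormatError(path, lineno, f"expected 3 columns, got {len(parts)}")
        a, b, grade = parts
        try:
            grade = int(grade)
        except ValueError:
            raise FormatError(path, lineno, f"grade {grade!r} is not an integer") from None
        if not 1 <= grade <= 5:
            raise FormatError(path, lineno, f"grade {grade} outside 1..5")
        records.append((a, b, grade))
    if not header_seen:
        raise FormatError(path, 0, "empty interaction table")
    return InteractionTable.from_records(records)


def write_interactions(table: InteractionTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_a\tprotein_b\tgrade\n")
        for r in table:
            fh.write(f"{r.protein_a}\t{r.protein_b}\t{r.grade}\n")


def read_edgelist(path) -> nx.Graph:
    """2-column edge-list TSV (header required)."""
    g = nx.Graph()
    header_seen = False
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if not header_seen:
            header_seen = True
            continue
        if len(parts) != 2:
            raise FormatError(path, lineno, f"expected 2 columns, got {len(parts)}")
        a, b = (canonical_symbol(p) for p in parts)
        if a == b:
            raise FormatError(path, lineno, f"self-loop on {a}")
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise FormatError(path, 0, "edge list is empty")
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_topology(profile: TopologyProfile, path) -> None:
    df = profile.to_frame()
    df.index.name = "node"
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_topology(path) -> TopologyProfile:
    df = pd.read_csv(path, sep="\t", index_col="node", comment="#")
    missing = [m for m in MEASURES if m not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing topology columns: {missing}")
    df.index = df.index.map(canonical_symbol)
    return TopologyProfile.from_frame(df)


def read_expression(expr_path, pheno_path) -> ExpressionMatrix:
    """Expression TSV (rows genes, columns samples) + phenotype TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    if values.empty:
        raise FormatError(expr_path, 0, "empty expression matrix")
    values.index = values.index.map(canonical_symbol)
    values.index.name = "gene"
    pheno = pd.read_csv(pheno_path, sep="\t", comment="#")
    cols = [c.strip().lower() for c in pheno.columns]
    if cols[:2] != ["sample", "label"]:
        raise FormatError(pheno_path, 1, "expected phenotype header 'sample\\tlabel'")
    labels = pd.Series(pheno.iloc[:, 1].values, index=pheno.iloc[:, 0].astype(str))
    return ExpressionMatrix(values=values, labels=labels)


def write_expression(m: ExpressionMatrix, expr_path, pheno_path) -> None:
    m.values.to_csv(expr_path, sep="\t", lineterminator="\n", float_format="%.10g")
    pd.DataFrame({"sample": m.labels.index, "label": m.labels.values}).to_csv(
        pheno_path, sep="\t", index=False, lineterminator="\n"
    )


def read_fold_table(path) -> pd.DataFrame:
    """Protein fold-change TSV: protein, fold, peptides."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["protein", "fold", "peptides"]:
        raise FormatError(path, 1, "expected header 'protein\\tfold\\tpeptides'")
    df.columns = cols
    df["protein"] = df["protein"].map(canonical_symbol)
    return df.set_index("protein")


def write_fold_table(df: pd.DataFrame, path) -> None:
    out = df.reset_index()[["protein", "fold", "peptides"]]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: term, description, then member symbols."""
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(path, lineno, "GMT rows need term, description, >=1 gene")
        sets[parts[0]] = {canonical_symbol(g) for g in parts[2:] if g.strip()}
    return sets


def read_gene_list(path) -> list[str]:
    return read_seed_list(path)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
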