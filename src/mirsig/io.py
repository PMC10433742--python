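"""Readers and writers for every on-disk format the pipeline touches.

Formats: plain tab-delimited gene × sample matrices, GEO series-matrix text
exports, GMT / one-symbol-per-line gene-set files, Cluster 3.0 CDT/GTR/ATR
dendrogram output, and a two-column sample→group table. All output uses period
decimals and roundtrips losslessly at 6 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line."""


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------


@dataclass
class TargetCollection:
    """Named gene-symbol sets (miR targets, RBP targets, annotation terms).

    ``background`` is the "whole chip": the universe against which every
    enrichment is evaluated. It defaults to the union of the sets but should
    normally be the gene list of the processed expression matrix.
    """

    sets: dict[str, set[str]]
    background: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set().union(*self.sets.values()) if self.sets else set()
        if not self.background:
            raise ValueError("target collection background is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetCollection):
            return NotImplemented
        return self.sets == other.sets and self.background == other.background


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _to_numeric_or_raise(table: pd.DataFrame, path) -> pd.DataFrame:
    """Coerce to float, raising a ParseError naming the first bad cell."""
    try:
        return table.astype(float)
    except (ValueError, TypeError):
        for col in table.columns:
            coerced = pd.to_numeric(table[col], errors="coerce")
            raw_na = table[col].isna()
            bad = coerced.isna() & ~raw_na
            if bad.any():
                gene = table.index[np.flatnonzero(bad.to_numpy())[0]]
                val = table.loc[gene, col]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: {val!r}"
                )
        raise ParseError(f"{path}: table could not be coerced to numeric")


def read_expression_matrix(
    path, format: str = "tsv", groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a gene × sample matrix from a TSV file or a GEO series-matrix export.

    For ``series_matrix``, header lines starting with ``!`` are parsed into
    sample annotations and the delimited region between
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` is read as the
    value table.
    """
    path = Path(path)
    if format == "tsv":
        table = pd.read_csv(path, sep="\t", index_col=0)
        table.index = table.index.astype(str)
        return ExpressionMatrix(_to_numeric_or_raise(table, path), groups)
    if format == "series_matrix":
        return _read_series_matrix(path, groups)
    raise ValueError(f"unknown expression format {format!r}")


def _unquote(token: str) -> str:
    return token.strip().strip('"')


def _read_series_matrix(path: Path, groups: pd.Series | None) -> ExpressionMatrix:
    annotations: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                if rest:
                    annotations.setdefault(key, []).extend(
                        _unquote(t) for t in rest.split("\t")
                    )
    if not table_lines:
        raise ParseError(f"{path}: no !series_matrix_table_begin/end block found")
    header = [_unquote(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids in series-matrix header")
    rows, index = [], []
    for offset, line in enumerate(table_lines[1:], start=2):
        fields = [_unquote(t) for t in line.split("\t")]
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: table row {offset} has {len(fields)} fields, expected {len(header)}"
            )
        index.append(fields[0])
        rows.append(fields[1:])
    table = pd.DataFrame(rows, index=index, columns=sample_ids)
    table = table.replace({"null": np.nan, "NULL": np.nan, "": np.nan})
    matrix = ExpressionMatrix(_to_numeric_or_raise(table, path), groups)
    matrix.sample_annotations = {
        k: v for k, v in annotations.items() if k.startswith("Sample_")
    }
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path, label: str = "GENE") -> None:
    values = matrix.values.copy()
    values.index.name = label
    values.to_csv(path, sep="\t", float_format="%.6g")


def read_groups(path) -> pd.Series:
    """Two-column TSV (sample, group) → sample-indexed label series."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if table["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in group file")
    return pd.Series(table["group"].values, index=table["sample"].values, name="group")


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def collapse_probes_to_genes(
    matrix: ExpressionMatrix,
    probe2gene: Mapping[str, str],
    method: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``max_mean`` (default) keeps, for each gene, the probe with the highest mean
    expression; ``mean`` averages all probes of a gene. Probes absent from the
    map are dropped and counted in the log.
    """
    values = matrix.values
    mapped = [p for p in values.index if probe2gene.get(p)]
    n_dropped = len(values.index) - len(mapped)
    if n_dropped:
        log.info("collapse_probes_to_genes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probes map to a gene symbol")
    sub = values.loc[mapped]
    genes = pd.Series([probe2gene[p] for p in mapped], index=sub.index)
    if method == "max_mean":
        means = sub.mean(axis=1)
        best = means.groupby(genes).idxmax()
        collapsed = sub.loc[best.values]
        collapsed.index = best.index
    elif method == "mean":
        collapsed = sub.groupby(genes).mean()
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    collapsed = collapsed.sort_index()
    log.info(
        "collapse_probes_to_genes: %d probes -> %d genes", len(mapped), len(collapsed)
    )
    return ExpressionMatrix(collapsed, matrix.groups)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(
    path, format: str = "gmt", background: Iterable[str] | None = None
) -> TargetCollection:
    """Read a GMT file (name, description, members...) or a one-symbol-per-line list."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    if format == "gmt":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: GMT row has fewer than 2 fields")
                name, desc, members = fields[0], fields[1], fields[2:]
                sets[name] = {m.strip() for m in members if m.strip()}
                descriptions[name] = desc
                if not sets[name]:
                    log.warning("gene set %r is empty (retained)", name)
    elif format == "list":
        with open(path) as fh:
            members = {line.strip() for line in fh if line.strip()}
        sets[path.stem] = members
        if not members:
            log.warning("gene list %s is empty (retained)", path)
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    bg = set(background) if background is not None else set()
    return TargetCollection(sets, bg, descriptions)


def write_gene_sets(collection: TargetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Cluster 3.0 CDT / GTR / ATR
# ---------------------------------------------------------------------------


def _write_tree_file(path, Z: np.ndarray, leaf_ids: list[str], kind: str) -> None:
    """One merge per row: NODEnX <tab> child <tab> child <tab> similarity.

    ``kind`` is GENE for gene trees (GTR) or ARRY for sample trees (ATR);
    similarity is 1 − merge distance, matching Cluster 3.0's convention.
    """
    n = len(leaf_ids)

    def node_name(idx: int) -> str:
        if idx < n:
            return f"{kind}{idx}X"
        return f"NODE{idx - n + 1}X"

    with open(path, "w") as fh:
        for i, (a, b, height, _) in enumerate(Z, start=1):
            fh.write(
                f"NODE{i}X\t{node_name(int(a))}\t{node_name(int(b))}\t{1.0 - height:.6g}\n"
            )


def write_clustered_output(
    matrix: ExpressionMatrix,
    gene_tree,
    sample_tree,
    path_prefix,
) -> list[Path]:
    """Emit Cluster 3.0 CDT (+ GTR/ATR when trees are given) for a clustered matrix.

    CDT rows follow the gene-tree leaf order and columns the sample-tree leaf
    order, so heat-map viewers (Java TreeView etc.) reproduce the dendrogram.
    """
    from scipy.cluster.hierarchy import leaves_list

    prefix = Path(path_prefix)
    written: list[Path] = []
    gene_order = np.arange(matrix.n_genes)
    sample_order = np.arange(matrix.n_samples)
    if gene_tree is not None:
        if len(gene_tree.leaf_ids) != matrix.n_genes or gene_tree.leaf_ids != matrix.gene_ids:
            raise ValueError("gene tree leaves do not match matrix genes")
        gene_order = leaves_list(gene_tree.Z)
        gtr = prefix.with_suffix(".gtr")
        _write_tree_file(gtr, gene_tree.Z, gene_tree.leaf_ids, "GENE")
        written.append(gtr)
    if sample_tree is not None:
        if len(sample_tree.leaf_ids) != matrix.n_samples or sample_tree.leaf_ids != matrix.sample_ids:
            raise ValueError("sample tree leaves do not match matrix samples")
        sample_order = leaves_list(sample_tree.Z)
        atr = prefix.with_suffix(".atr")
        _write_tree_file(atr, sample_tree.Z, sample_tree.leaf_ids, "ARRY")
        written.append(atr)

    cdt = prefix.with_suffix(".cdt")
    genes = [matrix.gene_ids[i] for i in gene_order]
    samples = [matrix.sample_ids[j] for j in sample_order]
    values = matrix.values.to_numpy()[np.ix_(gene_order, sample_order)]
    with open(cdt, "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(samples) + "\n")
        if sample_tree is not None:
            fh.write("AID\t\t\t\t" + "\t".join(f"ARRY{j}X" for j in sample_order) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in samples) + "\n")
        for pos, (i, gene) in enumerate(zip(gene_order, genes)):
            row = "\t".join(f"{v:.6g}" for v in values[pos])
            fh.write(f"GENE{i}X\t{gene}\t{gene}\t1\t{row}\n")
    written.append(cdt)
    return written
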