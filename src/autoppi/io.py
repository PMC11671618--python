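"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* pair lists: 2 or 3 tab-separated columns (``a<TAB>b[<TAB>label]``),
  optional header auto-detected;
* annotation tables: long-format TSV ``protein<TAB>term`` and GMT
  gene-set files (``term<TAB>description<TAB>member...``);
* expression matrices: TSV, first column gene id, header of sample names;
* networks: edge-list TSV, SIF (``a<TAB>pp<TAB>b``, the Cytoscape simple
  interaction dialect) and GraphML.

All writers are atomic (write to a temporary file, then rename) so a
crashed run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import networkx as nx
import pandas as pd

from .catalogs import AnnotationCatalog
from .pairs import POSITIVE, NEGATIVE, PairRecord, SelfPairError

log = logging.getLogger("autoppi")

_HEADER_TOKENS = {
    "protein_a", "protein_b", "protein1", "protein2",
    "source", "target", "node1", "node2", "label", "score", "gene_a", "gene_b",
}

NETWORK_FORMATS = ("edgelist", "sif", "graphml")
SIF_RELATION = "pp"


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def read_pair_list(path: str | Path, labeled: bool = False) -> list[PairRecord]:
    """Read a tab-delimited pair list into canonical :class:`PairRecord` s.

    Duplicate pairs (after canonicalization) are collapsed; self-pairs
    are rejected with a warning but do not abort the run.  With
    ``labeled=True`` a third column holding ``positive``/``negative`` is
    required.
    """
    path = Path(path)
    records: dict[tuple[str, str], PairRecord] = {}
    n_dup = n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated "
                                 f"columns, got {len(fields)}")
            label = None
            if labeled:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: labeled pair list needs a third column")
                label = fields[2].strip().lower()
                if label not in (POSITIVE, NEGATIVE):
                    raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            try:
                rec = PairRecord(fields[0], fields[1], label=label)
            except SelfPairError:
                log.warning("%s:%d: self-pair %r rejected", path, lineno, fields[0].strip())
                n_self += 1
                continue
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if rec.pair in records:
                n_dup += 1
            else:
                records[rec.pair] = rec
    if n_dup:
        log.info("read_pair_list(%s): collapsed %d duplicate pairs", path, n_dup)
    if n_self:
        log.warning("read_pair_list(%s): rejected %d self-pairs", path, n_self)
    return list(records.values())


def write_pair_list(records, path: str | Path, labeled: bool = False,
                    scores: bool = False) -> None:
    """Write records (PairRecord or plain 2-tuples) as a TSV pair list."""
    lines = []
    for rec in records:
        if not isinstance(rec, PairRecord):
            rec = PairRecord(rec[0], rec[1])
        fields = [rec.protein_a, rec.protein_b]
        if labeled:
            fields.append(rec.label or "")
        if scores:
            fields.append("" if rec.score is None else f"{rec.score:.6g}")
        lines.append("\t".join(fields))
    _atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_annotation_table(path: str | Path, namespace: str = "GO") -> AnnotationCatalog:
    """Read a long-format ``protein<TAB>term[<TAB>term name]`` TSV."""
    path = Path(path)
    associations: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in ("protein", "gene", "id"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected protein<TAB>term")
            associations.append((fields[0], fields[1]))
            if len(fields) >= 3 and fields[2].strip():
                names[fields[1].strip()] = fields[2].strip()
    if not associations:
        raise ValueError(f"{path}: empty annotation table")
    return AnnotationCatalog(associations, namespace=namespace, term_names=names or None)


def write_annotation_table(catalog: AnnotationCatalog, path: str | Path) -> None:
    lines = []
    for protein, term in catalog.associations():
        name = catalog.term_name(term)
        if name != term:
            lines.append(f"{protein}\t{term}\t{name}")
        else:
            lines.append(f"{protein}\t{term}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


def read_gmt(path: str | Path, namespace: str = "GO") -> AnnotationCatalog:
    """Read a GMT gene-set file (``term<TAB>description<TAB>member...``)."""
    path = Path(path)
    associations: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description "
                                 f"and at least one member")
            term, desc = fields[0].strip(), fields[1].strip()
            if desc and desc != term:
                names[term] = desc
            for member in fields[2:]:
                if member.strip():
                    associations.append((member, term))
    if not associations:
        raise ValueError(f"{path}: empty GMT file")
    return AnnotationCatalog(associations, namespace=namespace, term_names=names or None)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    Missing cells (empty or NA) stay missing (NaN), they are never
    silently treated as zero expression.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expression matrix needs >= 3 samples for Pearson "
                         f"correlation, got {df.shape[1]}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers: {dups[:5]}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", index_label="gene"))


# -- networks ------------------------------------------------------------

def write_network(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export an interaction graph in a Cytoscape-ingestible format."""
    if graph.number_of_edges() == 0:
        raise ValueError("refusing to write an empty network")
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; supported: "
                         f"{', '.join(NETWORK_FORMATS)}")
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    if fmt == "edgelist":
        _atomic_write_text(path, "\n".join(f"{a}\t{b}" for a, b in edges) + "\n")
    elif fmt == "sif":
        _atomic_write_text(path, "\n".join(f"{a}\t{SIF_RELATION}\t{b}" for a, b in edges) + "\n")
    else:  # graphml
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(graph, path)


def read_edgelist(path: str | Path) -> nx.Graph:
    records = read_pair_list(path, labeled=False)
    g = nx.Graph()
    g.add_edges_from(r.pair for r in records)
    return g


def write_json_report(report: dict, path: str | Path) -> None:
    _atomic_write_text(path, json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
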