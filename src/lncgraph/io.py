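"""Readers and writers for every on-disk format.

This module is the single place where file dialects are defined:

* **edge-list TSV** for associations and omic links — two ID columns,
  ``#``-prefixed comments; the directives ``#rows:``/``#cols:`` (associations)
  or ``#left:``/``#right:`` (links) enumerate the full entity universes so
  entities with no edges survive a round trip. Without directives the
  universes are inferred from the edges.
* **dense similarity TSV** — first row and first column are entity IDs.
* **ontology TSV** — ``child<TAB>parent`` rows.
* **prediction TSV** — header ``lncrna_id disease_id score label fold``.

Row/column order is lexicographic by ID everywhere; two reads of the same
file always produce identical orderings. Duplicate edges are de-duplicated
with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from lncgraph.types import (
    AssociationMatrix,
    OmicLinkTable,
    OntologyTable,
    SimilarityMatrix,
)

logger = logging.getLogger("lncgraph")


def _parse_edge_file(path: Path) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    edges: list[tuple[str, str]] = []
    directives: dict[str, list[str]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            for key in ("rows", "cols", "left", "right"):
                prefix = f"#{key}:"
                if line.startswith(prefix):
                    directives[key] = [t for t in line[len(prefix):].split("\t") if t]
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated IDs, got {len(parts)}")
        edges.append((parts[0], parts[1]))
    return edges, directives


def _edges_to_matrix(
    edges: list[tuple[str, str]],
    left_universe: list[str] | None,
    right_universe: list[str] | None,
    path: Path,
) -> tuple[list[str], list[str], np.ndarray]:
    left = sorted(left_universe) if left_universe is not None else sorted({a for a, _ in edges})
    right = sorted(right_universe) if right_universe is not None else sorted({b for _, b in edges})
    li = {v: i for i, v in enumerate(left)}
    ri = {v: i for i, v in enumerate(right)}
    values = np.zeros((len(left), len(right)), dtype=np.int8)
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for a, b in edges:
        if a not in li or b not in ri:
            raise ValueError(f"{path}: edge ({a}, {b}) references an ID outside the declared universe")
        if (a, b) in seen:
            n_dup += 1
            continue
        seen.add((a, b))
        values[li[a], ri[b]] = 1
    if n_dup:
        logger.warning("%s: %d duplicate edge row(s) de-duplicated", path, n_dup)
    return left, right, values


def read_associations(path: str | Path) -> AssociationMatrix:
    path = Path(path)
    edges, directives = _parse_edge_file(path)
    left, right, values = _edges_to_matrix(
        edges, directives.get("rows"), directives.get("cols"), path
    )
    return AssociationMatrix(left, right, values).validate()


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = ["# lncRNA-disease association edge list"]
    lines.append("#rows:\t" + "\t".join(assoc.lncrna_ids))
    lines.append("#cols:\t" + "\t".join(assoc.disease_ids))
    rows, cols = np.nonzero(assoc.values)
    for i, j in zip(rows, cols):
        lines.append(f"{assoc.lncrna_ids[i]}\t{assoc.disease_ids[j]}")
    path.write_text("\n".join(lines) + "\n")


def read_links(path: str | Path, view_name: str) -> OmicLinkTable:
    path = Path(path)
    edges, directives = _parse_edge_file(path)
    left, right, values = _edges_to_matrix(
        edges, directives.get("left"), directives.get("right"), path
    )
    return OmicLinkTable(view_name, left, right, values).validate()


def write_links(table: OmicLinkTable, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# omic link edge list: {table.view_name}"]
    lines.append("#left:\t" + "\t".join(table.left_ids))
    lines.append("#right:\t" + "\t".join(table.right_ids))
    rows, cols = np.nonzero(table.links)
    for i, j in zip(rows, cols):
        lines.append(f"{table.left_ids[i]}\t{table.right_ids[j]}")
    path.write_text("\n".join(lines) + "\n")


def read_ontology(path: str | Path) -> OntologyTable:
    path = Path(path)
    edges, _ = _parse_edge_file(path)
    deduped: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for e in edges:
        if e in seen:
            logger.warning("%s: duplicate ontology edge %s de-duplicated", path, e)
            continue
        seen.add(e)
        deduped.append(e)
    return OntologyTable(sorted(deduped)).validate()


def write_ontology(ontology: OntologyTable, path: str | Path) -> None:
    path = Path(path)
    lines = ["# IS_A ontology: child<TAB>parent"]
    lines.extend(f"{c}\t{p}" for c, p in sorted(ontology.edges))
    path.write_text("\n".join(lines) + "\n")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    """Dense similarity TSV: first row and first column carry entity IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    col_ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if col_ids != row_ids:
        raise ValueError(f"{path}: similarity header row and column IDs disagree")
    order = np.argsort(np.asarray(row_ids, dtype=object))
    ids = [row_ids[i] for i in order]
    values = df.to_numpy(dtype=np.float64)[np.ix_(order, order)]
    return SimilarityMatrix(ids, values, source_view=path.stem).validate(atol=1e-9)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(sim.entity_ids) + "\n")
        for i, eid in enumerate(sim.entity_ids):
            fh.write(eid + "\t" + "\t".join(f"{v:.17g}" for v in sim.values[i]) + "\n")


PREDICTION_COLUMNS = ["lncrna_id", "disease_id", "score", "label", "fold"]


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table (one row per scored pair) as TSV.

    Required columns: lncrna_id, disease_id, score; label and fold are
    optional and written as empty fields when absent.
    """
    out = table.copy()
    for col in PREDICTION_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    if not np.isfinite(out["score"].to_numpy(dtype=np.float64)).all():
        raise ValueError("prediction scores must be finite")
    out = out[PREDICTION_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prediction table missing columns {sorted(missing)}")
    return df
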