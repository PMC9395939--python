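"""Readers/writers for the plain-text interchange formats used across the pipeline.

Formats: whitespace-delimited word-vector text files, document tables (TSV),
hierarchy and association tables (TSV), and weighted edge lists.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DOC_COLUMNS = ["id", "title", "abstract", "label"]


def write_word_vectors(path: str | os.PathLike, ids: Sequence[str], matrix: np.ndarray,
                       fmt: str = "%.6g") -> None:
    """Write one ``id v1 v2 ...`` line per row, whitespace-delimited."""
    matrix = np.asarray(matrix)
    if len(ids) != matrix.shape[0]:
        raise ValueError(f"{len(ids)} ids but {matrix.shape[0]} rows")
    with open(path, "w", encoding="utf-8") as fh:
        for term, row in zip(ids, matrix):
            fh.write(str(term) + " " + " ".join(fmt % v for v in row) + "\n")


def read_word_vectors(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[float]] = []
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if dim is None:
                dim = len(parts) - 1
                if dim < 1:
                    raise ValueError(f"line {lineno}: no vector components")
            elif len(parts) - 1 != dim:
                raise ValueError(f"line {lineno}: expected {dim} components, got {len(parts) - 1}")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if not ids:
        raise ValueError(f"{path}: empty vector file")
    return ids, np.asarray(rows, dtype=np.float64)


def write_documents(path: str | os.PathLike, docs: pd.DataFrame) -> None:
    docs.loc[:, DOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_documents(path: str | os.PathLike) -> pd.DataFrame:
    docs = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in DOC_COLUMNS if c not in docs.columns and c != "label"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return docs


def write_table(path: str | os.PathLike, rows: Iterable[tuple], columns: Sequence[str]) -> None:
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_hierarchy(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with one row per (term_id, tree_number)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "tree_number"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns term_id, tree_number")
    return df


def read_associations(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "partner_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns term_id, partner_id")
    return df


def read_mesh_descriptor_xml(path: str | os.PathLike, category: str = "C") -> pd.DataFrame:
    """Parse a MeSH descriptor XML dump into the hierarchy-table format.

    Keeps descriptors with at least one tree number under the given category
    letter ("C" = diseases, "D" = drugs and chemicals) and drops their
    out-of-category tree numbers.  Returns the same ``term_id``/``tree_number``
    table that :func:`read_hierarchy` reads.
    """
    import xml.etree.ElementTree as ET

    rows = []
    for _event, record in ET.iterparse(str(path), events=("end",)):
        if record.tag != "DescriptorRecord":
            continue
        ui = record.findtext("DescriptorUI")
        trees = [t.text for t in record.iter("TreeNumber")
                 if t.text and t.text.startswith(category)]
        if ui and trees:
            rows.extend((ui, t) for t in trees)
        record.clear()
    return pd.DataFrame(rows, columns=["term_id", "tree_number"])


def write_edge_list(path: str | os.PathLike, edges: Iterable[tuple[str, str, float]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, w in edges:
            fh.write(f"{u}\t{v}\t{w:.6g}\n")
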