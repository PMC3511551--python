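"""Flat-file readers and writers.

Everything is tab-delimited text (matrices, ranked pair lists, edge lists,
cluster reports) or JSON (configs, ground truth).  Gene ids are matched
exactly after whitespace trimming, case preserved: probe ids and locus ids
follow different case conventions and silent case-folding risks false joins.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .network import CoordinationMatrix
from .triple_link import DecompositionResult, TFCluster

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_pathway_map",
    "write_ranked_list",
    "read_ranked_list",
    "write_edge_list",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_clusters_tsv",
    "write_clusters_json",
    "read_clusters_json",
]


def read_expression_matrix(path) -> pd.DataFrame:
    """Tab-delimited genes x samples table: header of sample ids, first
    column gene ids.  Duplicates, gaps and non-numeric cells are rejected
    with the offending coordinates."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows/columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing cell at gene {bad[0]!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_pathway_map(path) -> dict[str, frozenset]:
    """AraCyc-style dump: tab-delimited pathway_id, pathway_name, gene_id.

    Multi-assignment is preserved; records with empty gene ids are skipped.
    """
    import warnings

    path = Path(path)
    assignments: dict[str, set] = {}
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pwy_id, _name, gene_id = parts[0].strip(), parts[1], parts[2].strip()
            if not gene_id:
                warnings.warn(f"{path}:{lineno}: empty gene id skipped", stacklevel=2)
                continue
            assignments.setdefault(gene_id, set()).add(pwy_id)
            n_records += 1
    if n_records == 0:
        warnings.warn(f"{path}: no pathway records found", stacklevel=2)
    return {g: frozenset(s) for g, s in assignments.items()}


def write_ranked_list(ranked: pd.DataFrame, path) -> None:
    out = ranked.copy()
    out.insert(0, "query", ranked.attrs.get("query", ""))
    out["rank"] = np.arange(1, len(out) + 1)
    out.to_csv(path, sep="\t", index=False)


def read_ranked_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = df[["partner", "statistic", "p_value"]].copy()
    if len(df) and "query" in df:
        out.attrs["query"] = str(df["query"].iloc[0])
    return out


def write_edge_list(matrix: CoordinationMatrix, path) -> None:
    matrix.edge_list().to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: CoordinationMatrix, path) -> None:
    header = f"# n_top={matrix.n_top}\tk_min={matrix.k_min}\n"
    with open(path, "w") as fh:
        fh.write(header)
        matrix.to_frame().to_csv(fh, sep="\t", index_label="tf_id")


def read_matrix_tsv(path) -> CoordinationMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ParseError(f"{path}:1: missing parameter header")
        params = dict(
            tok.split("=", 1) for tok in first[1:].strip().split("\t") if "=" in tok
        )
        df = pd.read_csv(fh, sep="\t", index_col=0)
    overlaps = df.to_numpy(dtype=int)
    if overlaps.shape[0] != overlaps.shape[1] or not np.array_equal(overlaps, overlaps.T):
        raise ParseError(f"{path}: matrix is not symmetric")
    return CoordinationMatrix(
        tuple(str(t) for t in df.index),
        overlaps,
        n_top=int(params.get("n_top", 100)),
        k_min=int(params.get("k_min", 30)),
    )


def write_clusters_tsv(result: DecompositionResult, path) -> None:
    rows = []
    for cl in result.clusters:
        for rank, tf in enumerate(cl.members, 1):
            rows.append((cl.index, rank, tf, cl.seed_overlap))
    pd.DataFrame(
        rows, columns=["cluster_index", "member_rank", "tf_id", "seed_overlap"]
    ).to_csv(path, sep="\t", index=False)


def write_clusters_json(result: DecompositionResult, path) -> None:
    payload = {
        "threshold": result.threshold,
        "multiplier": result.multiplier,
        "clusters": [
            {
                "index": cl.index,
                "members": list(cl.members),
                "seed_overlap": cl.seed_overlap,
            }
            for cl in result.clusters
        ],
        "singletons": list(result.singletons),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_clusters_json(path) -> DecompositionResult:
    payload = json.loads(Path(path).read_text())
    clusters = tuple(
        TFCluster(c["index"], tuple(c["members"]), c["seed_overlap"])
        for c in payload["clusters"]
    )
    return DecompositionResult(
        clusters,
        tuple(payload["singletons"]),
        payload["threshold"],
        payload.get("multiplier", 1.0),
    )
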