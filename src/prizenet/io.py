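"""Readers and writers for the pipeline's standard formats.

Tables are tab-separated with a header row; comment lines start with '#'.
Gene identifiers are opaque strings (symbol/ENSEMBL mapping is the caller's
responsibility).  Structured results are JSON and carry a provenance block
(seed, parameters, input digests, tool version) for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import SubnetworkSolution, constraint_p_from_z
from .prefexp import ExpressionAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_scores",
    "write_gene_scores",
    "read_edge_list",
    "write_edge_list",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotation_table",
    "file_digest",
    "make_provenance",
    "write_results",
    "read_solution",
]

_READ_KW = dict(sep="\t", comment="#")


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_gene_scores(
    path,
    id_column: str = "gene_id",
    z_column: str = "z",
    p_column: str = "p",
) -> pd.DataFrame:
    """Load a per-gene constraint score table (TSV with header).

    At least the id column and one of z/p must be present.  If only z is
    given, p is the upper-tail normal probability; if only p is given, z is
    back-filled from the inverse survival function.  Returns a DataFrame
    indexed by gene id with columns ``z`` and ``p``.
    """
    df = pd.read_csv(path, **_READ_KW, dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    has_z = z_column in df.columns
    has_p = p_column in df.columns
    if not (has_z or has_p):
        raise ValueError(f"need at least one of columns {z_column!r}, {p_column!r}")
    ids = df[id_column]
    if ids.isna().any() or (ids.str.len() == 0).any():
        raise ValueError("empty gene id encountered")
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids: {list(dup)[:5]}")

    def _numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2  # 1-based incl. header
            raise ValueError(f"non-numeric value in column {col!r} at file row {row}")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0]) + 2
            raise ValueError(f"missing value in column {col!r} at file row {row}")
        return vals.to_numpy(dtype=float)

    out = pd.DataFrame(index=pd.Index(ids.to_numpy(), name="gene_id"))
    if has_z:
        out["z"] = _numeric(z_column)
    if has_p:
        p = _numeric(p_column)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p values must lie in (0, 1]")
        out["p"] = p
    if not has_p:
        out["p"] = constraint_p_from_z(out["z"].to_numpy())
    if not has_z:
        from scipy import stats

        out["z"] = stats.norm.isf(out["p"].to_numpy())
    return out[["z", "p"]]


def write_gene_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="gene_id")


def read_edge_list(path) -> nx.Graph:
    """Load a two-column TSV of gene-id pairs into an undirected graph.

    Duplicates (a-b == b-a) are merged and self-loops dropped with a logged
    count; an optional header row is tolerated when its pair repeats nowhere.
    """
    df = pd.read_csv(path, **_READ_KW, header=None, dtype=str)
    if df.shape[0] == 0:
        raise ValueError("edge list is empty")
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    rows = df.iloc[:, :2].to_numpy()
    # tolerate a header like "source\ttarget"
    if {str(rows[0][0]).lower(), str(rows[0][1]).lower()} & {
        "source",
        "target",
        "gene1",
        "gene2",
        "node1",
        "node2",
    }:
        rows = rows[1:]
    G = nx.Graph()
    n_self = 0
    for a, b in rows:
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        G.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop(s)", n_self)
    if G.number_of_nodes() == 0:
        raise ValueError("edge list contains no valid edges")
    return G


def write_edge_list(network: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression_matrix(matrix_path, sample_map_path) -> ExpressionAtlas:
    """Load a gene x sample TSV plus a two-column sample -> tissue map."""
    matrix = pd.read_csv(matrix_path, **_READ_KW, index_col=0)
    sm = pd.read_csv(sample_map_path, **_READ_KW, dtype=str)
    if sm.shape[1] < 2:
        raise ValueError("sample map needs two columns (sample, tissue)")
    sample_map = pd.Series(
        sm.iloc[:, 1].to_numpy(), index=pd.Index(sm.iloc[:, 0].to_numpy(), name="sample")
    )
    missing = [s for s in matrix.columns if s not in sample_map.index]
    if missing:
        raise ValueError(f"samples missing from sample map: {missing[:5]}")
    return ExpressionAtlas(matrix=matrix, sample_map=sample_map)


def write_expression_matrix(atlas: ExpressionAtlas, matrix_path, sample_map_path) -> None:
    atlas.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    atlas.sample_map.rename("tissue").to_csv(
        sample_map_path, sep="\t", index_label="sample"
    )


def read_gmt(path) -> dict:
    """Load a GMT gene-set collection: name, description, members per line."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno} has no members")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name: {name!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                raise ValueError(f"GMT line {lineno} has no members")
            sets[name] = members
    if not sets:
        raise ValueError("GMT file is empty")
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_annotation_table(path) -> dict:
    """Load a gene -> categories table (TSV: gene_id, comma-separated
    categories).  Returns a dict gene -> set of labels."""
    df = pd.read_csv(path, **_READ_KW, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two columns")
    ids = df.iloc[:, 0]
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids in annotation table: {list(dup)[:5]}")
    out = {}
    for g, cats in zip(ids, df.iloc[:, 1]):
        labels = {c.strip() for c in str(cats).split(",") if c.strip()}
        if labels:
            out[str(g)] = labels
    return out


# ---------------------------------------------------------------------------
# structured results
# ---------------------------------------------------------------------------

def make_provenance(seed=None, parameters=None, inputs=None) -> dict:
    """Provenance block attached to structured outputs."""
    from . import __version__

    digests = {}
    for name, path in (inputs or {}).items():
        try:
            digests[name] = file_digest(path)
        except OSError:
            digests[name] = None
    return {
        "tool": "prizenet",
        "version": __version__,
        "seed": seed,
        "parameters": parameters or {},
        "input_digests": digests,
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(bundle: dict, out_dir, provenance: dict | None = None) -> list:
    """Write a result bundle to ``out_dir``.

    DataFrames/Series go to TSV; solutions, dicts and dataclass-like objects
    (anything with ``to_dict``) go to JSON alongside the provenance block.
    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
        elif isinstance(obj, pd.Series):
            path = out_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
        else:
            path = out_dir / f"{name}.json"
            payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
            doc = {"result": payload, "provenance": provenance or make_provenance()}
            path.write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")
        logger.info("wrote %s", path)
        written.append(path)
    return written


def read_solution(path) -> SubnetworkSolution:
    """Read a solution JSON written by :func:`write_results`."""
    doc = json.loads(Path(path).read_text())
    res = doc["result"] if "result" in doc else doc
    return SubnetworkSolution(
        nodes=frozenset(res["nodes"]),
        tree_edges=frozenset(frozenset(e) for e in res["tree_edges"]),
        profit=float(res["profit"]),
        node_weights={k: float(v) for k, v in res["node_weights"].items()},
        rank=int(res.get("rank", 1)),
    )
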