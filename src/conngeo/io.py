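"""Reading and writing connectivity matrices, node tables, and embedding exports.

Connectivity matrices are plain-text delimited matrices (comma, tab, or
whitespace), optionally carrying a header row of node labels and a leading
label column.  Node metadata travels as a CSV with columns
``label,lobe,x,y,z,rich_club``; embeddings are exported as JSON for viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedConnectome",
    "NodeTable",
    "read_connectome",
    "write_connectome",
    "read_node_table",
    "write_node_table",
    "export_embedding_json",
    "validate_embedding_export",
    "load_embedding_schema",
]

#: maximum tolerated asymmetry |W - W.T| before read/validation errors out
SYMMETRY_TOL = 1e-9
#: diagonal entries at or below this magnitude are silently zeroed
DIAGONAL_TOL = 1e-12


def _default_labels(n: int) -> tuple[str, ...]:
    width = max(3, len(str(max(n - 1, 0))))
    return tuple(f"N{i:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class WeightedConnectome:
    """A symmetric, nonnegative, hollow coupling matrix with node labels.

    Weights are fiber counts or any nonnegative coupling strength.  Validity
    (square, symmetric within ``SYMMETRY_TOL``, zero diagonal, no negative
    entries, no isolated nodes) is enforced at construction.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValueError("connectome needs at least 2 nodes")
        asym = np.abs(w - w.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}")
        w = (w + w.T) / 2.0
        diag = np.abs(np.diag(w))
        if (diag > DIAGONAL_TOL).any():
            bad = int(np.argmax(diag))
            raise ValueError(f"nonzero diagonal at node index {bad} (value {w[bad, bad]:g})")
        np.fill_diagonal(w, 0.0)
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(f"negative weight at ({i}, {j}): {w[i, j]:g}")
        labels = tuple(self.labels) if len(self.labels) else _default_labels(n)
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} nodes")
        if len(set(labels)) != n:
            raise ValueError("node labels must be unique")
        isolated = np.flatnonzero(w.sum(axis=1) == 0)
        if isolated.size:
            raise ValueError(f"isolated node (no connections): {labels[isolated[0]]!r}")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedConnectome):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.weights, other.weights)

    def __hash__(self):  # frozen dataclass default is unusable with arrays
        return hash((self.labels, self.weights.tobytes()))


@dataclass(frozen=True)
class NodeTable:
    """Per-node metadata: labels plus optional lobe, anatomic centroid, rich-club flag."""

    label: tuple[str, ...]
    lobe: tuple[str, ...] | None = None
    anatomic_xyz: np.ndarray | None = None  # (n, 3) mm
    rich_club: np.ndarray | None = None  # (n,) bool

    def __post_init__(self):
        n = len(self.label)
        if len(set(self.label)) != n:
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "label", tuple(self.label))
        if self.lobe is not None:
            if len(self.lobe) != n:
                raise ValueError("lobe column length mismatch")
            object.__setattr__(self, "lobe", tuple(self.lobe))
        if self.anatomic_xyz is not None:
            xyz = np.asarray(self.anatomic_xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise ValueError(f"anatomic_xyz must be ({n}, 3), got {xyz.shape}")
            object.__setattr__(self, "anatomic_xyz", xyz)
        if self.rich_club is not None:
            rc = np.asarray(self.rich_club, dtype=bool)
            if rc.shape != (n,):
                raise ValueError("rich_club column length mismatch")
            object.__setattr__(self, "rich_club", rc)

    @property
    def n(self) -> int:
        return len(self.label)

    def require_match(self, connectome: WeightedConnectome) -> None:
        if self.n != connectome.n:
            raise ValueError(f"node table has {self.n} rows for a {connectome.n}-node connectome")

    def to_dataframe(self) -> pd.DataFrame:
        data: dict = {"label": list(self.label)}
        if self.lobe is not None:
            data["lobe"] = list(self.lobe)
        if self.anatomic_xyz is not None:
            data["x"], data["y"], data["z"] = self.anatomic_xyz.T
        if self.rich_club is not None:
            data["rich_club"] = self.rich_club
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# matrix files


def _detect_delimiter(first_line: str) -> str | None:
    """Choose among comma / tab / whitespace by what the header line uses."""
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # split on arbitrary whitespace


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_connectome(path: str | Path, delimiter: str | None = None) -> WeightedConnectome:
    """Read a plain-text connectivity matrix into a validated :class:`WeightedConnectome`.

    A first row and/or first column of non-numeric tokens is auto-detected as
    node labels.  The delimiter is auto-detected (comma, tab, whitespace)
    unless given explicitly.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = delimiter if delimiter is not None else _detect_delimiter(lines[0])
    rows = [ln.split(delim) if delim else ln.split() for ln in lines]

    labels: tuple[str, ...] = ()
    if rows and not all(_is_number(t) for t in rows[0]):
        header = rows.pop(0)
        if rows and not _is_number(rows[0][0]):  # leading label column too
            if len(header) == len(rows[0]):  # header includes a corner cell
                header = header[1:]
            rows = [r[1:] for r in rows]
        labels = tuple(t.strip() for t in header)
    elif rows and not _is_number(rows[0][0]):
        labels = tuple(r[0].strip() for r in rows)
        rows = [r[1:] for r in rows]

    try:
        w = np.array([[float(t) for t in r] for r in rows], dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix body ({exc})") from exc
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {w.shape})")
    return WeightedConnectome(w, labels)


def write_connectome(c: WeightedConnectome, path: str | Path, delimiter: str = ",") -> None:
    """Write a labeled text matrix; values use ``repr`` so the round trip is exact."""
    path = Path(path)
    out = [delimiter.join(c.labels)]
    for label, row in zip(c.labels, c.weights):
        out.append(delimiter.join([label] + [repr(float(v)) for v in row]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# node tables


def read_node_table(path: str | Path) -> NodeTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: node table needs a 'label' column")
    lobe = tuple(df["lobe"].astype(str)) if "lobe" in df.columns else None
    xyz = df[["x", "y", "z"]].to_numpy(float) if {"x", "y", "z"} <= set(df.columns) else None
    rc = df["rich_club"].astype(bool).to_numpy() if "rich_club" in df.columns else None
    return NodeTable(tuple(df["label"].astype(str)), lobe, xyz, rc)


def write_node_table(t: NodeTable, path: str | Path) -> None:
    t.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# embedding export for viewers


def export_embedding_json(embedding, table: NodeTable | None, c: WeightedConnectome,
                          path: str | Path) -> None:
    """Write a viewer-ready JSON file with per-node records and the edge list.

    The document layout is described by ``data/embedding_export.schema.json``.
    Node records carry label, lobe, 3-D coordinates, and the rich-club flag;
    the edge list keeps every nonzero weight (display thresholding is the
    viewer's job).
    """
    coords = np.asarray(embedding.coords, dtype=float)
    if coords.shape[1] != 3:
        raise ValueError("embedding must be 3-dimensional for export")
    if coords.shape[0] != c.n:
        raise ValueError(f"embedding has {coords.shape[0]} rows for a {c.n}-node connectome")
    if table is not None:
        table.require_match(c)
    nodes = []
    for i, label in enumerate(c.labels):
        nodes.append({
            "label": label,
            "lobe": (table.lobe[i] if table is not None and table.lobe is not None else ""),
            "xyz": [float(v) for v in coords[i]],
            "rich_club": bool(table.rich_club[i]) if table is not None
            and table.rich_club is not None else False,
        })
    ii, jj = np.nonzero(np.triu(c.weights, k=1))
    edges = [{"i": int(i), "j": int(j), "weight": float(c.weights[i, j])}
             for i, j in zip(ii, jj)]
    doc = {
        "format": "conngeo-embedding",
        "version": 1,
        "method": getattr(embedding, "method", "unknown"),
        "nodes": nodes,
        "edges": edges,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_embedding_schema() -> dict:
    text = resources.files("conngeo").joinpath("data/embedding_export.schema.json").read_text()
    return json.loads(text)


def _check(instance, schema, where: str, errors: list[str]) -> None:
    typ = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str, "boolean": bool,
               "integer": int, "number": (int, float)}
    if typ is not None and not isinstance(instance, typemap[typ]):
        errors.append(f"{where}: expected {typ}, got {type(instance).__name__}")
        return
    if typ == "number" and isinstance(instance, bool):
        errors.append(f"{where}: expected number, got bool")
    if typ == "object":
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{where}.{key}", errors)
    elif typ == "array":
        items = schema.get("items")
        if "minItems" in schema and len(instance) < schema["minItems"]:
            errors.append(f"{where}: fewer than {schema['minItems']} items")
        if "maxItems" in schema and len(instance) > schema["maxItems"]:
            errors.append(f"{where}: more than {schema['maxItems']} items")
        if items is not None:
            for k, element in enumerate(instance):
                _check(element, items, f"{where}[{k}]", errors)
    if "const" in schema and instance != schema["const"]:
        errors.append(f"{where}: expected constant {schema['const']!r}")


def validate_embedding_export(doc: dict | str | Path) -> None:
    """Validate an export document (or file path) against the shipped schema.

    Raises ``ValueError`` listing every violation; passes silently otherwise.
    """
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    errors: list[str] = []
    _check(doc, load_embedding_schema(), "$", errors)
    if errors:
        raise ValueError("embedding export violates schema:\n" + "\n".join(errors))
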