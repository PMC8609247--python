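"""Readers and writers for the coordinate/expression/annotation bundle.

The on-disk dialect consists of:

* ``.mds`` coordinate files — tab-separated, no header, 4 columns
  (``cell_id  x  y  z``) or 7 columns when per-cell velocity target
  coordinates are present (``cell_id  x  y  z  tx  ty  tz``).
* an SQLite expression database with a sparse triple store (only non-zero
  values are kept), see :data:`SCHEMA_VERSION`.
* tab-separated one-hot cell-type tables (header row of type names, first
  column the cell ID, body strictly 0/1).
* tab-separated cell/gene metadata tables and surface-marker intensity
  tables (header row, first column the row ID).

Coordinates are serialized with ``repr`` (shortest round-trip
representation), so write/read cycles are bit-stable.
"""

from __future__ import annotations

import difflib
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GeneLookupError, ParseError, ValidationError

SCHEMA_VERSION = "1"

MANIFEST_NAME = "manifest.json"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Per-cell coordinates of one dimension-reduction method.

    Parameters
    ----------
    name:
        Free-text label of the DR method (e.g. ``"umap3d"``).
    cell_ids:
        Ordered unique cell identifiers, one per coordinate row.
    coords:
        ``(C, D)`` float array with ``D`` in ``{2, 3}``.
    velocity_targets:
        Optional ``(C, 3)`` float array of per-cell destination coordinates;
        only allowed for 3D embeddings.
    """

    name: str
    cell_ids: list[str]
    coords: np.ndarray
    velocity_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"coords must be (C, 2) or (C, 3), got {self.coords.shape}"
            )
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell_ids length does not match coords rows")
        _check_unique(self.cell_ids, "cell ID")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite values")
        if self.velocity_targets is not None:
            self.velocity_targets = np.asarray(self.velocity_targets, dtype=float)
            if self.ndim != 3:
                raise ValidationError("velocity_targets require a 3D embedding")
            if self.velocity_targets.shape != (len(self.cell_ids), 3):
                raise ValidationError(
                    "velocity_targets must be (C, 3), got "
                    f"{self.velocity_targets.shape}"
                )
            if not np.all(np.isfinite(self.velocity_targets)):
                raise ValidationError("velocity_targets contain non-finite values")

    @property
    def ndim(self) -> int:
        return int(self.coords.shape[1])

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, cell_ids: Sequence[str]) -> "EmbeddingTable":
        """Return a new table restricted (and reordered) to ``cell_ids``."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            rows = [index[c] for c in cell_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown cell ID {exc.args[0]!r}") from exc
        vel = None
        if self.velocity_targets is not None:
            vel = self.velocity_targets[rows]
        return EmbeddingTable(self.name, list(cell_ids), self.coords[rows], vel)


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression values."""

    gene_names: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_names, "gene name")
        _check_unique(self.cell_ids, "cell ID")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class CellTypeTable:
    """Binary cell x type membership; a cell may carry 0..T labels."""

    cell_ids: list[str]
    type_names: list[str]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.type_names = [str(t) for t in self.type_names]
        self.membership = np.asarray(self.membership)
        if self.membership.shape != (len(self.cell_ids), len(self.type_names)):
            raise ValidationError(
                f"membership shape {self.membership.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.type_names)} types"
            )
        _check_unique(self.cell_ids, "cell ID")
        _check_unique(self.type_names, "type name")
        if not np.all(np.isin(self.membership, (0, 1))):
            raise ValidationError("membership entries must be exactly 0 or 1")
        self.membership = self.membership.astype(np.int8)

    def members(self, type_name: str) -> list[str]:
        """Cell IDs belonging to ``type_name``."""
        if type_name not in self.type_names:
            raise GeneLookupError(
                f"unknown population {type_name!r}; known: {self.type_names}"
            )
        col = self.type_names.index(type_name)
        mask = self.membership[:, col] == 1
        return [c for c, m in zip(self.cell_ids, mask) if m]

    def subset(self, cell_ids: Sequence[str]) -> "CellTypeTable":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in cell_ids]
        return CellTypeTable(list(cell_ids), list(self.type_names), self.membership[rows])


@dataclass
class MetadataTable:
    """Categorical attributes for cells or genes (values kept as text)."""

    row_ids: list[str]
    columns: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        _check_unique(self.row_ids, "row ID")
        if len(self.columns) != len(self.row_ids):
            raise ValidationError("metadata rows do not match row_ids")
        self.columns = self.columns.astype(str)
        self.columns.index = pd.Index(self.row_ids)


@dataclass
class SurfaceMarkerTable:
    """Cell x surface-marker intensity matrix (non-negative reals)."""

    cell_ids: list[str]
    marker_names: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.marker_names = [str(m) for m in self.marker_names]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.cell_ids), len(self.marker_names)):
            raise ValidationError("intensity shape mismatch")
        _check_unique(self.cell_ids, "cell ID")
        _check_unique(self.marker_names, "marker name")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValidationError("intensities must be finite and >= 0")


# ---------------------------------------------------------------------------
# .mds coordinate files
# ---------------------------------------------------------------------------


def write_mds(embedding: EmbeddingTable, path: str | Path) -> Path:
    """Write an embedding as a 4- or 7-column ``.mds`` file.

    2D embeddings are padded with a constant third coordinate of 0 and a
    sidecar note ``<path>.note`` records the padding.
    """
    path = Path(path)
    coords = embedding.coords
    padded = embedding.ndim == 2
    if padded:
        coords = np.column_stack([coords, np.zeros(embedding.n_cells)])
    lines = []
    for i, cid in enumerate(embedding.cell_ids):
        fields = [cid] + [repr(float(v)) for v in coords[i]]
        if embedding.velocity_targets is not None:
            fields += [repr(float(v)) for v in embedding.velocity_targets[i]]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if padded:
        Path(str(path) + ".note").write_text(
            "2D embedding padded with constant z = 0 on export\n"
        )
    return path


def read_mds(path: str | Path, name: str | None = None) -> EmbeddingTable:
    """Parse a 4- or 7-column ``.mds`` file into an :class:`EmbeddingTable`."""
    path = Path(path)
    cell_ids: list[str] = []
    rows: list[list[float]] = []
    ncol: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if ncol is None:
                ncol = len(fields)
                if ncol not in (4, 7):
                    raise ParseError(
                        f"{path}:{lineno}: expected 4 or 7 columns, found {ncol}"
                    )
            elif len(fields) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields)} columns, "
                    f"expected {ncol})"
                )
            cid = fields[0]
            if cid in set(cell_ids):
                raise ParseError(f"{path}:{lineno}: duplicate cell ID {cid!r}")
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            cell_ids.append(cid)
            rows.append(values)
    if ncol is None:
        raise ParseError(f"{path}: empty file")
    arr = np.array(rows, dtype=float)
    vel = arr[:, 3:6] if ncol == 7 else None
    return EmbeddingTable(name or path.stem, cell_ids, arr[:, :3], vel)


# ---------------------------------------------------------------------------
# SQLite expression database
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE genes (gene_idx INTEGER PRIMARY KEY, gene_name TEXT UNIQUE NOT NULL);
CREATE TABLE cells (cell_idx INTEGER PRIMARY KEY, cell_name TEXT UNIQUE NOT NULL);
CREATE TABLE expr (
    gene_idx INTEGER NOT NULL REFERENCES genes(gene_idx),
    cell_idx INTEGER NOT NULL REFERENCES cells(cell_idx),
    value REAL NOT NULL
);
CREATE INDEX expr_gene ON expr(gene_idx);
"""


def build_expression_db(
    expr: ExpressionMatrix, path: str | Path, overwrite: bool = False
) -> Path:
    """Store an expression matrix as a sparse SQLite triple store.

    Only non-zero values are written to the ``expr`` table; the ``genes``
    and ``cells`` tables are always complete so dense queries can be
    reconstructed. A ``meta`` table records the schema version.
    """
    path = Path(path)
    if path.exists():
        if not overwrite:
            raise ValidationError(
                f"refusing to overwrite existing database {path}; pass overwrite=True"
            )
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)", (SCHEMA_VERSION,)
        )
        con.executemany(
            "INSERT INTO genes VALUES (?, ?)", enumerate(expr.gene_names)
        )
        con.executemany(
            "INSERT INTO cells VALUES (?, ?)", enumerate(expr.cell_ids)
        )
        gi, ci = np.nonzero(expr.values)
        con.executemany(
            "INSERT INTO expr VALUES (?, ?, ?)",
            (
                (int(g), int(c), float(expr.values[g, c]))
                for g, c in zip(gi, ci)
            ),
        )
        con.commit()
    finally:
        con.close()
    return path


def db_cell_ids(db: str | Path) -> list[str]:
    """Cell IDs in stored order."""
    con = sqlite3.connect(db)
    try:
        rows = con.execute("SELECT cell_name FROM cells ORDER BY cell_idx").fetchall()
    finally:
        con.close()
    return [r[0] for r in rows]


def db_gene_names(db: str | Path) -> list[str]:
    con = sqlite3.connect(db)
    try:
        rows = con.execute("SELECT gene_name FROM genes ORDER BY gene_idx").fetchall()
    finally:
        con.close()
    return [r[0] for r in rows]


def query_expression(db: str | Path, gene: str) -> np.ndarray:
    """Dense per-cell expression vector of ``gene`` in stored cell order.

    Cells absent from the sparse value table receive 0. Unknown genes raise
    :class:`~embedsep.errors.GeneLookupError` listing near-matches.
    """
    con = sqlite3.connect(db)
    try:
        row = con.execute(
            "SELECT gene_idx FROM genes WHERE gene_name = ?", (gene,)
        ).fetchone()
        if row is None:
            names = [r[0] for r in con.execute("SELECT gene_name FROM genes")]
            close = difflib.get_close_matches(gene, names, n=3)
            raise GeneLookupError(
                f"unknown gene {gene!r}; close matches: {close or 'none'}"
            )
        gene_idx = row[0]
        n_cells = con.execute("SELECT COUNT(*) FROM cells").fetchone()[0]
        out = np.zeros(n_cells)
        for cell_idx, value in con.execute(
            "SELECT cell_idx, value FROM expr WHERE gene_idx = ?", (gene_idx,)
        ):
            out[cell_idx] = value
    finally:
        con.close()
    return out


def read_expression_db(db: str | Path) -> ExpressionMatrix:
    """Reconstruct the full dense matrix from a database file."""
    genes = db_gene_names(db)
    cells = db_cell_ids(db)
    values = np.zeros((len(genes), len(cells)))
    con = sqlite3.connect(db)
    try:
        for g, c, v in con.execute("SELECT gene_idx, cell_idx, value FROM expr"):
            values[g, c] = v
    finally:
        con.close()
    return ExpressionMatrix(genes, cells, values)


# ---------------------------------------------------------------------------
# Tab-separated annotation tables
# ---------------------------------------------------------------------------


def write_celltype_table(table: CellTypeTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(table.type_names) + "\n")
        for i, cid in enumerate(table.cell_ids):
            fh.write(cid + "\t" + "\t".join(str(int(v)) for v in table.membership[i]) + "\n")
    return path


def read_celltype_table(path: str | Path) -> CellTypeTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        type_names = header.split("\t")[1:]
        cell_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(type_names) + 1:
                raise ParseError(f"{path}:{lineno}: ragged row")
            cell_ids.append(fields[0])
            row = []
            for v in fields[1:]:
                if v not in ("0", "1"):
                    raise ParseError(
                        f"{path}:{lineno}: membership entry {v!r} is not 0 or 1"
                    )
                row.append(int(v))
            rows.append(row)
    return CellTypeTable(cell_ids, type_names, np.array(rows, dtype=np.int8).reshape(len(cell_ids), len(type_names)))


def write_metadata_table(table: MetadataTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.columns.copy()
    df.insert(0, "row_id", table.row_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_metadata_table(path: str | Path) -> MetadataTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    row_ids = df.iloc[:, 0].tolist()
    return MetadataTable(row_ids, df.iloc[:, 1:].reset_index(drop=True))


def write_marker_table(table: SurfaceMarkerTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\t" + "\t".join(table.marker_names) + "\n")
        for i, cid in enumerate(table.cell_ids):
            fh.write(
                cid + "\t" + "\t".join(repr(float(v)) for v in table.intensities[i]) + "\n"
            )
    return path


def read_marker_table(path: str | Path) -> SurfaceMarkerTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    return SurfaceMarkerTable(
        df.iloc[:, 0].tolist(), list(df.columns[1:]), df.iloc[:, 1:].to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Bundle export
# ---------------------------------------------------------------------------


def export_bundle(
    expr: ExpressionMatrix,
    embeddings: Sequence[EmbeddingTable],
    out_dir: str | Path,
    celltypes: CellTypeTable | None = None,
    metadata: MetadataTable | None = None,
    markers: SurfaceMarkerTable | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a complete bundle directory and a JSON manifest.

    All inputs must cover the same cell-ID set (any order); tables are
    reordered to the expression matrix's cell order before writing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = expr.cell_ids
    ref_set = set(ref)

    def _check(ids: Sequence[str], source: str) -> None:
        other = set(ids)
        if other != ref_set:
            missing = sorted(ref_set - other)[:5]
            extra = sorted(other - ref_set)[:5]
            raise ConsistencyError(
                f"cell IDs in {source} disagree with expression matrix "
                f"(missing e.g. {missing}, unexpected e.g. {extra})"
            )

    files: dict[str, dict] = {}

    db_path = out_dir / "expression.sqlite"
    build_expression_db(expr, db_path, overwrite=overwrite)
    files["expression.sqlite"] = {
        "kind": "expression_db",
        "n_genes": expr.n_genes,
        "n_cells": expr.n_cells,
    }

    for emb in embeddings:
        _check(emb.cell_ids, f"embedding {emb.name!r}")
        fname = f"{emb.name}.mds"
        write_mds(emb.subset(ref), out_dir / fname)
        files[fname] = {
            "kind": "embedding",
            "name": emb.name,
            "n_cells": emb.n_cells,
            "n_dims": emb.ndim,
            "has_velocity": emb.velocity_targets is not None,
        }

    if celltypes is not None:
        _check(celltypes.cell_ids, "cell-type table")
        write_celltype_table(celltypes.subset(ref), out_dir / "celltypes.tsv")
        files["celltypes.tsv"] = {
            "kind": "celltypes",
            "n_cells": len(celltypes.cell_ids),
            "n_types": len(celltypes.type_names),
        }

    if metadata is not None:
        _check(metadata.row_ids, "cell metadata table")
        order = {c: i for i, c in enumerate(metadata.row_ids)}
        rows = [order[c] for c in ref]
        reordered = MetadataTable(list(ref), metadata.columns.iloc[rows].reset_index(drop=True))
        write_metadata_table(reordered, out_dir / "cell_metadata.tsv")
        files["cell_metadata.tsv"] = {
            "kind": "cell_metadata",
            "n_rows": len(metadata.row_ids),
            "n_columns": metadata.columns.shape[1],
        }

    if markers is not None:
        _check(markers.cell_ids, "surface-marker table")
        order = {c: i for i, c in enumerate(markers.cell_ids)}
        rows = [order[c] for c in ref]
        reordered = SurfaceMarkerTable(
            list(ref), list(markers.marker_names), markers.intensities[rows]
        )
        write_marker_table(reordered, out_dir / "surface_markers.tsv")
        files["surface_markers.tsv"] = {
            "kind": "surface_markers",
            "n_cells": len(markers.cell_ids),
            "n_markers": len(markers.marker_names),
        }

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_cells": expr.n_cells,
        "files": files,
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


@dataclass
class Bundle:
    """In-memory view of an exported bundle directory."""

    path: Path
    manifest: dict
    expr_db: Path
    embeddings: dict[str, EmbeddingTable]
    celltypes: CellTypeTable | None
    metadata: MetadataTable | None
    markers: SurfaceMarkerTable | None


def read_bundle(bundle_dir: str | Path) -> Bundle:
    """Load a bundle directory written by :func:`export_bundle`."""
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ParseError(f"no {MANIFEST_NAME} in {bundle_dir}")
    manifest = json.loads(manifest_path.read_text())
    embeddings: dict[str, EmbeddingTable] = {}
    celltypes = metadata = markers = None
    expr_db = None
    for fname, info in manifest["files"].items():
        fpath = bundle_dir / fname
        kind = info["kind"]
        if kind == "embedding":
            emb = read_mds(fpath, name=info["name"])
            if info.get("n_dims") == 2:
                # stored padded with z = 0; restore the 2D table
                emb = EmbeddingTable(emb.name, emb.cell_ids, emb.coords[:, :2])
            embeddings[info["name"]] = emb
        elif kind == "expression_db":
            expr_db = fpath
        elif kind == "celltypes":
            celltypes = read_celltype_table(fpath)
        elif kind == "cell_metadata":
            metadata = read_metadata_table(fpath)
        elif kind == "surface_markers":
            markers = read_marker_table(fpath)
    if expr_db is None:
        raise ParseError(f"bundle {bundle_dir} lacks an expression database")
    return Bundle(bundle_dir, manifest, expr_db, embeddings, celltypes, metadata, markers)
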