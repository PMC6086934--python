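"""Core data containers and Loom-dialect HDF5 / TSV input-output.

All pipeline stages exchange :class:`ExpressionMatrix` (cells × genes UMI
counts with per-axis attribute tables and validity masks) and
:class:`ClusterProfile` (per-cluster aggregates with enrichment / q-value /
trinarization layers).  On disk the Loom convention is followed: the main
matrix is stored genes × cells under ``/matrix``, per-gene attributes under
``/row_attrs``, per-cell attributes under ``/col_attrs``, additional
cluster × gene layers under ``/layers`` and cell-cell graphs under
``/col_graphs/<name>/{a,b,w}``.  In memory, cells are rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "ClusterProfile",
    "FormatError",
    "IntegrityError",
    "read_matrix",
    "write_matrix",
    "read_profile",
    "write_profile",
]

#: cluster label reserved for cells excluded from every aggregate
OUTLIER_LABEL = -1

#: below this many cells a dense counts matrix is accepted as-is
DENSE_CELL_THRESHOLD = 5000


class FormatError(ValueError):
    """A container on disk is missing a required component."""


class IntegrityError(ValueError):
    """Dimensions or invariants of a container are inconsistent."""


@dataclass
class ExpressionMatrix:
    """Sparse cells × genes UMI count matrix with attributes and masks.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells as rows.  Stored sparse (CSR)
        unless the dataset is small.
    cell_attrs
        Per-cell table; ``CellID`` is created when absent.  The pipeline
        stores cluster labels under ``Clusters``, cluster names under
        ``ClusterName`` and the 2-D embedding under ``_X`` / ``_Y``.
    gene_attrs
        Per-gene table; must contain a unique ``Gene`` symbol column.
    cell_valid, gene_valid
        Boolean masks set by QC; default all-valid.
    """

    counts: sp.spmatrix | np.ndarray
    cell_attrs: pd.DataFrame = None
    gene_attrs: pd.DataFrame = None
    cell_valid: np.ndarray = None
    gene_valid: np.ndarray = None

    def __post_init__(self):
        if not sp.issparse(self.counts):
            self.counts = np.asarray(self.counts)
            if self.counts.ndim != 2:
                raise IntegrityError("counts must be a 2-D matrix")
            if self.counts.shape[0] >= DENSE_CELL_THRESHOLD:
                self.counts = sp.csr_matrix(self.counts)
        else:
            self.counts = self.counts.tocsr()
        if self.counts.shape[0] and self.counts.shape[1] and self.counts.min() < 0:
            raise IntegrityError("counts contain negative entries")
        n_cells, n_genes = self.counts.shape
        if self.cell_attrs is None:
            self.cell_attrs = pd.DataFrame(index=range(n_cells))
        if self.gene_attrs is None:
            self.gene_attrs = pd.DataFrame(
                {"Gene": [f"Gene{i:05d}" for i in range(n_genes)]}
            )
        self.cell_attrs = self.cell_attrs.reset_index(drop=True)
        self.gene_attrs = self.gene_attrs.reset_index(drop=True)
        if "CellID" not in self.cell_attrs:
            self.cell_attrs["CellID"] = [f"cell_{i}" for i in range(n_cells)]
        if "Gene" not in self.gene_attrs:
            raise IntegrityError("gene_attrs must contain a 'Gene' column")
        if len(self.cell_attrs) != n_cells:
            raise IntegrityError(
                f"cell attribute table has {len(self.cell_attrs)} rows "
                f"against {n_cells} cells"
            )
        if len(self.gene_attrs) != n_genes:
            raise IntegrityError(
                f"gene attribute table has {len(self.gene_attrs)} rows "
                f"against {n_genes} genes"
            )
        genes = self.gene_attrs["Gene"]
        if genes.duplicated().any():
            raise IntegrityError("gene symbols are not unique")
        if self.cell_valid is None:
            self.cell_valid = np.ones(n_cells, dtype=bool)
        if self.gene_valid is None:
            self.gene_valid = np.ones(n_genes, dtype=bool)
        self.cell_valid = np.asarray(self.cell_valid, dtype=bool)
        self.gene_valid = np.asarray(self.gene_valid, dtype=bool)
        if self.cell_valid.shape != (n_cells,) or self.gene_valid.shape != (n_genes,):
            raise IntegrityError("validity mask length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_symbols(self) -> np.ndarray:
        return self.gene_attrs["Gene"].to_numpy()

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell."""
        if sp.issparse(self.counts):
            return self.counts.getnnz(axis=1)
        return (self.counts > 0).sum(axis=1)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the given cell index/boolean mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            counts=self.counts[keep],
            cell_attrs=self.cell_attrs.iloc[keep].reset_index(drop=True),
            gene_attrs=self.gene_attrs.copy(),
            cell_valid=self.cell_valid[keep],
            gene_valid=self.gene_valid.copy(),
        )


@dataclass
class ClusterProfile:
    """Per-cluster aggregates over a clustered :class:`ExpressionMatrix`.

    ``mean_expr`` holds the mean molecule count mu[i, j] of gene *j* in
    cluster *i*, ``nonzero_frac`` the detection fraction f[i, j] in [0, 1],
    and ``cell_counts`` the cluster sizes.  ``enrichment``, ``enrichment_q``
    and ``trinaries`` are filled by the cluster-statistics stage.
    """

    mean_expr: np.ndarray
    nonzero_frac: np.ndarray
    cell_counts: np.ndarray
    gene_symbols: np.ndarray
    cluster_ids: np.ndarray = None
    nonzero_counts: np.ndarray = None
    enrichment: np.ndarray = None
    enrichment_q: np.ndarray = None
    trinaries: np.ndarray = None

    def __post_init__(self):
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        self.nonzero_frac = np.asarray(self.nonzero_frac, dtype=float)
        self.cell_counts = np.asarray(self.cell_counts, dtype=int)
        self.gene_symbols = np.asarray(self.gene_symbols)
        n_clusters, n_genes = self.mean_expr.shape
        if self.cluster_ids is None:
            self.cluster_ids = np.arange(n_clusters)
        self.cluster_ids = np.asarray(self.cluster_ids)
        if self.nonzero_frac.shape != (n_clusters, n_genes):
            raise IntegrityError("nonzero_frac shape mismatch")
        if self.nonzero_frac.min() < 0 or self.nonzero_frac.max() > 1:
            raise IntegrityError("nonzero_frac outside [0, 1]")
        if self.cell_counts.shape != (n_clusters,):
            raise IntegrityError("cell_counts length mismatch")
        if len(self.gene_symbols) != n_genes:
            raise IntegrityError("gene_symbols length mismatch")

    @property
    def n_clusters(self) -> int:
        return self.mean_expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.mean_expr.shape[1]


# ---------------------------------------------------------------------------
# Loom-dialect HDF5 I/O
# ---------------------------------------------------------------------------


def _encode_attr(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in ("U", "O"):
        return np.array([str(v).encode("utf-8") for v in arr])
    return arr


def _decode_attr(arr: np.ndarray) -> np.ndarray:
    if arr.dtype.kind == "S":
        return np.array([v.decode("utf-8") for v in arr])
    return arr


def _graph_to_h5(group: h5py.Group, name: str, adj: sp.spmatrix) -> None:
    coo = sp.coo_matrix(adj)
    g = group.create_group(name)
    g.create_dataset("a", data=coo.row.astype(np.int64))
    g.create_dataset("b", data=coo.col.astype(np.int64))
    g.create_dataset("w", data=coo.data.astype(np.float64))
    g.attrs["n"] = adj.shape[0]


def _graph_from_h5(g: h5py.Group) -> sp.csr_matrix:
    n = int(g.attrs["n"])
    return sp.csr_matrix(
        (g["w"][:], (g["a"][:], g["b"][:])), shape=(n, n)
    )


def write_matrix(
    m: ExpressionMatrix,
    path: str,
    graphs: dict[str, sp.spmatrix] | None = None,
    embedding: np.ndarray | None = None,
) -> str:
    """Write an :class:`ExpressionMatrix` to a Loom-dialect HDF5 file.

    Graphs are stored as column graphs (conventionally named ``KNN`` and
    ``MKNN``); a per-cell 2-D embedding is stored as column attributes
    ``_X`` / ``_Y``.  Returns the path written.
    """
    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        if embedding.shape != (m.n_cells, 2):
            raise IntegrityError(
                f"embedding shape {embedding.shape} does not match "
                f"({m.n_cells}, 2)"
            )
    if graphs is not None:
        for name, adj in graphs.items():
            if adj.shape != (m.n_cells, m.n_cells):
                raise IntegrityError(f"graph {name!r} shape mismatch")
    try:
        f = h5py.File(path, "w")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write {path!r}: {exc}") from exc
    with f:
        dense = m.counts.toarray() if sp.issparse(m.counts) else np.asarray(m.counts)
        # Loom convention: genes × cells on disk
        f.create_dataset("matrix", data=dense.T.astype(np.int64), compression="gzip")
        ra = f.create_group("row_attrs")
        for col in m.gene_attrs.columns:
            ra.create_dataset(col, data=_encode_attr(m.gene_attrs[col].to_numpy()))
        ra.create_dataset("Valid", data=m.gene_valid.astype(np.int8))
        ca = f.create_group("col_attrs")
        for col in m.cell_attrs.columns:
            ca.create_dataset(col, data=_encode_attr(m.cell_attrs[col].to_numpy()))
        ca.create_dataset("_Valid", data=m.cell_valid.astype(np.int8))
        if embedding is not None:
            ca.create_dataset("_X", data=embedding[:, 0])
            ca.create_dataset("_Y", data=embedding[:, 1])
        f.create_group("layers")
        cg = f.create_group("col_graphs")
        if graphs:
            for name, adj in graphs.items():
                _graph_to_h5(cg, name, adj)
    return path


def read_matrix(path: str, dialect: str | None = None) -> ExpressionMatrix:
    """Read an :class:`ExpressionMatrix` from a Loom-dialect HDF5 or TSV file.

    ``dialect`` is ``"loom"`` or ``"tsv"``; inferred from the extension when
    omitted.  Returns the matrix with graphs/embedding re-attached where
    present: column graphs are returned on the ``graphs`` attribute of the
    result and the embedding inside ``cell_attrs`` (``_X``, ``_Y``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "tsv" if path.endswith((".tsv", ".txt")) else "loom"
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect != "loom":
        raise ValueError(f"unknown dialect {dialect!r}")
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path}: missing main 'matrix' dataset")
        data = f["matrix"][:]
        if data.ndim != 2:
            raise FormatError(f"{path}: main matrix is not 2-D")
        counts = data.T  # cells × genes in memory
        n_cells, n_genes = counts.shape
        if "row_attrs" not in f or "col_attrs" not in f:
            raise FormatError(f"{path}: missing row_attrs/col_attrs groups")
        gene_attrs, gene_valid = _read_attr_group(f["row_attrs"], n_genes, "Valid")
        cell_attrs, cell_valid = _read_attr_group(f["col_attrs"], n_cells, "_Valid")
        graphs = {}
        if "col_graphs" in f:
            for name in f["col_graphs"]:
                graphs[name] = _graph_from_h5(f["col_graphs"][name])
    if "Gene" not in gene_attrs:
        raise FormatError(f"{path}: row_attrs lack a 'Gene' attribute")
    m = ExpressionMatrix(
        counts=counts,
        cell_attrs=cell_attrs,
        gene_attrs=gene_attrs,
        cell_valid=cell_valid,
        gene_valid=gene_valid,
    )
    m.graphs = graphs
    return m


def _read_attr_group(group, n, valid_key):
    attrs = {}
    valid = None
    for key in group:
        arr = _decode_attr(group[key][:])
        if len(arr) != n:
            raise IntegrityError(
                f"attribute {key!r} has length {len(arr)} against axis "
                f"length {n}"
            )
        if key == valid_key:
            valid = arr.astype(bool)
        else:
            attrs[key] = arr
    df = pd.DataFrame(attrs) if attrs else pd.DataFrame(index=range(n))
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return df, valid


# ---------------------------------------------------------------------------
# TSV fallback: genes × cells, header of cell ids, first column gene symbols
# ---------------------------------------------------------------------------


def _read_tsv(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no cell columns found")
    counts = df.to_numpy().T
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    return ExpressionMatrix(
        counts=counts.astype(np.int64),
        cell_attrs=pd.DataFrame({"CellID": df.columns.to_numpy()}),
        gene_attrs=pd.DataFrame({"Gene": df.index.to_numpy()}),
    )


def write_tsv(m: ExpressionMatrix, path: str) -> str:
    dense = m.counts.toarray() if sp.issparse(m.counts) else np.asarray(m.counts)
    df = pd.DataFrame(
        dense.T, index=m.gene_symbols, columns=m.cell_attrs["CellID"].to_numpy()
    )
    df.to_csv(path, sep="\t")
    return path


# ---------------------------------------------------------------------------
# Aggregated ("…agg.loom") profile I/O
# ---------------------------------------------------------------------------

_PROFILE_LAYERS = ("nonzero_frac", "enrichment", "enrichment_q", "trinaries")


def write_profile(profile: ClusterProfile, path: str) -> str:
    """Write a :class:`ClusterProfile` as an aggregated Loom-dialect file.

    The main matrix holds mean expression (genes × clusters on disk); the
    statistic layers live under ``/layers`` with the conventional names
    ``enrichment``, ``enrichment_q`` and ``trinaries``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=profile.mean_expr.T)
        layers = f.create_group("layers")
        for name in _PROFILE_LAYERS:
            arr = getattr(profile, name)
            if arr is not None:
                layers.create_dataset(name, data=np.asarray(arr, dtype=float).T)
        ra = f.create_group("row_attrs")
        ra.create_dataset("Gene", data=_encode_attr(profile.gene_symbols))
        ca = f.create_group("col_attrs")
        ca.create_dataset("Clusters", data=profile.cluster_ids.astype(np.int64))
        ca.create_dataset("NCells", data=profile.cell_counts.astype(np.int64))
        if profile.nonzero_counts is not None:
            layers.create_dataset(
                "nonzero_counts", data=profile.nonzero_counts.astype(np.int64).T
            )
    return path


def read_profile(path: str) -> ClusterProfile:
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"{path}: missing main 'matrix' dataset")
        mean_expr = f["matrix"][:].T
        layers = f.get("layers", {})
        kw = {}
        for name in _PROFILE_LAYERS:
            if name in layers:
                kw[name] = layers[name][:].T
        if "nonzero_counts" in layers:
            kw["nonzero_counts"] = layers["nonzero_counts"][:].T
        if "nonzero_frac" not in kw:
            raise FormatError(f"{path}: missing 'nonzero_frac' layer")
        nonzero_frac = kw.pop("nonzero_frac")
        return ClusterProfile(
            mean_expr=mean_expr,
            nonzero_frac=nonzero_frac,
            cell_counts=f["col_attrs/NCells"][:],
            gene_symbols=_decode_attr(f["row_attrs/Gene"][:]),
            cluster_ids=f["col_attrs/Clusters"][:],
            **kw,
        )
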