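"""Quality control, major-class classification and doublet removal.

Cells are valid when they carry at least 600 UMIs and at least a 1.2-fold
molecule-to-gene ratio; genes are valid when detected in at least 20 cells
and at most 60% of cells.  Filters are applied separately per input sample
when sample ids are available.

A calibrated linear support-vector classifier assigns each cell a major
class (neurons, astrocytes, vascular, ... plus doublet-composite labels
such as "Vascular-Neurons").  Between pipeline levels, clusters whose
majority class is a doublet-composite or poor-quality label are removed
whole, and cells whose predicted class conflicts with their cluster's
majority are removed individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .data_model import ExpressionMatrix, OUTLIER_LABEL
from .clustering import ClusterResult

__all__ = [
    "QCParams",
    "ClassModel",
    "filter_valid",
    "train_class_model",
    "remove_conflicts",
]


@dataclass
class QCParams:
    min_umis: int = 600
    min_molecule_gene_ratio: float = 1.2
    min_cells_per_gene: int = 20
    max_cell_fraction_per_gene: float = 0.6

    def __post_init__(self):
        if min(self.min_umis, self.min_molecule_gene_ratio, self.min_cells_per_gene) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0.0 < self.max_cell_fraction_per_gene <= 1.0:
            raise ValueError("max_cell_fraction_per_gene must lie in (0, 1]")


def filter_valid(
    m: ExpressionMatrix, p: QCParams = None, sample_key: str = "SampleID"
) -> ExpressionMatrix:
    """Set validity masks in place (and return the matrix).

    Cells are invalid when total UMIs < ``min_umis`` or total UMIs per
    detected gene < ``min_molecule_gene_ratio``.  Genes are invalid when
    detected in fewer than ``min_cells_per_gene`` cells or in more than
    ``max_cell_fraction_per_gene`` of cells.  When ``sample_key`` names an
    existing cell attribute, thresholds apply within each sample; a gene is
    kept if it passes in at least one sample.  Idempotent: masks are
    recomputed from counts alone.
    """
    p = p or QCParams()
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty matrix")
    totals = m.cell_totals()
    detected = m.genes_per_cell()
    ratio = np.divide(
        totals, detected, out=np.zeros(m.n_cells, dtype=float), where=detected > 0
    )
    m.cell_valid = (totals >= p.min_umis) & (ratio >= p.min_molecule_gene_ratio)

    if sample_key in m.cell_attrs:
        samples = m.cell_attrs[sample_key].to_numpy()
    else:
        samples = np.array(["_all"] * m.n_cells)
    binary = (m.counts > 0).astype(np.int64)
    gene_valid = np.zeros(m.n_genes, dtype=bool)
    for s in np.unique(samples):
        idx = np.flatnonzero(samples == s)
        det = np.asarray(binary[idx].sum(axis=0)).ravel()
        ok = (det >= p.min_cells_per_gene) & (
            det <= p.max_cell_fraction_per_gene * len(idx)
        )
        gene_valid |= ok
    m.gene_valid = gene_valid
    return m


@dataclass
class ClassModel:
    """Calibrated linear SVC over log-normalized expression."""

    classes: np.ndarray
    svc: SVC
    gene_indices: np.ndarray
    report: pd.DataFrame = None

    def _features(self, m: ExpressionMatrix) -> np.ndarray:
        x = m.counts[:, self.gene_indices]
        x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
        totals = m.cell_totals().astype(float)
        totals[totals == 0] = 1.0
        return np.log2(x * (5000.0 / totals[:, None]) + 1.0)

    def predict(self, m: ExpressionMatrix) -> np.ndarray:
        return self.svc.predict(self._features(m))

    def predict_proba(self, m: ExpressionMatrix) -> pd.DataFrame:
        proba = self.svc.predict_proba(self._features(m))
        return pd.DataFrame(proba, columns=self.svc.classes_)


def _pool_cycling(label: str) -> str:
    return label.split(",")[0].strip()


def train_class_model(
    m: ExpressionMatrix,
    labels: np.ndarray,
    holdout_fraction: float = 0.2,
    min_cells_per_class: int = 10,
    max_cells_per_class: int = 100,
    seed: int = 0,
) -> ClassModel:
    """Train the major-class classifier on an 80/20 split.

    Up to ``max_cells_per_class`` cells are sampled per class; classes with
    fewer than ``min_cells_per_class`` cells are dropped with a warning.
    The held-out report pools cycling variants ("astrocyte, cycling") with
    their base class.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    keep_idx = []
    for c in pd.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < min_cells_per_class:
            warnings.warn(f"class {c!r} has only {len(idx)} cells; dropped")
            continue
        if len(idx) > max_cells_per_class:
            idx = rng.choice(idx, size=max_cells_per_class, replace=False)
        keep_idx.append(idx)
    if len(keep_idx) < 2:
        raise ValueError("need at least two classes with enough cells")
    keep = np.sort(np.concatenate(keep_idx))

    genes = np.flatnonzero(m.gene_valid)
    model = ClassModel(
        classes=np.array(sorted(set(labels[keep]))),
        svc=SVC(kernel="linear", probability=True, random_state=seed),
        gene_indices=genes,
    )
    x = model._features(m.subset_cells(keep))
    y = labels[keep]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model.svc.fit(x_tr, y_tr)
    pred = model.svc.predict(x_te)
    pooled_true = np.array([_pool_cycling(v) for v in y_te])
    pooled_pred = np.array([_pool_cycling(v) for v in pred])
    rows = []
    for c in sorted(set(pooled_true)):
        tp = np.sum((pooled_pred == c) & (pooled_true == c))
        prec = tp / max(np.sum(pooled_pred == c), 1)
        rec = tp / max(np.sum(pooled_true == c), 1)
        rows.append({"class": c, "precision": prec, "recall": rec})
    model.report = pd.DataFrame(rows).set_index("class")
    return model


def remove_conflicts(
    m: ExpressionMatrix,
    clusters: ClusterResult,
    model: ClassModel = None,
    predicted: np.ndarray = None,
    poor_quality_labels: tuple = ("poor_quality", "low_quality"),
):
    """Remove doublet-suspect cells between pipeline levels.

    Clusters whose majority predicted class is ambiguous — a hyphenated
    doublet-composite label ("Vascular-Neurons") or a configured
    poor-quality label — are removed whole.  Within remaining clusters,
    cells whose predicted class differs from the cluster majority are
    removed.  Returns ``(reduced_matrix, kept_indices, log)``.
    """
    if predicted is None:
        if model is None:
            raise ValueError("either a ClassModel or predicted labels required")
        predicted = model.predict(m)
    predicted = np.asarray(predicted, dtype=object)
    labels = clusters.labels
    keep = np.ones(m.n_cells, dtype=bool)
    log_rows = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if c == OUTLIER_LABEL:
            continue
        vals, counts = np.unique(predicted[idx].astype(str), return_counts=True)
        majority = vals[np.argmax(counts)]
        ambiguous = "-" in majority or majority in poor_quality_labels
        if ambiguous:
            keep[idx] = False
            log_rows.append(
                {"cluster": c, "rule": "ambiguous_cluster", "majority": majority,
                 "n_removed": len(idx)}
            )
            continue
        conflict = idx[predicted[idx].astype(str) != majority]
        keep[conflict] = False
        if len(conflict):
            log_rows.append(
                {"cluster": c, "rule": "conflicting_cells", "majority": majority,
                 "n_removed": len(conflict)}
            )
    log = pd.DataFrame(log_rows, columns=["cluster", "rule", "majority", "n_removed"])
    if not keep.any():
        warnings.warn("conflict removal left no cells")
    kept = np.flatnonzero(keep)
    return m.subset_cells(kept), kept, log
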