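"""FPKM quantification, expression classes, and sample clustering.

FPKM(g, j) = count(g, j) * 1e9 / (length_bp(g) * library_size(j)) with the
library size taken as the column sum of assigned fragments.  Genes are
binned into the four expression classes (low: FPKM <= 5, medium-low:
5 < FPKM <= 20, medium: 20 < FPKM <= 100, high: FPKM > 100), and samples are
clustered by average linkage on 1 - Spearman correlation of the expressed
(FPKM > 1) gene profile.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .io_formats import GeneModel, HaplodynError, ValidationError, models_by_id

__all__ = [
    "fpkm",
    "expression_classes",
    "sample_correlation",
    "low_expression_filter",
    "EXPRESSION_CLASS_BOUNDS",
    "linkage_to_newick",
]

EXPRESSION_CLASS_BOUNDS = (5.0, 20.0, 100.0)
EXPRESSION_CLASS_NAMES = ("low", "medium_low", "medium", "high")


def _gene_lengths(row_ids: Sequence[str], models: Iterable[GeneModel]) -> np.ndarray:
    """Length per row id; allele ids inherit their gene's length unless the
    allele itself is listed as a gene model."""
    table = models_by_id(models)
    by_any_id = dict(table)
    for m in table.values():
        for aid in (m.allele_a_id, m.allele_b_id):
            if aid is not None and aid not in by_any_id:
                by_any_id[aid] = m
    lengths = np.empty(len(row_ids), dtype=float)
    for i, rid in enumerate(row_ids):
        m = by_any_id.get(rid)
        if m is None:
            raise HaplodynError(f"no gene model (length) for feature {rid!r}")
        lengths[i] = m.length_bp
    return lengths


def fpkm(counts: pd.DataFrame, models: Iterable[GeneModel]) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million assigned fragments."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise HaplodynError(f"zero library size for sample {counts.columns[zero[0]]!r}")
    lengths = _gene_lengths(list(counts.index), models)
    values = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * lib[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def expression_classes(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample gene counts in the four FPKM classes (rows = classes)."""
    low, mid, high = EXPRESSION_CLASS_BOUNDS
    vals = expr.to_numpy()
    out = pd.DataFrame(
        {
            "low": (vals <= low).sum(axis=0),
            "medium_low": ((vals > low) & (vals <= mid)).sum(axis=0),
            "medium": ((vals > mid) & (vals <= high)).sum(axis=0),
            "high": (vals > high).sum(axis=0),
        },
        index=expr.columns,
    ).T
    return out


def low_expression_filter(expr: pd.DataFrame, threshold: float = 5.0) -> pd.Index:
    """Ids of genes reaching FPKM >= threshold in at least one sample
    (i.e. drop genes with FPKM < threshold in all samples)."""
    keep = (expr.to_numpy() >= threshold).any(axis=1)
    return expr.index[keep]


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def sample_correlation(
    expr: pd.DataFrame,
    min_fpkm: float = 1.0,
    filter_mode: Literal["any", "all"] = "any",
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Spearman correlation between sample columns and its average-linkage
    clustering on 1 - rho.

    Genes are retained when FPKM > ``min_fpkm`` in at least one sample
    (``filter_mode="any"``) or in every sample (``"all"``).  Returns the
    correlation matrix, the scipy linkage matrix, and a Newick dendrogram.
    """
    if expr.shape[1] < 2:
        raise ValidationError("sample_correlation needs at least two samples")
    vals = expr.to_numpy()
    keep = (vals > min_fpkm).all(axis=1) if filter_mode == "all" else (vals > min_fpkm).any(axis=1)
    if keep.sum() < 2:
        raise ValidationError("fewer than two genes pass the expression filter")
    sub = vals[keep]
    rho = stats.spearmanr(sub, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=expr.columns, columns=expr.columns)
    dist = 1.0 - rho
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = sch.linkage(condensed, method="average")
    newick = linkage_to_newick(linkage, list(expr.columns))
    return corr, linkage, newick
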