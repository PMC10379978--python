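"""Weighted co-expression network: soft threshold, TOM, modules, hubs.

The unsigned network takes adjacency a_ij = |cor(x_i, x_j)|^beta (Pearson,
across samples), with beta chosen as the smallest power reaching a
scale-free topology fit R^2 >= 0.85.  Pairwise similarity is the
topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

modules come from average-linkage clustering on 1 - TOM with a static
branch cut, small clusters fall back to the unassigned "grey" label, and
modules whose eigengenes (first principal component of the standardized
member expression) are closer than the merge cut height are iteratively
merged.  Gene significance (GS) and module membership (MM) are Pearson
correlations of each gene's profile with sample traits and module
eigengenes; hub screening keeps genes with |GS| > 0.2 and |MM| > 0.8 ranked
by their within-module edge count at the export weight threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .io_formats import HaplodynError, SampleMeta, ValidationError, get_logger

__all__ = [
    "pick_soft_threshold",
    "adjacency_matrix",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait",
    "compute_gs_mm",
    "hub_screen",
    "build_network",
    "CoexprNetwork",
    "GREY",
]

GREY = "grey"
_log = get_logger("coexpression")

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of x (genes x samples)."""
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    if np.any(sd == 0):
        raise ValidationError("constant-expression gene in correlation input")
    xn = xc / sd[:, None]
    c = np.clip(xn @ xn.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta (genes x genes)."""
    c = _pearson_rows(expr.to_numpy(dtype=float))
    a = np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression (negative
    slope required for a scale-free signature)."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return 0.0
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    log_k, log_f = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_f.append(np.log10(mask.sum() / k.size))
    if len(log_k) < 3 or np.ptp(log_k) == 0:
        return 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_f)
    if not np.isfinite(slope) or not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = DEFAULT_POWERS,
    target_r2: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power beta.

    Returns the smallest beta whose scale-free fit reaches ``target_r2``;
    when none does, the beta with the best fit (preferring 6 on ties).  Also
    returns the per-power diagnostic table (fit, mean and max connectivity).
    """
    if expr.shape[1] < 4:
        raise ValidationError("need at least 4 samples to pick a soft threshold")
    if expr.shape[0] < 50:
        raise ValidationError("need at least 50 genes to pick a soft threshold")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        _log.warning("excluding %d constant-expression genes", int((sd == 0).sum()))
        vals = vals[sd > 0]
    c = np.abs(_pearson_rows(vals))
    rows = []
    for beta in powers:
        a = c**beta
        k = a.sum(axis=1) - 1.0
        rows.append((beta, _scale_free_fit(k), float(k.mean()), float(k.max())))
    diag = pd.DataFrame(rows, columns=["power", "fit_r2", "mean_k", "max_k"]).set_index("power")
    reaching = diag.index[diag["fit_r2"] >= target_r2]
    if len(reaching):
        return int(reaching[0]), diag
    best = diag["fit_r2"].max()
    candidates = list(diag.index[diag["fit_r2"] >= best - 1e-12])
    beta = 6 if (6 in candidates or not candidates) else candidates[0]
    return int(beta), diag


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix of a symmetric adjacency."""
    is_frame = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if is_frame else np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    k_min = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (k_min + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def module_eigengene(expr_module: np.ndarray) -> np.ndarray:
    """First principal component of the standardized member expression
    (genes x samples), sign-aligned with the module mean profile."""
    x = np.asarray(expr_module, dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    # PC1 across samples: right singular vector of the gene x sample z-matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc1, mean_profile) < 0:
        pc1 = -pc1
    return pc1


def _eigengene_frame(
    expr: pd.DataFrame, labels: pd.Series, module_names: Sequence[str]
) -> pd.DataFrame:
    cols = {}
    for name in module_names:
        members = labels.index[labels == name]
        if len(members) == 0:
            raise HaplodynError(f"module {name!r} has no members")
        cols[name] = module_eigengene(expr.loc[members].to_numpy())
    return pd.DataFrame(cols, index=expr.columns)


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 80,
    merge_cut_height: float = 0.3,
    branch_cut: float = 0.95,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster the TOM into co-expression modules.

    Average-linkage clustering of 1 - TOM is cut at the static height
    ``branch_cut``; clusters below ``min_module_size`` go to grey; module
    eigengenes closer than ``merge_cut_height`` (1 - correlation) are merged
    iteratively, closest pair first.  Returns the gene -> module label
    series (grey = unassigned) and the eigengene table (samples x modules).
    """
    genes = tom.index
    d = 1.0 - tom.to_numpy(dtype=float)
    condensed = d[np.triu_indices_from(d, k=1)]
    linkage = sch.linkage(np.clip(condensed, 0.0, None), method="average")
    raw = sch.fcluster(linkage, t=branch_cut, criterion="distance")
    labels = pd.Series([GREY] * len(genes), index=genes, dtype=object)
    next_id = 1
    for cluster in pd.unique(raw):
        members = genes[raw == cluster]
        if len(members) >= min_module_size:
            labels.loc[members] = f"M{next_id}"
            next_id += 1
    module_names = sorted(set(labels) - {GREY}, key=lambda s: int(s[1:]))
    if not module_names:
        _log.warning("no module reached min_module_size=%d; all genes grey", min_module_size)
        return labels, pd.DataFrame(index=expr.columns)

    eig = _eigengene_frame(expr, labels, module_names)
    # iterative eigengene merging, closest pair first
    while eig.shape[1] > 1:
        cor = np.corrcoef(eig.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            break
        keep, drop = eig.columns[min(i, j)], eig.columns[max(i, j)]
        labels[labels == drop] = keep
        module_names = [m for m in module_names if m != drop]
        eig = _eigengene_frame(expr, labels, module_names)
    # relabel modules by decreasing size for stable naming
    sizes = labels[labels != GREY].value_counts()
    rename = {old: f"M{i + 1}" for i, old in enumerate(sizes.index)}
    labels = labels.map(lambda v: rename.get(v, GREY))
    eig = eig.rename(columns=rename)[[rename[m] for m in sizes.index]]
    return labels, eig


def module_trait(
    eigengenes: pd.DataFrame, samples: Sequence[SampleMeta]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each module eigengene with one-hot
    (treatment, time) indicators, with two-sided t-test p-values."""
    sample_ids = list(eigengenes.index)
    meta = {s.sample_id: s for s in samples}
    conditions = sorted({(meta[sid].treatment, meta[sid].time_h) for sid in sample_ids})
    traits = pd.DataFrame(
        {
            f"{tr}_{t}h": [
                1.0 if (meta[sid].treatment, meta[sid].time_h) == (tr, t) else 0.0
                for sid in sample_ids
            ]
            for tr, t in conditions
        },
        index=sample_ids,
    )
    n = len(sample_ids)
    cor = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    pval = cor.copy()
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy()
        for trait in traits.columns:
            tvec = traits[trait].to_numpy()
            if tvec.std() == 0 or e.std() == 0:
                continue  # undefined, left missing
            r = float(np.corrcoef(e, tvec)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
            cor.loc[mod, trait] = r
            pval.loc[mod, trait] = p
    return cor, pval


def compute_gs_mm(
    expr: pd.DataFrame, eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene significance (gene x trait correlation) and module membership
    (gene x eigengene correlation)."""
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    sd[sd == 0] = np.nan
    xn = xc / sd[:, None]

    def _cor_with(cols: pd.DataFrame) -> pd.DataFrame:
        y = cols.to_numpy(dtype=float).T  # vars x samples
        yc = y - y.mean(axis=1, keepdims=True)
        ysd = np.sqrt((yc**2).sum(axis=1))
        ysd[ysd == 0] = np.nan
        yn = yc / ysd[:, None]
        return pd.DataFrame(xn @ yn.T, index=expr.index, columns=cols.columns)

    return _cor_with(traits), _cor_with(eigengenes)


@dataclass
class CoexprNetwork:
    """The assembled co-expression network and its derived statistics."""

    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    gs: pd.DataFrame
    mm: pd.DataFrame
    module_trait_cor: pd.DataFrame
    module_trait_p: pd.DataFrame
    soft_threshold_diag: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def connectivity(self) -> pd.Series:
        return self.adjacency.sum(axis=1) - 1.0


def hub_screen(
    network: CoexprNetwork,
    gs_min: float = 0.2,
    mm_min: float = 0.8,
    edge_weight_min: float = 0.3,
    top_k: int | None = 20,
    edge_tiers: Sequence[int] = (5, 50),
) -> dict:
    """Export within-module edges at the weight threshold and screen hubs.

    A hub passes |GS| > gs_min for at least one trait and |MM| > mm_min for
    its own module; hubs are ranked by their within-module edge count.  The
    per-gene edge counts and their >= tier indicator table are also
    returned for the ASE-connectivity intersection.
    """
    if network.eigengenes.shape[1] == 0:
        raise HaplodynError("network has no modules (no eigengenes)")
    a = network.adjacency
    labels = network.modules
    edges = []
    edge_count = pd.Series(0, index=a.index, dtype=int)
    for name in network.eigengenes.columns:
        members = list(labels.index[labels == name])
        sub = a.loc[members, members].to_numpy()
        iu, ju = np.triu_indices(len(members), k=1)
        strong = sub[iu, ju] >= edge_weight_min
        for ii, jj in zip(iu[strong], ju[strong]):
            edges.append((members[ii], members[jj], float(sub[ii, jj]), name))
        counts = (sub >= edge_weight_min).sum(axis=1) - (np.diag(sub) >= edge_weight_min)
        edge_count.loc[members] = counts
    edge_table = pd.DataFrame(edges, columns=["source", "target", "weight", "module"])

    gs_pass = (network.gs.abs() > gs_min).any(axis=1)
    mm_own = pd.Series(
        [
            abs(network.mm.loc[g, labels[g]]) if labels[g] != GREY else 0.0
            for g in network.mm.index
        ],
        index=network.mm.index,
    )
    hub_mask = gs_pass & (mm_own > mm_min) & (labels != GREY)
    hubs = (
        pd.DataFrame(
            {
                "gene_id": edge_count.index[hub_mask],
                "module": labels[hub_mask].to_numpy(),
                "edge_count": edge_count[hub_mask].to_numpy(),
                "mm_own": mm_own[hub_mask].to_numpy(),
            }
        )
        .sort_values(["edge_count", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    if top_k is not None:
        top = hubs.head(top_k)
    else:
        top = hubs
    tiers = pd.DataFrame(
        {f"ge_{t}": (edge_count >= t) for t in edge_tiers}, index=edge_count.index
    )
    return {
        "edges": edge_table,
        "edge_count": edge_count,
        "edge_tiers": tiers,
        "hubs": hubs,
        "top_hubs": top,
    }


def build_network(
    expr: pd.DataFrame,
    samples: Sequence[SampleMeta],
    powers: Sequence[int] = DEFAULT_POWERS,
    target_r2: float = 0.85,
    min_module_size: int = 80,
    merge_cut_height: float = 0.3,
    branch_cut: float = 0.95,
    beta: int | None = None,
) -> CoexprNetwork:
    """Run the full network construction on an FPKM matrix (genes x
    samples); fixes ``beta`` if given, otherwise picks it."""
    vals = expr.to_numpy(dtype=float)
    variable = vals.std(axis=1) > 0
    if not variable.all():
        _log.warning("excluding %d constant-expression genes", int((~variable).sum()))
        expr = expr.loc[expr.index[variable]]
    diag = None
    if beta is None:
        beta, diag = pick_soft_threshold(expr, powers=powers, target_r2=target_r2)
    adj = adjacency_matrix(expr, beta)
    tom = topological_overlap(adj)
    modules, eigengenes = detect_modules(
        tom, expr, min_module_size=min_module_size,
        merge_cut_height=merge_cut_height, branch_cut=branch_cut,
    )
    meta = {s.sample_id: s for s in samples}
    conditions = sorted({(meta[c].treatment, meta[c].time_h) for c in expr.columns})
    traits = pd.DataFrame(
        {
            f"{tr}_{t}h": [
                1.0 if (meta[c].treatment, meta[c].time_h) == (tr, t) else 0.0
                for c in expr.columns
            ]
            for tr, t in conditions
        },
        index=expr.columns,
    )
    gs, mm = compute_gs_mm(expr, eigengenes, traits)
    if eigengenes.shape[1]:
        mt_cor, mt_p = module_trait(eigengenes, samples)
    else:
        mt_cor = pd.DataFrame()
        mt_p = pd.DataFrame()
    return CoexprNetwork(
        beta=beta,
        adjacency=adj,
        tom=tom,
        modules=modules,
        eigengenes=eigengenes,
        gs=gs,
        mm=mm,
        module_trait_cor=mt_cor,
        module_trait_p=mt_p,
        soft_threshold_diag=diag,
    )
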