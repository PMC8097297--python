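"""Cross-assay specificity matrices, clustering, and design concordance.

The specificity heatmap collects, over all assays, every 8-mer class
enriched (E >= 0.45 by default) in at least one assay, transforms raw E
cellwise as s(E) = max(0, 10^(10 E) - 3) to emphasize the high-E regime,
and min-max normalizes the whole matrix to [0, 100].  Assays and 8-mers are
then grouped by hierarchical clustering; the displayed dendrograms use
complete linkage on Pearson distance (1 - r) while the cell grouping uses
average linkage on Euclidean distance of the scaled values.

Concordance asks, per protein assayed on two independent array designs,
whether its two 8-mer profiles agree with each other better than with any
other protein's assay — the hallmark of a successful, sequence-specific
PBM experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

from .kmers import KmerStatTable, enriched_kmers

__all__ = [
    "SpecificityMatrix", "ClusterResult", "ConcordanceReport",
    "scale_transform", "scale_escores", "build_specificity_matrix",
    "cluster_matrix", "concordance", "pearson_distance_matrix",
    "linkage_to_newick",
]


def scale_transform(E):
    """Cellwise scaled E-score before normalization: max(0, 10^(10 E) - 3)."""
    return np.maximum(10.0 ** (10.0 * np.asarray(E, dtype=float)) - 3.0, 0.0)


def scale_escores(E_matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the scaled-E transform and min-max normalize to [0, 100].

    Normalization is over the whole matrix (not per row); missing cells stay
    missing.  Raises on an all-missing matrix.  A constant matrix maps to 0.
    """
    E_matrix = pd.DataFrame(E_matrix).astype(float)
    if E_matrix.isna().all().all():
        raise ValueError("all E-scores missing")
    s = pd.DataFrame(np.where(E_matrix.isna(), np.nan, scale_transform(E_matrix.fillna(0.0))),
                     index=E_matrix.index, columns=E_matrix.columns)
    lo, hi = np.nanmin(s.to_numpy()), np.nanmax(s.to_numpy())
    if hi > lo:
        return (s - lo) / (hi - lo) * 100.0
    return s * 0.0


@dataclass
class SpecificityMatrix:
    """Assays x enriched-8-mer-classes matrix, scaled to [0, 100]."""

    scaled: pd.DataFrame
    raw_E: pd.DataFrame
    threshold: float = 0.45

    def to_tsv(self, path, raw: bool = False):
        df = self.raw_E if raw else self.scaled
        df.rename_axis("assay_id").to_csv(path, sep="\t", na_rep="NA",
                                          float_format="%.10g")


def build_specificity_matrix(tables: list[KmerStatTable],
                             threshold: float = 0.45) -> SpecificityMatrix:
    """Assemble the cross-assay matrix over the union of enriched classes."""
    if not tables:
        raise ValueError("no k-mer tables supplied")
    union: set = set()
    for t in tables:
        union |= enriched_kmers(t, threshold)
    if not union:
        maxima = {t.assay_id: float(t.df["E"].max()) for t in tables}
        raise ValueError(
            f"no 8-mer class reaches E >= {threshold} in any assay "
            f"(per-assay max E: {maxima})")
    cols = sorted(union)
    raw = pd.DataFrame({t.assay_id: t.df["E"].reindex(cols) for t in tables}).T
    raw.index.name = "assay_id"
    return SpecificityMatrix(scale_escores(raw), raw, threshold)


def pearson_distance_matrix(X: pd.DataFrame, min_shared: int = 20):
    """Pairwise Pearson distance (1 - r) with pairwise-complete cells.

    Pairs with fewer than ``min_shared`` shared non-missing columns (or zero
    variance) are reported missing and set to the maximal distance 2.0 for
    linkage purposes.  Returns (square distance DataFrame, missing-pair
    boolean DataFrame).
    """
    arr = X.to_numpy(dtype=float)
    mask = np.isfinite(arr)
    A = np.where(mask, arr, 0.0)
    M = mask.astype(float)
    n_shared = M @ M.T
    # pairwise-complete moments: S1[i, j] = sum of row i over cols shared
    # with row j, and so on; all O(n^2 m) BLAS products
    S1 = A @ M.T
    S2 = (A * A) @ M.T
    Sxy = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = S1 / n_shared
        my = mx.T
        cov = Sxy / n_shared - mx * my
        vx = np.maximum(S2 / n_shared - mx * mx, 0.0)
        vy = vx.T
        r = cov / np.sqrt(vx * vy)
    scale = np.maximum(np.nanmax(np.abs(A)), 1.0)
    degenerate = (vx <= (1e-13 * scale) ** 2) | (vy <= (1e-13 * scale) ** 2)
    bad = (n_shared < max(min_shared, 2)) | degenerate | ~np.isfinite(r)
    r = np.clip(np.where(bad, np.nan, r), -1.0, 1.0)
    D = np.where(bad, 2.0, 1.0 - r)
    np.fill_diagonal(D, 0.0)
    missing = bad.copy()
    np.fill_diagonal(missing, False)
    return (pd.DataFrame(D, index=X.index, columns=X.index),
            pd.DataFrame(missing, index=X.index, columns=X.index))


@dataclass
class ClusterResult:
    """Dendrograms and ordering for a specificity matrix.

    ``row_linkage``/``col_linkage`` are the displayed complete-linkage
    Pearson-distance dendrograms; ``row_linkage_avg``/``col_linkage_avg``
    are the average-linkage Euclidean groupings of the scaled cells.
    Singleton axes get a None linkage.
    """

    ordered: pd.DataFrame
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_linkage_avg: np.ndarray | None = None
    col_linkage_avg: np.ndarray | None = None
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)
    row_labels: list = field(default_factory=list)  # original (linkage leaf-id) order
    col_labels: list = field(default_factory=list)
    missing_row_pairs: pd.DataFrame | None = None


def _axis_linkages(X: pd.DataFrame, min_shared: int):
    if X.shape[0] < 2:
        return None, None, list(X.index), None
    D, missing = pearson_distance_matrix(X, min_shared=min_shared)
    Z_pearson = linkage(squareform(D.to_numpy(), checks=False), method="complete")
    D_eu = nan_euclidean_distances(X.to_numpy(dtype=float))
    np.fill_diagonal(D_eu, 0.0)
    D_eu = np.nan_to_num(D_eu, nan=float(np.nanmax(D_eu)) if np.isfinite(D_eu).any() else 0.0)
    Z_avg = linkage(squareform(D_eu, checks=False), method="average")
    order = [X.index[i] for i in leaves_list(Z_pearson)]
    return Z_pearson, Z_avg, order, missing


def cluster_matrix(matrix: SpecificityMatrix, min_shared_rows: int = 20,
                   min_shared_cols: int = 2) -> ClusterResult:
    """Cluster assays (rows) and 8-mer classes (columns) of the matrix.

    Row/column dendrograms: complete linkage on Pearson distances of the
    scaled profiles, missing cells pairwise-excluded; cell grouping:
    average linkage on (nan-aware) Euclidean distances.  Ordering is the
    dendrogram leaf order and is deterministic for a fixed input order
    (scipy breaks ties by input order).  A single-row matrix yields a
    singleton result with no row linkage.
    """
    X = matrix.scaled
    row_Z, row_Z_avg, row_order, missing_rows = _axis_linkages(
        X, min_shared=min_shared_rows)
    col_Z, col_Z_avg, col_order, _ = _axis_linkages(X.T, min_shared=min_shared_cols)
    ordered = X.loc[row_order, col_order]
    return ClusterResult(ordered=ordered, row_linkage=row_Z, col_linkage=col_Z,
                         row_linkage_avg=row_Z_avg, col_linkage_avg=col_Z_avg,
                         row_order=row_order, col_order=col_order,
                         row_labels=list(X.index), col_labels=list(X.columns),
                         missing_row_pairs=missing_rows)


def linkage_to_newick(Z: np.ndarray | None, labels: list) -> str:
    """Newick serialization of a scipy linkage matrix.

    ``labels`` must be in the original (leaf-id) order used to build the
    linkage, e.g. ``ClusterResult.row_labels``, not the displayed leaf
    order.
    """
    if Z is None:
        if len(labels) != 1:
            raise ValueError("linkage required for more than one leaf")
        return f"{labels[0]};"
    from skbio.tree import TreeNode
    tree = TreeNode.from_linkage_matrix(Z, [str(x) for x in labels])
    return str(tree).strip()


def _pair_correlation(t1: KmerStatTable, t2: KmerStatTable,
                      threshold: float) -> float:
    """Pearson r between two assays' E profiles over the union of classes
    enriched in either assay (pairwise-complete)."""
    classes = sorted(enriched_kmers(t1, threshold) | enriched_kmers(t2, threshold))
    if len(classes) < 2:
        return math.nan
    x = t1.df["E"].reindex(classes)
    y = t2.df["E"].reindex(classes)
    ok = x.notna() & y.notna()
    if ok.sum() < 2:
        return math.nan
    x, y = x[ok].to_numpy(), y[ok].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ConcordanceReport:
    """Per-protein cross-design agreement and success calls.

    ``df`` is indexed by protein with columns r_self, r_best_other,
    best_other_assay, n_shared_enriched, success.  Proteins lacking a
    design are listed in ``excluded``.
    """

    df: pd.DataFrame
    threshold: float
    excluded: list = field(default_factory=list)

    def to_tsv(self, path):
        self.df.rename_axis("protein_id").to_csv(path, sep="\t", na_rep="NA",
                                                 float_format="%.10g")


def concordance(tables_by_protein_and_design: dict,
                threshold: float = 0.45) -> ConcordanceReport:
    """Cross-design concordance and success calling.

    Input maps protein_id -> {design_id -> KmerStatTable}; each protein
    needs both designs (others are flagged and excluded).  For each protein:
    r_self is the Pearson r between its two designs' E profiles over the
    union of their enriched classes; r_best_other the maximum r between any
    of its assays and any assay of another protein (profiles compared on the
    union of the pair's enriched classes).  Success requires r_self finite,
    r_self > r_best_other, and at least one class enriched on both designs.
    """
    complete = {}
    excluded = []
    for pid, designs in tables_by_protein_and_design.items():
        if len(designs) >= 2:
            complete[pid] = designs
        else:
            excluded.append(pid)
    rows = {}
    for pid, designs in complete.items():
        design_ids = sorted(designs)
        t_a, t_b = designs[design_ids[0]], designs[design_ids[1]]
        r_self = _pair_correlation(t_a, t_b, threshold)
        shared = enriched_kmers(t_a, threshold) & enriched_kmers(t_b, threshold)
        r_best, best_assay = -math.inf, ""
        for qid, q_designs in complete.items():
            if qid == pid:
                continue
            for own in (t_a, t_b):
                for q_table in q_designs.values():
                    r = _pair_correlation(own, q_table, threshold)
                    if not math.isnan(r) and r > r_best:
                        r_best, best_assay = r, q_table.assay_id
        if math.isinf(r_best):
            r_best = math.nan
        success = (not math.isnan(r_self) and len(shared) > 0
                   and (math.isnan(r_best) or r_self > r_best))
        rows[pid] = {"r_self": r_self, "r_best_other": r_best,
                     "best_other_assay": best_assay,
                     "n_shared_enriched": len(shared), "success": success}
    df = pd.DataFrame.from_dict(rows, orient="index") if rows else pd.DataFrame(
        columns=["r_self", "r_best_other", "best_other_assay",
                 "n_shared_enriched", "success"])
    df.index.name = "protein_id"
    return ConcordanceReport(df, threshold, excluded)


def plot_heatmap(result: ClusterResult, path):
    """Optional SVG/PNG rendering of the ordered specificity matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, result.ordered.shape[1] / 12),
                                    max(3, result.ordered.shape[0] / 2)))
    im = ax.imshow(result.ordered.to_numpy(dtype=float), aspect="auto",
                   cmap="viridis", vmin=0, vmax=100)
    ax.set_yticks(range(len(result.row_order)), result.row_order, fontsize=7)
    ax.set_xticks([])
    ax.set_xlabel(f"{result.ordered.shape[1]} enriched 8-mer classes")
    fig.colorbar(im, ax=ax, label="scaled E-score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
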