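"""Relative qPCR quantification and RNA-Seq heatmap preprocessing.

Implements the geNorm reference-gene stability measure M with iterative
exclusion ranking, the 2^-ddCt relative-expression calculation against a
mean of reference genes and a calibrator group, and the heatmap stage used
for expression matrices: log-transform, per-gene z-scoring and Ward
hierarchical clustering.

Table layout convention: genes in rows, samples in columns (the cuffnorm-
style FPKM export and most qPCR exports).  Missing Ct / FPKM values are
NaN and are never silently imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree


class ExpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# geNorm stability
# ---------------------------------------------------------------------------

def genorm_m(ct: pd.DataFrame) -> pd.Series:
    """geNorm M value per candidate reference gene.

    ``ct`` holds Ct cycles, genes in rows, samples in columns.  Because
    expression is 2^-Ct (up to efficiency), the log2 expression ratio of
    genes j and k in a sample is Ct_k - Ct_j.  M(j) is the mean over the
    other candidates k of the SD across samples of that ratio.
    """
    if ct.shape[0] < 2:
        raise ExpressionError("need at least two candidate genes")
    if ct.shape[1] < 2:
        raise ExpressionError("need at least two samples")
    if ct.isna().any().any():
        raise ExpressionError("missing Ct values; drop or resolve them first")
    genes = list(ct.index)
    mat = ct.to_numpy(dtype=float)
    m = {}
    for i, g in enumerate(genes):
        sds = [np.std(mat[k] - mat[i], ddof=1)
               for k in range(len(genes)) if k != i]
        m[g] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_stability(ct: pd.DataFrame) -> pd.DataFrame:
    """Iterative-exclusion geNorm ranking of candidate reference genes.

    The gene with the highest M is removed and M recomputed until two
    remain.  Returns one row per gene with its M at the round it was
    dropped (the final pair shares rank 1); ``exclusion_order`` 1 marks the
    least stable (first excluded) gene.
    """
    if ct.shape[0] < 3:
        raise ExpressionError(
            "geNorm ranking needs >= 3 candidates (pairwise SDs of the "
            "final pair are indistinguishable)")
    remaining = ct.copy()
    rows = []
    order = 0
    while remaining.shape[0] > 2:
        m = genorm_m(remaining)
        worst = m.idxmax()
        order += 1
        rows.append((worst, float(m[worst]), order))
        remaining = remaining.drop(index=worst)
    m = genorm_m(remaining)
    for g in m.sort_values(ascending=False).index:
        rows.append((g, float(m[g]), 0))
    out = pd.DataFrame(rows, columns=["gene", "M", "exclusion_order"])
    return out.set_index("gene")


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

def ddct(ct: pd.DataFrame,
         reference_genes: list[str],
         sample_groups: dict[str, str] | pd.Series,
         calibrator_group: str,
         target_genes: list[str] | None = None,
         per_sample_folds: bool = False,
         ) -> pd.DataFrame:
    """Relative expression 2^-ddCt per target gene and sample group.

    dCt(sample) = Ct_target - mean(Ct of reference genes);
    ddCt(group)  = mean dCt over the group - mean dCt over the calibrator;
    fold = 2^-ddCt.  The calibrator group's fold change is 1 by
    construction.  With ``per_sample_folds`` the group value is instead the
    mean of per-sample fold changes (an alternative convention, off by
    default).
    """
    groups = pd.Series(sample_groups)
    missing = [s for s in ct.columns if s not in groups.index]
    if missing:
        raise ExpressionError(f"samples without group assignment: {missing}")
    if calibrator_group not in set(groups):
        raise ExpressionError(f"calibrator group {calibrator_group!r} absent")
    for g in reference_genes:
        if g not in ct.index:
            raise ExpressionError(f"reference gene {g!r} not in table")
    if target_genes is None:
        target_genes = [g for g in ct.index if g not in set(reference_genes)]
    ref_mean = ct.loc[reference_genes].mean(axis=0)
    rows = []
    for gene in target_genes:
        dct = ct.loc[gene] - ref_mean                     # per sample
        cal = dct[groups[ct.columns] == calibrator_group].mean()
        for grp in pd.unique(groups[ct.columns]):
            sel = dct[groups[ct.columns] == grp]
            if per_sample_folds:
                fold = float(np.power(2.0, -(sel - cal)).mean())
            else:
                fold = float(2.0 ** -(sel.mean() - cal))
            rows.append((gene, grp, fold))
    return pd.DataFrame(rows, columns=["gene", "group", "fold_change"])


# ---------------------------------------------------------------------------
# heatmap stage: log z-score + Ward clustering
# ---------------------------------------------------------------------------

def zscore_log(fpkm: pd.DataFrame,
               base: float = 2.0,
               pseudocount: float = 1.0,
               ) -> pd.DataFrame:
    """Row-wise z-scores of log(FPKM + pseudocount).

    Rows containing missing values are removed (never imputed), as are
    zero-variance rows, which cannot be scaled.  Every surviving row has
    mean 0 and SD 1 (sample SD, ddof=1).
    """
    if (fpkm.fillna(0) < 0).any().any():
        raise ExpressionError("FPKM values must be non-negative")
    kept = fpkm.dropna(axis=0)
    logged = np.log(kept + pseudocount) / np.log(base)
    sd = logged.std(axis=1, ddof=1)
    logged = logged[sd > 0]
    return logged.sub(logged.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


def ward_cluster(z: pd.DataFrame, axis: str = "rows") -> dict:
    """Ward (Ward.D2: squared Euclidean criterion) agglomerative clustering.

    Returns the scipy linkage matrix, leaf order and labels for the chosen
    axis.  Merge heights are non-decreasing (Ward is reducible).
    """
    if axis not in {"rows", "columns"}:
        raise ExpressionError("axis must be 'rows' or 'columns'")
    mat = z.to_numpy(dtype=float)
    labels = list(z.index) if axis == "rows" else list(z.columns)
    if axis == "columns":
        mat = mat.T
    if mat.shape[0] < 2:
        raise ExpressionError("need at least two observations to cluster")
    lk = linkage(mat, method="ward")
    return {"linkage": lk, "leaves": leaves_list(lk).tolist(), "labels": labels}


def cut_two(cluster: dict) -> np.ndarray:
    """Labels (0/1) of the top split of a clustering result."""
    from scipy.cluster.hierarchy import fcluster
    return fcluster(cluster["linkage"], t=2, criterion="maxclust") - 1


def to_newick(cluster: dict) -> str:
    """Serialize a clustering result as a Newick tree with merge heights."""
    tree = to_tree(cluster["linkage"])
    labels = cluster["labels"]

    def walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
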