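"""Morphotype discovery and classification.

Hierarchical clustering with Ward's objective on Manhattan distances of
z-scored descriptors, branch identity assignment with minority-cell
filtering, silhouette / Calinski-Harabasz k-selection, a linear
discriminant classifier with Wilks'-lambda significance, and PCA with
permutation-tested component/loading significance plus bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.model_selection import train_test_split

from .morphometrics import DESCRIPTOR_NAMES
from .synthetic import ROI_ORDER

__all__ = [
    "DendrogramResult",
    "LDAModel",
    "PCAPermResult",
    "cut_and_identify",
    "hca_ward_manhattan",
    "lda_train_test",
    "linkage_to_newick",
    "optimal_k",
    "pca_permutation",
    "wilks_test",
]

LDA_PREDICTORS: tuple[str, ...] = ("CA", "DEN", "CC")
PCA_PARAMETERS: tuple[str, ...] = tuple(n for n in DESCRIPTOR_NAMES if n not in LDA_PREDICTORS)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in DESCRIPTOR_NAMES] or [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]


class StandardizationRequiredError(ValueError):
    pass


def _require_standardized(x: np.ndarray, tol: float = 0.01) -> None:
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(np.abs(sd - 1.0) > tol)
    if bad.size:
        raise StandardizationRequiredError(
            f"input must be z-scored; column indices {bad.tolist()} have SD {sd[bad]}"
        )


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class DendrogramResult:
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    distance_summary: dict[str, float]
    cut_k: int | None = None
    labels: np.ndarray | None = None  # cluster id (1..k) per cell
    composition: pd.DataFrame | None = None  # cluster x ROI fractions
    identity: dict[int, str] | None = None  # cluster id -> ROI name
    minority_cells: np.ndarray | None = None  # indices of excluded cells
    ambiguous: bool = False
    cluster_sizes: dict[int, int] = field(default_factory=dict)


def hca_ward_manhattan(
    table: pd.DataFrame, columns: list[str] | None = None
) -> DendrogramResult:
    """Agglomerate z-scored cells with Ward's objective on Manhattan distances.

    The Lance-Williams Ward update is applied directly to the supplied
    Manhattan dissimilarities (Ward's derivation is Euclidean; using city-block
    input is a deliberate, documented choice). Merge heights are nondecreasing.
    """
    cols = columns if columns is not None else _feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    _require_standardized(x)
    d = pdist(x, metric="cityblock")
    z = linkage(d, method="ward")
    return DendrogramResult(
        linkage=z,
        distance_summary={
            "min": float(d.min()), "median": float(np.median(d)), "max": float(d.max())
        },
    )


def cut_and_identify(
    tree: DendrogramResult,
    k: int,
    roi_labels: np.ndarray,
    roi_order: tuple[str, ...] = ROI_ORDER,
) -> DendrogramResult:
    """Cut the dendrogram into ``k`` branches and name each by its modal ROI.

    Branch identity is the ROI most represented in the branch; ties break
    toward the larger cluster, then the fixed ROI order. Cells whose own ROI
    differs from their branch identity are flagged as minority cells (these
    are excluded before classification). Two branches sharing an identity
    set ``ambiguous`` rather than raising.
    """
    roi = np.asarray(roi_labels)
    n = roi.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    labels = fcluster(tree.linkage, t=k, criterion="maxclust")
    cluster_ids = sorted(np.unique(labels))

    rois_present = [r for r in roi_order if r in set(roi)] + [
        r for r in pd.unique(roi) if r not in roi_order
    ]
    comp = pd.DataFrame(
        0.0, index=cluster_ids, columns=rois_present
    )
    sizes: dict[int, int] = {}
    for cid in cluster_ids:
        members = roi[labels == cid]
        sizes[cid] = members.size
        for r in rois_present:
            comp.loc[cid, r] = float((members == r).sum()) / members.size

    # identity: argmax composition; ties by larger cluster then ROI order
    identity: dict[int, str] = {}
    order = sorted(cluster_ids, key=lambda c: -sizes[c])
    for cid in order:
        row = comp.loc[cid]
        best = row.max()
        candidates = [r for r in rois_present if row[r] == best]
        identity[cid] = candidates[0]
    ambiguous = len(set(identity.values())) < len(cluster_ids)

    minority = np.flatnonzero(
        np.array([roi[i] != identity[labels[i]] for i in range(n)])
    )
    return DendrogramResult(
        linkage=tree.linkage,
        distance_summary=tree.distance_summary,
        cut_k=k,
        labels=labels,
        composition=comp,
        identity=identity,
        minority_cells=minority,
        ambiguous=ambiguous,
        cluster_sizes=sizes,
    )


def optimal_k(
    table: pd.DataFrame,
    k_range: range = range(2, 9),
    columns: list[str] | None = None,
    low_confidence_silhouette: float = 0.25,
) -> dict:
    """Score Ward/Manhattan cuts over ``k_range`` and pick the silhouette max.

    Silhouette uses the same Manhattan metric as the clustering; the
    Calinski-Harabasz index is reported alongside for concordance. A best
    silhouette below ``low_confidence_silhouette`` sets ``low_confidence``.
    """
    cols = columns if columns is not None else _feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    if x.shape[0] <= max(k_range):
        raise ValueError("need more cells than max(k_range)")
    tree = hca_ward_manhattan(table, columns=cols)
    sil, ch = {}, {}
    for k in k_range:
        lab = fcluster(tree.linkage, t=k, criterion="maxclust")
        if np.unique(lab).size < 2:
            sil[k], ch[k] = -1.0, 0.0
            continue
        sil[k] = float(silhouette_score(x, lab, metric="cityblock"))
        ch[k] = float(calinski_harabasz_score(x, lab))
    chosen = max(sil, key=lambda k: sil[k])
    return {
        "silhouette": sil,
        "calinski_harabasz": ch,
        "chosen_k": chosen,
        "low_confidence": sil[chosen] < low_confidence_silhouette,
        "tree": tree,
    }


def linkage_to_newick(z: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = to_tree(z)
    names = leaf_names or [f"cell_{i}" for i in range(tree.get_count())]

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = recurse(node.get_left(), node.dist)
        right = recurse(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.get_left(), tree.dist)},{recurse(tree.get_right(), tree.dist)});"


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # (p, g-1) standardized discriminant coefficients
    proportion_of_trace: np.ndarray  # per discriminant axis
    n_groups: int
    n_axes: int
    train_n: int
    test_n: int
    seed: int
    accuracy: float
    predictions: pd.DataFrame
    scores_train: np.ndarray  # discriminant scores Y of training cells
    train_means: np.ndarray
    train_sds: np.ndarray
    _sk_model: LinearDiscriminantAnalysis | None = None
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None


def lda_train_test(
    table: pd.DataFrame,
    identities: np.ndarray,
    predictors: tuple[str, ...] = LDA_PREDICTORS,
    train_frac: float = 0.7,
    seed: int = 0,
) -> LDAModel:
    """Fisher discriminant classifier on a stratified 70/30 split.

    Predictors are standardized with training-set statistics; the model
    yields g-1 discriminant axes Y = A1 X1 + ... + Ap Xp with standardized
    coefficients, per-axis proportion of trace (explained between-group
    variance) and held-out accuracy.
    """
    y = np.asarray(identities)
    groups, counts = np.unique(y, return_counts=True)
    g = groups.size
    p = len(predictors)
    if g < 2:
        raise ValueError("need >= 2 groups")
    x = table[list(predictors)].to_numpy(dtype=float)

    idx_train, idx_test = train_test_split(
        np.arange(y.size), train_size=train_frac, stratify=y, random_state=seed
    )
    if any((y[idx_train] == gr).sum() < p + 1 for gr in groups):
        raise ValueError("each group needs >= p + 1 training members")

    mu = x[idx_train].mean(axis=0)
    sd = x[idx_train].std(axis=0, ddof=1)
    if (sd == 0).any():
        raise np.linalg.LinAlgError("constant predictor in training data")
    xs = (x - mu) / sd

    clf = LinearDiscriminantAnalysis(solver="eigen")
    clf.fit(xs[idx_train], y[idx_train])
    pred = clf.predict(xs[idx_test])
    accuracy = float((pred == y[idx_test]).mean())

    n_axes = min(g - 1, p)
    coef = clf.scalings_[:, :n_axes]
    evr = clf.explained_variance_ratio_[:n_axes]
    evr = evr / evr.sum()

    predictions = pd.DataFrame({
        "index": idx_test,
        "true": y[idx_test],
        "predicted": pred,
    })
    return LDAModel(
        predictors=tuple(predictors),
        coefficients=coef,
        proportion_of_trace=evr,
        n_groups=g,
        n_axes=n_axes,
        train_n=idx_train.size,
        test_n=idx_test.size,
        seed=seed,
        accuracy=accuracy,
        predictions=predictions,
        scores_train=xs[idx_train] @ coef,
        train_means=mu,
        train_sds=sd,
        _sk_model=clf,
        _train_X=xs[idx_train],
        _train_y=y[idx_train],
    )


def wilks_test(model: LDAModel) -> tuple[float, float, int, float]:
    """Wilks' lambda with Bartlett's chi-squared approximation.

    Lambda = det(W) / det(T) on the training data (W within-group, T total
    scatter); chi2 = -(N - 1 - (p + g)/2) ln(Lambda); df = p (g - 1).
    """
    x = model._train_X
    y = model._train_y
    if x is None or y is None:
        raise ValueError("model carries no training data")
    n, p = x.shape
    groups = np.unique(y)
    g = groups.size
    grand = x.mean(axis=0)
    t_mat = (x - grand).T @ (x - grand)
    w_mat = np.zeros_like(t_mat)
    for gr in groups:
        sub = x[y == gr]
        c = sub - sub.mean(axis=0)
        w_mat += c.T @ c
    det_t = np.linalg.det(t_mat)
    if det_t <= 0:
        raise np.linalg.LinAlgError("singular total scatter matrix")
    lam = float(np.linalg.det(w_mat) / det_t)
    chi2 = float(-(n - 1 - (p + g) / 2.0) * np.log(lam))
    df = p * (g - 1)
    pval = float(sps.chi2.sf(chi2, df))
    return lam, chi2, df, pval


# ---------------------------------------------------------------------------
# Permutation-tested PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAPermResult:
    parameters: tuple[str, ...]
    percent_variance: np.ndarray  # per PC, sums to 100
    percent_ci: np.ndarray  # (n_pc, 2) bootstrap CI bounds
    significant_pcs: list[int]  # 1-based indices
    index_loadings: np.ndarray  # (p, n_pc): squared loading x percent variance
    loading_significant: np.ndarray  # boolean (p, n_pc), for significant PCs
    null_percentiles: np.ndarray  # 95th percentile of null percent variance per rank
    n_permutations: int
    n_bootstrap: int
    seed: int
    scores: np.ndarray  # cell scores on all PCs


def _pca_percent_and_loadings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation-matrix PCA: percent variances, unit loadings, scores."""
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    cov = np.cov(xs, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude entry of each eigenvector positive
    flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])])
    evecs = evecs * flip
    percent = 100.0 * evals / evals.sum()
    return percent, evecs, xs @ evecs


def pca_permutation(
    table: pd.DataFrame,
    parameters: tuple[str, ...] | list[str] | None = None,
    n_permutations: int = 1000,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PCAPermResult:
    """PCA with permutation-based component and loading significance.

    PCA runs on the correlation matrix. The null is built by permuting each
    column independently across rows (destroying correlation, preserving
    marginals): a PC is significant when its observed percent variance
    exceeds the null's (1 - alpha) percentile at the same rank. The index
    loading of variable j on PC k is its squared unit loading times PC k's
    percent variance, tested against its own permutation null. Bootstrap
    resampling of cells gives percentile CIs for percent variance.
    """
    cols = list(parameters) if parameters is not None else _feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 cells and >= 2 columns")
    if (x.std(axis=0, ddof=1) == 0).any():
        bad = [c for c in cols if table[c].std(ddof=1) == 0]
        raise ValueError(f"constant column(s): {bad}")
    rng = np.random.default_rng(seed)

    percent, loadings, scores = _pca_percent_and_loadings(x)
    index_load = loadings**2 * percent[None, :]

    null_percent = np.empty((n_permutations, p))
    null_index = np.empty((n_permutations, p, p))
    for b in range(n_permutations):
        xp = np.column_stack([rng.permutation(x[:, j]) for j in range(p)])
        pc, ld, _ = _pca_percent_and_loadings(xp)
        null_percent[b] = pc
        null_index[b] = ld**2 * pc[None, :]
    null_q = np.quantile(null_percent, 1.0 - alpha, axis=0)
    significant = [k + 1 for k in range(p) if percent[k] > null_q[k]]

    load_sig = np.zeros((p, p), dtype=bool)
    load_q = np.quantile(null_index, 1.0 - alpha, axis=0)
    for k in range(p):
        if (k + 1) in significant:
            load_sig[:, k] = index_load[:, k] > load_q[:, k]

    if n_bootstrap > 0:
        boot = np.empty((n_bootstrap, p))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boot[b], _, _ = _pca_percent_and_loadings(x[idx])
        ci = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0).T
    else:  # CIs degenerate to the point estimates
        ci = np.column_stack([percent, percent])

    return PCAPermResult(
        parameters=tuple(cols),
        percent_variance=percent,
        percent_ci=ci,
        significant_pcs=significant,
        index_loadings=index_load,
        loading_significant=load_sig,
        null_percentiles=null_q,
        n_permutations=n_permutations,
        n_bootstrap=n_bootstrap,
        seed=seed,
        scores=scores,
    )
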