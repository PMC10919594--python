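"""Univariate and distribution-level statistics for descriptor cohorts.

Covers standardization, the multimodality index used for feature
selection, Pearson correlation screening, Kruskal-Wallis with Dunn's post
hoc, Welch's t, a permutational MANOVA on standardized features, and the
normality checks run as pipeline plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .morphometrics import DESCRIPTOR_NAMES

__all__ = [
    "DegenerateColumnError",
    "MMIResult",
    "PermanovaResult",
    "kruskal_dunn",
    "mmi",
    "normality_tests",
    "pearson_matrix",
    "permanova",
    "select_multimodal",
    "welch_t",
    "zscore_table",
]


class DegenerateColumnError(ValueError):
    pass


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in DESCRIPTOR_NAMES] or [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]


def zscore_table(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Standardize feature columns to mean 0 and sample SD 1 (ddof = 1).

    Non-feature columns (cell ids, region labels) pass through unchanged.
    """
    out = table.copy()
    cols = columns if columns is not None else _feature_columns(table)
    for c in cols:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"column {c!r} is constant; cannot standardize")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Multimodality index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMIResult:
    """Sarle-style bimodality score of one descriptor.

    value = (m3^2 + 1) / (m4 + 3 (n-1)^2 / ((n-2)(n-3))) where m3 is the
    bias-corrected sample skewness and m4 the bias-corrected sample excess
    kurtosis. A uniform distribution scores 5/9 ~ 0.556 and a normal 1/3;
    values above 0.55 flag likely multimodality.
    """

    m3: float
    m4: float
    n: int
    value: float


def mmi(values: np.ndarray, bias_corrected: bool = True) -> MMIResult:
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"MMI requires n >= 4, got n = {n}")
    m3 = float(sps.skew(x, bias=not bias_corrected))
    m4 = float(sps.kurtosis(x, fisher=True, bias=not bias_corrected))
    value = (m3**2 + 1.0) / (m4 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return MMIResult(m3=m3, m4=m4, n=n, value=float(value))


def select_multimodal(
    table: pd.DataFrame, threshold: float = 0.55
) -> tuple[list[str], pd.Series]:
    """Feature columns whose MMI exceeds ``threshold``, sorted descending.

    Returns ``(selected_names, mmi_series_for_all_columns)``.
    """
    cols = _feature_columns(table)
    scores = pd.Series(
        {c: mmi(table[c].to_numpy()).value for c in cols}, name="MMI"
    ).sort_values(ascending=False)
    return [c for c in scores.index if scores[c] > threshold], scores


def pearson_matrix(table: pd.DataFrame, subset: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of the selected feature columns."""
    cols = subset if subset is not None else _feature_columns(table)
    if len(cols) < 2 or len(table) < 3:
        raise ValueError("need >= 2 columns and >= 3 rows")
    for c in cols:
        if table[c].std(ddof=1) == 0:
            raise DegenerateColumnError(f"column {c!r} is constant")
    return table[cols].corr(method="pearson")


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def kruskal_dunn(
    values: np.ndarray,
    groups: np.ndarray,
    correction: str = "bonferroni",
) -> tuple[float, int, float, pd.DataFrame]:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post hoc.

    Dunn's z uses the rank sums on the pooled (tie-corrected) ranking; raw
    two-sided p-values are multiplied by the number of pairs for the
    Bonferroni correction. Returns ``(H, df, p, pairwise_table)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    h_stat, p = sps.kruskal(*samples)
    df = len(samples) - 1

    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: (groups == g).sum() for g in names}

    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, raw * len(pairs)) if correction == "bonferroni" else raw
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": raw, "p_adj": adj})
    return float(h_stat), df, float(p), pd.DataFrame(rows)


def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    SS_between: float
    SS_within: float
    df_between: int
    df_total: int
    n_permutations: int
    p_value: float
    pairwise: pd.DataFrame | None


def _permanova_f(dist2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Pseudo-F from a squared-distance matrix and group labels.

    Uses the distance-based sums of squares: SS_total = sum d^2 / n over
    all pairs, SS_within = per-group sum d^2 / n_g.
    """
    n = labels.size
    ss_total = dist2.sum() / (2.0 * n)
    ss_within = 0.0
    groups, counts = np.unique(labels, return_counts=True)
    for g, ng in zip(groups, counts):
        v = (labels == g).astype(float)
        ss_within += (v @ dist2 @ v) / (2.0 * ng)
    ss_between = ss_total - ss_within
    a = groups.size
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between, ss_within


def permanova(
    table: pd.DataFrame,
    labels: np.ndarray | str = "roi",
    n_permutations: int = 999,
    seed: int = 0,
    pairwise: bool = True,
    columns: list[str] | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on Euclidean distances of standardized features.

    p = (#{permuted F >= observed} + 1) / (n_permutations + 1); the same
    scheme runs per group pair with Bonferroni adjustment when ``pairwise``.
    """
    if isinstance(labels, str):
        lab = table[labels].to_numpy()
    else:
        lab = np.asarray(labels)
    cols = columns if columns is not None else _feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    groups = pd.unique(lab)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    dist2 = squareform(pdist(x, metric="euclidean")) ** 2
    rng = np.random.default_rng(seed)

    def run(d2: np.ndarray, la: np.ndarray, nperm: int) -> tuple[float, float, float, float]:
        f_obs, ssb, ssw = _permanova_f(d2, la)
        count = 0
        for _ in range(nperm):
            perm = rng.permutation(la)
            f_perm, _, _ = _permanova_f(d2, perm)
            if f_perm >= f_obs:
                count += 1
        return f_obs, ssb, ssw, (count + 1) / (nperm + 1)

    f_obs, ssb, ssw, p = run(dist2, lab, n_permutations)

    pw = None
    if pairwise:
        pairs = list(combinations(list(groups), 2))
        rows = []
        for a, b in pairs:
            idx = np.flatnonzero((lab == a) | (lab == b))
            f_ab, _, _, p_ab = run(dist2[np.ix_(idx, idx)], lab[idx], n_permutations)
            rows.append({
                "group_a": a, "group_b": b, "pseudo_F": f_ab,
                "p_raw": p_ab, "p_adj": min(1.0, p_ab * len(pairs)),
            })
        pw = pd.DataFrame(rows)

    return PermanovaResult(
        pseudo_F=f_obs, SS_between=ssb, SS_within=ssw,
        df_between=groups.size - 1, df_total=lab.size - 1,
        n_permutations=n_permutations, p_value=p, pairwise=pw,
    )


def permanova_exhaustive_p(x: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p-value by enumerating every label ordering.

    Only feasible for tiny samples; intended as a validation oracle for the
    Monte-Carlo test (with the +1 convention dropped, the Monte-Carlo p
    converges to this exact value).
    """
    lab = np.asarray(labels)
    dist2 = squareform(pdist(np.asarray(x, dtype=float))) ** 2
    f_obs, _, _ = _permanova_f(dist2, lab)
    count = 0
    total = 0
    for perm in permutations(range(lab.size)):
        f_p, _, _ = _permanova_f(dist2, lab[list(perm)])
        if f_p >= f_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def normality_tests(values: np.ndarray) -> tuple[float, float]:
    """(Kolmogorov-Smirnov p, Shapiro-Wilk p) for a sample.

    The KS test compares against a normal with the sample's own mean and SD
    (so its p-values are conservative in the Lilliefors sense); reported for
    pipeline logging, not inference.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample: normality undefined")
    ks_p = float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    sw_p = float(sps.shapiro(x).pvalue)
    return ks_p, sw_p
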