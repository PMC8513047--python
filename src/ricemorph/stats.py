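"""Descriptive multivariate layer: ANOVA/Tukey letters, PCA, clustering.

These are the analyses used to justify the feature set before classifier
training: a one-way ANOVA with Tukey–Kramer HSD post hoc comparisons and a
compact letter display per descriptor, a PCA of the feature table (on
standardized variables by default, so CIELab L's scale does not dominate),
and agglomerative (Ward) clustering of class mean vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import f as f_dist
from scipy.stats import studentized_range


@dataclass
class TukeyResult:
    feature: str
    F: float
    p: float
    group_letters: dict  # class -> letter string, e.g. "a", "bc"
    pairwise: pd.DataFrame  # columns: group1, group2, diff, q, p_adj
    alpha: float


@dataclass
class PcaResult:
    explained: np.ndarray  # percent variance per component, non-increasing
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    scores: np.ndarray  # (n_samples, n_components)
    feature_names: list


def _compact_letter_display(
    groups: list, significant: "set[tuple]"
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups that share a letter are not significantly different; every
    significantly different pair ends up sharing no letter.
    """
    # letters as a list of sets of groups
    letters: list[set] = [set(groups)]
    for g1, g2 in significant:
        for i in range(len(letters)):
            col = letters[i]
            if g1 in col and g2 in col:
                # split the column: duplicate without g1 and without g2
                letters[i] = col - {g1}
                letters.append(col - {g2})
        # absorb: drop columns that are subsets of another
        keep = []
        for i, col in enumerate(letters):
            if not any(
                i != j and col < other or (col == other and i > j)
                for j, other in enumerate(letters)
            ):
                keep.append(col)
        letters = keep
    # stable letter assignment: order columns by first group occurrence
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda col: min(order[g] for g in col) if col else 1e9)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, col in enumerate(letters):
        for g in sorted(col, key=order.get):
            out[g] += alphabet[i % len(alphabet)]
    return out


def anova_tukey(
    table: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    group_col: str = "class_id",
) -> TukeyResult:
    """One-way ANOVA plus Tukey–Kramer HSD pairwise comparisons.

    The Tukey–Kramer form handles unequal group sizes: for groups i, j the
    studentized-range statistic is
    q = |mean_i − mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    referred to the studentized-range distribution with k groups and
    N − k error degrees of freedom.  The compact letter display is built
    with the insert-and-absorb algorithm.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    grouped = table.groupby(group_col)[feature]
    sizes = grouped.size()
    small = sizes[sizes < 2]
    if len(sizes) < 2:
        raise ValueError("ANOVA needs at least two classes")
    if len(small):
        raise ValueError(
            f"classes with fewer than 2 rows: {sorted(small.index.tolist())}"
        )
    means = grouped.mean()
    k = len(sizes)
    N = int(sizes.sum())
    grand = table[feature].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((table[feature] - means.loc[table[group_col]].values) ** 2).sum())
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    F = ms_between / mse if mse > 0 else np.inf
    p = float(f_dist.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0

    groups = list(means.index)
    rows = []
    significant = set()
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            diff = float(means[g1] - means[g2])
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            q = abs(diff) / se if se > 0 else np.inf
            p_adj = float(studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            rows.append(
                {"group1": g1, "group2": g2, "diff": diff, "q": q, "p_adj": p_adj}
            )
            if p_adj < alpha:
                significant.add((g1, g2))
    letters = _compact_letter_display(groups, significant)
    return TukeyResult(
        feature=feature,
        F=float(F),
        p=p,
        group_letters=letters,
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def pca(
    table: pd.DataFrame, standardize: bool = True, n_components: int | None = None
) -> PcaResult:
    """Principal component analysis of the feature columns.

    Columns are centered and, by default, scaled to unit variance
    (correlation-matrix PCA); components come from the eigendecomposition
    of the covariance of the processed columns, ordered by variance.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 feature columns")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [c for c, s in zip(table.columns, sd) if s == 0]
            raise ValueError(f"constant columns cannot be standardized: {const}")
        X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    eigvec = eigvec * np.where(flip == 0, 1.0, flip)
    explained = 100.0 * eigval / eigval.sum()
    if n_components is not None:
        eigvec = eigvec[:, :n_components]
    return PcaResult(
        explained=explained,
        loadings=eigvec,
        scores=X @ eigvec,
        feature_names=list(table.columns),
    )


def hcluster(
    class_means: pd.DataFrame, method: str = "ward", standardize: bool = True
) -> np.ndarray:
    """Agglomerative clustering of class mean vectors.

    Standardizes the feature columns, then runs Euclidean-metric
    agglomerative clustering (Ward linkage by default).  Returns the scipy
    linkage matrix: each row (i, j, height, size) is one merge, heights
    non-decreasing.
    """
    if len(class_means) < 2:
        raise ValueError("clustering needs at least two classes")
    X = class_means.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return linkage(X, method=method, metric="euclidean")


def class_mean_table(table: pd.DataFrame, group_col: str = "class_id") -> pd.DataFrame:
    """Per-class feature means (rows = classes), for clustering or reporting."""
    feature_cols = [
        c for c in table.columns if c not in (group_col,) and table[c].dtype.kind in "fc"
    ]
    return table.groupby(group_col)[feature_cols].mean()
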