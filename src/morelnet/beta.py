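"""Between-sample community structure.

Bray-Curtis dissimilarity on TSS relative abundances, PCA ordination of
centered abundances, and a one-factor PERMANOVA with a seeded
permutation engine. The PERMANOVA partitions the squared dissimilarities

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_factor/(a-1)) / (SS_within/(N-a))

and the p-value counts permuted pseudo-F values at least as large as the
observed one, with the +1 correction, so p >= 1/(permutations+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = ["bray_curtis_matrix", "distance_matrix", "pca", "permanova", "PermanovaResult", "PCAResult"]


def distance_matrix(abund: pd.DataFrame, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise sample dissimilarity of an abundance table.

    ``metric`` is any scipy pdist metric; Bray-Curtis is the default and
    yields entries in [0, 1] on relative abundances.
    """
    if abund.shape[1] < 2:
        raise ValueError("need at least two samples")
    zero = list(abund.columns[abund.sum(axis=0) == 0])
    if zero:
        raise ValueError(f"all-zero samples have undefined dissimilarity: {zero}")
    x = abund.to_numpy(dtype=float).T  # samples x taxa
    condensed = pdist(x, metric=metric)
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in abund.columns])


def bray_curtis_matrix(abund: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix (see :func:`distance_matrix`)."""
    return distance_matrix(abund, metric="braycurtis")


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x retained axes
    explained_pct: np.ndarray     # % variance for every axis, sums to 100
    n_axes: int


def pca(abund: pd.DataFrame, n_axes: int = 2, hellinger: bool = False) -> PCAResult:
    """PCA ordination of samples from a (relative) abundance table.

    Taxa are mean-centered before eigen-decomposition of the sample
    covariance; with ``hellinger=True`` the square-root transform is
    applied first. Axes are ordered by decreasing variance; sample scores
    are reproducible up to sign. ``n_axes`` beyond the matrix rank is
    clipped with a warning.
    """
    from sklearn.decomposition import PCA

    if abund.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = abund.to_numpy(dtype=float).T  # samples x taxa
    if hellinger:
        x = np.sqrt(x)
    max_axes = min(x.shape)
    if n_axes > max_axes:
        warnings.warn(f"n_axes={n_axes} clipped to {max_axes}")
        n_axes = max_axes
    model = PCA(n_components=max_axes, svd_solver="full")
    scores = model.fit_transform(x)
    pct = 100.0 * model.explained_variance_ratio_
    cols = [f"PC{i+1}" for i in range(n_axes)]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :n_axes], index=abund.columns, columns=cols),
        explained_pct=pct,
        n_axes=n_axes,
    )


@dataclass
class PermanovaResult:
    df_factor: int
    df_residual: int
    pseudo_F: float
    R2: float
    p_value: float
    permutations: int
    seed: int | None

    def as_table(self, factor_name: str = "Factor") -> pd.DataFrame:
        """Layout with rows Factor / Residuals / Total and the usual columns."""
        ss_factor = self.R2
        return pd.DataFrame(
            {
                "Df": [self.df_factor, self.df_residual, self.df_factor + self.df_residual],
                "F.Model": [self.pseudo_F, np.nan, np.nan],
                "R2": [self.R2, 1 - self.R2, 1.0],
                "p": [self.p_value, np.nan, np.nan],
            },
            index=[factor_name, "Residuals", "Total"],
        )


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova(dm: DistanceMatrix, grouping, permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    *grouping* maps each sample id in *dm* to a group label (mapping,
    Series, or sequence aligned with ``dm.ids``). The permutation null
    shuffles the labels with a seeded generator.
    """
    ids = list(dm.ids)
    if isinstance(grouping, (dict, pd.Series)):
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length does not match distance matrix")
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = {g: labels.count(g) for g in uniq}
    empty = [g for g, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")

    codes = np.array([uniq.index(g) for g in labels])
    n = len(ids)
    a = len(uniq)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_factor = ss_total - ss_within
    df_factor = a - 1
    df_resid = n - a
    pseudo_f = (ss_factor / df_factor) / (ss_within / df_resid) if ss_within > 0 else np.inf
    r2 = ss_factor / ss_total if ss_total > 0 else np.nan

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        ss_w = _ss_within(d2, perm, a)
        f_perm = (ss_total - ss_w) / df_factor / (ss_w / df_resid) if ss_w > 0 else np.inf
        if f_perm >= pseudo_f:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermanovaResult(
        df_factor=df_factor,
        df_residual=df_resid,
        pseudo_F=float(pseudo_f),
        R2=float(r2),
        p_value=float(p),
        permutations=permutations,
        seed=seed,
    )
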