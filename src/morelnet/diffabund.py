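"""Two-group per-genus differential abundance, Metastats-style.

For each genus, counts are converted to within-sample proportions, a
Welch t-statistic compares the two groups, and its p-value comes from
permuting sample labels (B permutations, seeded, with the +1
correction). Genera whose pooled count across all samples is below a
sparsity threshold are instead tested with a two-sided Fisher exact test
on the pooled 2x2 table (genus reads vs all-other reads per group),
because a permutation t on near-empty proportions is uninformative.
q-values are Benjamini-Hochberg adjusted across all genera in the
comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .network import bh_adjust

__all__ = ["metastats_test"]


def _welch_t(mean1, var1, n1, mean2, var2, n2):
    """Vectorized Welch t; 0 where both variances and the mean gap vanish."""
    se2 = var1 / n1 + var2 / n2
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(se2 == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return t


def metastats_test(table: pd.DataFrame, group_labels, permutations: int = 1000,
                   sparse_threshold: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Differential abundance of every genus between two groups.

    *group_labels* maps sample id -> group (mapping/Series) or is a
    sequence aligned with the table's columns; exactly two groups, each
    with >= 2 samples. ``sparse_threshold`` defaults to the number of
    samples (a genus averaging under one read per sample routes to the
    exact test).

    Returns one row per genus: group means/variances of proportions,
    ``t_statistic``, permutation (or exact) ``p``, BH ``q``,
    ``test_used`` in {permutation-t, fisher-exact}, ``n_permutations``,
    and a ``constant`` flag for all-zero genera (p = 1).
    """
    samples = list(table.columns)
    if isinstance(group_labels, (dict, pd.Series)):
        labels = [group_labels[s] for s in samples]
    else:
        labels = list(group_labels)
        if len(labels) != len(samples):
            raise ValueError("group_labels length does not match samples")
    groups = sorted(set(labels), key=str)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    idx1 = np.array([l == g1 for l in labels])
    idx2 = ~idx1
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    if sparse_threshold is None:
        sparse_threshold = len(samples)

    counts = table.to_numpy(dtype=float)
    col_sums = counts.sum(axis=0)
    if np.any(col_sums == 0):
        bad = [samples[i] for i in np.flatnonzero(col_sums == 0)]
        raise ValueError(f"all-zero samples: {bad}")
    props = counts / col_sums

    x1, x2 = props[:, idx1], props[:, idx2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    var1 = x1.var(axis=1, ddof=1)
    var2 = x2.var(axis=1, ddof=1)
    t_obs = _welch_t(mean1, var1, n1, mean2, var2, n2)

    pooled = counts.sum(axis=1)
    constant = pooled == 0
    sparse = (pooled < sparse_threshold) & ~constant
    dense = ~sparse & ~constant

    p = np.ones(len(table))
    # permutation null for the dense genera, vectorized over permutations
    if dense.any():
        rng = np.random.default_rng(seed)
        pd_dense = props[dense]
        obs = np.abs(t_obs[dense])
        exceed = np.zeros(dense.sum(), dtype=np.int64)
        n = len(samples)
        for _ in range(permutations):
            perm = rng.permutation(n)
            m1 = perm[:n1]
            m2 = perm[n1:]
            y1, y2 = pd_dense[:, m1], pd_dense[:, m2]
            t_perm = _welch_t(
                y1.mean(axis=1), y1.var(axis=1, ddof=1), n1,
                y2.mean(axis=1), y2.var(axis=1, ddof=1), n2,
            )
            exceed += np.abs(t_perm) >= obs - 1e-12
        p[dense] = (exceed + 1.0) / (permutations + 1.0)
    # exact test on pooled counts for sparse genera
    tot1 = counts[:, idx1].sum()
    tot2 = counts[:, idx2].sum()
    for i in np.flatnonzero(sparse):
        a = counts[i, idx1].sum()
        b = counts[i, idx2].sum()
        tab = np.array([[a, tot1 - a], [b, tot2 - b]])
        p[i] = stats.fisher_exact(tab.round().astype(np.int64), alternative="two-sided")[1]

    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            f"mean_{g1}": mean1, f"mean_{g2}": mean2,
            f"var_{g1}": var1, f"var_{g2}": var2,
            "t_statistic": np.where(constant, 0.0, t_obs),
            "p": p, "q": q,
            "test_used": np.where(sparse, "fisher-exact", "permutation-t"),
            "n_permutations": np.where(dense, permutations, 0),
            "constant": constant,
        },
        index=table.index,
    )
    return out.sort_values(["q", "p"], kind="mergesort")
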