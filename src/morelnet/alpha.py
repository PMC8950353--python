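"""Within-sample richness and diversity estimators.

Richness extrapolators (Chao1, ACE) work from the rare-taxon frequency
counts F_k = number of taxa observed exactly k times; Shannon and Simpson
weight evenness. Simpson is reported in its Gini-Simpson "diversity"
form 1 - sum(p_i^2), so larger means more diverse; note that the raw
dominance D = sum(p_i^2) is also commonly called "Simpson's index".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "chao1",
    "ace",
    "shannon",
    "simpson",
    "rarefaction_curve",
    "alpha_table",
    "compare_alpha",
    "AlphaComparison",
]

log = logging.getLogger(__name__)


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    c = c.astype(np.int64)
    if c.sum() == 0:
        raise ValueError("counts are all zero")
    return c[c > 0]


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1)).

    Defined even when there are no doubletons (F2 = 0); with no
    singletons it reduces to the observed richness.
    """
    c = _as_counts(counts)
    s_obs = len(c)
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Taxa with at most ``rare_cutoff`` individuals are the "rare" pool
    used to estimate sample coverage C_ACE = 1 - F1/N_rare; the squared
    coefficient of variation of the rare counts inflates the estimate,
    floored at zero:

        ACE = S_abund + S_rare/C_ACE + F1/C_ACE * gamma^2

    When every rare taxon is a singleton C_ACE is 0 and the estimator is
    undefined; the function then falls back to :func:`chao1` with a
    logged warning.
    """
    c = _as_counts(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int(np.sum(c > rare_cutoff))
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    if f1 == n_rare:
        log.warning("ACE undefined (all rare taxa are singletons); falling back to Chao1")
        return chao1(counts)
    c_ace = 1.0 - f1 / n_rare
    fk = np.bincount(rare, minlength=rare_cutoff + 1)
    ssum = sum(k * (k - 1) * fk[k] for k in range(1, rare_cutoff + 1))
    gamma2 = max(s_rare / c_ace * ssum / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def shannon(counts, log_base: float = math.e) -> float:
    """Shannon diversity -sum(p_i * log(p_i)) over positive proportions."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(-np.sum(p * np.log(p)) / np.log(log_base))


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2)."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(1.0 - np.sum(p * p))


def rarefaction_curve(counts, depths, mode: str = "analytic", seed: int | None = None,
                      n_resamples: int = 100):
    """Expected richness at subsampled read depths.

    Analytic mode uses the hypergeometric expectation
    ``E[S(d)] = sum_i (1 - C(N - N_i, d) / C(N, d))``; Monte-Carlo mode
    subsamples reads without replacement ``n_resamples`` times with a
    seeded generator. Returns a list of (depth, expected richness).
    """
    c = _as_counts(counts)
    n = int(c.sum())
    out = []
    depths = [int(d) for d in np.atleast_1d(depths)]
    for d in depths:
        if d > n:
            raise ValueError(f"depth {d} exceeds total count {n}")
    if mode == "analytic":
        for d in depths:
            # log C(N-Ni, d) - log C(N, d), with C(N-Ni, d) = 0 when d > N-Ni
            with np.errstate(all="ignore"):
                log_num = gammaln(n - c + 1) - gammaln(d + 1) - gammaln(n - c - d + 1)
                log_den = gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1)
            p_absent = np.where(d > n - c, 0.0, np.exp(log_num - log_den))
            out.append((d, float(np.sum(1.0 - p_absent))))
    elif mode == "monte-carlo":
        rng = np.random.default_rng(seed)
        reads = np.repeat(np.arange(len(c)), c)
        for d in depths:
            richness = [
                len(np.unique(rng.choice(reads, size=d, replace=False)))
                for _ in range(n_resamples)
            ]
            out.append((d, float(np.mean(richness))))
    else:
        raise ValueError(f"unknown rarefaction mode: {mode!r}")
    return out


def alpha_table(table: pd.DataFrame, log_base: float = math.e) -> pd.DataFrame:
    """Per-sample alpha-diversity summary of a count table.

    Columns: observed richness S_obs, chao1, ace, shannon, simpson.
    """
    rows = {}
    for s in table.columns:
        c = table[s].to_numpy()
        rows[s] = {
            "S_obs": int(np.sum(c > 0)),
            "chao1": chao1(c),
            "ace": ace(c),
            "shannon": shannon(c, log_base=log_base),
            "simpson": simpson(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class AlphaComparison:
    """One-way ANOVA across groups plus Tukey HSD letters."""

    f_statistic: float
    df_factor: int
    df_residual: int
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    letters: dict = field(default_factory=dict)  # group -> compact letter string


def _compact_letters(groups: list[str], means: dict, nonsig: set) -> dict:
    """Greedy compact-letter display.

    Groups sharing a letter are not significantly different. Groups are
    visited in descending-mean order; each is appended to every existing
    letter class it is compatible with, or opens a new class.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    classes: list[list[str]] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(frozenset((g, h)) in nonsig for h in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    letters = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        letter = chr(ord("a") + i)
        for g in cls:
            letters[g] += letter
    return letters


def compare_alpha(values_by_group: dict, alpha: float = 0.05) -> AlphaComparison:
    """Compare an alpha-diversity index across groups.

    One-way ANOVA (df = k-1, N-k) followed by Tukey HSD pairwise
    comparisons; the compact letter display marks groups that share a
    letter as not significantly different at *alpha*.

    Each group needs at least two values.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    n_total = sum(len(a) for a in arrays)
    k = len(groups)
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical values everywhere: no variance to partition
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        f_stat, p_val = float(f_stat), float(p_val)

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey.columns = ["group1", "group2", "meandiff", "p_adj", "reject"]

    nonsig = {frozenset((g, g)) for g in groups}
    for _, row in tukey.iterrows():
        if not bool(row["reject"]):
            nonsig.add(frozenset((str(row["group1"]), str(row["group2"]))))
    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    letters = _compact_letters(groups, means, nonsig)
    return AlphaComparison(
        f_statistic=f_stat,
        df_factor=k - 1,
        df_residual=n_total - k,
        p_value=p_val,
        tukey=tukey,
        letters=letters,
    )
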