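"""Count-table transforms that precede every downstream analysis.

The processing order mirrors the standard amplicon workflow: drop rare
taxa (grand-total relative abundance below a fraction of all reads),
collapse OTU rows to genus via the taxonomy map, convert to relative
abundance by total-sum scaling (TSS), and select the most abundant genera
within a sample group for network construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import genus_from_lineage

__all__ = ["aggregate_to_genus", "filter_rare", "tss_normalize", "top_n_taxa"]

log = logging.getLogger(__name__)


def aggregate_to_genus(table: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum count rows by genus.

    Every taxon id in *table* must appear in *taxonomy*; rows whose
    lineage has an empty ``g__`` rank are pooled under
    ``unclassified_<family>``. The grand total is conserved exactly.
    """
    missing = [t for t in table.index if t not in taxonomy.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy map: {missing}")
    genera = [genus_from_lineage(taxonomy[t]) for t in table.index]
    out = table.groupby(pd.Index(genera, name="TaxonID"), sort=True).sum()
    return out


def filter_rare(table: pd.DataFrame, fraction: float = 1e-5) -> pd.DataFrame:
    """Drop taxa whose grand-total count is below ``fraction`` of all reads.

    The comparison is strictly less-than: a taxon with exactly
    ``fraction * grand_total`` reads is kept. Dropped taxon ids are
    recorded in ``result.attrs["dropped_taxa"]`` and logged.

    Raises
    ------
    ValueError
        If ``fraction`` is outside (0, 1) or every taxon would be dropped.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    totals = table.sum(axis=1)
    grand = totals.sum()
    keep = totals >= fraction * grand
    dropped = list(table.index[~keep])
    if not keep.any():
        raise ValueError("rare-taxon filter would drop every taxon")
    out = table.loc[keep].copy()
    out.attrs["dropped_taxa"] = dropped
    if dropped:
        log.info("filter_rare dropped %d taxa: %s", len(dropped), dropped)
    return out


def tss_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: divide each cell by its sample's column total.

    Raises
    ------
    ValueError
        Naming any all-zero sample.
    """
    sums = table.sum(axis=0)
    zero = list(table.columns[sums == 0])
    if zero:
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")
    return table.astype(float).div(sums.astype(float), axis=1)


def top_n_taxa(abund: pd.DataFrame, n: int = 50, samples=None) -> list[str]:
    """Genera with the top-*n* mean relative abundance over *samples*.

    Ranking uses the unweighted mean relative abundance across the scoped
    samples; exact ties are broken lexicographically (smaller name first).
    Returns ``min(n, n_genera)`` names, in rank order.
    """
    if samples is None:
        samples = list(abund.columns)
    samples = list(samples)
    if not samples:
        raise ValueError("top_n_taxa: empty sample scope")
    missing = [s for s in samples if s not in abund.columns]
    if missing:
        raise KeyError(f"samples not in table: {missing}")
    means = abund[samples].mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], str(g)))
    return order[: min(n, len(order))]
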