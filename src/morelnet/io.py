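"""Reading and writing of on-disk artifacts.

All tables are plain UTF-8 TSV. The count-table dialect is
``#TaxonID<TAB>S1<TAB>S2...`` with taxa as rows and samples as columns
(the amplicon convention); taxonomy is ``TaxonID<TAB>lineage`` with
semicolon-delimited ranks and ``g__`` genus prefixes; metadata is one row
per sample. Networks are exported as edge-list TSV or GraphML so they can
be opened in standard graph viewers.
"""

from __future__ import annotations

import numbers
from collections import Counter
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "genus_from_lineage",
    "read_metadata",
    "write_metadata",
    "write_network",
    "read_network",
]

#: rank prefixes in a standard 7-rank lineage
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

METADATA_COLUMNS = ["site", "plot", "replicate", "group_I", "yield_class", "analysis_group"]


def _check_unique(ids, what: str) -> None:
    dups = sorted(k for k, v in Counter(ids).items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} ids: {dups}")


def read_count_table(path) -> pd.DataFrame:
    """Read a taxon-by-sample integer count table.

    Returns a DataFrame with taxon ids as the index and sample ids as
    columns, dtype int64. Row and column order are preserved from disk.

    Raises
    ------
    ValueError
        On duplicate taxon/sample ids (listing them) or on negative or
        non-integer cells (naming the offending row and column).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    _check_unique(samples, "sample")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.columns = samples
    df.index = df.index.astype(str)
    df.index.name = "TaxonID"
    _check_unique(list(df.index), "taxon")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (row, raw) in enumerate(df[col].items()):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric count at taxon {row!r}, sample {col!r}: {raw!r}")
            if val < 0:
                raise ValueError(f"negative count at taxon {row!r}, sample {col!r}: {raw}")
            if val != int(val):
                raise ValueError(f"non-integer count at taxon {row!r}, sample {col!r}: {raw}")
            values[i, j] = int(val)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_count_table(table: pd.DataFrame, path) -> None:
    """Write a count (or abundance) table as ``#TaxonID``-headed TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#TaxonID\t" + "\t".join(str(s) for s in table.columns) + "\n")
        for taxon, row in table.iterrows():
            fh.write(str(taxon) + "\t" + "\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def genus_from_lineage(lineage: str) -> str:
    """Extract the genus key from a semicolon-delimited ranked lineage.

    The genus is the string after ``g__`` at rank 6. Hyphenated
    multi-genus labels (e.g. Burkholderia-Caballeronia-Paraburkholderia)
    are kept verbatim as single keys. An empty genus falls back to
    ``unclassified_<family>`` (or ``unclassified`` when the family is
    empty too).
    """
    ranks = [r.strip() for r in lineage.split(";")]
    genus = ""
    family = ""
    for r in ranks:
        if r.startswith("g__"):
            genus = r[3:]
        elif r.startswith("f__"):
            family = r[3:]
    if genus:
        return genus
    if family:
        return f"unclassified_{family}"
    return "unclassified"


def read_taxonomy(path) -> pd.Series:
    """Read ``TaxonID<TAB>lineage`` into a Series mapping id -> lineage."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs columns: TaxonID, lineage")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values, name="lineage")
    _check_unique(list(ser.index), "taxon")
    if ser.isna().any():
        missing = list(ser.index[ser.isna()])
        raise ValueError(f"null lineage for taxa: {missing}")
    return ser


def write_taxonomy(tax: pd.Series, path) -> None:
    pd.DataFrame({"TaxonID": tax.index, "lineage": tax.values}).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata.

    Expected columns: SampleID, site, plot, replicate, group_I,
    yield_class, analysis_group. ``analysis_group`` may hold zero or more
    of {II, III}, semicolon-separated.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    if "SampleID" not in df.columns:
        raise ValueError("metadata missing required column: SampleID")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata missing required column: {col}")
    _check_unique(list(df["SampleID"]), "sample")
    df = df.set_index("SampleID")
    df["replicate"] = df["replicate"].astype(int)
    return df[METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index()
    out = out.rename(columns={out.columns[0]: "SampleID"})
    out.to_csv(path, sep="\t", index=False)


def samples_in_analysis_group(meta: pd.DataFrame, group: str) -> list[str]:
    """Sample ids whose ``analysis_group`` field contains *group* (II or III)."""
    mask = meta["analysis_group"].astype(str).apply(
        lambda s: group in [g for g in s.split(";") if g]
    )
    return list(meta.index[mask])


def _edge_sign(rho: float) -> str:
    return "positive" if rho >= 0 else "negative"


def write_network(net: nx.Graph, path, format: str = "edge-list") -> None:
    """Export a correlation network.

    ``edge-list`` writes a TSV with columns source, target, rho, p, q,
    sign; ``graphml`` additionally carries per-node degree and module id
    as attributes. An empty network yields a valid file with zero edges.
    """
    path = Path(path)
    if format == "edge-list":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\trho\tp\tq\tsign\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{d['rho']!r}\t{d['p']!r}\t{d['q']!r}\t{_edge_sign(d['rho'])}\n"
                )
    elif format == "graphml":
        g = net.copy()
        for u, v, d in g.edges(data=True):
            d["sign"] = _edge_sign(d["rho"])
        for n in g.nodes:
            g.nodes[n]["degree"] = int(g.degree(n))
            g.nodes[n].setdefault("module_id", -1)
        # GraphML attribute values must be scalars
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if isinstance(v, numbers.Integral):
                    d[k] = int(v)
                elif isinstance(v, numbers.Real):
                    d[k] = float(v)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Read back a network written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    if format == "edge-list":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(
                str(row["source"]), str(row["target"]),
                rho=float(row["rho"]), p=float(row["p"]), q=float(row["q"]),
            )
        return g
    raise ValueError(f"unknown network format: {format!r}")
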