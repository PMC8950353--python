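"""Synthetic genus-level count tables with planted structure.

The generative model is logistic-normal-multinomial: each sample draws a
latent log-abundance vector from a multivariate normal whose correlation
matrix carries the planted blocks and hub, the latent means carry group
effects and per-plot random effects, a softmax maps the latent vector to
proportions, and a multinomial draw of the library size produces integer
counts. This admits an explicit planted correlation/edge/hub/differential
truth against which recovery can be scored, which a Dirichlet-multinomial
would not.

Group effects act on the latent (log) scale, so a planted log2 fold
change is exact in latent space but only approximate in the observed
relative abundances (the softmax renormalizes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "build_latent_correlation",
    "simulate_counts",
    "emulate_study_design",
    "STUDY_DESIGN",
]

#: The 23-plot morel-farm design: plot code, site, morel-production detail,
#: cultivation class (group I), yield class (H >= 1500 kg/ha; L/N < 450
#: kg/ha; control = no cultivation), and high-yield (II) / low-or-no-yield
#: (III) analysis-group membership. 23 plots x 4 replicates = 92 samples.
STUDY_DESIGN = [
    # (plot, site, group_I, yield_class, analysis_groups)
    ("NC", 1, "MUCS", "control", ""),
    ("NF", 1, "MCS", "H", "II"),
    ("NN", 1, "MCS", "L", "III"),
    ("NSN", 1, "MCS", "N", "III"),
    ("OC", 2, "MUCS", "control", ""),
    ("OO", 2, "MUCS", "control", ""),
    ("OCP", 2, "MCS", "H", "II"),
    ("OCF", 2, "MCS", "H", "II"),
    ("ORF", 2, "MCS", "H", "II"),
    ("GHC", 3, "MUCS", "control", ""),
    ("GH1", 3, "MCS", "N", "III"),
    ("GH2", 3, "MCS", "L", "III"),
    ("GH3", 3, "MCS", "N", "III"),
    ("GH4", 3, "MCS", "H", "II"),
    ("GH5", 3, "MCS", "H", "II"),
    ("SM0", 4, "", "N", "III"),
    ("SM1", 4, "", "H", "II"),
    ("SM2", 4, "", "H", "II"),
    ("SM3", 4, "", "H", "II"),
    ("WD1", 5, "", "H", "II"),
    ("WD2", 5, "", "H", "II"),
    ("WD3", 5, "", "H", "II"),
    ("DY1", 6, "", "N", "III"),
]


@dataclass
class SimulationConfig:
    """Parameters of the logistic-normal-multinomial generator.

    ``n_samples_per_group`` maps group label -> sample count.
    ``correlation_blocks`` is a list of (taxon-index set, latent pairwise
    correlation in (-1, 1)); ``hub_spec`` an optional (hub index, spoke
    index set, correlation) one-factor block; ``differential_taxa`` a
    list of (taxon index, group_a, group_b, log2 fold change) with the
    shift applied to group_b. ``library_sd`` > 0 makes library sizes
    log-normal around ``library_size``; 0 keeps them fixed.
    """

    n_taxa: int = 50
    n_samples_per_group: dict = field(default_factory=lambda: {"A": 20})
    library_size: int = 10_000
    library_sd: float = 0.0
    correlation_blocks: list = field(default_factory=list)
    hub_spec: tuple | None = None
    differential_taxa: list = field(default_factory=list)
    base_log_abundance: np.ndarray | None = None
    base_log_range: tuple = (0.0, 4.0)
    latent_sd: float = 1.0
    repair_tolerance: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        for grp, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {grp!r} needs at least one sample")
        for members, r in self.correlation_blocks:
            if not all(0 <= i < self.n_taxa for i in members):
                raise ValueError(f"block indices out of range: {sorted(members)}")
            if not -1 < r < 1:
                raise ValueError(f"block correlation must be in (-1, 1), got {r}")
        if self.hub_spec is not None:
            hub, spokes, r = self.hub_spec
            idx = [hub, *spokes]
            if not all(0 <= i < self.n_taxa for i in idx):
                raise ValueError(f"hub indices out of range: {idx}")
            if not -1 < r < 1:
                raise ValueError(f"hub correlation must be in (-1, 1), got {r}")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground truth the simulator plants, for recovery scoring.

    ``true_edges`` maps frozenset{i, j} -> sign (+1/-1); ``true_hubs`` is
    the hub taxon index set; ``true_differential`` maps taxon index ->
    (group_a, group_b, log2fc); ``latent_correlation`` is the full
    (repaired) latent matrix; ``repair_perturbation`` the max absolute
    entry change the positive-definiteness repair introduced.
    """

    true_edges: dict
    true_hubs: set
    true_differential: dict
    latent_correlation: np.ndarray
    repair_perturbation: float = 0.0

    def edge_set(self) -> set:
        return set(self.true_edges)


def build_latent_correlation(config: SimulationConfig):
    """Assemble and PSD-repair the latent correlation matrix.

    Within-block entries get the block's r; the hub block is one-factor
    (hub-spoke r, spoke-spoke r^2, PSD by construction). Eigenvalues
    below 1e-8 are clipped and the diagonal renormalized to 1; the max
    absolute perturbation is returned and must not exceed
    ``config.repair_tolerance``.
    """
    k = config.n_taxa
    corr = np.eye(k)
    for members, r in config.correlation_blocks:
        members = sorted(members)
        for i, j in itertools.combinations(members, 2):
            corr[i, j] = corr[j, i] = r
    if config.hub_spec is not None:
        hub, spokes, r = config.hub_spec
        spokes = sorted(spokes)
        for s in spokes:
            corr[hub, s] = corr[s, hub] = r
        for i, j in itertools.combinations(spokes, 2):
            corr[i, j] = corr[j, i] = r * r
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < 1e-8:
        clipped = np.clip(vals, 1e-8, None)
        repaired = (vecs * clipped) @ vecs.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        perturb = float(np.max(np.abs(repaired - corr)))
        if perturb > config.repair_tolerance:
            blocks = [sorted(m) for m, _ in config.correlation_blocks]
            raise ValueError(
                "latent correlation not positive definite within repair "
                f"tolerance (max perturbation {perturb:.3f} > "
                f"{config.repair_tolerance}); check blocks {blocks} and hub "
                f"{config.hub_spec}"
            )
        corr = repaired
    else:
        perturb = 0.0
    return corr, perturb


def _planted_truth(config: SimulationConfig, corr: np.ndarray, perturb: float) -> PlantedTruth:
    edges = {}
    for members, r in config.correlation_blocks:
        for i, j in itertools.combinations(sorted(members), 2):
            edges[frozenset((i, j))] = 1 if r >= 0 else -1
    hubs = set()
    if config.hub_spec is not None:
        hub, spokes, r = config.hub_spec
        hubs.add(hub)
        for s in spokes:
            edges[frozenset((hub, s))] = 1 if r >= 0 else -1
    diff = {t: (ga, gb, fc) for t, ga, gb, fc in config.differential_taxa}
    return PlantedTruth(
        true_edges=edges,
        true_hubs=hubs,
        true_differential=diff,
        latent_correlation=corr,
        repair_perturbation=perturb,
    )


def _taxon_ids(k: int) -> list:
    return [f"Genus_{i:03d}" for i in range(k)]


def _draw_counts(rng, config, corr, means_by_sample, sample_ids):
    """Latent MVN -> softmax -> multinomial, one column per sample."""
    k = config.n_taxa
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    n = len(sample_ids)
    z = rng.standard_normal((n, k)) @ chol.T * config.latent_sd
    latent = z + means_by_sample
    latent -= latent.max(axis=1, keepdims=True)  # softmax stability
    props = np.exp(latent)
    props /= props.sum(axis=1, keepdims=True)
    if config.library_sd > 0:
        mu = np.log(config.library_size) - 0.5 * config.library_sd**2
        libs = np.maximum(
            1, np.round(rng.lognormal(mu, config.library_sd, size=n)).astype(int)
        )
    else:
        libs = np.full(n, config.library_size, dtype=int)
    counts = np.vstack([rng.multinomial(libs[i], props[i]) for i in range(n)]).T
    return pd.DataFrame(counts, index=_taxon_ids(k), columns=sample_ids, dtype=np.int64)


def _base_means(rng, config) -> np.ndarray:
    if config.base_log_abundance is not None:
        base = np.asarray(config.base_log_abundance, dtype=float)
        if base.shape != (config.n_taxa,):
            raise ValueError("base_log_abundance length must equal n_taxa")
        return base
    lo, hi = config.base_log_range
    return rng.uniform(lo, hi, size=config.n_taxa)


def _group_shift(config, base: np.ndarray, group: str) -> np.ndarray:
    mean = base.copy()
    for taxon, ga, gb, log2fc in config.differential_taxa:
        if group == gb:
            mean[taxon] += log2fc * np.log(2.0)
    return mean


def simulate_counts(config: SimulationConfig):
    """Draw a count table and its planted truth.

    Sample ids are ``<group>_s<k>``; columns are grouped in the order of
    ``n_samples_per_group``. The same config and seed give a
    bit-identical table and truth.
    """
    rng = np.random.default_rng(config.seed)
    corr, perturb = build_latent_correlation(config)
    base = _base_means(rng, config)
    sample_ids = []
    means = []
    for grp, n in config.n_samples_per_group.items():
        shift = _group_shift(config, base, grp)
        for i in range(n):
            sample_ids.append(f"{grp}_s{i+1:02d}")
            means.append(shift)
    table = _draw_counts(rng, config, corr, np.vstack(means), sample_ids)
    truth = _planted_truth(config, corr, perturb)
    return table, truth


def emulate_study_design(config: SimulationConfig | None = None, n_plots: int = 23,
                         n_replicates: int = 4, plot_sd: float = 0.5,
                         seed: int | None = None):
    """Simulate the 23-plot x 4-replicate morel-farm sampling design.

    Each plot contributes a shared per-taxon latent mean shift (sd
    ``plot_sd``) so replicates of a plot resemble each other; sample
    metadata records plot, replicate, site, cultivation class, yield
    class (H = high yield >= 1500 kg/ha; L/N = low/no yield < 450 kg/ha)
    and analysis-group (II/III) membership. With the default 23 plots the
    codes, sites and classes follow the study layout; other plot counts
    get generic codes cycling over sites and yield classes.

    ``config.differential_taxa`` group names refer to yield classes
    (H/L/N/control). Returns ``(counts, metadata, truth)``.
    """
    if config is None:
        config = SimulationConfig()
    if n_replicates < 1:
        raise ValueError("need at least one replicate per plot")
    if n_plots < 1:
        raise ValueError("need at least one plot")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    if n_plots == len(STUDY_DESIGN):
        design = STUDY_DESIGN
    else:
        classes = ["H", "L", "N", "control"]
        design = [
            (f"P{i+1:02d}", i % 6 + 1, "", classes[i % 4],
             {"H": "II", "L": "III", "N": "III", "control": ""}[classes[i % 4]])
            for i in range(n_plots)
        ]

    corr, perturb = build_latent_correlation(config)
    base = _base_means(rng, config)
    sample_ids, means, meta_rows = [], [], []
    for plot, site, group_i, yclass, agroups in design:
        plot_effect = rng.normal(0.0, plot_sd, size=config.n_taxa)
        shift = _group_shift(config, base, yclass) + plot_effect
        for rep in range(1, n_replicates + 1):
            sid = f"{plot}_r{rep}"
            sample_ids.append(sid)
            means.append(shift)
            meta_rows.append(
                {"SampleID": sid, "site": str(site), "plot": plot,
                 "replicate": rep, "group_I": group_i, "yield_class": yclass,
                 "analysis_group": agroups}
            )
    table = _draw_counts(rng, config, corr, np.vstack(means), sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("SampleID")
    truth = _planted_truth(config, corr, perturb)
    return table, meta, truth
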