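"""Bayesian microbial source tracking between FL and PA communities.

Each particle-associated (sink) community is modelled as a mixture of
free-living (source) communities plus one Unknown source.  Every read of
the sink carries a latent source assignment z_i, resampled by collapsed
Gibbs with conditional

    P(z_i = v)  ∝  (m_tv + n_tv^-i + alpha) / (m_.v + n_.v^-i + T*alpha)
                   * (n_v^-i + beta)

where m are the training counts of taxon t in source v (zero for the
Unknown source, whose taxon distribution is learned from the current
assignments), n^-i the current sink assignments excluding read i, and T
the number of taxa.  After the burn-in one draw is recorded per restart
and the reported mixing proportions are the mean over restarts.  The
default configuration is burn-in 100, 10 restarts, alpha = beta = 0.001,
with samples rarefied to 5000 reads beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .asv import AsvTable

UNKNOWN = "Unknown"


@dataclass
class MstConfig:
    alpha: float = 0.001
    beta: float = 0.001
    burn_in: int = 100
    restarts: int = 10
    rarefaction_depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Dirichlet hyperparameters must be positive")
        if self.burn_in < 1 or self.restarts < 1:
            raise ValueError("burn_in and restarts must be >= 1")


@dataclass
class MixingProportions:
    """Posterior source fractions per sink (rows sum to 1) and their
    standard deviation over restarts."""

    proportions: pd.DataFrame
    sd: pd.DataFrame


def rarefy(table: AsvTable, depth: int = 5000,
           seed: int | None = 0) -> AsvTable:
    """Sub-sample every sample to exactly ``depth`` reads without
    replacement (multivariate hypergeometric); samples with fewer reads
    are dropped with a warning."""
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.totals()
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} sample(s) below "
                      f"{depth} reads: {list(dropped)}")
    if len(keep) == 0:
        raise ValueError("all samples fall below the rarefaction depth")
    rng = np.random.default_rng(seed)
    rows = [rng.multivariate_hypergeometric(
        table.counts.loc[s].to_numpy().astype(np.int64), depth)
        for s in keep]
    counts = pd.DataFrame(np.asarray(rows, dtype=int), index=keep,
                          columns=table.counts.columns)
    counts.index.name = table.counts.index.name
    return AsvTable(counts, table.sample_metadata.loc[keep], table.taxonomy)


def pool_sources(table: AsvTable,
                 by: tuple[str, ...] = ("layer", "region")) -> pd.DataFrame:
    """Sum counts of source samples into one row per metadata group;
    rows are named by joining the group values with '/'."""
    meta = table.sample_metadata
    groups = meta.groupby(list(by), sort=True).groups
    rows, names = [], []
    for key, samples in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        names.append("/".join(str(k) for k in key))
        rows.append(table.counts.loc[samples].sum(axis=0))
    return pd.DataFrame(rows, index=names)


@njit(cache=True)
def _gibbs_kernel(read_taxa, m, m_col, alpha, beta, n_taxa,
                  burn_in, n_restarts, seed):  # pragma: no cover - numba
    n_known = m.shape[1]
    n_src = n_known + 1                      # + Unknown
    n_reads = read_taxa.size
    props = np.zeros((n_restarts, n_src))
    probs = np.empty(n_src)
    for r in range(n_restarts):
        np.random.seed(seed + r)
        z = np.empty(n_reads, np.int64)
        n_tv = np.zeros((n_taxa, n_src), np.int64)
        n_v = np.zeros(n_src, np.int64)
        for i in range(n_reads):
            v0 = np.random.randint(0, n_src)
            z[i] = v0
            n_tv[read_taxa[i], v0] += 1
            n_v[v0] += 1
        for sweep in range(burn_in + 1):
            for i in range(n_reads):
                t = read_taxa[i]
                vold = z[i]
                n_tv[t, vold] -= 1
                n_v[vold] -= 1
                total = 0.0
                for v in range(n_src):
                    if v < n_known:
                        num = m[t, v] + n_tv[t, v] + alpha
                        den = m_col[v] + n_v[v] + n_taxa * alpha
                    else:
                        num = n_tv[t, v] + alpha
                        den = n_v[v] + n_taxa * alpha
                    p = num / den * (n_v[v] + beta)
                    probs[v] = p
                    total += p
                u = np.random.random() * total
                acc = 0.0
                vnew = n_src - 1
                for v in range(n_src):
                    acc += probs[v]
                    if u <= acc:
                        vnew = v
                        break
                z[i] = vnew
                n_tv[t, vnew] += 1
                n_v[vnew] += 1
        for v in range(n_src):
            props[r, v] = n_v[v] / n_reads
    return props


def fit_sources(sinks: AsvTable | pd.DataFrame, sources: pd.DataFrame,
                cfg: MstConfig | None = None) -> MixingProportions:
    """Mixing proportions of the named sources (+ Unknown) in each sink.

    ``sources`` is a sources x ASVs count matrix (see
    :func:`pool_sources`); ``sinks`` an :class:`AsvTable` or a sinks x
    ASVs count frame sharing the same ASV universe.  Tables are expected
    to be rarefied already.
    """
    if cfg is None:
        cfg = MstConfig()
    sink_counts = sinks.counts if isinstance(sinks, AsvTable) else sinks
    if sources.shape[0] == 0:
        raise ValueError("empty source set")
    if not sink_counts.columns.equals(sources.columns):
        sources = sources.reindex(columns=sink_counts.columns, fill_value=0)
    m = sources.to_numpy().astype(np.float64).T          # taxa x sources
    m_col = m.sum(axis=0)
    n_taxa = m.shape[0]
    source_names = list(sources.index) + [UNKNOWN]

    means, sds = [], []
    ss = np.random.SeedSequence([cfg.seed, 0x51])
    for k, (_, row) in enumerate(sink_counts.iterrows()):
        counts = row.to_numpy().astype(np.int64)
        read_taxa = np.repeat(np.arange(n_taxa), counts)
        kernel_seed = int(ss.spawn(k + 1)[0].generate_state(1)[0] % 2**31)
        draws = _gibbs_kernel(read_taxa, m, m_col, cfg.alpha, cfg.beta,
                              n_taxa, cfg.burn_in, cfg.restarts,
                              kernel_seed)
        means.append(draws.mean(axis=0))
        sds.append(draws.std(axis=0))
    proportions = pd.DataFrame(means, index=sink_counts.index,
                               columns=source_names)
    sd = pd.DataFrame(sds, index=sink_counts.index, columns=source_names)
    return MixingProportions(proportions=proportions, sd=sd)


def leave_one_out(sources_table: AsvTable, cfg: MstConfig | None = None,
                  by: tuple[str, ...] = ("layer", "region")) -> pd.DataFrame:
    """Validate the tracker by hiding each source sample in turn.

    Every source sample is treated as a sink and fitted against the
    remaining samples pooled by ``by``; returns the full proportion
    table (rows sum to 1)."""
    if sources_table.n_samples < 2:
        raise ValueError("need at least 2 source samples")
    rows = []
    for sample in sources_table.counts.index:
        rest = sources_table.subset_samples(
            sources_table.counts.index != sample)
        pooled = pool_sources(rest, by=by)
        sink = sources_table.counts.loc[[sample]]
        mp = fit_sources(sink, pooled, cfg)
        rows.append(mp.proportions.iloc[0])
    return pd.DataFrame(rows, index=sources_table.counts.index).fillna(0.0)


def summarize_by_layer(mixing: MixingProportions, metadata: pd.DataFrame,
                       pool_surface_epi: bool = False) -> pd.DataFrame:
    """Mean +/- sd of source fractions per (layer, region) sink group.

    With ``pool_surface_epi`` the surface and epipelagic source columns
    are summed before aggregation (the combined shallow-origin
    fraction)."""
    props = mixing.proportions.copy()
    if pool_surface_epi:
        shallow = [c for c in props.columns
                   if c.split("/")[0] in ("surface", "epi")]
        if shallow:
            props["surface+epi"] = props[shallow].sum(axis=1)
            props = props.drop(columns=shallow)
    meta = metadata.loc[props.index]
    grouped = props.groupby([meta["layer"], meta["region"]], sort=True)
    mean = grouped.mean()
    sd = grouped.std().fillna(0.0)
    mean.columns = pd.MultiIndex.from_product([["mean"], mean.columns])
    sd.columns = pd.MultiIndex.from_product([["sd"], sd.columns])
    return pd.concat([mean, sd], axis=1)
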