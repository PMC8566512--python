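"""Depth-enrichment of particle-associated ASVs and their footprint in
deep free-living and sediment communities.

ASVs are tested between consecutive water layers with a
negative-binomial model using median-of-ratios size factors, a
method-of-moments dispersion estimate and a Wald test on the log2 layer
coefficient, followed by Benjamini-Hochberg adjustment within each
contrast.  An ASV is called enriched when |log2 fold change| exceeds the
threshold (default 1) and the adjusted p-value falls below it (default
0.1).  This is a deliberately transparent simplification of
shrinkage-based differential-abundance machinery: calibration is
established by simulation rather than by numerical identity with any
external tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .asv import AsvTable

DEFAULT_CONTRASTS = (("surface", "epi"), ("epi", "meso"), ("meso", "bathy"))

_DISPERSION_FLOOR = 1e-8


@dataclass
class EnrichmentConfig:
    lfc_threshold: float = 1.0        # log2 units
    padj_threshold: float = 0.1
    prevalence_min: float = 0.04      # fraction of samples
    contrasts: tuple = DEFAULT_CONTRASTS
    min_asvs_per_family: int = 3      # strictly more than this reported

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.padj_threshold <= 0:
            raise ValueError("thresholds must be positive")


def prevalence_filter(table: AsvTable, min_frac: float = 0.04) -> AsvTable:
    """Keep ASVs present (count >= 1) in at least
    ``ceil(min_frac * n_samples)`` samples (inclusive boundary)."""
    presence = (table.counts > 0).sum(axis=0)
    cutoff = int(np.ceil(min_frac * table.n_samples))
    keep = presence.index[presence >= cutoff]
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every ASV")
    return table.subset_asvs(keep)


def size_factors(table: AsvTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    Each sample's factor is the median ratio of its counts to the
    per-ASV geometric mean across samples, over ASVs with no zero in any
    sample.  When no such reference ASV exists the factors fall back to
    relative library size (with a warning).
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=0)
    if all_positive.any():
        log_ref = np.log(arr[:, all_positive])
        geo = log_ref.mean(axis=0)
        factors = np.exp(np.median(log_ref - geo, axis=1))
    else:
        warnings.warn("no ASV positive in every sample; falling back to "
                      "library-size scaling")
        totals = arr.sum(axis=1)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.index, name="size_factor")


def vst(table: AsvTable | pd.DataFrame,
        factors: pd.Series | None = None) -> pd.DataFrame:
    """Shifted-log variance stabilisation: log2(count / factor + 1).

    Monotone in counts with zeros mapping to 0; used for ordination and
    distance computation, not for the enrichment test itself.
    """
    counts = table.counts if isinstance(table, AsvTable) else table
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=0)
    return np.log2(norm + 1.0)


def _nb_wald(counts_a: np.ndarray, counts_b: np.ndarray,
             s_a: np.ndarray, s_b: np.ndarray) -> tuple[float, float, float]:
    """NB Wald test for one ASV between two sample groups.

    Group means are normalized-total estimates with a half-read
    pseudocount; dispersion is pooled method-of-moments; the test
    statistic lfc/se is referred to a t distribution with n-2 degrees of
    freedom (the dispersion being estimated).  Returns (lfc, se, p).
    """
    n_a, n_b = counts_a.size, counts_b.size
    q_a = (counts_a.sum() + 0.5) / s_a.sum()
    q_b = (counts_b.sum() + 0.5) / s_b.sum()

    mu_a = s_a * q_a
    mu_b = s_b * q_b
    resid = np.concatenate([(counts_a - mu_a) ** 2 - mu_a,
                            (counts_b - mu_b) ** 2 - mu_b])
    mu_sq = np.concatenate([mu_a ** 2, mu_b ** 2])
    n = n_a + n_b
    disp = resid.sum() / mu_sq.sum() * n / max(n - 2, 1)
    disp = max(disp, _DISPERSION_FLOOR)

    var_ln_a = 1.0 / (q_a * s_a.sum()) + disp * (s_a ** 2).sum() / s_a.sum() ** 2
    var_ln_b = 1.0 / (q_b * s_b.sum()) + disp * (s_b ** 2).sum() / s_b.sum() ** 2
    lfc = np.log2(q_b / q_a)
    se = np.sqrt(var_ln_a + var_ln_b) / np.log(2.0)
    t = lfc / se
    p = 2.0 * sps.t.sf(abs(t), df=max(n - 2, 1))
    return float(lfc), float(se), float(p)


def nb_contrast(table: AsvTable, contrast: tuple[str, str],
                cfg: EnrichmentConfig | None = None,
                factors: pd.Series | None = None) -> pd.DataFrame:
    """Test every ASV between two water layers.

    ``contrast`` is (shallower, deeper); a positive log2 fold change
    means enrichment in the deeper layer.  Returns a DataFrame with
    columns asv, contrast, lfc, se, p, padj, direction, enriched.
    """
    if cfg is None:
        cfg = EnrichmentConfig()
    shallow, deep = contrast
    layers = table.sample_metadata["layer"]
    idx_a = layers.index[layers == shallow]
    idx_b = layers.index[layers == deep]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(f"need >=2 samples per layer in contrast "
                         f"{shallow}-{deep}")
    if factors is None:
        factors = size_factors(table.counts.loc[idx_a.union(idx_b)])
    s_a = factors.loc[idx_a].to_numpy()
    s_b = factors.loc[idx_b].to_numpy()
    arr_a = table.counts.loc[idx_a].to_numpy(dtype=float)
    arr_b = table.counts.loc[idx_b].to_numpy(dtype=float)

    rows = []
    for j, asv in enumerate(table.counts.columns):
        lfc, se, p = _nb_wald(arr_a[:, j], arr_b[:, j], s_a, s_b)
        rows.append((asv, f"{shallow}-{deep}", lfc, se, p))
    out = pd.DataFrame(rows, columns=["asv", "contrast", "lfc", "se", "p"])
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["lfc"] > 0, "deeper", "shallower")
    out["enriched"] = (out["lfc"].abs() > cfg.lfc_threshold) \
        & (out["padj"] < cfg.padj_threshold)
    return out


def run_contrasts(table: AsvTable,
                  cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Prevalence-filter the table and run every configured consecutive
    layer contrast; results concatenated (BH within each contrast)."""
    if cfg is None:
        cfg = EnrichmentConfig()
    filtered = prevalence_filter(table, cfg.prevalence_min)
    pieces = []
    for contrast in cfg.contrasts:
        layers = filtered.sample_metadata["layer"]
        if not ((layers == contrast[0]).sum() >= 2
                and (layers == contrast[1]).sum() >= 2):
            continue
        pieces.append(nb_contrast(filtered, contrast, cfg))
    if not pieces:
        raise ValueError("no contrast had enough samples")
    return pd.concat(pieces, ignore_index=True)


def family_summary(results: pd.DataFrame, taxonomy: pd.DataFrame,
                   cfg: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Family-level view of the enriched ASVs per contrast.

    Only families with strictly more than ``min_asvs_per_family``
    enriched ASVs in a contrast are reported; the mean log2 fold change
    is positive for enrichment in the deeper layer.
    """
    if cfg is None:
        cfg = EnrichmentConfig()
    enriched = results[results["enriched"]].copy()
    enriched["family"] = taxonomy.loc[enriched["asv"], "family"].to_numpy()
    rows = []
    for (contrast, fam), grp in enriched.groupby(["contrast", "family"],
                                                 sort=True):
        if len(grp) <= cfg.min_asvs_per_family:
            continue
        lfc = grp["lfc"].to_numpy()
        rows.append((contrast, fam, len(grp), float(lfc.mean()),
                     float(lfc.std(ddof=1) / np.sqrt(len(lfc)))
                     if len(lfc) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["contrast", "family",
                                       "n_enriched", "mean_lfc", "se"])


def enriched_footprint(enriched_asvs, target: AsvTable) -> tuple[pd.Series,
                                                                 pd.DataFrame]:
    """Fraction of sequences belonging to the enriched ASV set.

    Returns the per-sample fraction and a (region, fraction, layer)
    summary with mean and standard error.  An empty enriched set gives
    all-zero fractions.
    """
    enriched_asvs = [a for a in enriched_asvs
                     if a in target.counts.columns]
    totals = target.totals()
    if len(enriched_asvs) == 0:
        frac = pd.Series(0.0, index=target.counts.index, name="footprint")
    else:
        frac = (target.counts[enriched_asvs].sum(axis=1)
                / totals).rename("footprint")
    meta = target.sample_metadata
    grouped = frac.groupby([meta["region"], meta["fraction"],
                            meta["layer"]], sort=True)
    summary = grouped.agg(mean="mean",
                          se=lambda s: s.std(ddof=1) / np.sqrt(len(s))
                          if len(s) > 1 else 0.0,
                          n="count").reset_index()
    return frac, summary
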