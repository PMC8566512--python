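"""Community ecology statistics: alpha diversity, ordination, FL-PA
distance contrasts and PERMANOVA.

Alpha diversity uses the bias-corrected Chao1 richness estimator and
Shannon's index in nats.  Ordination is a plain PCA of the
variance-stabilised count matrix.  The free-living vs particle-associated
contrast pairs the two filter fractions per station and water layer and
compares their Euclidean distances between regions with a rank test.
PERMANOVA follows the standard one-way decomposition of squared
distances with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1)).

    f1 and f2 are the numbers of singleton and doubleton ASVs.  Always
    at least the observed richness.
    """
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty sample: richness undefined")
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon diversity in nats: -sum p_i ln p_i over positive taxa."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty sample: diversity undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def extrapolate_richness(counts, depth_factor: float = 2.0) -> float:
    """Asymptotic richness expected at a multiple of the sequencing depth.

    A Chao1-based approximation of the sample-size-based extrapolation
    estimator: the expected richness at m = (factor-1) * n additional
    reads is S_obs + f0 * (1 - (1 - f1 / (n f0 + f1))^m) where f0 is the
    Chao1 estimate of the number of unseen species.
    """
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty sample")
    n = int(c.sum())
    s_obs = c.size
    f1 = int((c == 1).sum())
    f0 = chao1(c) - s_obs
    if f0 <= 0 or f1 == 0:
        return float(s_obs)
    m = (depth_factor - 1.0) * n
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m))


def pca(matrix: pd.DataFrame, n_components: int | None = None):
    """PCA of a samples x features matrix.

    Columns are mean-centred and the SVD taken; scores are returned per
    sample with the percentage of variance explained per axis.  Signs
    follow the convention that the largest-|loading| element of each
    component is positive, which makes the output deterministic.

    Returns ``(scores, explained_pct)`` where scores is a DataFrame
    (samples x PCs) and explained_pct a 1-D array.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: ordination degenerate")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s ** 2 / (X.shape[0] - 1)
    explained = 100.0 * var / var.sum()
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame(scores, index=idx, columns=cols), explained


def fl_pa_distance(matrix: pd.DataFrame, metadata: pd.DataFrame,
                   layer_order: tuple[str, ...] = ("surface", "epi",
                                                   "meso", "bathy")):
    """Euclidean FL-PA distances per station/layer plus a region contrast.

    For every (station, layer) with both a free-living and a
    particle-associated sample, the Euclidean distance between the two
    community profiles (rows of ``matrix``, typically variance
    stabilised) is computed.  Within each layer the distances of the two
    regions are compared with a two-sided Mann-Whitney rank test and the
    p-values BH-adjusted across layers.

    Returns ``(distances, tests)`` DataFrames.
    """
    meta = metadata.loc[matrix.index]
    rows = []
    for (station, layer), grp in meta.groupby(["station", "layer"],
                                              sort=True):
        fl = grp.index[grp["fraction"] == "FL"]
        pa = grp.index[grp["fraction"] == "PA"]
        if len(fl) != 1 or len(pa) != 1:
            continue  # unmatched pair: skipped
        d = float(np.linalg.norm(matrix.loc[fl[0]].to_numpy()
                                 - matrix.loc[pa[0]].to_numpy()))
        rows.append((station, layer, grp["region"].iloc[0], d))
    distances = pd.DataFrame(rows, columns=["station", "layer", "region",
                                            "distance"])
    tests = []
    for layer in layer_order:
        sub = distances[distances["layer"] == layer]
        regions = sorted(sub["region"].unique())
        if len(regions) != 2:
            continue
        a = sub.loc[sub["region"] == regions[0], "distance"]
        b = sub.loc[sub["region"] == regions[1], "distance"]
        if len(a) == 0 or len(b) == 0:
            continue
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        tests.append((layer, regions[0], regions[1], float(stat), float(p)))
    tests = pd.DataFrame(tests, columns=["layer", "region_a", "region_b",
                                         "statistic", "p"])
    if len(tests):
        tests["padj"] = multipletests(tests["p"], method="fdr_bh")[1]
    return distances, tests


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    df_among: int
    df_within: int
    n_permutations: int


def permanova(distance_matrix: np.ndarray, grouping, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum of squared distances / n; SS_within sums the same
    quantity within each group; the pseudo-F statistic is
    ``(SS_among/(k-1)) / (SS_within/(n-k))`` and the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` under free
    permutation of the group labels.  R^2 = SS_among / SS_total.
    """
    d = np.asarray(distance_matrix, dtype=float)
    groups = np.asarray(grouping)
    n = d.shape[0]
    if d.shape != (n, n) or groups.shape[0] != n:
        raise ValueError("distance matrix and grouping sizes disagree")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(np.bincount(inverse) < 2):
        raise ValueError("each group needs at least 2 samples")

    d2 = d ** 2

    def f_stat(inv):
        ss_total = d2.sum() / (2.0 * n)
        ss_within = 0.0
        for g in range(k):
            idx = np.flatnonzero(inv == g)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k)), \
            ss_among / ss_total

    f_obs, r2 = f_stat(inverse)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = f_stat(rng.permutation(inverse))
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=float(p),
                           df_among=k - 1, df_within=n - k,
                           n_permutations=n_permutations)


def euclidean_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances between the rows of a matrix."""
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(np.asarray(matrix, dtype=float)))


def alpha_diversity_table(counts: pd.DataFrame,
                          metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon with metadata columns attached."""
    rows = []
    for sample, row in counts.iterrows():
        c = row.to_numpy()
        rows.append((sample, chao1(c), shannon(c), int(c.sum()),
                     int((c > 0).sum())))
    out = pd.DataFrame(rows, columns=["sample", "chao1", "shannon",
                                      "reads", "observed_asvs"])
    out = out.set_index("sample")
    return out.join(metadata)
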