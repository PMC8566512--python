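"""Diversity, ordination and fraction/layer structure of the communities.

Computes per-sample Chao1 and Shannon diversity, a PCA of the
variance-stabilised water-column table, paired FL-PA Euclidean
distances per station and layer with a between-region rank test, and
PERMANOVA of the fraction (FL vs PA) and layer groupings.

Run after 01:  python analysis/06_community_stats.py
"""

from pathlib import Path

from icesink import community as cs
from icesink import enrichment as enr
from icesink.asv import AsvTable

INPUTS = Path("results/inputs")
OUT = Path("results")
SEED = 7


def main() -> None:
    suite = AsvTable.read(INPUTS / "asv")
    water = suite.select(fraction=("FL", "PA"))
    filtered = enr.prevalence_filter(water)

    alpha = cs.alpha_diversity_table(filtered.counts,
                                     filtered.sample_metadata)
    alpha.round(3).to_csv(OUT / "alpha_diversity.tsv", sep="\t")
    by_layer = alpha.groupby("layer")[["chao1", "shannon"]].mean()
    print("mean alpha diversity by layer:")
    print(by_layer.round(1).to_string())

    v = enr.vst(filtered)
    scores, explained = cs.pca(v, n_components=2)
    scores.join(filtered.sample_metadata).round(3).to_csv(
        OUT / "pca_scores.tsv", sep="\t")
    print(f"PCA: PC1 {explained[0]:.1f}%, PC2 {explained[1]:.1f}% of "
          "variance")

    d = cs.euclidean_distance_matrix(v)
    meta = filtered.sample_metadata
    res_frac = cs.permanova(d, meta["fraction"].to_numpy(),
                            n_permutations=999, seed=SEED)
    res_layer = cs.permanova(d, meta["layer"].to_numpy(),
                             n_permutations=999, seed=SEED + 1)
    print(f"PERMANOVA FL vs PA: F = {res_frac.pseudo_f:.2f}, "
          f"R^2 = {res_frac.r2:.3f}, p = {res_frac.p:.4f}")
    print(f"PERMANOVA layers:   F = {res_layer.pseudo_f:.2f}, "
          f"R^2 = {res_layer.r2:.3f}, p = {res_layer.p:.4f}")

    distances, tests = cs.fl_pa_distance(v, meta)
    distances.round(3).to_csv(OUT / "fl_pa_distances.tsv", sep="\t",
                              index=False)
    tests.round(5).to_csv(OUT / "fl_pa_distance_tests.tsv", sep="\t",
                          index=False)
    med = distances.groupby("layer")["distance"].median()
    print("median FL-PA distance by layer:")
    print(med.round(1).to_string())


if __name__ == "__main__":
    main()
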