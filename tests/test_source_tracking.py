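"""Rarefaction and the collapsed-Gibbs source tracker."""

import numpy as np
import pandas as pd
import pytest

from icesink import source_tracking as mst
from icesink import synthetic as syn
from icesink.asv import AsvTable

from conftest import two_source_gamma


def make_table(count_rows, meta_rows, columns):
    counts = pd.DataFrame(np.asarray(count_rows, dtype=int),
                          index=[m[0] for m in meta_rows], columns=columns)
    counts.index.name = "sample"
    meta = pd.DataFrame([m[1:] for m in meta_rows], index=counts.index,
                        columns=["fraction", "layer", "region", "station"])
    return AsvTable(counts, meta)


class TestRarefy:
    def test_exact_depth_and_drop(self, rng):
        cols = [f"a{i}" for i in range(20)]
        rows = [rng.multinomial(8000, np.ones(20) / 20),
                rng.multinomial(4999, np.ones(20) / 20)]
        meta = [("deep", "FL", "epi", "r", "s1"),
                ("shallow", "FL", "epi", "r", "s2")]
        table = make_table(rows, meta, cols)
        with pytest.warns(UserWarning):
            out = mst.rarefy(table, 5000, seed=0)
        assert list(out.counts.index) == ["deep"]
        assert out.totals().iloc[0] == 5000

    def test_sample_at_depth_unchanged_total(self, rng):
        cols = [f"a{i}" for i in range(10)]
        row = rng.multinomial(5000, np.ones(10) / 10)
        table = make_table([row], [("s", "FL", "epi", "r", "st")], cols)
        out = mst.rarefy(table, 5000, seed=0)
        assert (out.counts.iloc[0].to_numpy() == row).all()

    def test_hypergeometric_mean(self, rng):
        cols = [f"a{i}" for i in range(4)]
        row = np.array([6000, 3000, 800, 200])
        table = make_table([row], [("s", "FL", "epi", "r", "st")], cols)
        draws = np.array([mst.rarefy(table, 5000, seed=k)
                          .counts.iloc[0].to_numpy()
                          for k in range(400)])
        expect = 5000 * row / row.sum()
        se = np.sqrt(5000 * (row / row.sum())
                     * (1 - row / row.sum())) / np.sqrt(400)
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 5 * se + 1)

    def test_all_below_depth(self, rng):
        cols = [f"a{i}" for i in range(5)]
        table = make_table([[10, 5, 3, 2, 1]],
                           [("s", "FL", "epi", "r", "st")], cols)
        with pytest.raises(ValueError):
            mst.rarefy(table, 5000, seed=0)


def disjoint_sources(rng, n_taxa=300, depth=5000):
    """Three sources over disjoint 100-taxon pools."""
    cols = [f"a{i}" for i in range(n_taxa)]
    rows = []
    for k in range(3):
        p = np.zeros(n_taxa)
        p[100 * k:100 * (k + 1)] = 1.0 / 100
        rows.append(rng.multinomial(depth, p))
    return pd.DataFrame(rows, index=["s1", "s2", "s3"], columns=cols)


class TestFitSources:
    def test_sink_identical_to_one_source(self, rng):
        sources = disjoint_sources(rng)
        p = np.zeros(300)
        p[:100] = 1.0 / 100
        sink = pd.DataFrame([rng.multinomial(5000, p)], index=["x"],
                            columns=sources.columns)
        mix = mst.fit_sources(sink, sources, mst.MstConfig(seed=2))
        assert mix.proportions.loc["x", "s1"] > 0.95

    def test_unexplained_sink_goes_to_unknown(self, rng):
        sources = disjoint_sources(rng)
        cols = list(sources.columns) + [f"b{i}" for i in range(100)]
        sources = sources.reindex(columns=cols, fill_value=0)
        counts = np.zeros(400, int)
        counts[300:] = rng.multinomial(5000, np.ones(100) / 100)
        sink = pd.DataFrame([counts], index=["x"], columns=cols)
        mix = mst.fit_sources(sink, sources, mst.MstConfig(seed=3))
        assert mix.proportions.loc["x", "Unknown"] > 0.95

    def test_proportions_sum_to_one(self, rng):
        sources = disjoint_sources(rng)
        sink = pd.DataFrame([rng.multinomial(5000, np.ones(300) / 300)],
                            index=["x"], columns=sources.columns)
        mix = mst.fit_sources(sink, sources, mst.MstConfig(seed=4))
        assert mix.proportions.sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_label_permutation_equivariance(self, rng):
        sources = disjoint_sources(rng)
        p = np.zeros(300)
        p[:100] = 0.7 / 100
        p[100:200] = 0.3 / 100
        sink = pd.DataFrame([rng.multinomial(5000, p)], index=["x"],
                            columns=sources.columns)
        cfg = mst.MstConfig(seed=5)
        mix1 = mst.fit_sources(sink, sources, cfg)
        mix2 = mst.fit_sources(sink, sources.iloc[[1, 0, 2]], cfg)
        for s in ("s1", "s2", "s3"):
            assert mix1.proportions.loc["x", s] \
                == pytest.approx(mix2.proportions.loc["x", s], abs=0.02)

    def test_monotone_in_planted_fraction(self, rng):
        sources = disjoint_sources(rng)
        estimates = []
        for frac in (0.2, 0.5, 0.8):
            p = np.zeros(300)
            p[:100] = frac / 100
            p[100:200] = (1 - frac) / 100
            sink = pd.DataFrame([rng.multinomial(5000, p)], index=["x"],
                                columns=sources.columns)
            mix = mst.fit_sources(sink, sources, mst.MstConfig(seed=6))
            estimates.append(mix.proportions.loc["x", "s1"])
        assert estimates[0] < estimates[1] < estimates[2]

    def test_fixed_seed_reproducible(self, rng):
        sources = disjoint_sources(rng)
        sink = pd.DataFrame([rng.multinomial(5000, np.ones(300) / 300)],
                            index=["x"], columns=sources.columns)
        m1 = mst.fit_sources(sink, sources, mst.MstConfig(seed=7))
        m2 = mst.fit_sources(sink, sources, mst.MstConfig(seed=7))
        pd.testing.assert_frame_equal(m1.proportions, m2.proportions)

    def test_empty_sources_rejected(self, rng):
        sink = pd.DataFrame([[1, 2]], index=["x"], columns=["a", "b"])
        with pytest.raises(ValueError):
            mst.fit_sources(sink, pd.DataFrame(columns=["a", "b"]),
                            mst.MstConfig(seed=0))


class TestLeaveOneOut:
    def test_identical_pair_predicts_each_other(self, rng):
        cols = [f"a{i}" for i in range(100)]
        p = np.ones(100) / 100
        rows = [rng.multinomial(5000, p) for _ in range(2)]
        meta = [("s1", "FL", "epi", "r", "st1"),
                ("s2", "FL", "epi", "r", "st2")]
        table = make_table(rows, meta, cols)
        out = mst.leave_one_out(table, mst.MstConfig(seed=8), by=("layer",))
        assert out.loc["s1", "epi"] > 0.9
        assert out.loc["s2", "epi"] > 0.9
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_disjoint_pools_map_within_pool(self, rng):
        cols = [f"a{i}" for i in range(200)]
        p1 = np.zeros(200)
        p1[:100] = 1.0 / 100
        p2 = np.zeros(200)
        p2[100:] = 1.0 / 100
        rows = [rng.multinomial(5000, p1), rng.multinomial(5000, p1),
                rng.multinomial(5000, p2), rng.multinomial(5000, p2)]
        meta = [("a1", "FL", "surface", "r", "s1"),
                ("a2", "FL", "surface", "r", "s2"),
                ("b1", "FL", "bathy", "r", "s3"),
                ("b2", "FL", "bathy", "r", "s4")]
        table = make_table(rows, meta, cols)
        out = mst.leave_one_out(table, mst.MstConfig(seed=9), by=("layer",))
        assert out.loc["a1", "surface"] > 0.9
        assert out.loc["b1", "bathy"] > 0.9
        assert out.loc["a1", "bathy"] < 0.05

    def test_single_sample_rejected(self, rng):
        cols = [f"a{i}" for i in range(10)]
        table = make_table([rng.multinomial(100, np.ones(10) / 10)],
                           [("s", "FL", "epi", "r", "st")], cols)
        with pytest.raises(ValueError):
            mst.leave_one_out(table)


class TestLayerSummary:
    def test_single_sink_equals_own_proportions(self):
        props = pd.DataFrame([[0.5, 0.3, 0.2]], index=["x"],
                             columns=["surface/ice-free", "epi/ice-free",
                                      "Unknown"])
        mix = mst.MixingProportions(props, props * 0.0)
        meta = pd.DataFrame({"layer": ["meso"], "region": ["ice-free"]},
                            index=["x"])
        out = mst.summarize_by_layer(mix, meta)
        assert out.loc[("meso", "ice-free"),
                       ("mean", "surface/ice-free")] == 0.5

    def test_pooling_is_additive(self):
        props = pd.DataFrame([[0.5, 0.3, 0.2]], index=["x"],
                             columns=["surface/ice-free", "epi/ice-free",
                                      "Unknown"])
        mix = mst.MixingProportions(props, props * 0.0)
        meta = pd.DataFrame({"layer": ["meso"], "region": ["ice-free"]},
                            index=["x"])
        out = mst.summarize_by_layer(mix, meta, pool_surface_epi=True)
        assert out.loc[("meso", "ice-free"),
                       ("mean", "surface+epi")] == pytest.approx(0.8)

    def test_suite_mixture_recovery(self):
        """Bathypelagic PA sinks built as 25% surface FL recover ~0.25."""
        gamma = syn.default_mixing_matrix()
        gamma.loc["bathy"] = [0.25, 0.0, 0.0, 0.05, 0.70]
        cfg = syn.SyntheticConfig(seed=21)
        cfg.community = syn.CommunityConfig(mixing_matrix=gamma,
                                            n_planted=0)
        suite, _ = syn.make_community_suite(cfg)
        r = mst.rarefy(suite.select(fraction=("FL", "PA")), 5000, seed=0)
        pooled = mst.pool_sources(r.select(fraction="FL"), by=("layer",))
        sinks = r.select(fraction="PA", layer="bathy")
        mix = mst.fit_sources(sinks.counts.iloc[:3], pooled,
                              mst.MstConfig(seed=10))
        est = mix.proportions["surface"].mean()
        assert est == pytest.approx(0.25, abs=0.06)
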