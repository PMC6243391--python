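import numpy as np
import pandas as pd
import pytest

from turftraits.community_bootstrap import (
    _draw_many,
    bootstrap_all,
    bootstrap_community_distribution,
    draw_individual,
    select_trait_pool,
    summarize_bootstrap,
)
from turftraits.data_model import DataError

from conftest import make_trait_rows


def taxonomy(*species_genus):
    return pd.DataFrame(
        [(s, g, f"f_{g}", f"o_{g}") for s, g in species_genus],
        columns=["species", "genus", "family", "order"],
    )


def community(site, **biomass):
    return pd.DataFrame(
        [(site, "plot1", sp, b) for sp, b in biomass.items()],
        columns=["site", "plot_id", "species", "biomass"],
    )


class TestTraitPoolHierarchy:
    def test_species_at_site_first(self):
        df = make_trait_rows(
            [("g1_sp1", "S1", "p", "wild", "SLA", v) for v in range(5)]
            + [("g1_sp1", "S2", "p", "wild", "SLA", 99.0)]
        )
        tax = taxonomy(("g1_sp1", "g1"))
        pool = select_trait_pool("g1_sp1", "S1", "SLA", df, tax)
        assert pool.source_level == "species_at_site"
        assert pool.values.size == 5

    def test_genus_at_site_with_congener_groups(self):
        df = make_trait_rows(
            [("g1_sp2", "S1", "p", "wild", "SLA", 1.0),
             ("g1_sp2", "S1", "p", "wild", "SLA", 2.0),
             ("g1_sp3", "S1", "p", "wild", "SLA", 3.0)]
        )
        tax = taxonomy(("g1_sp1", "g1"), ("g1_sp2", "g1"), ("g1_sp3", "g1"))
        pool = select_trait_pool("g1_sp1", "S1", "SLA", df, tax)
        assert pool.source_level == "genus_at_site"
        assert len(pool.congener_groups) == 2

    def test_species_anywhere_beats_genus_anywhere(self):
        df = make_trait_rows(
            [("g1_sp1", "S2", "p", "wild", "SLA", 7.0),
             ("g1_sp2", "S2", "p", "wild", "SLA", 8.0)]
        )
        tax = taxonomy(("g1_sp1", "g1"), ("g1_sp2", "g1"))
        pool = select_trait_pool("g1_sp1", "S1", "SLA", df, tax)
        assert pool.source_level == "species_anywhere"
        assert pool.values.tolist() == [7.0]

    def test_exhausted_hierarchy_returns_none(self):
        df = make_trait_rows([("g2_sp1", "S1", "p", "wild", "SLA", 1.0)])
        tax = taxonomy(("g1_sp1", "g1"), ("g2_sp1", "g2"))
        assert select_trait_pool("g1_sp1", "S1", "SLA", df, tax) is None

    def test_manipulated_leaves_must_be_excluded_by_caller(self):
        # the hierarchy operates on whatever table it is given; the pipeline
        # passes only unmanipulated leaves
        df = make_trait_rows([("g1_sp1", "S1", "p", "control", "SLA", 1.0)])
        tax = taxonomy(("g1_sp1", "g1"))
        pool = select_trait_pool("g1_sp1", "S1", "SLA", df, tax)
        assert pool is not None


class TestDrawIndividual:
    def test_congener_rarefaction(self, rng):
        """A 1-leaf congener is as likely as a 100-leaf congener."""
        from turftraits.community_bootstrap import TraitPool

        pool = TraitPool(
            "sp", "S1", "SLA",
            values=np.concatenate([np.ones(100), [0.0]]),
            source_level="genus_at_site",
            congener_groups=[np.ones(100), np.zeros(1)],
        )
        draws = _draw_many(pool, 40_000, rng)
        assert np.mean(draws == 0.0) == pytest.approx(0.5, abs=0.02)

    def test_single_value_pool(self, rng):
        from turftraits.community_bootstrap import TraitPool

        pool = TraitPool("sp", "S1", "SLA", np.array([4.2]), "species_at_site")
        assert draw_individual(pool, rng) == 4.2

    def test_species_pool_uniformity(self, rng):
        from turftraits.community_bootstrap import TraitPool

        pool = TraitPool("sp", "S1", "SLA", np.array([1.0, 2.0, 3.0]), "species_at_site")
        draws = _draw_many(pool, 300_000, rng)
        for v in (1.0, 2.0, 3.0):
            assert np.mean(draws == v) == pytest.approx(1 / 3, abs=0.01)

    def test_scalar_and_vector_draws_share_distribution(self, rng):
        from turftraits.community_bootstrap import TraitPool

        pool = TraitPool(
            "sp", "S1", "SLA",
            values=np.array([0.0, 0.0, 1.0]),
            source_level="genus_at_site",
            congener_groups=[np.zeros(2), np.ones(1)],
        )
        scalar = np.array([draw_individual(pool, rng) for _ in range(20_000)])
        vector = _draw_many(pool, 20_000, rng)
        assert scalar.mean() == pytest.approx(0.5, abs=0.02)
        assert vector.mean() == pytest.approx(0.5, abs=0.02)


class TestBootstrap:
    def test_degenerate_pools_exact_weighted_mean(self):
        df = make_trait_rows(
            [("g1_sp1", "S1", "p", "wild", "SLA", 10.0),
             ("g2_sp1", "S1", "p", "wild", "SLA", 2.0)]
        )
        tax = taxonomy(("g1_sp1", "g1"), ("g2_sp1", "g2"))
        comm = community("S1", g1_sp1=3.0, g2_sp1=1.0)
        res = bootstrap_community_distribution(
            "S1", "SLA", comm, df, tax, B=50, n_draws=40, seed=0
        )
        assert np.allclose(res.replicate_means, 8.0)  # (3*10 + 1*2) / 4
        s = summarize_bootstrap(res)
        assert (s.mean, s.ci_low, s.ci_high) == (8.0, 8.0, 8.0)

    def test_single_species_plain_bootstrap(self, rng):
        vals = [1.0, 2.0, 3.0, 4.0]
        df = make_trait_rows([("g1_sp1", "S1", "p", "wild", "SLA", v) for v in vals])
        tax = taxonomy(("g1_sp1", "g1"))
        comm = community("S1", g1_sp1=5.0)
        res = bootstrap_community_distribution(
            "S1", "SLA", comm, df, tax, B=400, n_draws=100, seed=1
        )
        assert res.coverage == 1.0
        assert res.replicate_means.mean() == pytest.approx(np.mean(vals), abs=0.05)

    def test_biomass_scale_invariance(self):
        df = make_trait_rows(
            [("g1_sp1", "S1", "p", "wild", "SLA", 10.0),
             ("g2_sp1", "S1", "p", "wild", "SLA", 20.0),
             ("g2_sp1", "S1", "p", "wild", "SLA", 30.0)]
        )
        tax = taxonomy(("g1_sp1", "g1"), ("g2_sp1", "g2"))
        a = bootstrap_community_distribution(
            "S1", "SLA", community("S1", g1_sp1=3.0, g2_sp1=1.0), df, tax,
            B=20, n_draws=30, seed=7,
        )
        b = bootstrap_community_distribution(
            "S1", "SLA", community("S1", g1_sp1=300.0, g2_sp1=100.0), df, tax,
            B=20, n_draws=30, seed=7,
        )
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    def test_seed_determinism(self):
        df = make_trait_rows(
            [("g1_sp1", "S1", "p", "wild", "SLA", v) for v in range(6)]
        )
        tax = taxonomy(("g1_sp1", "g1"))
        comm = community("S1", g1_sp1=1.0)
        a = bootstrap_community_distribution("S1", "SLA", comm, df, tax, B=30, n_draws=20, seed=42)
        b = bootstrap_community_distribution("S1", "SLA", comm, df, tax, B=30, n_draws=20, seed=42)
        np.testing.assert_array_equal(a.replicate_means, b.replicate_means)

    def test_coverage_accounts_for_missing_species(self):
        df = make_trait_rows([("g1_sp1", "S1", "p", "wild", "SLA", 1.0)])
        tax = taxonomy(("g1_sp1", "g1"), ("g9_sp1", "g9"))
        comm = community("S1", g1_sp1=1.0, g9_sp1=3.0)
        res = bootstrap_community_distribution("S1", "SLA", comm, df, tax, B=10, n_draws=10, seed=0)
        assert res.coverage == pytest.approx(0.25)

    def test_no_data_at_all_raises(self):
        df = make_trait_rows([("g1_sp1", "S1", "p", "wild", "SLA", 1.0)])
        tax = taxonomy(("g9_sp1", "g9"))
        comm = community("S2", g9_sp1=1.0)
        with pytest.raises(DataError, match="S2"):
            bootstrap_community_distribution("S2", "SLA", comm, df, tax, B=10, n_draws=10, seed=0)

    def test_replicate_mean_centers_on_plugin_weighted_mean(self, small_dataset):
        from turftraits.data_model import unmanipulated

        ds = small_dataset
        res = bootstrap_community_distribution(
            "S1", "SLA", ds.community, unmanipulated(ds.traits), ds.taxonomy,
            B=800, n_draws=400, seed=3,
        )
        # plug-in target: biomass-weighted mean of per-species pool means
        comm = ds.community[ds.community["site"] == "S1"]
        pools = unmanipulated(ds.traits)
        pools = pools[(pools["trait"] == "SLA") & (pools["site"] == "S1")]
        sp_means = pools.groupby("species")["value"].mean()
        merged = comm[comm["species"].isin(sp_means.index)]
        w = merged["biomass"].to_numpy()
        target = float(np.average(sp_means[merged["species"]].to_numpy(), weights=w))
        se = res.replicate_means.std(ddof=1) / np.sqrt(res.B)
        assert abs(res.replicate_means.mean() - target) < 4 * se


class TestSummaries:
    def test_quantile_oracle_linear_interpolation(self):
        from turftraits.community_bootstrap import BootstrapResult

        res = BootstrapResult(
            "S1", "SLA", np.arange(1.0, 1001.0), n_draws_per_replicate=1,
            weighted=True, coverage=1.0,
        )
        s = summarize_bootstrap(res, level=0.95)
        assert s.ci_low == pytest.approx(25.975)
        assert s.ci_high == pytest.approx(975.025)

    def test_level_zero_collapses_to_median(self):
        from turftraits.community_bootstrap import BootstrapResult

        res = BootstrapResult(
            "S1", "SLA", np.array([1.0, 2.0, 10.0]), 1, True, 1.0
        )
        s = summarize_bootstrap(res, level=0.0)
        assert s.ci_low == s.ci_high == 2.0

    def test_bootstrap_all_shape_and_determinism(self, small_dataset):
        from turftraits.data_model import unmanipulated

        ds = small_dataset
        kw = dict(B=40, n_draws=30, seed=5)
        a = bootstrap_all(ds.community, unmanipulated(ds.traits), ds.taxonomy, **kw)
        b = bootstrap_all(ds.community, unmanipulated(ds.traits), ds.taxonomy, **kw)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 3 * 2  # sites x traits
        assert ((a["ci_low"] <= a["mean"]) & (a["mean"] <= a["ci_high"])).all()
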