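import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from turftraits.convergence import (
    ContingencyTable,
    HomeSummary,
    build_convergence_records,
    classify_transplant,
    g_test,
    outcome_proportions,
    summarize_home,
    summarize_homes,
    tabulate_outcomes,
)
from turftraits.data_model import DataError, InsufficientDataError, unmanipulated

from conftest import make_trait_rows


class TestHomeSummary:
    def test_hand_computation(self):
        df = make_trait_rows(
            [("sp1", "S1", "p", "wild", "SLA", v) for v in (1, 2, 3, 4, 5)]
        )
        s = summarize_home(df, "sp1", "S1", "SLA")
        assert s.mean == 3.0
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        t_q = stats.t.ppf(0.995, 4)
        assert t_q == pytest.approx(4.604, abs=1e-3)
        assert s.ci_low == pytest.approx(3 - t_q * s.sd / np.sqrt(5), abs=1e-9)
        assert s.ci_low == pytest.approx(-0.2556, abs=1e-3)
        assert s.ci_high == pytest.approx(6.2556, abs=1e-3)

    def test_identical_values_zero_width(self):
        df = make_trait_rows(
            [("sp1", "S1", "p", "wild", "SLA", 7.0) for _ in range(4)]
        )
        s = summarize_home(df, "sp1", "S1", "SLA")
        assert s.ci_low == s.ci_high == 7.0

    def test_single_leaf_insufficient(self):
        df = make_trait_rows([("sp1", "S1", "p", "wild", "SLA", 1.0)])
        with pytest.raises(InsufficientDataError):
            summarize_home(df, "sp1", "S1", "SLA")

    def test_bulk_summaries_count_insufficient(self):
        df = make_trait_rows(
            [("sp1", "S1", "p", "wild", "SLA", 1.0),
             ("sp2", "S1", "p", "wild", "SLA", 1.0),
             ("sp2", "S1", "p", "wild", "SLA", 2.0),
             ("sp2", "S1", "p", "warmed", "SLA", 9.0)]  # manipulated: ignored
        )
        df.loc[3, "origin_site"] = "S2"
        out = summarize_homes(df)
        assert out["_n_insufficient"] == 1
        assert out[("sp2", "S1", "SLA")].n == 2


HOME = HomeSummary("sp1", "S1", "SLA", mean=10.0, sd=1.0, n=9,
                   ci_low=8.0, ci_high=12.0)


class TestClassification:
    def test_significant_shift_toward_destination(self):
        outcome, start = classify_transplant(15.0, HOME, 10.0, 20.0)
        assert outcome == "converging"
        assert start == "home"

    def test_inside_ci_is_no_change_regardless_of_distance(self):
        outcome, _ = classify_transplant(11.0, HOME, 10.0, 20.0)
        assert outcome == "no_change"

    def test_shift_away_is_diverging(self):
        outcome, _ = classify_transplant(5.0, HOME, 10.0, 20.0)
        assert outcome == "diverging"

    def test_start_group_destination(self):
        _, start = classify_transplant(15.0, HOME, 0.0, 11.0)
        assert start == "destination"

    def test_equidistant_ties(self):
        # start tie -> home; outcome tie (equal distances, significant) -> diverging
        outcome, start = classify_transplant(14.0, HOME, 4.0, 16.0)
        assert start == "home"
        out2, _ = classify_transplant(26.0, HOME, 10.0, 18.0)
        assert out2 == "diverging"


class TestTabulate:
    def make_records(self, rows):
        return pd.DataFrame(
            rows, columns=["outcome", "start_group", "treatment"]
        )

    def test_all_cells_one(self):
        rows = [
            (o, s, "warming")
            for o in ("converging", "diverging", "no_change")
            for s in ("home", "destination")
        ]
        recs = self.make_records(rows)
        tab = tabulate_outcomes(recs, "start_group")
        assert tab.counts.tolist() == [[1, 1], [1, 1], [1, 1]]

    def test_empty_factor_level_kept(self):
        recs = self.make_records([("converging", "home", "warming")] * 3)
        tab = tabulate_outcomes(recs, "start_group")
        assert tab.counts[:, tab.columns.index("destination")].sum() == 0
        assert tab.counts.sum() == 3

    def test_marginals_match_frequencies(self):
        rng = np.random.default_rng(0)
        rows = [
            (rng.choice(["converging", "diverging", "no_change"]),
             rng.choice(["home", "destination"]), "warming")
            for _ in range(50)
        ]
        recs = self.make_records(rows)
        tab = tabulate_outcomes(recs, "start_group")
        for i, outcome in enumerate(tab.rows):
            assert tab.counts[i].sum() == (recs["outcome"] == outcome).sum()


class TestGTest:
    def test_no_association_gives_zero(self):
        tab = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 10], [10, 10]]))
        res = g_test(tab)
        assert res.G == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        tab = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 0], [0, 10]]))
        res = g_test(tab)
        assert res.G == pytest.approx(40 * np.log(2), rel=1e-12)
        assert res.df == 1

    def test_partial_association_closed_form(self):
        tab = ContingencyTable(("a", "b"), ("x", "y"), np.array([[30, 10], [10, 30]]))
        res = g_test(tab)
        assert res.G == pytest.approx(120 * np.log(1.5) - 40 * np.log(2), rel=1e-12)
        assert res.G == pytest.approx(20.930, abs=1e-3)

    def test_matches_scipy_log_likelihood(self):
        counts = np.array([[23, 41, 12], [7, 30, 19]])
        tab = ContingencyTable(("a", "b"), ("x", "y", "z"), counts)
        res = g_test(tab)
        g, p, df, _ = stats.chi2_contingency(counts, correction=False,
                                             lambda_="log-likelihood")
        assert res.G == pytest.approx(g, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df == df

    def test_close_to_pearson_for_large_expected(self):
        rng = np.random.default_rng(1)
        base = np.array([[120.0, 140.0], [150.0, 110.0]])
        counts = (base + rng.integers(0, 10, size=(2, 2))).astype(int)
        tab = ContingencyTable(("a", "b"), ("x", "y"), counts)
        res = g_test(tab)
        chi2 = stats.chi2_contingency(counts, correction=False)[0]
        assert res.G == pytest.approx(chi2, rel=0.01)

    def test_all_zero_column_dropped_with_df_adjust(self):
        counts = np.array([[10, 0, 5], [3, 0, 12]])
        tab = ContingencyTable(("a", "b"), ("x", "y", "z"), counts)
        res = g_test(tab)
        assert res.df == 1

    def test_degenerate_table_rejected(self):
        tab = ContingencyTable(("a",), ("x", "y"), np.array([[3, 4]]))
        with pytest.raises(DataError):
            g_test(tab)
        empty = ContingencyTable(("a", "b"), ("x", "y"), np.zeros((2, 2), dtype=int))
        with pytest.raises(DataError):
            g_test(empty)


@settings(max_examples=40, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=30), min_size=4, max_size=4),
    k=st.integers(min_value=2, max_value=5),
)
def test_g_scales_linearly_with_counts(counts, k):
    """G(k*O) = k*G(O): the statistic grows with sample size, unlike the
    association strength it measures."""
    o = np.array(counts).reshape(2, 2)
    if (o.sum(axis=0) == 0).any() or (o.sum(axis=1) == 0).any():
        return
    g1 = g_test(ContingencyTable(("a", "b"), ("x", "y"), o)).G
    gk = g_test(ContingencyTable(("a", "b"), ("x", "y"), k * o)).G
    assert gk == pytest.approx(k * g1, rel=1e-9, abs=1e-9)


class TestPipelineIntegration:
    def test_records_internally_consistent(self, small_dataset):
        from turftraits.community_bootstrap import bootstrap_all

        ds = small_dataset
        summaries = bootstrap_all(
            ds.community, unmanipulated(ds.traits), ds.taxonomy,
            B=100, n_draws=80, seed=2,
        )
        recs = build_convergence_records(ds.traits, ds.design, summaries)
        assert not recs.empty
        inside = (recs["T_mean"] >= recs["ci99_low"]) & (recs["T_mean"] <= recs["ci99_high"])
        assert ((recs["outcome"] == "no_change") == inside).all()
        sig = recs[~inside]
        conv = (
            (sig["T_mean"] - sig["dest_comm_mean"]).abs()
            < (sig["H_mean"] - sig["dest_comm_mean"]).abs()
        )
        assert ((sig["outcome"] == "converging") == conv).all()
        props = outcome_proportions(recs)
        sums = props.groupby(["treatment", "start_group"])["proportion"].sum()
        assert np.allclose(sums, 1.0)
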