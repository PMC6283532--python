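import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devgraph import (
    CountryTable,
    DegenerateIndicatorError,
    IndicatorSpec,
    orient,
    percentile_tscore,
    score_table,
    tscore,
)


def normal_quantile_oracle(p: float) -> float:
    """Invert the standard normal CDF by bisection on math.erf —
    independent of the scipy quantile routine used in the package."""
    lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if 0.5 * (1 + math.erf(mid / math.sqrt(2))) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestTscore:
    def test_one_two_three(self):
        """{1,2,3} has mean 2 and sample SD 1: scores are {40,50,60}."""
        np.testing.assert_allclose(
            tscore(np.array([1.0, 2.0, 3.0])), [40.0, 50.0, 60.0]
        )

    def test_mean_maps_to_fifty(self):
        """A value equal to the sample mean scores exactly the reference 50."""
        x = np.array([3.0, 5.0, 7.0, 9.0])
        out = tscore(np.append(x, x.mean()))  # appending the mean keeps the mean
        assert out[-1] == pytest.approx(50.0, abs=1e-12)

    def test_missing_preserved(self):
        s = pd.Series([1.0, np.nan, 2.0, 3.0], index=list("abcd"))
        out = tscore(s)
        assert np.isnan(out["b"])
        np.testing.assert_allclose(out[["a", "c", "d"]], [40.0, 50.0, 60.0])

    def test_zero_sd_raises(self):
        with pytest.raises(DegenerateIndicatorError, match="degenerate"):
            tscore(np.array([5.0, 5.0, 5.0]))

    def test_too_few_raises(self):
        with pytest.raises(DegenerateIndicatorError):
            tscore(np.array([1.0, 2.0]))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                      allow_infinity=False),
            min_size=3, max_size=200, unique=True,
        )
    )
    def test_conservation(self, values):
        """Non-missing deviation values always have mean 50 and sample
        SD 10, whatever the input distribution."""
        out = pd.Series(tscore(np.asarray(values)))
        assert out.mean() == pytest.approx(50.0, rel=1e-9)
        assert out.std(ddof=1) == pytest.approx(10.0, rel=1e-9)


class TestPercentile:
    def test_median_of_odd_vector_is_fifty(self):
        out = percentile_tscore(np.array([10.0, 20.0, 30.0, 40.0, 50.0]))
        assert out[2] == pytest.approx(50.0)

    def test_quarter_percentile(self):
        """The country ranked 2nd of 6 has p = (2-0.5)/6 = 0.25 and
        scores 50 + 10*Phi^-1(0.25) = 43.26."""
        x = np.array([5.0, 1.0, 9.0, 12.0, 30.0, 21.0])
        out = percentile_tscore(x)
        expected = 50.0 + 10.0 * normal_quantile_oracle(0.25)
        assert out[x == 5.0][0] == pytest.approx(expected, abs=1e-9)
        assert out[x == 5.0][0] == pytest.approx(43.26, abs=0.01)

    def test_ties_get_midranks(self):
        out = percentile_tscore(np.array([1.0, 2.0, 2.0, 3.0]))
        assert out[1] == out[2]
        assert out[0] < out[1] < out[3]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e5, max_value=1e5, allow_nan=False),
            min_size=3, max_size=100, unique=True,
        )
    )
    def test_strictly_increasing_in_rank(self, values):
        x = np.asarray(values)
        out = percentile_tscore(x)
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) > 0)

    def test_missing_preserved(self):
        s = pd.Series([1.0, np.nan, 3.0, 2.0])
        out = percentile_tscore(s)
        assert np.isnan(out[1])
        assert out[0] < out[3] < out[2]


class TestOrient:
    def test_reflection(self):
        assert orient(40.0, "lower_desirable") == 60.0
        assert orient(73.0, "lower_desirable") == 27.0

    def test_identity_for_higher_and_neutral(self):
        x = np.array([30.0, 50.0, 77.0])
        np.testing.assert_array_equal(orient(x, "higher_desirable"), x)
        np.testing.assert_array_equal(orient(x, "neutral"), x)

    def test_involution(self):
        x = np.array([12.3, 50.0, 88.8])
        np.testing.assert_allclose(
            orient(orient(x, "lower_desirable"), "lower_desirable"), x
        )

    def test_oriented_scores_keep_calibration(self):
        """Reflecting about 50 preserves mean 50 and SD 10."""
        rng = np.random.default_rng(5)
        t = pd.Series(tscore(rng.gamma(2, 10, 120)))
        o = pd.Series(orient(t, "lower_desirable"))
        assert o.mean() == pytest.approx(50.0, rel=1e-9)
        assert o.std(ddof=1) == pytest.approx(10.0, rel=1e-9)

    def test_unknown_polarity(self):
        with pytest.raises(ValueError):
            orient(50.0, "sideways")


def _make_table(columns: dict, registry: list[IndicatorSpec],
                income: str = "low") -> CountryTable:
    data = pd.DataFrame(columns)
    data.index = pd.Index([f"C{i:02d}" for i in range(len(data))], name="country")
    return CountryTable(
        data=data,
        income_class=pd.Series(income, index=data.index),
        registry=registry,
    )


class TestScoreTable:
    def test_constant_indicator_isolated(self):
        """A degenerate indicator is reported; the rest still score."""
        rng = np.random.default_rng(0)
        table = _make_table(
            {
                "flat": np.full(30, 4.0),
                "ok": rng.normal(50, 10, 30),
            },
            [
                IndicatorSpec("flat", "Flat", "wash"),
                IndicatorSpec("ok", "Ok", "wash"),
            ],
        )
        matrix = score_table(table)
        assert "flat" in matrix.errors
        assert list(matrix.values.columns) == ["ok"]

    def test_ceiling_flag_selects_percentile(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.uniform(99.0, 100.0, 18), rng.uniform(50, 95, 12)])
        table = _make_table(
            {"lit": vals},
            [IndicatorSpec("lit", "Literacy", "socioeconomic", ceiling=True)],
        )
        matrix = score_table(table)
        assert matrix.method["lit"] == "percentile"

    def test_ceiling_heuristic_warns_but_does_not_switch(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.uniform(99.0, 100.0, 18), rng.uniform(50, 95, 12)])
        table = _make_table(
            {"lit": vals},
            [IndicatorSpec("lit", "Literacy", "socioeconomic", ceiling=False)],
        )
        with pytest.warns(UserWarning, match="percentile"):
            matrix = score_table(table)
        assert matrix.method["lit"] == "boxcox_tscore"

    def test_method_override(self):
        rng = np.random.default_rng(3)
        table = _make_table(
            {"x": rng.normal(50, 10, 40)}, [IndicatorSpec("x", "X", "wash")]
        )
        matrix = score_table(table, method_overrides={"x": "percentile"})
        assert matrix.method["x"] == "percentile"

    def test_gaussian_table_conserves_mean_and_sd(self):
        rng = np.random.default_rng(4)
        table = _make_table(
            {f"g{i}": rng.normal(30 + i, 5, 80) for i in range(4)},
            [IndicatorSpec(f"g{i}", f"G{i}", "adult_biomarker") for i in range(4)],
        )
        matrix = score_table(table)
        for col in matrix.values:
            s = matrix.values[col].dropna()
            assert s.mean() == pytest.approx(50.0, rel=1e-9)
            assert s.std(ddof=1) == pytest.approx(10.0, rel=1e-9)

    def test_lower_desirable_is_reflected(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(3, 5, 60)
        lower = _make_table(
            {"a": x}, [IndicatorSpec("a", "A", "infancy_under5", "lower_desirable")]
        )
        higher = _make_table(
            {"a": x}, [IndicatorSpec("a", "A", "infancy_under5", "higher_desirable")]
        )
        np.testing.assert_allclose(
            score_table(lower).values["a"], 100.0 - score_table(higher).values["a"]
        )
        assert score_table(lower).oriented["a"]

    def test_missing_country_does_not_influence_others(self):
        """A country missing an indicator leaves the other countries'
        scores on that indicator unchanged; a country WITH data shifts
        them (scores are relative positions)."""
        rng = np.random.default_rng(7)
        x = rng.normal(20, 4, 40)
        spec = [IndicatorSpec("a", "A", "wash")]
        full = _make_table({"a": x}, spec)
        withheld = x.copy()
        withheld[0] = np.nan
        partial = _make_table({"a": withheld}, spec)
        sub = score_table(partial).values["a"].iloc[1:]
        # dropping C00's value entirely reproduces the partial scores
        dropped = _make_table({"a": x[1:]}, spec)
        np.testing.assert_allclose(
            sub.to_numpy(), score_table(dropped).values["a"].to_numpy()
        )
        # but they differ from the full-table scores
        assert not np.allclose(
            sub.to_numpy(), score_table(full).values["a"].iloc[1:].to_numpy()
        )

    def test_export_carries_method_and_orientation(self, tmp_path):
        rng = np.random.default_rng(8)
        table = _make_table(
            {"a": rng.normal(10, 2, 30), "b": rng.uniform(90, 100, 30)},
            [
                IndicatorSpec("a", "A", "wash", "lower_desirable"),
                IndicatorSpec("b", "B", "socioeconomic", ceiling=True),
            ],
        )
        matrix = score_table(table)
        out = tmp_path / "matrix.csv"
        matrix.to_csv(out)
        text = out.read_text().splitlines()
        assert text[1].startswith("#method,boxcox_tscore,percentile")
        assert text[2].startswith("#oriented,True,False")
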