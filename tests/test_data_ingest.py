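import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tradepgls import data_ingest as di


def _csv_table(rows):
    df = pd.DataFrame(rows)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


def _row(sp="sp1", price=100.0, **kw):
    base = dict(species_id=sp, price_twd=price, n_for_sale=5, status="native",
                realm="none", iucn="LC", cites_listed=0, body_mass_g=20.0,
                range_km2=1e6, song_count=3)
    base.update(kw)
    return base


class TestReadSpeciesTable:
    def test_reads_valid_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame([_row("a"), _row("b"), _row("c")]).to_csv(p, index=False)
        table = di.read_species_table(p)
        assert table.n == 3
        assert table.species == ["a", "b", "c"]

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "t.csv"
        df = pd.DataFrame([_row()]).drop(columns=["price_twd"])
        df.to_csv(p, index=False)
        with pytest.raises(di.SchemaError, match="price_twd"):
            di.read_species_table(p)

    def test_non_numeric_price_reports_row(self):
        df = pd.DataFrame([_row("a"), _row("b", price="expensive")])
        with pytest.raises(di.SchemaError, match="row 1"):
            di.validate_table(df)

    def test_duplicate_species_rejected(self):
        df = pd.DataFrame([_row("a"), _row("a")])
        with pytest.raises(di.SchemaError, match="duplicate"):
            di.validate_table(df)

    def test_missing_values_retained_and_flagged(self):
        df = pd.DataFrame([_row("a"), _row("b", body_mass_g=np.nan)])
        table = di.validate_table(df)
        assert table.n == 2
        assert table.df["has_missing"].tolist() == [False, True]

    def test_synthetic_fixture_round_trips(self, tmp_path):
        from tradepgls.synthetic import build_synthetic_study

        table, _, _, _ = build_synthetic_study(seed=7, n_species=217,
                                               n_trees_univariate=1,
                                               n_trees_candidate=1)
        p = tmp_path / "s1.csv"
        table.df.drop(columns=["has_missing"]).to_csv(p, index=False)
        assert di.read_species_table(p).n == 217


class TestExclusions:
    def _table(self, n):
        return di.validate_table(
            pd.DataFrame([_row(f"sp{i}") for i in range(n)]))

    def test_drop_listed_ids(self):
        table = self._table(221)
        out = di.apply_exclusions(table, ["sp0", "sp1", "sp2", "sp3"])
        assert out.n == 217

    def test_empty_drop_list_is_identity(self):
        table = self._table(5)
        out = di.apply_exclusions(table, [])
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_absent_id_warns_not_errors(self):
        table = self._table(3)
        with pytest.warns(UserWarning, match="ghost"):
            out = di.apply_exclusions(table, ["ghost"])
        assert out.n == 3


class TestColourMetrics:
    def _sheet(self, per_colour_parts):
        sheet = pd.DataFrame(0, index=list(di.BODY_PARTS),
                             columns=list(di.COLOURS))
        for colour, k in per_colour_parts.items():
            sheet.iloc[:k, sheet.columns.get_loc(colour)] = 1
        return sheet

    def test_coverage_fraction_of_parts(self):
        cov = di.colour_coverage(self._sheet({"red": 7}))
        assert cov["red"] == pytest.approx(0.5)
        assert cov["blue"] == 0.0

    def test_coverage_saturation(self):
        cov = di.colour_coverage(self._sheet({"black": 14}))
        assert cov["black"] == 1.0

    def test_wrong_part_count_rejected(self):
        bad = self._sheet({"red": 3}).iloc[:10]
        with pytest.raises(ValueError, match="body parts"):
            di.colour_coverage(bad)

    def test_diversity_counts_above_threshold(self):
        cov = np.zeros(11)
        cov[:2] = 0.5
        assert di.colour_diversity(cov) == 2

    def test_diversity_excludes_sub_threshold_coverage(self):
        # a colour on <3% of the body does not count; 3% exactly does
        assert di.colour_diversity(np.array([0.02] + [0.0] * 10)) == 0
        assert di.colour_diversity(np.array([0.03] + [0.0] * 10)) == 1

    def test_diversity_upper_bound(self):
        assert di.colour_diversity(np.full(11, 0.2)) == 11

    @given(st.lists(st.floats(0, 1), min_size=11, max_size=11),
           st.integers(0, 10), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_diversity_monotone_in_each_coverage(self, cov, i, bump):
        base = np.array(cov)
        upped = base.copy()
        upped[i] = min(1.0, upped[i] + bump)
        assert di.colour_diversity(upped) >= di.colour_diversity(base)


class TestSongAttractiveness:
    def test_perfect_fit_gives_zero_residuals(self):
        ranges = np.array([1e4, 1e5, 1e6])
        counts = np.expm1(0.1 + 0.3 * np.log(ranges))
        resid = di.song_attractiveness(counts, ranges)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_over_recorded_species_gets_positive_residual(self):
        ranges = np.array([1e4, 1e5, 1e6, 1e7])
        counts = np.expm1(0.1 + 0.3 * np.log(ranges))
        counts[2] *= 10  # far more recordings than its range predicts
        resid = di.song_attractiveness(counts, ranges)
        assert resid[2] > 0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ranges = np.exp(rng.normal(14, 1.5, 50))
        counts = np.maximum(
            np.expm1(0.2 + 0.35 * np.log(ranges) + rng.normal(0, 0.5, 50)), 0)
        resid = di.song_attractiveness(counts, ranges)
        # independent closed-form OLS via the normal equations
        X = np.column_stack([np.ones(50), np.log(ranges)])
        y = np.log1p(counts)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(resid, y - X @ beta, atol=1e-10)
        assert abs(resid.sum()) < 1e-9

    def test_identical_ranges_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            di.song_attractiveness([1, 2, 3], [1e5, 1e5, 1e5])


class TestTransforms:
    def _table(self):
        rows = [_row("a", price=30.0, body_mass_g=10.0),
                _row("b", price=100.0, body_mass_g=250.0, status="alien",
                     iucn="EN", realm="Neotropic")]
        t = di.validate_table(pd.DataFrame(rows))
        t.df["cov_yellow"] = [0.5, 0.0]
        t.df["cov_grey"] = [1.0, 0.25]
        return t

    def test_arcsine_sqrt_values(self):
        out = di.transform_predictors(self._table()).df
        assert out["asin_yellow"].iloc[0] == pytest.approx(np.pi / 4)
        assert out["asin_yellow"].iloc[1] == 0.0
        assert out["asin_grey"].iloc[0] == pytest.approx(np.pi / 2)

    def test_natural_log_price(self):
        out = di.transform_predictors(self._table()).df
        assert out["ln_price"].iloc[0] == pytest.approx(3.4012, abs=1e-4)

    def test_round_trip_invertible(self):
        out = di.transform_predictors(self._table()).df
        assert np.allclose(np.exp(out["ln_price"]), out["price_twd"],
                           rtol=1e-12)
        assert np.allclose(np.sin(out["asin_grey"]) ** 2, out["cov_grey"],
                           atol=1e-12)

    def test_categorical_recodes(self):
        out = di.transform_predictors(self._table()).df
        assert out["status_alien"].tolist() == [0.0, 1.0]
        assert out["iucn_threatened"].tolist() == [0.0, 1.0]
        assert out["iucn_EN"].tolist() == [0.0, 1.0]

    def test_coverage_outside_unit_interval_rejected(self):
        t = self._table()
        t.df.loc[0, "cov_yellow"] = 1.5
        with pytest.raises(ValueError, match="cov_yellow"):
            di.transform_predictors(t)


class TestSummaryTallies:
    # the ten largest per-species counts from the survey's printed ranking,
    # with the remaining 207 species filled in to reach the printed grand
    # total of 26,165 individuals
    TOP10 = (7420, 6381, 2649, 956, 928, 722, 492, 465, 437, 405)

    def _survey_like_table(self):
        rows = [_row(f"top{i}", n_for_sale=n) for i, n in enumerate(self.TOP10)]
        remainder = 26165 - sum(self.TOP10)
        filler = [25] * 206 + [remainder - 25 * 206]
        assert all(f < min(self.TOP10) for f in filler)
        rows += [_row(f"rest{i}", n_for_sale=f) for i, f in enumerate(filler)]
        return di.validate_table(pd.DataFrame(rows))

    def test_top_ten_share_rounds_to_80_percent(self):
        tallies = di.summary_tallies(self._survey_like_table())
        assert tallies["total_individuals"] == 26165
        assert round(tallies["top_k_share_pct"]) == 80

    def test_single_species_share_is_total(self):
        t = di.validate_table(pd.DataFrame([_row("only", n_for_sale=7)]))
        assert di.summary_tallies(t)["top_k_share_pct"] == 100.0

    def test_usd_conversion(self):
        t = di.validate_table(pd.DataFrame(
            [_row("a", price=30.0), _row("b", price=240000.0)]))
        tallies = di.summary_tallies(t, twd_per_usd=30.0)
        assert tallies["min_price_usd"] == pytest.approx(1.00)
        assert tallies["max_price_usd"] == pytest.approx(8000.00)

    def test_row_order_invariance(self):
        t = self._survey_like_table()
        shuffled = di.TraitTable(
            t.df.sample(frac=1, random_state=1).reset_index(drop=True))
        a = di.summary_tallies(t)
        b = di.summary_tallies(shuffled)
        for key in ("total_individuals", "top_k_share", "total_value_twd",
                    "alien_individuals"):
            assert a[key] == b[key]
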