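"""Dataset container, CSV IO, proxy annualization, centering, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countflux import (
    ProxyRecord,
    TimeSeriesDataset,
    align_window,
    annualize_proxy,
    mean_center,
    read_dataset,
    write_dataset,
)
from countflux.datasets import read_proxy
from countflux.exceptions import CoverageError, SchemaError, ValidationError


def make_dataset(start=300, n=10, conflicts=None, monuments=None):
    years = np.arange(start, start + n)
    return TimeSeriesDataset(
        years=years,
        conflicts=conflicts if conflicts is not None else np.zeros(n, int),
        monuments=monuments if monuments is not None else np.ones(n, int),
        covariates=pd.DataFrame(
            {"temperature": np.linspace(0, 1, n), "rainfall": np.zeros(n)}
        ),
    )


class TestDatasetValidation:
    def test_year_gap_is_reported_with_missing_years(self):
        with pytest.raises(ValidationError, match="303"):
            TimeSeriesDataset(
                years=[301, 302, 304],
                conflicts=[0, 0, 0],
                monuments=[1, 1, 1],
                covariates=pd.DataFrame({"temperature": [0.0, 0.0, 0.0]}),
            )

    def test_duplicate_year_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            TimeSeriesDataset(
                years=[301, 301, 302],
                conflicts=[0, 0, 0],
                monuments=[1, 1, 1],
                covariates=pd.DataFrame({"temperature": [0.0, 0.0, 0.0]}),
            )

    @pytest.mark.parametrize("bad", [[-1, 0, 0], [0.5, 0, 0]])
    def test_counts_must_be_nonnegative_integers(self, bad):
        with pytest.raises(ValidationError):
            TimeSeriesDataset(
                years=[1, 2, 3],
                conflicts=bad,
                monuments=[1, 1, 1],
                covariates=pd.DataFrame({"temperature": [0.0, 0.0, 0.0]}),
            )


class TestCsvRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        ds = make_dataset(conflicts=np.arange(10), monuments=np.arange(10) + 1)
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        assert read_dataset(path) == ds

    def test_missing_monuments_column_names_it(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"year": [1, 2], "conflicts": [0, 1]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="monuments"):
            read_dataset(path)

    def test_column_map_renames(self, tmp_path):
        ds = make_dataset()
        df = ds.to_frame().rename(columns={"conflicts": "events"})
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        assert read_dataset(path, column_map={"events": "conflicts"}) == ds

    def test_classic_period_window_has_706_rows(self):
        # 292-997 CE inclusive
        ds = make_dataset(start=292, n=706)
        assert ds.n_years == 706
        assert ds.end_year == 997


class TestAnnualizeProxy:
    def test_constant_record_gives_constant_years(self):
        rec = ProxyRecord(times=np.linspace(99.0, 106.0, 30), values=np.full(30, 2.5))
        out = annualize_proxy(rec, 100, 105)
        assert out.shape == (6,)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_linear_record_gives_midpoint_values(self):
        t = np.linspace(99.0, 106.0, 40)
        rec = ProxyRecord(times=t, values=3.0 * t - 10.0)
        out = annualize_proxy(rec, 100, 105)
        mid = 3.0 * (np.arange(100, 106) + 0.5) - 10.0
        np.testing.assert_allclose(out, mid, rtol=1e-9)

    def test_two_point_segment_average(self):
        rec = ProxyRecord(times=[200.0, 201.0], values=[1.0, 3.0])
        np.testing.assert_allclose(annualize_proxy(rec, 200, 200), [2.0], rtol=1e-12)

    def test_window_outside_record_support_raises(self):
        rec = ProxyRecord(times=[100.0, 104.0], values=[0.0, 1.0])
        with pytest.raises(CoverageError):
            annualize_proxy(rec, 100, 104)  # needs coverage through 105.0

    def test_commutes_with_adding_a_constant(self, rng):
        t = np.sort(rng.uniform(49.5, 61.0, 80))
        t[0], t[-1] = 49.5, 61.0
        v = rng.normal(size=80)
        base = annualize_proxy(ProxyRecord(t, v), 50, 60)
        shifted = annualize_proxy(ProxyRecord(t, v + 7.25), 50, 60)
        np.testing.assert_allclose(shifted, base + 7.25, atol=1e-9)

    def test_grid_refinement_converges_to_exact_integral(self, rng):
        t = np.sort(rng.uniform(49.5, 61.0, 60))
        t[0], t[-1] = 49.5, 61.0
        v = rng.normal(size=60)
        rec = ProxyRecord(t, v)
        exact = annualize_proxy(rec, 50, 60)
        errs = [
            np.max(np.abs(annualize_proxy(rec, 50, 60, points_per_year=p) - exact))
            for p in (12, 96, 768)
        ]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-6 * np.ptp(v)

    def test_read_proxy_two_column_csv(self, tmp_path):
        path = tmp_path / "p.csv"
        pd.DataFrame({"t": [1.0, 2.0], "v": [0.5, 0.7]}).to_csv(path, index=False)
        rec = read_proxy(path)
        np.testing.assert_array_equal(rec.times, [1.0, 2.0])


class TestMeanCenter:
    def test_simple_column(self):
        ds = make_dataset(n=3)
        ds.covariates["temperature"] = [1.0, 2.0, 3.0]
        out = mean_center(ds, ["temperature"])
        np.testing.assert_allclose(out.covariates["temperature"], [-1, 0, 1])
        assert out.covariate_means["temperature"] == pytest.approx(2.0)

    def test_constant_column_becomes_zero(self):
        ds = make_dataset(n=4)
        ds.covariates["rainfall"] = [5.0] * 4
        out = mean_center(ds)
        np.testing.assert_allclose(out.covariates["rainfall"], 0.0)

    def test_unknown_name_raises(self):
        with pytest.raises(ValidationError, match="humidity"):
            mean_center(make_dataset(), ["humidity"])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6),
            min_size=2,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_on_values(self, values):
        n = len(values)
        ds = TimeSeriesDataset(
            years=np.arange(n),
            conflicts=np.zeros(n, int),
            monuments=np.ones(n, int),
            covariates=pd.DataFrame({"temperature": values}),
        )
        once = mean_center(ds)
        twice = mean_center(once)
        np.testing.assert_allclose(
            twice.covariates["temperature"],
            once.covariates["temperature"],
            atol=1e-6 * (1 + np.max(np.abs(values))),
        )
        # accumulated means still point back to the original scale
        assert twice.covariate_means["temperature"] == pytest.approx(
            np.mean(values), abs=1e-6 * (1 + abs(np.mean(values)))
        )


class TestClampExposure:
    def test_raises_zero_monuments_to_floor(self):
        from countflux import clamp_exposure

        ds = make_dataset(monuments=np.array([0, 2, 0, 5, 1]), n=5)
        out = clamp_exposure(ds, 1)
        np.testing.assert_array_equal(out.monuments, [1, 2, 1, 5, 1])
        # original untouched: the rule is opt-in preprocessing
        np.testing.assert_array_equal(ds.monuments, [0, 2, 0, 5, 1])


class TestAlignWindow:
    def test_full_span_is_identity(self):
        ds = make_dataset(start=300, n=10)
        assert align_window(ds, 300, 309) == ds

    def test_wide_dataset_trims_to_706(self):
        ds = make_dataset(start=200, n=901)  # 200-1100
        out = align_window(ds, 292, 997)
        assert out.n_years == 706
        assert (out.start_year, out.end_year) == (292, 997)

    def test_partial_coverage_lists_missing_years(self):
        ds = make_dataset(start=300, n=10)
        with pytest.raises(CoverageError, match="292"):
            align_window(ds, 292, 305)
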