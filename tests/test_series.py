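"""SEC-SAXS series: traces, window bookkeeping, rolling parameters, I/O."""

import csv

import numpy as np
import pytest

from saxskit import ScatteringProfile, make_series, rolling_analysis, synthetic
from saxskit.series import (
    SERIES_CSV_COLUMNS,
    export_series_csv,
    extract,
    intensity_trace,
    load_series,
    save_series,
)
from conftest import SPHERE_RG_FACTOR


def constant_series(n_frames=10, value=4.0, n_q=25):
    q = np.linspace(0.01, 0.25, n_q)
    return make_series([
        ScatteringProfile(f"f{k}", q, np.full(n_q, value), np.ones(n_q))
        for k in range(n_frames)
    ])


@pytest.fixture(scope="module")
def elution_series():
    """Single Gaussian elution of a sphere (R = 30 A) over a flat buffer."""
    q = np.linspace(0.005, 0.25, 200)
    buffer = ScatteringProfile("buf", q, np.full_like(q, 10.0), np.zeros_like(q))
    comp = synthetic.ComponentSpec(
        synthetic.sphere_profile(30.0, 80.0, q), 50.0, 6.0)
    frames = synthetic.simulate_sec([comp], buffer, 100, noise=0.01,
                                    floor=1e-3, seed=11)
    series = make_series(frames)
    rolling_analysis(series, [(0, 14), (85, 99)], 5)
    return series, comp


class TestMakeSeries:
    def test_frames_numbered_in_order(self):
        s = constant_series(100)
        assert s.frame_numbers == list(range(100))

    def test_single_profile_rejected(self):
        q = np.linspace(0.01, 0.25, 10)
        with pytest.raises(ValueError):
            make_series([ScatteringProfile("f", q, np.ones(10), np.ones(10))])

    def test_grid_mismatch_rejected(self):
        q1 = np.linspace(0.01, 0.25, 10)
        q2 = np.linspace(0.02, 0.25, 10)
        with pytest.raises(Exception, match="grid"):
            make_series([
                ScatteringProfile("a", q1, np.ones(10), np.ones(10)),
                ScatteringProfile("b", q2, np.ones(10), np.ones(10)),
            ])


class TestIntensityTrace:
    def test_total_mean_at_q_of_constant(self):
        s = constant_series(5, value=3.0, n_q=25)
        np.testing.assert_allclose(intensity_trace(s, "total"), 75.0)
        np.testing.assert_allclose(intensity_trace(s, "mean"), 3.0)
        np.testing.assert_allclose(intensity_trace(s, "at_q", 0.1), 3.0)

    def test_at_q_requires_in_range(self):
        s = constant_series(5)
        with pytest.raises(ValueError, match="outside"):
            intensity_trace(s, "at_q", 0.5)

    def test_at_q_nearest_tie_lower(self):
        q = np.array([1.0, 3.0])  # exact float tie at q_value = 2.0
        s = make_series([
            ScatteringProfile("a", q, np.array([1.0, 2.0]), np.ones(2)),
            ScatteringProfile("b", q, np.array([1.0, 2.0]), np.ones(2)),
        ])
        np.testing.assert_array_equal(intensity_trace(s, "at_q", 2.0), [1.0, 1.0])


class TestWindowBookkeeping:
    def test_window5_stepping_pattern(self):
        """A 5-frame window steps over frames 1-5, 2-6, 3-7 ... (1-based)."""
        n, w = 10, 5
        starts = list(range(0, n - w + 1))
        one_based = [(s + 1, s + w) for s in starts]
        assert one_based[:3] == [(1, 5), (2, 6), (3, 7)]
        assert len(starts) == n - w + 1

    def test_record_count_and_centers(self):
        s = constant_series(100)
        rolling_analysis(s, [(0, 9)], 5)
        placed = [f for f, r in enumerate(s.results) if r is not None]
        assert len(placed) == 100 - 5 + 1
        assert placed[0] == 0 + 5 // 2 == 2
        assert placed[-1] == 95 + 5 // 2 == 97

    def test_window_larger_than_series_rejected(self):
        s = constant_series(10)
        with pytest.raises(ValueError, match="window"):
            rolling_analysis(s, [(0, 2)], 11)

    def test_overlapping_buffer_ranges_rejected(self):
        s = constant_series(10)
        with pytest.raises(ValueError, match="verlap"):
            rolling_analysis(s, [(0, 3), (2, 5)], 2)


class TestRollingAnalysis:
    def test_peak_rg_recovered(self, elution_series):
        series, comp = elution_series
        rec = series.results[int(comp.elution_center)]
        assert rec is not None and rec["valid"]
        assert rec["rg"] == pytest.approx(30.0 * SPHERE_RG_FACTOR, rel=0.05)

    def test_rg_flat_across_peak_core(self, elution_series):
        series, comp = elution_series
        core = range(45, 56)
        rgs = [series.results[f]["rg"] for f in core
               if series.results[f] and series.results[f]["valid"]]
        assert len(rgs) >= 8
        assert (max(rgs) - min(rgs)) / np.mean(rgs) < 0.05

    def test_i0_tracks_concentration(self, elution_series):
        """The I(0) trace is proportional to the generating elution."""
        series, comp = elution_series
        frames, i0s = [], []
        for f, rec in enumerate(series.results):
            if rec is not None and rec["valid"]:
                frames.append(f)
                i0s.append(rec["i0"])
        conc = comp.concentration(np.array(frames, dtype=float))
        # correlate only where the component meaningfully elutes
        sel = conc > 0.05 * conc.max()
        corr = np.corrcoef(conc[sel], np.array(i0s)[sel])[0, 1]
        assert corr > 0.99

    def test_buffer_frames_have_no_valid_fit(self, elution_series):
        series, _ = elution_series
        rec = series.results[5]
        assert rec is None or not rec["valid"]

    def test_deterministic_rerun(self, elution_series):
        series, _ = elution_series
        import copy

        before = copy.deepcopy(series.results)
        rolling_analysis(series, series.buffer_ranges, series.window)
        for a, b in zip(before, series.results):
            if a is None:
                assert b is None
            else:
                assert a == b


class TestExtract:
    def test_single_frame(self):
        s = constant_series(10)
        out = extract(s, (3, 3), "each")
        assert len(out) == 1

    def test_average_of_identical_frames(self):
        s = constant_series(10, value=2.0)
        avg = extract(s, (2, 6), "average")
        np.testing.assert_allclose(avg.intensity, 2.0)
        assert len(avg.history.parents) == 5

    def test_uses_subtracted_when_available(self, elution_series):
        series, _ = elution_series
        out = extract(series, (50, 50), "each")[0]
        assert out.history.operation == "subtract"


class TestSeriesIO:
    def test_roundtrip(self, elution_series, tmp_path):
        series, _ = elution_series
        path = tmp_path / "series.json"
        save_series(series, path)
        back = load_series(path)
        assert len(back) == len(series)
        assert back.buffer_ranges == series.buffer_ranges
        assert back.window == series.window
        np.testing.assert_allclose(back.profiles[0].intensity,
                                   series.profiles[0].intensity)

    def test_results_restored_without_recompute(self, elution_series, tmp_path):
        series, _ = elution_series
        path = tmp_path / "series.json"
        save_series(series, path)
        back = load_series(path)
        for a, b in zip(series.results, back.results):
            if a is None:
                assert b is None
            else:
                assert b["rg"] == pytest.approx(a["rg"])

    def test_version_checked(self, tmp_path):
        import json

        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format": "saxskit-series", "version": 99}))
        with pytest.raises(ValueError, match="version"):
            load_series(path)


class TestSeriesCsv:
    def test_columns_exact(self, elution_series, tmp_path):
        series, _ = elution_series
        path = tmp_path / "series.csv"
        export_series_csv(series, path)
        with open(path) as fh:
            header = next(csv.reader(fh))
        assert header == SERIES_CSV_COLUMNS
        assert header == [
            "total_intensity", "average_intensity", "intensity_at_q",
            "frame_number", "rg", "rg_uncertainty", "mw", "i0",
            "i0_uncertainty", "filename",
        ]

    def test_one_row_per_frame(self, elution_series, tmp_path):
        series, _ = elution_series
        path = tmp_path / "series.csv"
        export_series_csv(series, path)
        assert len(path.read_text().strip().splitlines()) == len(series) + 1

    def test_absent_values_empty(self, tmp_path):
        s = constant_series(10)
        path = tmp_path / "s.csv"
        export_series_csv(s, path)
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert rows[0]["rg"] == ""
        assert rows[0]["filename"] == ""
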