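import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from apoclust import neighbor_graph as ng
from apoclust import reporter_dynamics as rd

from conftest import make_fates


class TestNucCytRatio:
    def test_basic_ratios(self):
        df = pd.DataFrame(dict(cell_id=[1, 2], nuclear=[200.0, 50.0],
                               cytoplasmic=[100.0, 50.0]))
        out, summary = rd.nuc_cyt_ratio(df)
        assert list(out["ratio"]) == [2.0, 1.0]
        assert summary["mean"].iloc[0] == pytest.approx(1.5)

    def test_nonpositive_cytoplasm_rejected(self, caplog):
        df = pd.DataFrame(dict(cell_id=[1, 2], nuclear=[200.0, 50.0],
                               cytoplasmic=[100.0, 0.0]))
        with caplog.at_level("WARNING"):
            out, _ = rd.nuc_cyt_ratio(df)
        assert len(out) == 1
        assert any("non-positive" in r.message for r in caplog.records)

    def test_noisy_population_recovers_true_ratio(self):
        rng = np.random.default_rng(0)
        cyt = np.exp(rng.normal(np.log(100), 0.1, 50))
        nuc = 1.5 * cyt * np.exp(rng.normal(0, 0.05, 50))
        df = pd.DataFrame(dict(cell_id=range(50), nuclear=nuc, cytoplasmic=cyt))
        _, summary = rd.nuc_cyt_ratio(df)
        assert abs(summary["mean"].iloc[0] - 1.5) < 3 * summary["sem"].iloc[0] + 0.01


class TestNormalizePerCell:
    def test_constant_trace_all_ones(self):
        np.testing.assert_allclose(rd.normalize_per_cell([5.0, 5.0, 5.0]), 1.0)

    def test_two_point_example(self):
        np.testing.assert_allclose(rd.normalize_per_cell([1.0, 3.0]), [0.5, 1.5])

    @given(hst.lists(hst.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_normalized_mean_is_one(self, values):
        assert rd.normalize_per_cell(values).mean() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            rd.normalize_per_cell([0.0, 0.0])


class TestDetectPulses:
    @staticmethod
    def grid(n=60):
        return np.arange(n) * 10.0

    def test_monotone_increase_no_pulses(self):
        t = self.grid()
        rec = rd.detect_pulses(t, 100 + 0.1 * t)
        assert rec.n_pulses == 0 and np.isnan(rec.mean_decrease)

    def test_clean_dip_recovered(self):
        t = self.grid()
        v = np.full(t.size, 100.0)
        dip = np.interp(t, [200, 230, 260, 290], [0, -30, -30, 0])
        rec = rd.detect_pulses(t, v + dip, min_depth=10.0)
        assert rec.n_pulses == 1
        assert rec.decreases[0] == pytest.approx(30.0, rel=0.1)
        start, end = rec.intervals[0]
        assert start <= 210 and end >= 230

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        t = self.grid()
        v = 100 + rng.normal(0, 3, t.size)
        v += np.interp(t, [200, 230, 280, 310], [0, -30, -30, 0])
        a = rd.detect_pulses(t, v)
        b = rd.detect_pulses(t, v + 500.0)
        assert a.intervals == b.intervals
        assert a.decreases == pytest.approx(b.decreases, abs=1e-9)

    def test_shallow_dip_below_threshold_ignored(self):
        t = self.grid()
        v = np.full(t.size, 100.0) + np.interp(t, [200, 230, 260, 290], [0, -4, -4, 0])
        rec = rd.detect_pulses(t, v, min_depth=10.0)
        assert rec.n_pulses == 0

    def test_short_trace_gives_no_pulses(self):
        rec = rd.detect_pulses(np.array([0.0, 10.0]), np.array([5.0, 1.0]))
        assert rec.n_pulses == 0

    def test_noise_rarely_triggers_default_threshold(self):
        rng = np.random.default_rng(2)
        t = np.arange(120) * 10.0
        n_false = sum(
            rd.detect_pulses(t, 100 + rng.normal(0, 3, t.size)).n_pulses
            for _ in range(50)
        )
        assert n_false <= 2


class TestAssignRoles:
    @staticmethod
    def star_fates(neighbor_last, movie_end=30):
        recs = [("P", 10, 0.0, 0.0)]
        for k, last in enumerate(neighbor_last):
            ang = 2 * np.pi * k / len(neighbor_last)
            recs.append((f"N{k}", last, 10 * np.cos(ang), 10 * np.sin(ang)))
        recs.append(("far", movie_end, 500.0, 500.0))
        return make_fates(recs, movie_end_frame=movie_end)

    @staticmethod
    def star_graph(fates):
        return ng.static_initial_graph(fates, max_dist_um=20.0)

    def test_all_neighbors_survive(self):
        fates = self.star_fates([30] * 6)
        roles = rd.assign_roles(fates, self.star_graph(fates), "P")
        assert roles["P"] == "primary"
        assert sum(r == "surviving_neighbor" for r in roles.values()) == 6
        assert roles["far"] == "non_neighbor"

    def test_concurrent_neighbor_is_secondary(self):
        fates = self.star_fates([10, 30, 30, 30])
        roles = rd.assign_roles(fates, self.star_graph(fates), "P")
        assert roles["N0"] == "secondary_concurrent"
        assert sum(r == "surviving_neighbor" for r in roles.values()) == 3

    def test_neighbor_dying_past_margin_is_surviving(self):
        # dies 4 frames (40 min) after the primary: outside the 1-frame margin
        fates = self.star_fates([14, 30, 30])
        roles = rd.assign_roles(fates, self.star_graph(fates), "P")
        assert roles["N0"] == "surviving_neighbor"

    def test_censored_primary_rejected(self):
        fates = self.star_fates([30])
        with pytest.raises(ValueError):
            rd.assign_roles(fates, self.star_graph(fates), "far")


class TestAlignment:
    @staticmethod
    def tracks_for(cells):
        rows = []
        for cid, (frames, values) in cells.items():
            for f, v in zip(frames, values):
                rows.append(dict(cell_id=cid, frame=f, t_min=10.0 * f,
                                 x_um=0.0, y_um=0.0, nuclear=float(v)))
        return pd.DataFrame(rows)

    def test_relative_time_and_truncation(self):
        tracks = self.tracks_for({
            "P": (range(0, 33), [100] * 33),
            "S": (range(0, 35), [90] * 35),
        })
        ev = rd.ClusterEvent(0, "P", 300.0, {"P": "primary", "S": "surviving_neighbor"})
        aligned = rd.align_to_event(tracks, "nuclear", [ev])
        prim = aligned[aligned["role"] == "primary"]
        assert prim["t_rel_min"].max() <= 0.0  # sample at +10 excluded
        assert -50.0 in set(aligned["t_rel_min"])  # t=250 -> -50
        surv = aligned[aligned["role"] == "surviving_neighbor"]
        assert surv["t_rel_min"].max() == pytest.approx(40.0)
        assert bool(surv["partial"].iloc[0])  # does not reach +60

    def test_pooled_mean_matches_hand_average(self):
        tracks = self.tracks_for({
            "A": (range(0, 31), np.full(31, 10.0)),
            "B": (range(0, 31), np.full(31, 20.0)),
            "C": (range(0, 31), np.full(31, 60.0)),
        })
        roles = {c: "surviving_neighbor" for c in "ABC"}
        ev = rd.ClusterEvent(0, "A", 200.0, roles)
        aligned = rd.align_to_event(tracks, "nuclear", [ev])
        summary = rd.pooled_summary(aligned)
        at0 = summary[(summary["t_rel_min"] == 0.0)]
        assert at0["mean"].iloc[0] == pytest.approx(30.0)
        assert at0["n"].iloc[0] == 3


class TestWindowedChange:
    def test_basic_drop(self):
        t = np.array([-50.0, -20.0])
        assert rd.windowed_change(t, np.array([100.0, 70.0])) == pytest.approx(-30.0)

    def test_flat_trace_zero(self):
        t = np.arange(-120, 0, 10.0)
        assert rd.windowed_change(t, np.full(t.size, 5.0)) == pytest.approx(0.0)

    def test_interpolates_offgrid_endpoints(self):
        t = np.array([-55.0, -45.0, -25.0, -15.0])
        v = np.array([100.0, 110.0, 80.0, 90.0])
        # value(-50) = 105 (midpoint), value(-20) = 85
        assert rd.windowed_change(t, v) == pytest.approx(-20.0)

    def test_uncovered_window_missing(self):
        t = np.array([-10.0, 0.0])
        assert np.isnan(rd.windowed_change(t, np.array([1.0, 2.0])))

    @given(hst.floats(min_value=-100, max_value=-60),
           hst.floats(min_value=-50, max_value=-10))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_antisymmetric_under_window_swap(self, ta, tb):
        t = np.arange(-120, 10, 10.0)
        rng = np.random.default_rng(0)
        v = 100 + rng.normal(0, 5, t.size)
        fwd = rd.windowed_change(t, v, (ta, tb))
        rev = rd.windowed_change(t, v, (tb, ta))
        assert fwd == pytest.approx(-rev)


class TestOptoResponse:
    def test_basic_increase(self):
        t = np.array([0.0, 60.0])
        assert rd.opto_response(t, np.array([120.0, 90.0])) == pytest.approx(30.0)

    def test_unchanged_trace_zero(self):
        t = np.arange(0, 70, 10.0)
        assert rd.opto_response(t, np.full(t.size, 7.0)) == pytest.approx(0.0)

    def test_recovers_injected_neighbor_dip(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(60):
            t = np.arange(-10, 90, 10.0)
            v = 100 + rng.normal(0, 3, t.size)
            v += np.interp(t, [20, 50, 80, 110], [0, -25, -25, 0])
            vals.append(rd.opto_response(t, v))
        assert np.mean(vals) == pytest.approx(25.0, rel=0.15)
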