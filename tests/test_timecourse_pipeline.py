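import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neemscreen as ns
from neemscreen.errors import DataError, DesignError, InsufficientDataError
from tests.conftest import make_matrix


def _raw_matrix(values_by_sample, times=None):
    n = len(next(iter(values_by_sample.values())))
    times = times or [5.0] * 99
    rows = []
    for i, sample in enumerate(values_by_sample):
        rows.append((sample, "treated", times[i], f"B{i + 1}"))
    return make_matrix(values_by_sample, rows, scale="raw")


class TestVst:
    def test_closed_form(self):
        m = _raw_matrix({"s1": [2.0 ** 10 - 1.0] * 3}, times=[5.0])
        out = ns.vst_transform(m)
        assert out.scale == "log2"
        assert np.allclose(out.values["s1"], 10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(0.01, 1e6), st.floats(0.01, 1e6)))
    def test_monotone(self, pair):
        lo, hi = sorted(pair)
        if lo == hi:
            hi = lo + 1e-6
        m = _raw_matrix({"s1": [lo, hi]}, times=[5.0])
        out = ns.vst_transform(m).values["s1"]
        assert out.iloc[0] < out.iloc[1]

    def test_constant_array_stays_constant(self):
        m = _raw_matrix({"s1": [7.0] * 5}, times=[5.0])
        out = ns.vst_transform(m).values["s1"]
        assert out.nunique() == 1

    def test_non_positive_value_names_coordinates(self):
        m = _raw_matrix({"s1": [1.0, -3.0, 2.0]}, times=[5.0])
        with pytest.raises(DataError, match="G1.*s1"):
            ns.vst_transform(m)


class TestLoess:
    def _log2_matrix(self, cols, times=None):
        m = _raw_matrix(cols, times=times or [5.0 * (i + 1) for i in range(len(cols))])
        return ns.ExpressionMatrix(values=m.values, samples=m.samples, scale="log2")

    def test_identical_arrays_unchanged(self):
        base = np.linspace(4, 14, 60)
        m = self._log2_matrix({"s1": base, "s2": base})
        out = ns.loess_normalize(m)
        assert np.allclose(out.values, m.values, atol=1e-9)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(4, 14, 200))
        m = self._log2_matrix({"s1": base, "s2": base + 1.0})
        out = ns.loess_normalize(m)
        resid = out.values["s2"] - out.values["s1"]
        assert abs(resid.mean()) < 0.01

    def test_linear_bias_flattened(self):
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(4, 14, 300))
        biased = base + 0.15 * base - 1.0  # slope 0.15 against mean intensity
        m = self._log2_matrix({"s1": base, "s2": biased})
        out = ns.loess_normalize(m)
        pseudo = out.values.mean(axis=1)
        resid = out.values["s2"] - pseudo
        slope = np.polyfit(pseudo, resid, 1)[0]
        assert abs(slope) < 0.01

    def test_too_few_genes_rejected(self):
        m = self._log2_matrix({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            ns.loess_normalize(m)


class TestBatchCorrect:
    def _matrix(self, n_genes=100, offset=1.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1, n_genes)
        cols = {}
        rows = []
        for i in range(4):
            batch = "A" if i < 2 else "B"
            shift = 0.0 if batch == "A" else offset
            cols[f"s{i}"] = base + rng.normal(0, 0.1, n_genes) + shift
            rows.append((f"s{i}", "treated", 5.0 * (i + 1), batch))
        return make_matrix(cols, rows, scale="log2")

    def test_single_batch_is_identity(self):
        m = self._matrix()
        m.samples["batch"] = "one"
        out = ns.batch_correct(m)
        assert np.allclose(out.values, m.values)

    def test_planted_offset_removed(self):
        m = self._matrix(offset=1.0)
        out = ns.batch_correct(m)
        a = out.values[["s0", "s1"]].mean(axis=1)
        b = out.values[["s2", "s3"]].mean(axis=1)
        assert abs((a - b).mean()) < 0.01

    def test_pooled_gene_mean_preserved(self):
        m = self._matrix()
        out = ns.batch_correct(m)
        assert np.allclose(out.values.mean(axis=1), m.values.mean(axis=1),
                           atol=1e-9)

    def test_singleton_batch_handling(self, caplog):
        m = self._matrix()
        m.samples.loc[m.samples.sample_id == "s3", "batch"] = "C"
        with pytest.raises(DesignError):
            ns.batch_correct(m)
        with caplog.at_level("WARNING", logger="neemscreen"):
            out = ns.batch_correct(m, allow_singleton=True)
        assert any("singleton" in r.message for r in caplog.records)
        assert np.allclose(out.values.mean(axis=1), m.values.mean(axis=1),
                           atol=1e-9)


class TestFoldChanges:
    def _design(self, treated, control, rescue=None):
        cols, rows = {}, []
        times = [5.0, 10.0, 15.0, 30.0]
        for t, vec in zip(times, np.array(treated).T):
            cols[f"tr{t}"] = vec
            rows.append((f"tr{t}", "treated", t, "B1"))
        for t, vec in zip(times, np.array(control).T):
            cols[f"ct{t}"] = vec
            rows.append((f"ct{t}", "control", t, "B1"))
        if rescue is not None:
            for t, vec in zip(times, np.array(rescue).T):
                cols[f"re{t}"] = vec
                rows.append((f"re{t}", "rescue", t, "B1"))
        return make_matrix(cols, rows, scale="log2")

    def test_identical_treated_and_control_give_unit_ratios(self):
        x = [[8.0, 9.0, 10.0, 11.0]] * 2
        profiles = ns.compute_fold_changes(self._design(x, x))
        for p in profiles:
            assert np.allclose(p.fc_treatment, 1.0)

    def test_one_log2_unit_gives_ratio_two(self):
        treated = [[9.0, 8.0, 8.0, 8.0]]
        control = [[8.0, 8.0, 8.0, 8.0]]
        [p] = ns.compute_fold_changes(self._design(treated, control))
        assert p.fc_treatment[0] == pytest.approx(2.0)
        assert np.allclose(p.fc_treatment[1:], 1.0)

    def test_replicates_averaged_on_log_scale(self):
        # three treated replicates (log2 8, 9, 10) vs control 8 -> ratio 2^1
        cols = {"t1": [8.0], "t2": [9.0], "t3": [10.0], "c1": [8.0]}
        rows = [("t1", "treated", 5.0, "B1"), ("t2", "treated", 5.0, "B2"),
                ("t3", "treated", 5.0, "B3"), ("c1", "control", 5.0, "B1")]
        m = make_matrix(cols, rows, scale="log2")
        [p] = ns.compute_fold_changes(m)
        assert p.fc_treatment[0] == pytest.approx(2.0)

    def test_missing_control_is_design_error(self):
        x = [[8.0, 9.0, 10.0, 11.0]]
        m = self._design(x, x)
        m.samples.loc[m.samples.condition == "control", "condition"] = "rescue"
        m = ns.ExpressionMatrix(values=m.values, samples=m.samples, scale="log2")
        with pytest.raises(DesignError):
            ns.compute_fold_changes(m)


def brute_force_serial(ratios, up=1.2, down=0.8, min_run=4):
    """Independent oracle: scan every window of every length >= min_run."""
    n = len(ratios)
    for width in range(n, min_run - 1, -1):
        for start in range(0, n - width + 1):
            win = ratios[start:start + width]
            if all(r > up for r in win) or all(r < down for r in win):
                return True
    return False


class TestSerialRegulation:
    def test_reference_up_run(self, profile_factory):
        p = profile_factory([1.3, 1.25, 1.4, 1.3, 1.0, 1.0, 1.0, 1.0, 1.0])
        call = ns.detect_serial_regulation(p)
        assert call.selected and call.direction == "up"
        assert call.run_start_index == 0 and call.run_length == 4

    def test_broken_run_not_selected(self, profile_factory):
        p = profile_factory([1.3, 1.3, 1.3, 1.19, 1.3, 1.3, 1.3, 1.0, 1.0])
        assert not ns.detect_serial_regulation(p).selected

    def test_boundary_values_do_not_qualify(self, profile_factory):
        p = profile_factory([1.2, 1.2, 1.2, 1.2, 1.2, 1.0, 1.0, 1.0, 1.0])
        assert not ns.detect_serial_regulation(p).selected
        p = profile_factory([0.8, 0.8, 0.8, 0.8, 0.8, 1.0, 1.0, 1.0, 1.0])
        assert not ns.detect_serial_regulation(p).selected

    def test_all_512_patterns_match_window_scan_oracle(self, profile_factory):
        for bits in itertools.product([0, 1], repeat=9):
            ratios = [1.3 if b else 1.0 for b in bits]
            call = ns.detect_serial_regulation(profile_factory(ratios))
            assert call.selected == brute_force_serial(ratios), bits

    def test_down_patterns_match_oracle(self, profile_factory):
        for bits in itertools.product([0, 1], repeat=9):
            ratios = [0.7 if b else 1.0 for b in bits]
            call = ns.detect_serial_regulation(profile_factory(ratios))
            assert call.selected == brute_force_serial(ratios), bits

    def test_invariant_to_values_outside_window(self, profile_factory):
        base = [1.3, 1.3, 1.3, 1.3, 1.0, 1.0, 1.0, 1.0, 1.0]
        ref = ns.detect_serial_regulation(profile_factory(base))
        # tails vary freely but never form a qualifying run of their own
        for tail in ([1.19] * 5, [0.5, 2.0, 1.0, 1.1, 0.9], [0.7, 0.7, 0.7, 1.3, 1.0]):
            alt = base[:4] + list(tail)
            call = ns.detect_serial_regulation(profile_factory(alt))
            assert (call.run_start_index, call.run_length >= 4) == \
                   (ref.run_start_index, True)

    def test_direction_antisymmetry_in_symmetric_bounds_mode(self, profile_factory):
        rng = np.random.default_rng(9)
        up, down = 1.2, 1 / 1.2
        for _ in range(50):
            ratios = np.exp2(rng.normal(0, 0.4, 9))
            fwd = ns.detect_serial_regulation(profile_factory(ratios),
                                              up_bound=up, down_bound=down)
            rev = ns.detect_serial_regulation(profile_factory(1.0 / ratios),
                                              up_bound=up, down_bound=down)
            assert fwd.selected == rev.selected
            swap = {"up": "down", "down": "up", "none": "none"}
            assert rev.direction == swap[fwd.direction]

    def test_rescue_reversal_flag(self, profile_factory):
        serial = [1.3] * 5 + [1.0] * 4
        reversed_p = profile_factory(serial, fc_rescue=[1.0] * 9)
        assert ns.detect_serial_regulation(reversed_p).rescue_reversed
        persistent = profile_factory(serial, fc_rescue=[1.3] * 9)
        assert not ns.detect_serial_regulation(persistent).rescue_reversed


class TestNonRescued:
    def test_constant_vector_true(self):
        assert ns.detect_non_rescued([0.5] * 10)

    def test_two_point_example(self):
        # SD of [0, 0.1] is 0.0707 > 0.01
        assert not ns.detect_non_rescued([0.0, 0.1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=2, max_size=12))
    def test_matches_direct_sd_formula(self, values):
        import statistics

        expected = statistics.stdev(values) <= 0.01
        assert ns.detect_non_rescued(values) == expected


class TestTemporalCorrelation:
    def test_strictly_increasing_is_up(self, profile_factory):
        p = profile_factory(np.exp2(np.linspace(0, 1, 9)))
        klass, r = ns.temporal_correlation(p)
        assert klass == "up" and r == pytest.approx(1.0)

    def test_strictly_decreasing_is_down(self, profile_factory):
        p = profile_factory(np.exp2(np.linspace(0, -1, 9)))
        klass, r = ns.temporal_correlation(p)
        assert klass == "down" and r == pytest.approx(-1.0)

    def test_constant_profile_is_none_with_nan(self, profile_factory):
        klass, r = ns.temporal_correlation(profile_factory([1.0] * 9))
        assert klass == "none" and np.isnan(r)


class TestPathwayTrajectories:
    def test_single_gene_set_is_identity(self, profile_factory):
        p = profile_factory([1.5, 2.0, 1.0, 0.5], gene="A")
        gs = ns.PathwayGeneSet("SOLO", "d", frozenset({"A"}))
        summary = ns.pathway_trajectory_summary([p], [gs])
        assert np.allclose(summary.trajectories.loc[("SOLO", "treatment")],
                           p.log2fc_treatment)

    def test_opposite_genes_cancel(self, profile_factory):
        a = profile_factory([2.0] * 4, gene="A")
        b = profile_factory([0.5] * 4, gene="B")
        gs = ns.PathwayGeneSet("PAIR", "d", frozenset({"A", "B"}))
        summary = ns.pathway_trajectory_summary([a, b], [gs])
        assert np.allclose(summary.trajectories.loc[("PAIR", "treatment")], 0.0)
        assert summary.max_abs_log2fc["PAIR"] == pytest.approx(0.0)

    def test_planted_pathway_max_recovered(self):
        """A pathway whose members peak at mean log2 ratio 0.75 reports that max."""
        rng = np.random.default_rng(21)
        profiles = []
        peak = np.array([0.1, 0.2, 0.4, 0.6, 0.75, 0.7, 0.5, 0.3, 0.1])
        for i in range(6):
            jitter = rng.normal(0, 0.01, 9)
            profiles.append(ns.TimecourseProfile(
                gene=f"J{i}", fc_treatment=np.exp2(peak + jitter),
                fc_rescue=np.empty(0)))
        gs = ns.PathwayGeneSet("JAKSTAT_LIKE", "d",
                               frozenset(p.gene for p in profiles))
        summary = ns.pathway_trajectory_summary(profiles, [gs])
        assert summary.max_abs_log2fc["JAKSTAT_LIKE"] == pytest.approx(0.75, abs=0.02)

    def test_empty_intersection_skipped_with_warning(self, profile_factory, caplog):
        p = profile_factory([1.0] * 4, gene="A")
        gs = ns.PathwayGeneSet("GHOSTS", "d", frozenset({"X", "Y"}))
        with caplog.at_level("WARNING", logger="neemscreen"):
            summary = ns.pathway_trajectory_summary([p], [gs])
        assert summary.trajectories.empty
        assert any("skipped" in r.message for r in caplog.records)


class TestRunTimecourse:
    def test_raw_matrix_end_to_end(self, tmp_path):
        truth = ns.make_planted_timecourse_truth(5, 5, 2, 0, 0)
        m = ns.simulate_timecourse_matrix(truth, 200, seed=6)
        raw = ns.ExpressionMatrix(values=np.exp2(m.values), samples=m.samples,
                                  scale="raw")
        result = ns.run_timecourse(raw, ns.example_gene_sets(),
                                   out_dir=tmp_path, make_plot=False)
        selected = {c.gene for c in result["calls"] if c.selected}
        planted = truth.serial_up_genes | truth.serial_down_genes
        assert len(selected & planted) >= 9
        assert (tmp_path / "serial_calls.tsv").exists()
        assert (tmp_path / "fold_changes.tsv").exists()
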