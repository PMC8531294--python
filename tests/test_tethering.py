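"""Rupture extraction, thresholds, density maps, masks, classification."""

import numpy as np
import pytest

from stembond.forcecurve import Segment
from stembond.synth import gen_retract_curve
from stembond.tethering import (
    DensityGrid,
    EventSet,
    RuptureEvent,
    SignificanceMask,
    TetherSignificanceClassifier,
    Thresholds,
    classify_events,
    control_thresholds,
    density_map,
    extract_rupture,
    make_grid_edges,
    significant_mask,
    summarize_tethering,
)

from conftest import make_event_set


class TestExtractRupture:
    def test_single_planted_dip_roundtrip(self):
        seg = gen_retract_curve([(120.0, 80.0)], spring_constant=0.05, n_points=2000)
        event = extract_rupture(seg, 0.05, min_force_pN=20.0)
        assert event is not None
        assert event.rupture_force_pN == pytest.approx(120.0, rel=5e-3)
        assert event.rupture_length_nm == pytest.approx(80.0, rel=5e-3)

    def test_two_dips_keeps_global_minimum(self):
        seg = gen_retract_curve([(60.0, 30.0), (140.0, 90.0)], spring_constant=0.05, n_points=4000)
        event = extract_rupture(seg, 0.05, min_force_pN=20.0)
        # brute-force oracle: deepest sampled force and its separation
        i_min = int(np.argmin(seg.force_pN))
        deepest = -seg.force_pN[i_min]
        assert event.rupture_force_pN == pytest.approx(deepest)
        assert event.rupture_force_pN == pytest.approx(140.0, rel=5e-3)
        assert event.rupture_length_nm == pytest.approx(90.0, rel=5e-3)

    def test_noise_only_returns_none(self, rng):
        z = np.linspace(300.0, 1.0, 400)
        seg = Segment("retract", z, rng.normal(0, 5, 400))
        assert extract_rupture(seg, 0.05, min_force_pN=20.0) is None

    def test_uncorrected_baseline_rejected(self):
        z = np.linspace(300.0, 1.0, 400)
        seg = Segment("retract", z, np.full(400, 50.0))
        with pytest.raises(ValueError, match="baseline"):
            extract_rupture(seg, 0.05)


class TestControlThresholds:
    def test_odd_n_median(self):
        control = make_event_set(
            [10, 20, 30, 40, 50], [1, 2, 3, 4, 5], probe="anti_IgG"
        )
        thr = control_thresholds(control)
        assert thr.force_threshold_pN == 30.0
        assert thr.length_threshold_nm == 3.0

    def test_even_n_median_is_midpoint(self):
        control = make_event_set([10, 20], [5, 15], probe="anti_IgG")
        assert control_thresholds(control).length_threshold_nm == 10.0

    def test_requires_control_probe_and_events(self):
        sample = make_event_set([10], [5], probe="anti_FN")
        with pytest.raises(ValueError, match="anti_IgG"):
            control_thresholds(sample)
        empty = EventSet(events=(), sample_id="c", probe="anti_IgG", substrate="x")
        with pytest.raises(ValueError, match="pool"):
            control_thresholds(empty)


class TestDensityMap:
    def test_all_mass_in_one_bin(self):
        events = make_event_set([100.0] * 4, [50.0] * 4)
        thr = Thresholds(0.0, 0.0)
        grid = density_map(events, thr, np.array([40.0, 60.0, 80.0]), np.array([1.9, 2.1, 2.3]))
        np.testing.assert_array_equal(grid.density, [[1.0, 0.0], [0.0, 0.0]])
        assert grid.n_events == 4

    def test_nothing_retained_gives_zero_grid(self):
        events = make_event_set([10.0], [5.0])
        thr = Thresholds(50.0, 50.0)
        grid = density_map(events, thr, np.linspace(0, 100, 4), np.linspace(0, 3, 4))
        assert grid.density.sum() == 0.0
        assert grid.n_events == 0

    def test_uniform_binomial_sampling(self, rng):
        """Per-bin density of uniform events matches binomial expectation."""
        n = 10_000
        lengths = rng.uniform(0.0, 10.0, n)
        log_forces = rng.uniform(1.0, 2.0, n)
        events = make_event_set(10.0**log_forces, lengths)
        thr = Thresholds(0.0, 0.0)
        grid = density_map(
            events, thr, np.linspace(0.0, 10.0, 11), np.linspace(1.0, 2.0 + 1e-9, 11)
        )
        p = 0.01
        sigma = np.sqrt(p * (1 - p) / n)
        z = np.abs(grid.density - p) / sigma
        # per-bin binomial error: nearly all of the 100 bins within 3 sigma,
        # none wildly off
        assert (z < 3).mean() >= 0.95
        assert z.max() < 5
        assert grid.density.sum() == pytest.approx(1.0, abs=1e-9)

    def test_density_sums_to_one(self, lognormal_events):
        events = lognormal_events(300, "anti_FN")
        thr = Thresholds(30.0, 15.0)
        le, fe = make_grid_edges([events], thr)
        grid = density_map(events, thr, le, fe)
        assert grid.density.sum() == pytest.approx(1.0, abs=1e-9)


def median_filter_oracle(raw: np.ndarray, k: int = 3) -> np.ndarray:
    """Majority vote over the k x k neighbourhood, False-padded, naive loops."""
    pad = k // 2
    padded = np.zeros((raw.shape[0] + 2 * pad, raw.shape[1] + 2 * pad), dtype=bool)
    padded[pad:-pad, pad:-pad] = raw
    out = np.zeros_like(raw, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            window = padded[i : i + k, j : j + k]
            out[i, j] = window.sum() > (k * k) // 2
    return out


class TestSignificantMask:
    @staticmethod
    def _grid(density, n_events):
        density = np.asarray(density, dtype=float)
        nr, nc = density.shape
        return DensityGrid(
            np.arange(nr + 1.0), np.arange(nc + 1.0), density, n_events=n_events
        )

    def test_identical_sample_and_control_all_false(self, lognormal_events):
        events = lognormal_events(400, "anti_FN")
        thr = Thresholds(0.0, 0.0)
        le, fe = make_grid_edges([events], thr)
        grid = density_map(events, thr, le, fe)
        mask = significant_mask(grid, grid)
        assert not mask.mask.any()

    def test_block_above_ratio_survives_filter(self):
        control = np.full((9, 9), 1.0 / 81.0)
        sample = np.full((9, 9), 0.5 / 81.0)
        sample[3:6, 3:6] = 3.0 / 81.0  # 3x control in a 3x3 block
        sample /= sample.sum()
        sg = self._grid(sample, 810)
        cg = self._grid(control, 810)
        mask = significant_mask(sg, cg, ratio=2.0, kernel_size=3)
        expected_raw = sg.density > 2.0 * cg.density
        np.testing.assert_array_equal(mask.mask, median_filter_oracle(expected_raw))
        assert mask.mask[4, 4]

    def test_isolated_bin_removed(self):
        control = np.zeros((7, 7))
        control[0, 0] = 1.0
        sample = np.zeros((7, 7))
        sample[3, 3] = 0.5
        sample[0, 0] = 0.5
        mask = significant_mask(self._grid(sample, 100), self._grid(control, 100))
        assert not mask.mask.any()

    def test_matches_majority_vote_oracle_on_random_grids(self, rng):
        """scipy median filter equals the naive majority-vote oracle."""
        for _ in range(20):
            control = rng.random((12, 12))
            control[rng.random((12, 12)) < 0.3] = 0.0
            control /= control.sum()
            sample = rng.random((12, 12))
            sample /= sample.sum()
            sg = self._grid(sample, 500)
            cg = self._grid(control, 400)
            raw = np.where(
                cg.density > 0,
                sg.density > 2.0 * cg.density,
                sg.density > 2.0 / cg.n_events,
            )
            raw &= sg.density > 1.0 / sg.n_events
            mask = significant_mask(sg, cg, ratio=2.0, kernel_size=3)
            np.testing.assert_array_equal(mask.mask, median_filter_oracle(raw))

    def test_mismatched_grids_rejected(self):
        a = self._grid(np.ones((3, 3)) / 9.0, 9)
        b = DensityGrid(np.arange(5.0), np.arange(4.0), np.ones((4, 3)) / 12.0, 12)
        with pytest.raises(ValueError, match="grids"):
            significant_mask(a, b)


class TestClassifyEvents:
    def _setup(self, rng):
        events = make_event_set(
            rng.lognormal(np.log(100), 0.3, 200), rng.lognormal(np.log(50), 0.3, 200)
        )
        thr = Thresholds(20.0, 10.0)
        le, fe = make_grid_edges([events], thr)
        return events, thr, le, fe

    def test_all_false_mask_empty_subset(self, rng):
        events, thr, le, fe = self._setup(rng)
        mask = SignificanceMask(np.zeros((30, 30), dtype=bool))
        subset, n_out = classify_events(events, thr, mask, le, fe)
        assert len(subset) == 0

    def test_all_true_mask_keeps_threshold_passers(self, rng):
        events, thr, le, fe = self._setup(rng)
        mask = SignificanceMask(np.ones((30, 30), dtype=bool))
        subset, n_out = classify_events(events, thr, mask, le, fe)
        expected = sum(
            1
            for e in events.events
            if e.rupture_force_pN > thr.force_threshold_pN
            and e.rupture_length_nm > thr.length_threshold_nm
        )
        assert len(subset) + n_out == expected
        assert n_out == 0  # grid spans the events by construction

    def test_outside_grid_counted_not_classified(self):
        events = make_event_set([100.0, 5000.0], [50.0, 900.0])
        thr = Thresholds(0.0, 0.0)
        le = np.linspace(0.0, 100.0, 4)
        fe = np.linspace(1.0, 3.0, 4)
        mask = SignificanceMask(np.ones((3, 3), dtype=bool))
        subset, n_out = classify_events(events, thr, mask, le, fe)
        assert len(subset) == 1
        assert n_out == 1

    def test_matches_rebinning_oracle(self, rng):
        """Bin lookup equals an independent digitize-based oracle."""
        events, thr, le, fe = self._setup(rng)
        mask_arr = rng.random((30, 30)) < 0.4
        mask = SignificanceMask(mask_arr)
        subset, _ = classify_events(events, thr, mask, le, fe)
        kept = {e.curve_id for e in subset.events}
        for e in events.events:
            if not (
                e.rupture_force_pN > thr.force_threshold_pN
                and e.rupture_length_nm > thr.length_threshold_nm
            ):
                assert e.curve_id not in kept
                continue
            i = np.digitize(e.rupture_length_nm, le) - 1
            j = np.digitize(np.log10(e.rupture_force_pN), fe) - 1
            inside = 0 <= i < 30 and 0 <= j < 30
            assert (e.curve_id in kept) == (inside and bool(mask_arr[i, j]))


class TestSummarizeTethering:
    def test_mean_of_sample_means_and_sem(self):
        sets = [
            make_event_set([10 ** 2.0] * 3, [50] * 3, sample_id="s1"),
            make_event_set([10 ** 2.2] * 3, [50] * 3, sample_id="s2"),
            make_event_set([10 ** 2.4] * 3, [50] * 3, sample_id="s3"),
        ]
        summary = summarize_tethering(sets)
        assert summary.overall_mean_log10_force == pytest.approx(2.2)
        assert summary.sem_log10_force == pytest.approx(0.2 / np.sqrt(3), rel=1e-6)
        assert summary.n_samples == 3

    def test_single_sample_sem_zero(self):
        summary = summarize_tethering([make_event_set([100.0], [50.0], sample_id="s1")])
        assert summary.sem_log10_force == 0.0
        assert summary.n_samples == 1

    def test_all_empty_is_no_significant_binding(self):
        sets = [
            EventSet(events=(), sample_id=f"s{i}", probe="anti_FN", substrate="stiff")
            for i in range(3)
        ]
        summary = summarize_tethering(sets)
        assert summary.no_significant_binding
        assert summary.overall_mean_log10_force is None
        assert summary.empty_sample_ids == ("s1", "s2", "s3") or set(
            summary.empty_sample_ids
        ) == {"s0", "s1", "s2"}


class TestClassifierEstimator:
    def test_null_false_positive_rate_small(self, lognormal_events):
        clf = TetherSignificanceClassifier()
        control = lognormal_events(500, "anti_IgG", "c")
        sample = lognormal_events(500, "anti_FN", "s")
        flags = clf.fit(control).predict(sample)
        assert flags.mean() <= 0.05

    def test_power_monotone_in_force_scale(self):
        """Stronger planted specific forces -> more significant events and
        higher mean log10 force of the significant subset (averaged over
        replicate draws to beat Monte-Carlo noise)."""
        fractions = []
        mean_logf = []
        for scale in [40.0, 80.0, 160.0, 320.0]:
            frac_reps = []
            logf_reps = []
            for rep in range(5):
                rng = np.random.default_rng(1000 * rep + int(scale))
                control = make_event_set(
                    rng.lognormal(np.log(30), 0.8, 600),
                    rng.lognormal(np.log(15), 0.8, 600),
                    probe="anti_IgG",
                )
                # lengths match the control population, so the planted
                # events emerge from the control cloud along force only
                f = np.concatenate(
                    [
                        rng.lognormal(np.log(scale), 0.3, 400),
                        rng.lognormal(np.log(30), 0.8, 100),
                    ]
                )
                lengths = rng.lognormal(np.log(15), 0.8, 500)
                sample = make_event_set(f, lengths)
                clf = TetherSignificanceClassifier().fit(control)
                flags = clf.predict(sample)
                frac_reps.append(flags.mean())
                if flags.any():
                    logf_reps.append(np.log10(f[flags]).mean())
            fractions.append(np.mean(frac_reps))
            mean_logf.append(np.mean(logf_reps))
        assert (np.diff(fractions) > 0).all()
        assert (np.diff(mean_logf) > 0).all()

    def test_params_roundtrip(self):
        clf = TetherSignificanceClassifier(ratio=3.0, n_bins=20)
        clone = TetherSignificanceClassifier(**clf.get_params())
        assert clone.get_params() == clf.get_params()

    def test_predict_requires_fit(self, lognormal_events):
        clf = TetherSignificanceClassifier()
        with pytest.raises(ValueError, match="not fitted"):
            clf.predict(lognormal_events(10, "anti_FN"))
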