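"""AOI assignment, gap-tolerant binning, the 100 ms filter and QC rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazebias.design import TrialSpec
from gazebias.preproc import (
    PreprocError,
    QcThresholds,
    assign_aoi,
    bin_samples,
    compute_trial_dwell,
    default_geometry,
    filter_bins,
    preprocess_dataset,
    qc_exclude,
)

GEOM = default_geometry()
PERIOD = 1000.0 / 60.0


def _samples(t_ms, x, y, valid=None):
    n = len(t_ms)
    return pd.DataFrame(
        {
            "subject_id": ["s1"] * n,
            "trial_id": [1] * n,
            "t_ms": np.asarray(t_ms, dtype=float),
            "x_px": np.asarray(x, dtype=float),
            "y_px": np.asarray(y, dtype=float),
            "valid": valid if valid is not None else [True] * n,
        }
    )


LEFT_X, LEFT_Y = 320.0, 512.0  # centroid of the left AOI
RIGHT_X, RIGHT_Y = 960.0, 512.0
CENTER_X, CENTER_Y = 640.0, 512.0


class TestAssignAoi:
    def test_center_fixation_is_none(self):
        assert assign_aoi(CENTER_X, CENTER_Y, GEOM) == "none"

    def test_left_centroid(self):
        assert assign_aoi(LEFT_X, LEFT_Y, GEOM) == "left"

    def test_invalid_sample_is_none(self):
        assert assign_aoi(LEFT_X, LEFT_Y, GEOM, valid=False) == "none"

    def test_half_open_boundary(self):
        """Low edges belong to the rectangle, high edges do not; verified
        against a brute-force point-in-rect check."""
        x0, y0, x1, y1 = GEOM.right_rect
        assert assign_aoi(x0, (y0 + y1) / 2, GEOM) == "right"
        assert assign_aoi(x1, (y0 + y1) / 2, GEOM) == "none"
        assert assign_aoi((x0 + x1) / 2, y1, GEOM) == "none"

        def brute(x, y, rect):
            return rect[0] <= x < rect[2] and rect[1] <= y < rect[3]

        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.uniform(0, 1280)
            y = rng.uniform(0, 1024)
            expected = (
                "left" if brute(x, y, GEOM.left_rect) else "right" if brute(x, y, GEOM.right_rect) else "none"
            )
            assert assign_aoi(x, y, GEOM) == expected


class TestBinSamples:
    def test_gap_splits_hand_trace(self):
        """Left samples at 0/17/33/100 ms split into {0..33} and {100}."""
        df = _samples([0, 17, 33, 100], [LEFT_X] * 4, [LEFT_Y] * 4)
        bins = bin_samples(df)
        assert len(bins) == 2
        assert (bins[0].t_start_ms, bins[0].t_end_ms, bins[0].n_samples) == (0.0, 33.0, 3)
        assert (bins[1].t_start_ms, bins[1].t_end_ms, bins[1].n_samples) == (100.0, 100.0, 1)

    def test_aoi_change_always_splits(self):
        n = 20
        x = [LEFT_X if i % 2 == 0 else RIGHT_X for i in range(n)]
        df = _samples(np.arange(n) * PERIOD, x, [LEFT_Y] * n)
        bins = bin_samples(df)
        assert len(bins) == n
        assert all(b.n_samples == 1 for b in bins)

    def test_unbroken_run_single_bin(self):
        n = 600
        df = _samples(np.arange(n) * PERIOD, [LEFT_X] * n, [LEFT_Y] * n)
        bins = bin_samples(df)
        assert len(bins) == 1
        assert bins[0].duration_ms == pytest.approx(599 * PERIOD, abs=1e-6)
        assert bins[0].n_samples == 600

    def test_off_aoi_terminates_bin(self):
        df = _samples([0, 17, 33, 50], [LEFT_X, LEFT_X, CENTER_X, LEFT_X], [LEFT_Y] * 4)
        bins = bin_samples(df)
        assert [b.n_samples for b in bins] == [2, 1]

    def test_unsorted_raises(self):
        df = _samples([0, 33, 17], [LEFT_X] * 3, [LEFT_Y] * 3)
        with pytest.raises(PreprocError, match="sorted"):
            bin_samples(df)

    @given(
        mask=st.lists(st.booleans(), min_size=2, max_size=120),
        aois=st.lists(st.sampled_from([0, 1, 2]), min_size=120, max_size=120),
        gap=st.sampled_from([33.0, 66.0, 133.0]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_and_conservation(self, mask, aois, gap):
        """Every in-AOI sample lands in exactly one bin; dwell never exceeds
        the span; counted samples x nominal period bounds binned dwell."""
        keep = np.array(mask + [True] * (120 - len(mask)))
        t = (np.arange(120) * PERIOD)[keep]
        code = np.array(aois)[keep]
        xmap = {0: CENTER_X, 1: LEFT_X, 2: RIGHT_X}
        df = _samples(t, [xmap[c] for c in code], [LEFT_Y] * keep.sum())
        bins = bin_samples(df, QcThresholds(gap_ms=gap))
        assert sum(b.n_samples for b in bins) == int((code != 0).sum())
        total = sum(b.duration_ms for b in bins)
        assert total <= t[-1] - t[0] + 1e-9
        assert total <= (code != 0).sum() * PERIOD + 1e-9  # grid-timed upper bound

    @given(
        mask=st.lists(st.booleans(), min_size=2, max_size=120),
        aois=st.lists(st.sampled_from([0, 1, 2]), min_size=120, max_size=120),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dialect_monotonicity(self, mask, aois):
        """Raising gap_ms never increases bin count nor total binned dwell loss."""
        keep = np.array(mask + [True] * (120 - len(mask)))
        t = (np.arange(120) * PERIOD)[keep]
        code = np.array(aois)[keep]
        xmap = {0: CENTER_X, 1: LEFT_X, 2: RIGHT_X}
        df = _samples(t, [xmap[c] for c in code], [LEFT_Y] * keep.sum())
        prev_bins, prev_total = None, None
        for gap in (33.0, 66.0, 133.0):
            bins = bin_samples(df, QcThresholds(gap_ms=gap))
            total = sum(b.duration_ms for b in bins)
            if prev_bins is not None:
                assert len(bins) <= prev_bins
                assert total >= prev_total - 1e-9
            prev_bins, prev_total = len(bins), total


class TestFilterBins:
    def test_boundary_cases(self):
        short = bin_samples(_samples([0, 17, 33], [LEFT_X] * 3, [LEFT_Y] * 3))
        assert filter_bins(short) == []
        n = 7  # 0..100 ms inclusive
        exact = bin_samples(_samples(np.arange(n) * PERIOD, [LEFT_X] * n, [LEFT_Y] * n))
        assert exact[0].duration_ms == pytest.approx(100.0, abs=1e-9)
        assert len(filter_bins(exact)) == 1
        assert filter_bins([]) == []


class TestComputeTrialDwell:
    TRIAL = TrialSpec(1, "positive-neutral", "a", "b", "left")

    def test_single_bin_arithmetic(self):
        t = np.concatenate([[0.0], np.arange(500.0, 7300.0 + 1, PERIOD)])
        df = _samples(t, [CENTER_X] + [LEFT_X] * (len(t) - 1), [CENTER_Y] + [LEFT_Y] * (len(t) - 1))
        td = compute_trial_dwell(df, self.TRIAL)
        assert td.dwell_emotional_ms == pytest.approx(t[-1] - 500.0, abs=1e-6)  # ~6800 ms
        assert td.dwell_neutral_ms == 0.0
        assert td.first_saccade_latency_ms == 500.0
        assert not td.start_in_aoi

    def test_all_off_aoi(self):
        df = _samples(np.arange(10) * PERIOD, [CENTER_X] * 10, [CENTER_Y] * 10)
        td = compute_trial_dwell(df, self.TRIAL)
        assert td.dwell_left_ms == td.dwell_right_ms == 0.0
        assert td.first_saccade_latency_ms is None

    def test_zero_samples(self):
        td = compute_trial_dwell(_samples([], [], []), self.TRIAL, subject_id="s1")
        assert td.n_samples_total == 0
        assert td.dwell_left_ms == 0.0

    def test_start_in_aoi_flag(self):
        df = _samples([0, 17], [LEFT_X, CENTER_X], [LEFT_Y, CENTER_Y])
        assert compute_trial_dwell(df, self.TRIAL).start_in_aoi

    def test_invalid_samples_excluded_from_count_by_default(self):
        df = _samples([0, 17, 33], [CENTER_X] * 3, [CENTER_Y] * 3, valid=[True, False, True])
        td = compute_trial_dwell(df, self.TRIAL)
        assert td.n_samples_total == 2
        thr = QcThresholds(count_invalid_samples=True)
        assert compute_trial_dwell(df, self.TRIAL, thresholds=thr).n_samples_total == 3

    def test_sample_count_upper_bound_oracle(self, rng):
        """Brute-force in-AOI sample count x period bounds the binned dwell."""
        for _ in range(25):
            keep = rng.random(600) > 0.2
            code = rng.integers(0, 3, 600)[keep]
            t = (np.arange(600) * PERIOD)[keep]
            xmap = {0: CENTER_X, 1: LEFT_X, 2: RIGHT_X}
            df = _samples(t, [xmap[c] for c in code], [LEFT_Y] * keep.sum())
            td = compute_trial_dwell(df, self.TRIAL)
            assert td.dwell_left_ms + td.dwell_right_ms <= (code != 0).sum() * PERIOD + 1e-9


def _dwell_row(subj, trial, latency, n_samples, start=False):
    return {
        "subject_id": subj,
        "trial_id": trial,
        "condition": "positive-neutral",
        "emotional_side": "left",
        "dwell_left_ms": 1000.0,
        "dwell_right_ms": 1000.0,
        "dwell_emotional_ms": 1000.0,
        "dwell_neutral_ms": 1000.0,
        "first_saccade_latency_ms": latency,
        "n_samples_total": n_samples,
        "start_in_aoi": start,
    }


class TestQcExclude:
    def test_threshold_arithmetic_on_planted_cohort(self):
        """Cohort mean 310 / SD 250 puts the limit at 1060 ms: a 1200 ms trial
        is excluded, a 900 ms one kept."""
        rng = np.random.default_rng(1)
        lat = list(310.0 + 250.0 * np.array([-1, 1] * 50))  # mean 310, sd ~251.3
        rows = [_dwell_row("s", i + 1, l, 600) for i, l in enumerate(lat)]
        rows.append(_dwell_row("probe", 1, 1200.0, 600))
        rows.append(_dwell_row("probe", 2, 900.0, 600))
        df = pd.DataFrame(rows)
        result = qc_exclude(df)
        limit = result.cohort_stats["latency_limit_ms"]
        assert 1050 < limit < 1150  # ~1060 from the planted stats, nudged by the probes
        excluded = set(zip(result.excluded_trials["subject_id"], result.excluded_trials["trial_id"]))
        assert ("probe", 1) in excluded
        assert ("probe", 2) not in excluded

    def test_subject_excluded_at_full_loss(self):
        rows = [_dwell_row("bad", i + 1, 300.0, 600, start=True) for i in range(48)]
        rows += [_dwell_row(f"ok{j}", i + 1, 300.0 + (i % 5), 600) for j in range(3) for i in range(48)]
        result = qc_exclude(pd.DataFrame(rows))
        assert result.excluded_subjects == ["bad"]
        assert "bad" not in set(result.kept["subject_id"])

    def test_zero_variance_disables_criterion(self):
        rows = [_dwell_row("s", i + 1, 300.0, 600) for i in range(10)]
        result = qc_exclude(pd.DataFrame(rows))
        assert len(result.excluded_trials) == 0

    def test_needs_two_defined_latencies(self):
        rows = [_dwell_row("s", 1, 300.0, 600), _dwell_row("s", 2, np.nan, 600)]
        with pytest.raises(PreprocError):
            qc_exclude(pd.DataFrame(rows))

    def test_artifact_free_cohort_no_start_flags(self):
        from gazebias.synth import simulate_dataset

        ds = simulate_dataset(n_control=3, n_mdd=0, seed=8)
        dwell = preprocess_dataset(ds.samples, ds.trials)
        assert not dwell["start_in_aoi"].any()

    def test_injected_artifacts_all_flagged(self, study, study_dwell, study_qc):
        """Every manifest trial is excluded; QC ground truth is exact."""
        excluded = set(zip(study_qc.excluded_trials["subject_id"], study_qc.excluded_trials["trial_id"]))
        for row in study.manifest.itertuples(index=False):
            assert (row.subject_id, row.trial_id) in excluded
        # and no clean trial carries the start_in_aoi flag
        manifest_keys = set(
            zip(
                study.manifest.loc[study.manifest["artifact"] == "start_in_aoi", "subject_id"],
                study.manifest.loc[study.manifest["artifact"] == "start_in_aoi", "trial_id"],
            )
        )
        flagged = study_dwell.loc[study_dwell["start_in_aoi"]]
        assert set(zip(flagged["subject_id"], flagged["trial_id"])) == manifest_keys
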