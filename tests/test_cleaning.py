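"""Cleaning rules: non-wear consolidation (with a brute-force interval
oracle), wake-window restriction, and the 6-hour valid-day rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import actiflux as af
from actiflux.kinds import ActivityKind

NW = ActivityKind.non_wear.value
SIT = ActivityKind.sitting.value
WALK = ActivityKind.walk_slow.value
EPM = 24  # 2.5 s epochs per minute


def epochs_of(labels, epoch_s=2.5, start="2013-04-08 00:00:00", child="c"):
    return af.LabeledEpochs(child, start, np.asarray(labels, dtype=np.int8),
                            epoch_s=epoch_s)


def oracle_consolidate(labels, win_ep, tol_ep):
    """Brute-force rule: enumerate every epoch interval, merge the union
    of qualifying ones, then re-classify short non-wear runs."""
    labels = np.asarray(labels)
    n = len(labels)
    isnw = labels == NW
    mark = np.zeros(n, bool)
    for i in range(n):
        for j in range(i, n):
            if not (isnw[i] and isnw[j]):
                continue
            seg = isnw[i:j + 1]
            bursts, cur = [], 0
            for v in seg:
                if not v:
                    cur += 1
                elif cur:
                    bursts.append(cur)
                    cur = 0
            if cur:
                bursts.append(cur)
            if bursts and max(bursts) > tol_ep:
                continue
            if sum(bursts) > tol_ep:
                continue
            if seg.sum() >= win_ep:
                mark[i:j + 1] = True
    out = labels.copy()
    out[mark] = NW
    i = 0
    while i < n:
        if out[i] == NW:
            j = i
            while j < n and out[j] == NW:
                j += 1
            if j - i < win_ep:
                out[i:j] = SIT
            i = j
        else:
            i += 1
    return out


class TestConsolidation:
    def test_embedded_burst_becomes_nonwear(self):
        # 70 min of non-wear interrupted by a 4 min walking burst: the
        # whole 74 min block is spurious-activity-free non-wear
        lab = np.concatenate([
            np.full(35 * EPM, NW), np.full(4 * EPM, WALK), np.full(35 * EPM, NW)
        ])
        out = af.consolidate_nonwear(epochs_of(lab))
        assert (out.labels == NW).all()
        burst = slice(35 * EPM, 39 * EPM)
        assert (out.flags[burst] == af.EpochFlag.reclassified_to_nonwear).all()

    def test_burst_over_tolerance_not_merged(self):
        lab = np.concatenate([
            np.full(35 * EPM, NW), np.full(6 * EPM, WALK), np.full(35 * EPM, NW)
        ])
        out = af.consolidate_nonwear(epochs_of(lab))
        assert (out.labels[35 * EPM:41 * EPM] == WALK).all()

    def test_short_nonwear_becomes_sedentary(self):
        lab = np.concatenate([
            np.full(60 * EPM, SIT), np.full(30 * EPM, NW), np.full(60 * EPM, SIT)
        ])
        out = af.consolidate_nonwear(epochs_of(lab))
        assert (out.labels == SIT).all()
        mid = slice(60 * EPM, 90 * EPM)
        assert (out.flags[mid] == af.EpochFlag.reclassified_to_sedentary).all()

    def test_all_wear_day_is_fixpoint(self):
        lab = np.full(4000, SIT)
        out = af.consolidate_nonwear(epochs_of(lab))
        assert np.array_equal(out.labels, lab)
        assert (out.flags == af.EpochFlag.original).all()

    @pytest.mark.parametrize("win_min,tol_min", [(60, 10), (30, 10), (30, 20)])
    def test_matches_bruteforce_oracle_on_short_sequences(self, win_min, tol_min):
        # exhaustive: all non-wear/sitting sequences up to 12 coarse
        # (10 min) epochs
        win_ep = int(win_min * 60 / 600)
        tol_ep = int(tol_min * 60 / 600)
        for L in range(1, 13):
            for combo in itertools.product([NW, SIT], repeat=L):
                lab = np.array(combo, dtype=np.int8)
                got = af.consolidate_nonwear(
                    epochs_of(lab.copy(), epoch_s=600.0),
                    window_min=win_min, tolerance_min=tol_min,
                ).labels
                exp = oracle_consolidate(lab, win_ep, tol_ep)
                assert np.array_equal(got, exp), (win_min, tol_min, lab.tolist())

    @given(st.lists(st.sampled_from([NW, SIT, WALK]), min_size=1, max_size=400))
    @settings(max_examples=200)
    def test_conservation_and_idempotence(self, labs):
        ep = epochs_of(labs, epoch_s=150.0)  # coarse grid to hit the rules
        once = af.consolidate_nonwear(ep)
        assert len(once) == len(labs)  # epoch count and timing unchanged
        assert once.start_time == ep.start_time
        # every label change carries a flag
        changed = once.labels != np.asarray(labs, dtype=np.int8)
        assert (once.flags[changed] != af.EpochFlag.original).all()
        twice = af.consolidate_nonwear(once)
        assert np.array_equal(twice.labels, once.labels)


class TestWakeWindow:
    def window(self, wake="2013-04-08 07:00:00", bed="2013-04-08 21:00:00"):
        return af.DayWindow("c", pd.Timestamp(wake).date(),
                            pd.Timestamp(wake), pd.Timestamp(bed))

    def test_full_day_restriction_counts(self):
        lab = np.full(24 * 1440, SIT)  # 24 h of epochs from midnight
        ep = af.CleanedEpochs.from_labeled(epochs_of(lab))
        out = af.restrict_to_wake_window(ep, self.window())
        assert int(out.retained.sum()) == 20160  # 14 h x 1440 epochs/h

    def test_half_open_boundary(self):
        start = "2013-04-08 06:59:57.5"
        ep = af.CleanedEpochs.from_labeled(epochs_of([SIT, SIT, SIT], start=start))
        out = af.restrict_to_wake_window(ep, self.window())
        # epochs start 06:59:57.5, 07:00:00, 07:00:02.5
        assert list(out.retained) == [False, True, True]
        # epoch starting exactly at bed time is excluded
        ep2 = af.CleanedEpochs.from_labeled(
            epochs_of([SIT, SIT], start="2013-04-08 20:59:57.5"))
        out2 = af.restrict_to_wake_window(ep2, self.window())
        assert list(out2.retained) == [True, False]

    def test_missing_report_invalidates_day(self):
        ep = af.CleanedEpochs.from_labeled(epochs_of(np.full(20000, SIT)))
        out = af.restrict_to_wake_window(ep, None)
        assert int(out.retained.sum()) == 0
        assert not af.summarize_wear(out).is_valid_day


class TestWearSummary:
    def make(self, wear_hours, nonwear_hours=0.0):
        n_wear = int(wear_hours * 1440)
        n_nw = int(nonwear_hours * 1440)
        lab = np.concatenate([np.full(n_wear, SIT), np.full(n_nw, NW)])
        return af.CleanedEpochs.from_labeled(epochs_of(lab, start="2013-04-08 07:00:00"))

    @pytest.mark.parametrize("hours,valid", [(11.5, True), (6.0, True),
                                             (5.983, False), (2.0, False)])
    def test_six_hour_rule_inclusive(self, hours, valid):
        s = af.summarize_wear(self.make(hours))
        assert s.wear_hours == pytest.approx(hours, abs=1e-3)
        assert s.is_valid_day is valid

    def test_nonwear_excluded_and_monotone(self):
        base = af.summarize_wear(self.make(8.0)).wear_hours
        with_nw = af.summarize_wear(self.make(8.0, nonwear_hours=3.0)).wear_hours
        assert with_nw == pytest.approx(base)  # non-wear adds no wear time


class TestDayWindows:
    def test_windows_pair_consecutive_reports(self):
        reports = pd.DataFrame({
            "child_id": ["c", "c"],
            "date": ["2013-04-08", "2013-04-09"],
            "bed_time": ["2013-04-07 21:10:00", "2013-04-08 20:50:00"],
            "wake_time": ["2013-04-08 07:05:00", "2013-04-09 06:55:00"],
        })
        wins = af.build_day_windows(reports)
        assert len(wins) == 2
        first = wins[0]
        assert first.wake_time == pd.Timestamp("2013-04-08 07:05:00")
        # bed time of day 1 comes from day 2's morning report
        assert first.bed_time == pd.Timestamp("2013-04-08 20:50:00")
        # last day falls back to the median bed clock-time
        assert wins[1].bed_time.date() == pd.Timestamp("2013-04-09").date()
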