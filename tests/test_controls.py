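"""Glove motion metrics, repeated-measures ANOVA, behavioral statistics."""

import numpy as np
import pandas as pd
import pytest

from numtopo import controls, synth
from numtopo import timeline as tl


def _toy_run(n_epochs=4, duration=3.0, period=7.5):
    events = tuple(
        tl.StimulusEvent(onset=i * period, duration=duration, numerosity=(i % 7) + 1, condition="haptic_equal_size")
        for i in range(n_epochs)
    )
    total = n_epochs * period
    return tl.RunTimeline(events=events, tr=1.5, n_frames_total=int(total / 1.5) + 2, n_frames_discarded=2, modality="haptic")


def _trace_with_bumps(run, rate, counts):
    """One-finger trace with a known number of bumps per epoch."""
    n = int(round(run.retained_duration * rate))
    t = np.arange(n) / rate
    x = np.full(n, 0.5)
    for ev, k in zip(run.events, counts):
        i0, i1 = int(round(ev.onset * rate)), int(round(ev.offset * rate))
        x[i0:i1] += synth.bump_train(i1 - i0, rate, k)
    return pd.DataFrame({"time": t, "finger_1": x})


class TestEpochMetrics:
    def test_flat_epoch_all_zero(self):
        run = _toy_run(3)
        trace = _trace_with_bumps(run, 52.0, [0, 0, 0])
        m = controls.epoch_metrics(trace, run)
        assert (m["n_peaks"] == 0).all()
        assert (m["motion_std"] == 0).all()
        assert (m["motion_duration_s"] == 0).all()

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_injected_bump_count_recovered(self, k):
        run = _toy_run(1)
        trace = _trace_with_bumps(run, 52.0, [k])
        m = controls.epoch_metrics(trace, run)
        assert m["n_peaks"].iloc[0] == k

    def test_single_bump_duration_spans_rise_and_fall(self):
        run = _toy_run(1)
        trace = _trace_with_bumps(run, 52.0, [1])
        m = controls.epoch_metrics(trace, run)
        # one 0.4 s bump: motion duration close to the bump width
        assert 0.2 < m["motion_duration_s"].iloc[0] < 0.8

    def test_offset_invariance(self):
        run = _toy_run(3)
        trace = _trace_with_bumps(run, 52.0, [2, 1, 3])
        shifted = trace.copy()
        shifted["finger_1"] = shifted["finger_1"] + 100.0
        m0 = controls.epoch_metrics(trace, run)
        m1 = controls.epoch_metrics(shifted, run)
        pd.testing.assert_frame_equal(m0, m1)

    def test_short_epoch_flagged_invalid(self):
        events = (tl.StimulusEvent(onset=0.0, duration=0.05, numerosity=1, condition="haptic_equal_size"),)
        run = tl.RunTimeline(events=events, tr=1.5, n_frames_total=4, n_frames_discarded=0, modality="haptic")
        n = int(round(run.retained_duration * 20))
        trace = pd.DataFrame({"time": np.arange(n) / 20, "finger_1": np.zeros(n)})
        m = controls.epoch_metrics(trace, run)
        assert not m["valid"].iloc[0]
        assert controls.average_across_fingers(m).empty


class TestMotionAnova:
    @staticmethod
    def _cells(values_by_participant):
        rows = []
        for p, grid in values_by_participant.items():
            for cond, by_num in grid.items():
                for num, v in by_num.items():
                    rows.append((p, cond, num, v))
        return pd.DataFrame(rows, columns=["participant", "condition", "numerosity", "n_peaks"])

    def test_matches_hand_computed_rm_anova(self):
        """2 conditions x 3 numerosities x 4 participants: the numerosity F
        equals the textbook within-subject sums-of-squares computation."""
        rng = np.random.default_rng(0)
        parts = [f"p{i}" for i in range(4)]
        data = {
            p: {c: {n: float(rng.normal(n * 0.1, 1.0)) for n in (1, 2, 3)} for c in ("A", "B")}
            for p in parts
        }
        cells = self._cells(data)
        out = controls.motion_anova(cells, "n_peaks")

        # independent hand computation of the numerosity main effect
        arr = np.array([[[data[p][c][n] for n in (1, 2, 3)] for c in ("A", "B")] for p in parts])
        # arr: participants x conditions x numerosities
        num_means = arr.mean(axis=(0, 1))
        subj_num = arr.mean(axis=1)  # participants x numerosities
        subj_means = arr.mean(axis=(1, 2))
        grand = arr.mean()
        n_p, n_c, n_n = arr.shape
        ss_num = n_p * n_c * np.sum((num_means - grand) ** 2)
        ss_err = n_c * np.sum((subj_num - subj_means[:, None] - num_means[None, :] + grand) ** 2)
        f_oracle = (ss_num / (n_n - 1)) / (ss_err / ((n_p - 1) * (n_n - 1)))
        assert out["f_numerosity"] == pytest.approx(f_oracle, rel=1e-9)

    def test_null_profile_not_significant_and_bf01_supports_null(self):
        rng = np.random.default_rng(1)
        parts = [f"p{i}" for i in range(5)]
        data = {
            p: {c: {n: float(rng.normal(2.0, 0.3)) for n in range(1, 8)} for c in ("A", "B")}
            for p in parts
        }
        out = controls.motion_anova(self._cells(data), "n_peaks")
        assert out["p_numerosity"] > 0.05
        assert out["bf01_numerosity_bic_approx"] > 1.0

    def test_missing_cells_reported(self):
        cells = self._cells({"p0": {"A": {1: 1.0, 2: 2.0}}, "p1": {"A": {1: 1.0}}})
        with pytest.raises(ValueError, match="missing cells"):
            controls.motion_anova(cells, "n_peaks")


class TestBehaviorSummary:
    def test_all_correct_zero_error(self):
        t = synth.simulate_behavior(10, error_slope=0.0, seed=0)
        s = controls.behavior_summary(t)
        assert (s["group"]["mean_error_pct"] == 0.0).all()

    def test_error_rate_arithmetic(self):
        t = pd.DataFrame(
            {
                "participant": ["p0"] * 20,
                "modality": ["haptic"] * 20,
                "condition": ["equal_size"] * 20,
                "numerosity": [5] * 20,
                "response": [5] * 15 + [4] * 5,
                "rt_s": np.linspace(1, 2, 20),
            }
        )
        s = controls.behavior_summary(t)
        assert s["per_participant"]["error_rate_pct"].iloc[0] == pytest.approx(25.0)

    def test_generator_error_curve_recovered(self):
        tables = [synth.simulate_behavior(20, subitizing_limit=3, error_slope=0.15, seed=i, participant=f"p{i}") for i in range(5)]
        s = controls.behavior_summary(pd.concat(tables))
        g = s["group"].set_index("numerosity")["mean_error_pct"]
        for n in range(1, 8):
            expected = 100 * max(0.0, 0.15 * (n - 3))
            # binomial 3-sigma band, 100 trials per numerosity
            band = 300 * np.sqrt(max(expected / 100 * (1 - expected / 100), 0.002) / 100)
            assert abs(g.loc[n] - expected) <= band


class TestBehaviorTests:
    @staticmethod
    def _study(seed0=0, rt_slope=0.35):
        tabs = []
        for i in range(5):
            tabs.append(
                synth.simulate_behavior(
                    20, seed=seed0 + i, participant=f"p{i}", rt_params=synth.RtParams(per_item=rt_slope)
                )
            )
            tabs.append(
                synth.simulate_behavior(
                    20, seed=seed0 + 100 + i, participant=f"p{i}", modality="visual", condition="standard",
                    rt_params=synth.RtParams(per_item=rt_slope),
                )
            )
        return pd.concat(tabs, ignore_index=True)

    def test_flat_rt_profiles_give_null_friedman(self):
        rows = []
        for p in range(4):
            for n in range(1, 8):
                rows.append((f"p{p}", "haptic", "equal_size", n, n, 1.0))
        t = pd.DataFrame(rows, columns=["participant", "modality", "condition", "numerosity", "response", "rt_s"])
        out = controls.behavior_tests(t)
        assert out["friedman"]["chi2"].iloc[0] == pytest.approx(0.0)

    def test_rt_increase_detected(self):
        out = controls.behavior_tests(self._study())
        assert (out["friedman"]["p"] < 0.05).all()

    def test_pairwise_chi_square_matches_hand_formula(self):
        out = controls.behavior_tests(self._study())
        t = self._study()
        t["error"] = (t["response"] != t["numerosity"]).astype(int)
        sub = t[(t["modality"] == "haptic")]
        pooled = sub.groupby("numerosity")["error"].agg(["sum", "size"])
        a, b = 1, 7
        tbl = np.array(
            [
                [pooled.loc[a, "sum"], pooled.loc[a, "size"] - pooled.loc[a, "sum"]],
                [pooled.loc[b, "sum"], pooled.loc[b, "size"] - pooled.loc[b, "sum"]],
            ],
            dtype=float,
        )
        n = tbl.sum()
        exp = np.outer(tbl.sum(axis=1), tbl.sum(axis=0)) / n
        chi_oracle = ((tbl - exp) ** 2 / exp).sum()
        row = out["error_pairwise"]
        got = row[(row["modality"] == "haptic") & (row["numerosity_a"] == a) & (row["numerosity_b"] == b)]["chi2"].iloc[0]
        assert got == pytest.approx(chi_oracle, rel=1e-9)

    def test_cross_modal_profiles_correlate(self):
        out = controls.behavior_tests(self._study())
        rt = out["spearman"][out["spearman"]["measure"] == "median_rt_s"]
        assert (rt["r_s"] > 0.5).all()

    def test_perfectly_monotone_profiles_spearman_one(self):
        rows = []
        for mod, cond in [("haptic", "equal_size"), ("visual", "standard")]:
            for p in range(3):
                for n in range(1, 8):
                    rows.append((f"p{p}", mod, cond, n, n, 1.0 + 0.1 * n + 0.01 * p))
        t = pd.DataFrame(rows, columns=["participant", "modality", "condition", "numerosity", "response", "rt_s"])
        out = controls.behavior_tests(t)
        rt = out["spearman"][out["spearman"]["measure"] == "median_rt_s"]
        assert rt["r_s"].iloc[0] == pytest.approx(1.0)
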