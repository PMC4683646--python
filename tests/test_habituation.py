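import math

import numpy as np
import pandas as pd
import pytest

import wormhab as wh
from wormhab.habituation import HabituationProfile, detect_reversals, score_stimulus
from conftest import piecewise_track


def _profile_from_p(p_values, n_tracked=100, plate_id="synthetic"):
    p = np.asarray(p_values, dtype=float)
    n = np.full(p.size, n_tracked)
    df = pd.DataFrame(
        {
            "stimulus": np.arange(1, p.size + 1),
            "n_tracked": n,
            "n_responded": np.round(p * n).astype(int),
            "p": p,
            "mean_duration_s": np.full(p.size, 2.74),
            "mean_speed_mm_s": np.full(p.size, 0.282),
        }
    )
    return HabituationProfile(plate_id=plate_id, n_stimuli=p.size, data=df)


class TestDetectReversals:
    def test_single_clean_reversal(self):
        tr = piecewise_track("w", [(5.0, 0.2), (2.0, -0.3)])
        evs = detect_reversals(tr)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.duration_s == pytest.approx(2.0)
        assert ev.mean_speed_mm_s == pytest.approx(0.3)
        assert ev.net_displacement_mm == pytest.approx(0.6)
        assert ev.t_start == pytest.approx(5.0)

    def test_subthreshold_displacement_ignored(self):
        tr = piecewise_track("w", [(5.0, 0.2), (0.5, -0.1), (5.0, 0.2)])  # 0.05 mm net
        assert detect_reversals(tr, min_disp_mm=0.1) == []

    def test_separated_bouts_are_separate_events(self):
        tr = piecewise_track("w", [(3.0, 0.2), (2.0, -0.3), (3.0, 0.2), (1.0, -0.3), (3.0, 0.2)])
        evs = detect_reversals(tr)
        assert len(evs) == 2
        assert evs[0].t_end < evs[1].t_start


class TestScoreStimulus:
    def _plate(self, tracks):
        proto = wh.Protocol(baseline_s=100.0, n_stimuli=1, isi_s=10.0, total_s=110.0)
        return wh.PlateRecording("p", "WT-HAB", proto, [100.0], tracks)

    def _events(self, plate):
        return {tr.worm_id: detect_reversals(tr) for tr in plate.tracks}

    def test_onset_within_2s_is_responder(self):
        tr = piecewise_track("w", [(6.5, 0.2), (2.0, -0.3), (6.5, 0.2)], t0=95.0)
        plate = self._plate([tr])  # reversal onset at 101.5 s
        recs = score_stimulus(plate, self._events(plate), 1)
        assert len(recs) == 1 and recs[0].responded
        assert recs[0].duration_s == pytest.approx(2.0)
        assert recs[0].mean_speed_mm_s == pytest.approx(0.3)

    def test_onset_after_window_is_nonresponder(self):
        tr = piecewise_track("w", [(8.0, 0.2), (2.0, -0.3), (5.0, 0.2)], t0=95.0)
        plate = self._plate([tr])  # onset at 103 s
        recs = score_stimulus(plate, self._events(plate), 1)
        assert len(recs) == 1 and not recs[0].responded

    def test_untracked_worm_excluded_from_denominator(self):
        # lost at 99 s, reappears at 104 s: not tracked through the window
        tr = piecewise_track("w", [(5.0, 0.2)], t0=104.0)
        plate = self._plate([tr])
        assert score_stimulus(plate, self._events(plate), 1) == []

    def test_ongoing_reversal_not_counted_by_default(self):
        tr = piecewise_track("w", [(1.0, 0.2), (4.0, -0.3), (8.0, 0.2)], t0=98.0)
        plate = self._plate([tr])  # reversing since 99 s when tap arrives
        recs = score_stimulus(plate, self._events(plate), 1)
        assert not recs[0].responded
        recs = score_stimulus(plate, self._events(plate), 1, count_ongoing=True)
        assert recs[0].responded

    def test_magnitude_is_whole_event_even_past_window(self):
        tr = piecewise_track("w", [(6.0, 0.2), (5.0, -0.3), (2.0, 0.2)], t0=95.0)
        plate = self._plate([tr])  # onset 101 s, ends 106 s
        recs = score_stimulus(plate, self._events(plate), 1)
        assert recs[0].responded and recs[0].duration_s == pytest.approx(5.0)


class TestResponseProfile:
    def test_proportions_are_counts_over_denominators(self, small_wt_plate):
        prof = wh.response_profile(small_wt_plate)
        d = prof.data
        defined = d[d["n_tracked"] > 0]
        assert np.allclose(defined["p"], defined["n_responded"] / defined["n_tracked"])
        assert (d["n_responded"] <= d["n_tracked"]).all()

    def test_scoring_invariant_to_relabeling_and_rigid_motion(self, small_wt_plate):
        """Track-id permutation and rigid rotation+translation of all
        coordinates leave the profile unchanged."""
        base = wh.response_profile(small_wt_plate).data
        ang, dx, dy = 0.7, 12.0, -3.0
        c, s = math.cos(ang), math.sin(ang)
        moved = [
            wh.WormTrack(
                f"relabeled-{i}",
                tr.t,
                c * tr.x - s * tr.y + dx,
                s * tr.x + c * tr.y + dy,
                tr.theta + ang,
            )
            for i, tr in enumerate(reversed(small_wt_plate.tracks))
        ]
        plate2 = wh.PlateRecording(
            "p2", small_wt_plate.genotype, small_wt_plate.protocol, small_wt_plate.stimuli, moved
        )
        got = wh.response_profile(plate2).data
        assert np.allclose(base["p"], got["p"], equal_nan=True)
        assert np.allclose(base["mean_duration_s"], got["mean_duration_s"], equal_nan=True)

    def test_no_stimuli_is_error(self):
        proto = wh.Protocol.exploration(60.0)
        plate = wh.PlateRecording("p", "x", proto, [], [piecewise_track("w", [(60.0, 0.2)])])
        with pytest.raises(wh.WormhabError):
            wh.response_profile(plate)


class TestFitExponential:
    def test_closed_form_example(self):
        """Noiseless p(k) = 0.4 + 0.5 exp(-(k-1)/5) over 30 stimuli."""
        k = np.arange(1, 31)
        prof = _profile_from_p(0.4 + 0.5 * np.exp(-(k - 1) / 5.0))
        fit = wh.fit_exponential(prof)
        assert fit.habituation_level == pytest.approx(0.4 + 0.5 * math.exp(-29 / 5.0), abs=1e-6)
        assert fit.half_life == pytest.approx(5.0 * math.log(2), abs=1e-4)
        assert fit.converged

    @pytest.mark.parametrize("a", [0.2, 0.4, 0.6])
    @pytest.mark.parametrize("b", [0.2, 0.5])
    @pytest.mark.parametrize("lam", [2.0, 5.0, 10.0])
    def test_noiseless_recovery_oracle_grid(self, a, b, lam):
        """Fitting a noiseless 30-point curve recovers the generating
        curve's value at the final stimulus to 1e-6."""
        k = np.arange(1, 31)
        truth = a + b * np.exp(-(k - 1) / lam)
        fit = wh.fit_exponential(_profile_from_p(truth))
        assert fit.habituation_level == pytest.approx(a + b * math.exp(-29 / lam), abs=1e-6)

    def test_flat_profile_reports_mean_and_undefined_half_life(self):
        fit = wh.fit_exponential(_profile_from_p(np.full(30, 0.9)))
        assert fit.habituation_level == pytest.approx(0.9)
        assert math.isnan(fit.half_life)

    def test_too_few_points_is_error(self):
        with pytest.raises(wh.WormhabError):
            wh.fit_exponential(_profile_from_p([0.9, 0.7, 0.5]))

    def test_monotone_profile_level_below_initial(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p1 = rng.uniform(0.5, 1.0)
            pn = rng.uniform(0.1, p1)
            lam = rng.uniform(2, 8)
            k = np.arange(1, 31)
            p = pn + (p1 - pn) * np.exp(-(k - 1) / lam)
            fit = wh.fit_exponential(_profile_from_p(p))
            assert fit.habituation_level <= p1 + 1e-6

    def test_binomial_noise_recovery(self):
        """Mean fitted level over 200 binomially-noised profiles
        (n_tracked = 75) is within 0.01 of the true curve at k = 30."""
        params = wh.make_preset("WT-HAB")
        k = np.arange(1, 31)
        truth = params.response_probability(k)
        rng = np.random.default_rng(12345)
        levels = []
        for _ in range(200):
            p = rng.binomial(75, truth) / 75.0
            levels.append(wh.fit_exponential(_profile_from_p(p, n_tracked=75)).habituation_level)
        assert np.mean(levels) == pytest.approx(truth[-1], abs=0.01)

    def test_undefined_stimuli_excluded_from_fit(self):
        k = np.arange(1, 31)
        p = 0.4 + 0.5 * np.exp(-(k - 1) / 5.0)
        prof = _profile_from_p(p)
        prof.data.loc[6, ["p", "mean_duration_s", "mean_speed_mm_s"]] = np.nan
        prof.data.loc[6, ["n_tracked", "n_responded"]] = 0
        fit = wh.fit_exponential(prof)
        assert fit.habituation_level == pytest.approx(0.4 + 0.5 * math.exp(-29 / 5.0), abs=1e-6)


class TestPhenotypeAccessors:
    def test_initial_response_is_p1(self):
        prof = _profile_from_p([0.92, 0.8, 0.7, 0.6])
        assert wh.initial_response(prof) == pytest.approx(0.92)

    def test_constant_magnitude_recovered(self):
        prof = _profile_from_p([0.9, 0.8, 0.7, 0.6])
        dur, spd = wh.response_magnitude(prof)
        assert dur == pytest.approx(2.74)
        assert spd == pytest.approx(0.282)

    def test_no_responders_at_stimulus1_gives_nan_magnitude(self):
        prof = _profile_from_p([0.0, 0.5, 0.5, 0.5])
        prof.data.loc[0, ["mean_duration_s", "mean_speed_mm_s"]] = np.nan
        dur, spd = wh.response_magnitude(prof)
        assert math.isnan(dur) and math.isnan(spd)

    def test_undefined_stimulus1_is_error(self):
        prof = _profile_from_p([0.5, 0.5, 0.5, 0.5])
        prof.data.loc[0, "n_tracked"] = 0
        with pytest.raises(wh.WormhabError):
            wh.initial_response(prof)


def test_mean_profile_averages_defined_plates():
    a = _profile_from_p([0.9, 0.7, 0.5, 0.4], plate_id="a")
    b = _profile_from_p([0.8, 0.6, 0.4, 0.3], plate_id="b")
    m = wh.mean_profile([a, b])
    assert np.allclose(m.data["p"], [0.85, 0.65, 0.45, 0.35])
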