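import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from eegate import Recording
from eegate.erp import (EpochSet, baseline_correct, epoch_and_baseline,
                        exclude_noisy_subjects, grand_average, p300_amplitude,
                        p300_predictor_model, peak_latency, reject_epochs,
                        trial_logistic_model)


def make_epochs(data, fs=100.0, conditions=None, subjects=None, corrected=True):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    info = pd.DataFrame(dict(subject=subjects or ["s1"] * n,
                             condition=conditions or ["ignore"] * n,
                             correct=1))
    names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data, fs, names, info, baseline_corrected=corrected)


class TestEpochingAndBaseline:
    def _recording(self, fs=100.0, dur=30.0):
        n = int(fs * dur)
        return Recording(np.full((2, n), 5.0), fs, ["Pz", "Cz"])

    def test_constant_channel_zeroed_by_baseline(self):
        rec = self._recording()
        events = pd.DataFrame(dict(onset_s=[5.0, 10.0], condition=["ignore", "update"]))
        ep = epoch_and_baseline(rec, events)
        assert ep.n_epochs == 2
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-9)

    def test_post_stimulus_bump_survives_baseline(self):
        fs = 100.0
        rec = self._recording(fs)
        i0 = int(5.5 * fs)
        rec.data[0, i0:i0 + 20] += 10.0      # bump 0.5 s after the event at 5 s
        ep = epoch_and_baseline(rec, pd.DataFrame(dict(onset_s=[5.0], condition=["ignore"])))
        t = ep.times
        assert ep.data[0, 0][(t >= 0.5) & (t < 0.7)].mean() == pytest.approx(10.0, abs=1e-9)
        base = ep.data[0, 0][(t >= -0.5) & (t <= -0.05)]
        assert abs(base.mean()) < 1e-9

    def test_edge_events_dropped_with_reason(self):
        rec = self._recording()
        events = pd.DataFrame(dict(onset_s=[0.2, 10.0], condition=["ignore", "ignore"]))
        ep = epoch_and_baseline(rec, events)
        assert ep.n_epochs == 1
        assert len(ep.dropped) == 1
        assert "edge" in ep.dropped["dropped_reason"].iloc[0]

    def test_baseline_correction_idempotent(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.normal(size=(4, 3, 230)), corrected=False)
        ep.tmin = -0.5
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


class TestRejection:
    def _epoch_with_square(self, n_channels_bad, duty=0.40, amp=20.0, n_ch=5, n_t=200):
        data = np.zeros((1, n_ch, n_t))
        bad_len = int(duty * n_t)
        for c in range(n_channels_bad):
            data[0, c, :bad_len] = amp * np.where(np.arange(bad_len) % 2, 1, -1)
        return make_epochs(data)

    def test_three_channel_square_wave_rejected(self):
        ep = reject_epochs(self._epoch_with_square(3))
        assert ep.rejected[0]
        assert "amplitude" in ep.reject_reason[0]

    def test_two_channels_not_enough(self):
        ep = reject_epochs(self._epoch_with_square(2))
        assert not ep.rejected[0]

    def test_exactly_30_percent_not_rejected(self):
        ep = reject_epochs(self._epoch_with_square(3, duty=0.30))
        assert not ep.rejected[0]

    def test_clean_epochs_untouched(self):
        rng = np.random.default_rng(2)
        ep = reject_epochs(make_epochs(rng.normal(scale=3, size=(10, 4, 150))))
        assert not ep.rejected.any()

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            data = rng.normal(scale=12, size=(6, 4, 50))
            ep = reject_epochs(make_epochs(data))
            for ti in range(6):
                n_bad = sum(np.mean(np.abs(data[ti, ci]) > 15.0) > 0.30
                            for ci in range(4))
                assert ep.rejected[ti] == (n_bad >= 3)


class TestSubjectExclusion:
    def _epochs_with_rejection_fracs(self, fracs):
        n_per = 100
        subjects, rejected = [], []
        for i, f in enumerate(fracs):
            subjects += [f"s{i}"] * n_per
            rejected += [True] * int(round(f * n_per)) + [False] * (n_per - int(round(f * n_per)))
        data = np.zeros((len(subjects), 1, 10))
        ep = make_epochs(data, subjects=subjects, conditions=["ignore"] * len(subjects))
        ep.rejected = np.array(rejected)
        return ep

    def test_strict_sixty_percent_rule(self):
        ep = self._epochs_with_rejection_fracs([0.61, 0.60, 0.10])
        rep = exclude_noisy_subjects(ep).set_index("subject")
        assert not rep.loc["s0", "keep"]
        assert rep.loc["s1", "keep"]
        assert rep.loc["s2", "keep"]


class TestP300:
    def test_constant_window_amplitude(self):
        fs = 100.0
        n_t = 230
        data = np.zeros((1, 1, n_t))
        times = -0.5 + np.arange(n_t) / fs
        data[0, 0, (times >= 0.31) & (times <= 0.5)] = 2.0
        ep = make_epochs(data, fs)
        ep.channel_names[0] = "Pz"
        out = p300_amplitude(ep)
        assert out["amplitude"].item() == pytest.approx(2.0)
        assert out["amplitude_group"].item() == "high"

    def test_linearity_in_the_signal(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(5, 1, 230))
        ep = make_epochs(data, 100.0)
        ep.channel_names[0] = "Pz"
        a1 = p300_amplitude(ep)["amplitude"].to_numpy()
        ep2 = make_epochs(3.0 * data + 1.5, 100.0)
        ep2.channel_names[0] = "Pz"
        a2 = p300_amplitude(ep2)["amplitude"].to_numpy()
        np.testing.assert_allclose(a2, 3.0 * a1 + 1.5, atol=1e-12)

    def test_symmetric_noise_splits_groups_evenly(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(400, 1, 230))
        ep = make_epochs(data, 100.0)
        ep.channel_names[0] = "Pz"
        out = p300_amplitude(ep)
        frac_high = (out["amplitude_group"] == "high").mean()
        assert frac_high == pytest.approx(0.5, abs=0.08)

    def test_missing_channel_error(self):
        ep = make_epochs(np.zeros((1, 1, 230)))
        with pytest.raises(ValueError):
            p300_amplitude(ep, channel="Pz")


class TestPeakLatency:
    def test_noiseless_bump_located_exactly(self):
        fs = 500.0
        times = -0.5 + np.arange(int(2.3 * fs) + 1) / fs
        w = np.exp(-0.5 * ((times - 0.320) / 0.06) ** 2)
        assert peak_latency(times, w) == pytest.approx(0.320, abs=1 / fs)

    def test_equal_peaks_resolve_to_earlier(self):
        times = np.linspace(0, 1, 101)
        w = np.zeros(101)
        w[[30, 50]] = 1.0
        assert peak_latency(times, w, search=(0.1, 0.9)) == pytest.approx(0.30, abs=0.01)

    def test_flat_signal_rejected(self):
        times = np.linspace(0, 1, 101)
        with pytest.raises(ValueError):
            peak_latency(times, np.ones(101), search=(0.2, 0.8))


class TestTrialLogistic:
    def _simulate(self, rng, n_subj=30, n_trial=60, b_inter=-0.8, sigma=0.5):
        rows = []
        for i in range(n_subj):
            u = rng.normal(0, sigma)
            for t in range(n_trial):
                ig = t % 2
                amp = rng.normal(0, 1)
                eta = 1.0 + 0.1 * amp - 0.3 * ig + b_inter * amp * ig + u
                rows.append(dict(subject=f"s{i:02d}",
                                 condition="ignore" if ig else "update",
                                 amplitude=amp, correct=int(rng.random() < expit(eta))))
        return pd.DataFrame(rows)

    def test_planted_interaction_recovered(self):
        rng = np.random.default_rng(6)
        df = self._simulate(rng)
        out = trial_logistic_model(df)
        assert out["converged"] and not out["separation"]
        coefs = out["coefficients"]
        est = coefs.loc["p300:ignore", "beta"]
        assert est == pytest.approx(-0.8, abs=3 * coefs.loc["p300:ignore", "se"])
        assert coefs.loc["p300:ignore", "p"] < 0.01

    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Cross-check the Gauss-Hermite ML fit against R lme4 on a tiny fixture."""
        rng = np.random.default_rng(7)
        df = self._simulate(rng, n_subj=15, n_trial=40)
        csv = tmp_path / "trials.csv"
        df.assign(ig=(df.condition == "ignore").astype(int),
                  z=(df.amplitude - df.amplitude.mean()) / df.amplitude.std(ddof=0)
                  ).to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(correct ~ z * ig + (1|subject), data=d, family=binomial,
                       nAGQ=15)
            cat(fixef(m)["z:ig"], sqrt(diag(vcov(m)))["z:ig"], sep=",")
        """)
        res = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        beta_r, se_r = map(float, res.stdout.strip().split(","))
        out = trial_logistic_model(df)
        assert out["coefficients"].loc["p300:ignore", "beta"] == pytest.approx(beta_r, abs=0.02)
        assert out["coefficients"].loc["p300:ignore", "se"] == pytest.approx(se_r, rel=0.10)

    def test_requires_both_conditions(self):
        df = pd.DataFrame(dict(subject=["s1"] * 4, condition=["ignore"] * 4,
                               amplitude=[0.1, 0.2, -0.1, 0.0], correct=[1, 0, 1, 1]))
        with pytest.raises(ValueError):
            trial_logistic_model(df)


class TestMarkerToP300Models:
    def _p300_table(self, rng, coupling=0.0, n_subj=25, n_trial=40):
        marker = pd.Series(rng.normal(size=n_subj),
                           index=[f"s{i:02d}" for i in range(n_subj)])
        zm = (marker - marker.mean()) / marker.std(ddof=0)
        rows = []
        for s in marker.index:
            for t in range(n_trial):
                ig = t % 2
                amp = 1.2 + 0.4 * ig + (coupling * zm[s] if ig else 0.0) + rng.normal(0, 1.5)
                rows.append(dict(subject=s, condition="ignore" if ig else "update",
                                 amplitude=amp, correct=1))
        return pd.DataFrame(rows), marker

    def test_planted_coupling_detected(self):
        rng = np.random.default_rng(8)
        p300, marker = self._p300_table(rng, coupling=0.8)
        out = p300_predictor_model(p300, marker)
        assert out["beta"] == pytest.approx(0.8, abs=3 * out["se"])
        assert out["p"] < 0.01

    def test_null_coupling_not_flagged(self):
        rng = np.random.default_rng(9)
        p300, marker = self._p300_table(rng, coupling=0.0)
        out = p300_predictor_model(p300, marker)
        assert out["p"] > 0.01

    def test_seeded_reproducibility(self):
        rng1 = np.random.default_rng(10)
        rng2 = np.random.default_rng(10)
        p1, m1 = self._p300_table(rng1)
        p2, m2 = self._p300_table(rng2)
        o1 = p300_predictor_model(p1, m1)
        o2 = p300_predictor_model(p2, m2)
        assert o1["beta"] == o2["beta"] and o1["p"] == o2["p"]
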