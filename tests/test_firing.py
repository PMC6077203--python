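"""Spike detection and drug-effect valence scoring."""
import numpy as np
import pandas as pd
import pytest

from gabashift import (
    AcquisitionSpec,
    TracePatch,
    assign_valence,
    detect_spikes,
    drug_effect,
    mean_valence_by_age,
    simulate_firing_trace,
)
from gabashift.firing import DrugEffect


class TestDetectSpikes:
    def test_spike_free_noise_gives_empty_train(self, rng):
        acq = AcquisitionSpec(fs=10_000.0, fc=2_000.0, noise_sd=1.0, duration=15.0, V=0.0)
        tr = TracePatch(rng.normal(0, 1.0, 150_000), acq)
        assert detect_spikes(tr).spike_times.size == 0

    def test_regular_train_count(self):
        tr = simulate_firing_trace(30.0, 50.0, (20.0, 40.0), effect="none", seed=3,
                                   duration=60.0)
        train = detect_spikes(tr)
        assert abs(train.spike_times.size - 1800) <= 2

    def test_precision_and_recall_on_moderate_noise(self):
        # recall and precision >= 0.99 at noise 0.2x spike amplitude, 50 seeds
        tp = fp = fn = 0
        for seed in range(50):
            tr = simulate_firing_trace(
                20.0, 50.0, (10.0, 20.0), effect="none", seed=seed,
                duration=30.0, noise_sd=10.0 / 5.0,  # threshold 5 sd under the peak
            )
            truth = tr.meta["true_spike_times"]
            det = detect_spikes(tr).spike_times
            matched = np.zeros(det.size, dtype=bool)
            for t in truth:
                j = np.argmin(np.abs(det - t)) if det.size else None
                if j is not None and abs(det[j] - t) < 0.003 and not matched[j]:
                    matched[j] = True
                else:
                    fn += 1
            tp += matched.sum()
            fp += (~matched).sum()
        assert tp / (tp + fn) >= 0.99
        assert tp / (tp + fp) >= 0.99

    def test_amplitude_decline_during_excitation(self):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 180.0), effect="excite", seed=4,
                                   duration=240.0)
        train = detect_spikes(tr)
        sel = (train.spike_times >= 60.0) & (train.spike_times < 180.0)
        amps = train.spike_amplitudes[sel]
        first, last = amps[: amps.size // 5].mean(), amps[-amps.size // 5 :].mean()
        assert last < 0.7 * first

    def test_short_trace_rejected(self, rng):
        acq = AcquisitionSpec(fs=10_000.0, fc=2_000.0, noise_sd=1.0, duration=5.0, V=0.0)
        with pytest.raises(ValueError):
            detect_spikes(TracePatch(rng.normal(0, 1, 50_000), acq))


class TestDrugEffect:
    def windows(self):
        return (0.0, 60.0), (60.0, 180.0), (180.0, 240.0)

    def run(self, effect, seed=4, **kw):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 180.0), effect=effect, seed=seed,
                                   duration=240.0, **kw)
        return drug_effect(detect_spikes(tr), *self.windows())

    def test_full_block(self):
        eff = self.run("inhibit", inhibit_factor=0.0)
        assert eff.freq_change == pytest.approx(-1.0)
        assert eff.reversible

    def test_default_inhibition_near_75_percent(self):
        eff = self.run("inhibit")
        assert eff.freq_change == pytest.approx(-0.75, abs=0.05)

    def test_excitation_near_220_percent(self):
        eff = self.run("excite")
        assert eff.freq_change == pytest.approx(2.2, abs=0.25)
        assert eff.amp_trend < 0

    def test_no_effect(self):
        eff = self.run("none")
        assert abs(eff.freq_change) < 0.1

    def test_silent_at_baseline_flagged(self):
        tr = simulate_firing_trace(0.0, 50.0, (60.0, 180.0), effect="none", seed=1,
                                   duration=240.0)
        eff = drug_effect(detect_spikes(tr), *self.windows())
        assert eff.silent_at_baseline
        assert eff.freq_change is None

    def test_overlapping_windows_rejected(self):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 180.0), seed=1, duration=240.0)
        with pytest.raises(ValueError):
            drug_effect(detect_spikes(tr), (0, 60), (50, 180), (180, 240))


class TestAssignValence:
    def make(self, fc, transient=False, silent=False):
        return DrugEffect(freq_change=fc, transient_inhibition=transient,
                          amp_trend=0.0, reversible=True, silent_at_baseline=silent)

    @pytest.mark.parametrize(
        "fc, transient, expected",
        [
            (-0.75, False, -1.0),
            (2.2, False, 1.0),
            (2.2, True, 0.5),
            (0.0, False, 0.0),
            (0.1, False, 0.0),  # inside the +/-15% no-effect band
        ],
    )
    def test_valence_rules(self, fc, transient, expected):
        assert assign_valence(self.make(fc, transient)) == expected

    def test_silent_cells_excluded(self):
        assert assign_valence(self.make(None, silent=True)) is None

    def test_scale_invariance(self):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 180.0), effect="inhibit", seed=9,
                                   duration=240.0)
        scaled = TracePatch(tr.samples * 3.0, tr.acquisition, dict(tr.meta))
        wins = ((0.0, 60.0), (60.0, 180.0), (180.0, 240.0))
        v0 = assign_valence(drug_effect(detect_spikes(tr), *wins))
        v1 = assign_valence(drug_effect(detect_spikes(scaled), *wins))
        assert v0 == v1


class TestMeanValence:
    def test_all_inhibited_bin(self):
        df = pd.DataFrame({"age": [21] * 6, "sex": ["female"] * 6, "valence": [-1.0] * 6})
        out = mean_valence_by_age(df, [(20, 25)])
        assert out.loc[0, "mean_valence"] == -1.0
        assert out.loc[0, "n"] == 6

    def test_mixed_composition_mean(self):
        # 3x(+1), 2x(+0.5), 1x(0), 7x(-1) -> (3 + 1 + 0 - 7)/13
        vals = [1.0] * 3 + [0.5] * 2 + [0.0] * 1 + [-1.0] * 7
        df = pd.DataFrame({"age": [17] * 13, "sex": ["female"] * 13, "valence": vals})
        out = mean_valence_by_age(df, [(15, 19)])
        assert out.loc[0, "mean_valence"] == pytest.approx(-0.230769, abs=1e-6)

    def test_empty_bins_omitted_and_sexes_separated(self):
        df = pd.DataFrame(
            {"age": [6, 20], "sex": ["male", "female"], "valence": [1.0, -1.0]}
        )
        out = mean_valence_by_age(df, [(5, 10), (15, 25), (30, 40)])
        assert len(out) == 2
        assert set(out["sex"]) == {"male", "female"}

    def test_inadmissible_valence_rejected(self):
        df = pd.DataFrame({"age": [6], "sex": ["male"], "valence": [0.7]})
        with pytest.raises(ValueError):
            mean_valence_by_age(df, [(5, 10)])

    def test_valence_curve_crosses_zero_near_generator_switch(self):
        # cohort generated with excite below P14.4 and inhibit above it:
        # the mean-valence sign change falls within 2 days of the switch
        rows = []
        for age in range(12, 18):
            for c in range(2):
                effect = "excite" if age < 14.4 else "inhibit"
                tr = simulate_firing_trace(
                    20.0, 50.0, (40.0, 90.0), effect=effect,
                    seed=1000 + 10 * age + c, duration=150.0,
                )
                eff = drug_effect(detect_spikes(tr), (0, 40), (40, 90), (90, 150))
                rows.append({"age": age, "sex": "male", "valence": assign_valence(eff)})
        curve = mean_valence_by_age(pd.DataFrame(rows), [(a, a) for a in range(12, 18)])
        signs = np.sign(curve["mean_valence"].to_numpy())
        flips = np.flatnonzero(np.diff(signs) != 0)
        assert flips.size == 1
        crossing_age = curve.loc[flips[0], "bin_lo"] + 0.5
        assert abs(crossing_age - 14.4) <= 2.0
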