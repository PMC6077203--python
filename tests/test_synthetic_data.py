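"""Generator contracts: Ohmic amplitudes, gating statistics, population sigmoids."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gabashift import (
    PRESETS,
    PROFILES,
    AcquisitionSpec,
    ChannelSpec,
    generate_population,
    hill4,
    simulate_channel_trace,
    simulate_firing_trace,
    simulate_patch_protocol,
)


class TestChannelSpec:
    def test_ohmic_current_two_level_patch(self):
        # one channel: 19 pS driven by 91 mV -> 1.729 pA above baseline
        assert PRESETS["fig1-example"][0].current(80.0) == pytest.approx(1.729)
        assert PRESETS["fig1-example"][1].current(80.0) == pytest.approx(0.6643)

    def test_preset_amplitudes_match_arithmetic(self):
        # P32 preset: 10.8 pS reversing at -8 mV -> 0.950 pA at +80 mV
        assert PRESETS["fig2-P32"][0].current(80.0) == pytest.approx(0.9504)
        # P6 preset amplitudes across the protocol potentials
        amps = [PRESETS["fig2-P6"][0].current(v) for v in (20, 40, 60, 80)]
        assert amps == pytest.approx([0.09, 0.45, 0.81, 1.17])

    @given(
        g=st.floats(1.0, 50.0),
        erev=st.floats(-30.0, 30.0),
        v=st.floats(-100.0, 100.0),
    )
    def test_noise_free_level_is_exactly_ohmic(self, g, erev, v):
        assert ChannelSpec(g=g, erev=erev).current(v) == pytest.approx(
            g * (v - erev) / 1000.0, abs=1e-12
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec(g=-1.0, erev=0.0)
        with pytest.raises(ValueError):
            ChannelSpec(g=np.nan, erev=0.0)
        with pytest.raises(ValueError):
            AcquisitionSpec(fs=1000.0, fc=1000.0)  # fs must exceed 2*fc


class TestSimulateChannelTrace:
    def test_trace_length_and_finiteness(self, fig1_patch):
        acq = fig1_patch.acquisition
        assert fig1_patch.samples.size == round(acq.fs * acq.duration)
        assert np.all(np.isfinite(fig1_patch.samples))

    def test_same_seed_bit_identical(self):
        acq = AcquisitionSpec(duration=1.0)
        a = simulate_channel_trace(PRESETS["fig1-example"], acq, seed=3)
        b = simulate_channel_trace(PRESETS["fig1-example"], acq, seed=3)
        c = simulate_channel_trace(PRESETS["fig1-example"], acq, seed=4)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_open_fraction_matches_kinetics(self):
        # long noiseless trace: sojourn fraction ~ mean_open/(mean_open+mean_closed)
        spec = ChannelSpec(g=19.0, erev=-11.0, mean_open=5.0, mean_closed=20.0)
        acq = AcquisitionSpec(noise_sd=0.0, duration=60.0, V=80.0)
        tr = simulate_channel_trace([spec], acq, seed=5)
        amp = spec.current(80.0)
        frac = float(np.mean(tr.samples > amp / 2))
        p = spec.p_open
        n_cycles = acq.duration / ((spec.mean_open + spec.mean_closed) / 1000.0)
        se = np.sqrt(p * (1 - p) / n_cycles)
        assert abs(frac - p) < 3 * se

    def test_zero_driving_force_gives_flat_trace(self):
        spec = ChannelSpec(g=19.0, erev=-11.0)
        acq = AcquisitionSpec(noise_sd=0.0, duration=2.0, V=-11.0)
        tr = simulate_channel_trace([spec], acq, seed=1)
        assert np.allclose(tr.samples, 0.0)

    def test_two_channel_noise_free_levels(self):
        # levels restricted to {0, 0.664, 1.729, 2.393} pA
        acq = AcquisitionSpec(noise_sd=0.0, duration=5.0, V=80.0, fc=10_000.0)
        tr = simulate_channel_trace(PRESETS["fig1-example"], acq, seed=2)
        expected = np.array([0.0, 0.6643, 1.729, 2.3933])
        dist = np.min(np.abs(tr.samples[:, None] - expected[None, :]), axis=1)
        # nearly all samples sit on a level; the rest are filter transitions
        assert np.mean(dist < 0.02) > 0.95

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            simulate_channel_trace([], AcquisitionSpec(), seed=0)


class TestPatchProtocol:
    def test_one_trace_per_potential_with_shared_specs(self):
        acq = AcquisitionSpec(duration=0.5)
        patches = simulate_patch_protocol(PRESETS["fig2-P6"], acq, [20, 40, 60, 80], seed=1)
        assert [p.acquisition.V for p in patches] == [20, 40, 60, 80]
        assert all(p.meta["channels"] == PRESETS["fig2-P6"] for p in patches)

    def test_single_potential_rejected(self):
        with pytest.raises(ValueError):
            simulate_patch_protocol(PRESETS["fig2-P6"], AcquisitionSpec(), [80.0], seed=1)


class TestGeneratePopulation:
    def test_noiseless_generation_lies_on_the_sigmoid(self):
        import dataclasses

        prof = dataclasses.replace(
            PROFILES["male_control"], erev_noise_sd=0.0, ages={d: 1 for d in range(5, 37)}
        )
        cells = generate_population(prof, seed=1)
        expected = hill4(cells["age_days"].to_numpy(), *prof.erev_sigmoid)
        np.testing.assert_allclose(cells["erev_mV"].to_numpy(), expected, atol=1e-12)

    def test_sigmoid_midpoint_identity(self):
        # male control Erev sigmoid at X0 = 14.4: Y0 + a/2 = -2.5 mV
        assert hill4(14.4, *PROFILES["male_control"].erev_sigmoid) == pytest.approx(-2.5)

    def test_female_newborn_plateau_mean(self):
        # female control cells at P8-12 average near the +15.8 mV plateau
        import dataclasses

        prof = dataclasses.replace(
            PROFILES["female_control"], erev_noise_sd=3.6, ages={d: 3 for d in range(8, 13)}
        )
        vals = []
        for s in range(40):
            cells = generate_population(prof, seed=s)
            vals.append(cells["erev_mV"].mean())
        assert np.mean(vals) == pytest.approx(15.8, abs=0.8)

    def test_empty_ages_gives_empty_table(self):
        import dataclasses

        prof = dataclasses.replace(PROFILES["male_control"], ages={})
        cells = generate_population(prof, seed=1)
        assert len(cells) == 0
        assert list(cells.columns) == [
            "cell_id", "age_days", "sex", "treatment", "level", "g_pS", "erev_mV",
        ]

    def test_direct_mode_follows_conductance_sigmoid(self):
        import dataclasses

        prof = dataclasses.replace(
            PROFILES["male_control"], cond_noise_sd=0.0, ages={d: 1 for d in range(5, 46)}
        )
        cells = generate_population(prof, seed=1, mode="direct")
        expected = hill4(cells["age_days"].to_numpy(), *prof.cond_sigmoid)
        np.testing.assert_allclose(cells["g_pS"].to_numpy(), expected, atol=1e-12)

    def test_negative_counts_rejected(self):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(PROFILES["male_control"], ages={5: -1})


class TestFiringTrace:
    def test_regular_train_spike_count(self):
        tr = simulate_firing_trace(30.0, 50.0, (20.0, 40.0), effect="none", seed=3,
                                   duration=60.0)
        assert abs(tr.meta["true_spike_times"].size - 1800) <= 2

    def test_full_block_silences_drug_window(self):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 120.0), effect="inhibit", seed=5,
                                   duration=180.0, inhibit_factor=0.0)
        t = tr.meta["true_spike_times"]
        assert np.sum((t >= 60.0) & (t < 120.0)) == 0

    def test_excite_rate_and_amplitude_decay(self):
        tr = simulate_firing_trace(30.0, 50.0, (60.0, 180.0), effect="excite", seed=4,
                                   duration=240.0)
        t = tr.meta["true_spike_times"]
        a = tr.meta["true_spike_amps"]
        drug = (t >= 60.0) & (t < 180.0)
        rate = drug.sum() / 120.0
        assert rate == pytest.approx(96.0, rel=0.05)
        # amplitudes decline monotonically through the drug epoch
        assert np.all(np.diff(a[drug]) <= 1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_firing_trace(-1.0, 50.0, (10.0, 20.0), seed=0, duration=30.0)
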