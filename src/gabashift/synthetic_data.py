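"""Generative models of cell-attached Purkinje-cell recordings.

This module produces every input the analysis pipeline consumes, so the whole
chain — idealization, I-V fitting, level classification, developmental
sigmoid fitting, valence scoring — can be verified by parameter recovery:

* single-channel current traces at one or several command potentials, with
  1-3 independently gating GABA-A channels per patch (two-state Markov
  gating, Ohmic open-level current, Gaussian noise, Gaussian low-pass
  filtering that emulates the analog filter);
* spontaneous-spiking traces with a drug-application epoch (GABA-A agonist
  effects on firing rate and spike amplitude);
* per-cell population tables (age, sex, treatment, conductance, reversal
  potential) whose age dependence follows configurable four-parameter Hill
  sigmoids.

Sign convention: the command potential V is the patch membrane-potential
displacement relative to the resting potential (RP), positive = depolarized;
the single-channel current is ``i = g * (V - Erev) / 1000`` pA and is plotted
positive for a positive driving force.  The pipette-potential sign inversion
of the cell-attached configuration is hidden inside the generator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .devfit import hill4

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSpec",
    "AcquisitionSpec",
    "TracePatch",
    "PopulationProfile",
    "PRESETS",
    "PROFILES",
    "simulate_channel_trace",
    "simulate_patch_protocol",
    "generate_population",
    "simulate_firing_trace",
    "GAUSS_SIGMA_FC",
    "RISE_TIME_FC",
]

# Gaussian low-pass filter: sigma_t * fc for a -3 dB cutoff at fc, and the
# corresponding 10-90% rise time Tr * fc (standard single-channel values).
GAUSS_SIGMA_FC = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi))  # ~0.1325
RISE_TIME_FC = 0.3321


@dataclass(frozen=True)
class ChannelSpec:
    """One GABA-A channel: slope conductance, reversal potential, gating kinetics.

    g : slope conductance, pS.
    erev : reversal potential, mV relative to RP.
    mean_open / mean_closed : mean exponential dwell times, ms.  Cell-attached
    recordings of this kind do not constrain kinetics; the defaults
    (5/20 ms, Po = 0.2) are slow enough that a 1 kHz filter passes most
    events at full amplitude.
    """

    g: float
    erev: float
    mean_open: float = 5.0
    mean_closed: float = 20.0

    def __post_init__(self):
        if not np.isfinite([self.g, self.erev, self.mean_open, self.mean_closed]).all():
            raise ValueError("non-finite channel parameters")
        if self.g <= 0 or self.mean_open <= 0 or self.mean_closed <= 0:
            raise ValueError("g, mean_open and mean_closed must be positive")

    @property
    def p_open(self) -> float:
        return self.mean_open / (self.mean_open + self.mean_closed)

    def current(self, v_mv: float) -> float:
        """Ohmic open-level current i = g*(V - Erev)/1000, in pA."""
        return self.g * (v_mv - self.erev) / 1000.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition settings for one trace.

    fs: sampling rate, Hz (recordings digitized at 50 kHz); fc: low-pass
    cutoff, Hz (1-1.5 kHz analysis filter); noise_sd: per-sample baseline
    noise SD in pA before filtering; duration in s; V: command potential in
    mV relative to RP.
    """

    fs: float = 50_000.0
    fc: float = 1_000.0
    noise_sd: float = 0.15
    duration: float = 10.0
    V: float = 80.0

    def __post_init__(self):
        if not np.isfinite([self.fs, self.fc, self.noise_sd, self.duration, self.V]).all():
            raise ValueError("non-finite acquisition parameters")
        if self.fs <= 2.0 * self.fc:
            raise ValueError(f"sampling rate {self.fs} Hz must exceed 2*fc = {2 * self.fc} Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class TracePatch:
    """A sampled current trace with acquisition metadata and provenance.

    ``samples`` are in pA.  ``meta`` carries provenance (age, sex, treatment,
    cell id) and, for synthetic traces, generator truth: the channel specs
    and per-channel open intervals.
    """

    samples: np.ndarray
    acquisition: AcquisitionSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.acquisition.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.acquisition.fs


# Named single-patch presets with figure-derived conductances (pS) and
# reversal potentials (mV relative to RP).
PRESETS: dict[str, tuple[ChannelSpec, ...]] = {
    "fig1-example": (ChannelSpec(g=19.0, erev=-11.0), ChannelSpec(g=7.3, erev=-11.0)),
    "fig2-P6": (ChannelSpec(g=18.0, erev=15.0),),
    "fig2-P32": (ChannelSpec(g=10.8, erev=-8.0),),
    "fig3-male-P16": (ChannelSpec(g=15.2, erev=-14.0),),
    "fig3-female-P16": (ChannelSpec(g=17.5, erev=4.0),),
}


def _gating_open_mask(
    spec: ChannelSpec, acq: AcquisitionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Simulate one channel's two-state gating; return per-sample open mask
    and the list of true (t_open, t_close) intervals in seconds."""
    mo = spec.mean_open / 1000.0
    mc = spec.mean_closed / 1000.0
    cycle = mo + mc
    # draw dwells in batches until the trace duration is covered
    n_guess = max(16, int(2.5 * acq.duration / cycle) + 16)
    closed = rng.exponential(mc, size=n_guess)
    opened = rng.exponential(mo, size=n_guess)
    t = np.empty(2 * n_guess)
    t[0::2] = closed
    t[1::2] = opened
    edges = np.cumsum(t)
    while edges[-1] < acq.duration:
        extra_c = rng.exponential(mc, size=n_guess)
        extra_o = rng.exponential(mo, size=n_guess)
        t2 = np.empty(2 * n_guess)
        t2[0::2] = extra_c
        t2[1::2] = extra_o
        edges = np.concatenate([edges, edges[-1] + np.cumsum(t2)])
    sample_t = np.arange(acq.n_samples) / acq.fs
    idx = np.searchsorted(edges, sample_t, side="right")
    open_mask = (idx % 2) == 1  # state sequence starts closed
    open_starts = edges[0::2]
    open_ends = edges[1::2]
    keep = open_starts < acq.duration
    events = [
        (float(s), float(min(e, acq.duration)))
        for s, e in zip(open_starts[keep], open_ends[keep])
    ]
    return open_mask, events


def simulate_channel_trace(
    specs, acq: AcquisitionSpec, seed, meta: dict | None = None
) -> TracePatch:
    """Simulate a cell-attached single-channel current trace.

    Each channel in ``specs`` gates independently as a two-state Markov
    process with exponential open/closed dwell times.  The instantaneous
    current is the sum of ``g*(V - Erev)/1000`` over open channels; Gaussian
    noise of SD ``acq.noise_sd`` is added per sample and the trace is then
    low-pass filtered with a Gaussian filter whose -3 dB point equals
    ``acq.fc``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  The true
    channel specs and open intervals are stored in ``meta`` for oracle
    comparisons.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    for s in specs:
        if not isinstance(s, ChannelSpec):
            raise TypeError("specs must be ChannelSpec instances")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    current = np.zeros(acq.n_samples)
    events_per_channel = []
    for spec in specs:
        mask, events = _gating_open_mask(spec, acq, rng)
        current += mask * spec.current(acq.V)
        events_per_channel.append(events)
    if acq.noise_sd > 0:
        current = current + rng.normal(0.0, acq.noise_sd, size=current.size)
    sigma_samples = GAUSS_SIGMA_FC / acq.fc * acq.fs
    current = gaussian_filter1d(current, sigma_samples, mode="nearest")

    m = dict(meta or {})
    m.setdefault("channels", tuple(specs))
    m.setdefault("true_open_intervals", events_per_channel)
    m.setdefault("seed", repr(ss.entropy))
    return TracePatch(samples=current, acquisition=acq, meta=m)


def simulate_patch_protocol(
    specs, acq_base: AcquisitionSpec, potentials, seed, meta: dict | None = None
) -> list[TracePatch]:
    """Simulate one patch recorded at several command potentials.

    The channel specs are shared; the gating realization is independent at
    each potential (separate sweeps).  At least two distinct potentials are
    required for a subsequent I-V regression; duplicates are allowed but
    logged.
    """
    potentials = [float(v) for v in potentials]
    if len(set(potentials)) < 2:
        raise ValueError("need at least 2 distinct potentials for an I-V protocol")
    if len(set(potentials)) < len(potentials):
        logger.warning("duplicate potentials in protocol: %s", potentials)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(potentials))
    patches = []
    for v, child in zip(potentials, children):
        acq = replace(acq_base, V=v)
        m = dict(meta or {})
        m["V_mV"] = v
        patches.append(simulate_channel_trace(specs, acq, child, meta=m))
    return patches


@dataclass(frozen=True)
class PopulationProfile:
    """Developmental profile of one sex x treatment group.

    Sigmoid parameter tuples are ``(a, b, X0, Y0)`` of the four-parameter
    Hill function.  ``level1_dist``/``level2_dist`` are (mean, SD) of the
    high- and low-conductance channel classes in pS; ``p_level1_sigmoid`` is
    on the percent scale and clipped to [0, 100].  ``ages`` maps postnatal
    day to the number of cells recorded that day.
    """

    sex: str
    treatment: str
    erev_sigmoid: tuple[float, float, float, float]
    cond_sigmoid: tuple[float, float, float, float]
    p_level1_sigmoid: tuple[float, float, float, float]
    level1_dist: tuple[float, float] = (17.8, 2.1)
    level2_dist: tuple[float, float] = (10.9, 1.6)
    erev_noise_sd: float = 5.0
    cond_noise_sd: float = 1.5
    ages: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.level1_dist[0] <= self.level2_dist[0]:
            raise ValueError("level 1 mean conductance must exceed level 2 mean")
        if any(n < 0 for n in self.ages.values()):
            raise ValueError("per-day cell counts must be non-negative")

    def with_ages(self, lo: int, hi: int, per_day: int = 2) -> "PopulationProfile":
        return replace(self, ages={d: per_day for d in range(lo, hi + 1)})


def _age_table(lo: int, hi: int, per_day: int = 2) -> dict[int, int]:
    return {d: per_day for d in range(lo, hi + 1)}


# Group profiles anchored to the printed developmental fits.  Valproate
# conductance / %level-1 sigmoids are not printed; the same-sex control
# curves stand in so the table schema stays uniform (only the Erev path is
# used for valproate recovery runs).
_MALE_COND = (6.2, -1.33, 14.7, 11.1)
_FEMALE_COND = (7.8, -3.3, 17.7, 10.5)
_MALE_P1 = (99.0, -1.9, 15.3, 3.2)
_FEMALE_P1 = (100.0, -2.42, 18.5, 0.43)

PROFILES: dict[str, PopulationProfile] = {
    "male_control": PopulationProfile(
        sex="male",
        treatment="control",
        erev_sigmoid=(22.0, -0.31, 14.4, -13.5),
        cond_sigmoid=_MALE_COND,
        p_level1_sigmoid=_MALE_P1,
        ages=_age_table(5, 36),
    ),
    "female_control": PopulationProfile(
        sex="female",
        treatment="control",
        erev_sigmoid=(24.2, -1.25, 18.5, -8.3),
        cond_sigmoid=_FEMALE_COND,
        p_level1_sigmoid=_FEMALE_P1,
        ages=_age_table(8, 36),
    ),
    "male_valproate": PopulationProfile(
        sex="male",
        treatment="valproate",
        erev_sigmoid=(21.0, -0.16, 17.7, -8.0),
        cond_sigmoid=_MALE_COND,
        p_level1_sigmoid=_MALE_P1,
        ages=_age_table(10, 30),
    ),
    "female_valproate": PopulationProfile(
        sex="female",
        treatment="valproate",
        erev_sigmoid=(17.0, -0.28, 23.0, -5.0),
        cond_sigmoid=_FEMALE_COND,
        p_level1_sigmoid=_FEMALE_P1,
        ages=_age_table(6, 30),
    ),
}


def generate_population(
    profile: PopulationProfile, seed, mode: str = "mixture"
) -> pd.DataFrame:
    """Generate a per-cell population table for one group.

    Per cell at age X:

    * ``mode="mixture"`` — the cell's dominant channel is level 1 with
      probability ``p_level1_sigmoid(X)/100`` (clipped to [0, 100]); its
      conductance is drawn from the corresponding level Gaussian.
    * ``mode="direct"`` — the conductance follows the conductance-vs-age
      sigmoid directly, ``g = cond_sigmoid(X) + N(0, cond_noise_sd)``; the
      level column is the >= 14 pS classification of the draw.

    In both modes ``Erev = erev_sigmoid(X) + N(0, erev_noise_sd)``.

    Returns a DataFrame with columns
    ``cell_id, age_days, sex, treatment, level, g_pS, erev_mV``.
    """
    if mode not in ("mixture", "direct"):
        raise ValueError(f"unknown mode {mode!r}; use 'mixture' or 'direct'")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    rows = []
    cell = 0
    for age in sorted(profile.ages):
        for _ in range(profile.ages[age]):
            erev = hill4(age, *profile.erev_sigmoid) + rng.normal(0, profile.erev_noise_sd)
            if mode == "mixture":
                p1 = float(np.clip(hill4(age, *profile.p_level1_sigmoid), 0.0, 100.0))
                is_l1 = rng.random() < p1 / 100.0
                mu, sd = profile.level1_dist if is_l1 else profile.level2_dist
                g = rng.normal(mu, sd)
                level = 1 if is_l1 else 2
            else:
                g = hill4(age, *profile.cond_sigmoid) + rng.normal(0, profile.cond_noise_sd)
                level = 1 if g >= 14.0 else 2
            rows.append(
                {
                    "cell_id": f"{profile.sex[0]}{profile.treatment[0]}{cell:04d}",
                    "age_days": int(age),
                    "sex": profile.sex,
                    "treatment": profile.treatment,
                    "level": level,
                    "g_pS": float(g),
                    "erev_mV": float(erev),
                }
            )
            cell += 1
    columns = ["cell_id", "age_days", "sex", "treatment", "level", "g_pS", "erev_mV"]
    return pd.DataFrame(rows, columns=columns)


def _spike_waveform(fs: float, width_ms: float = 2.0) -> np.ndarray:
    """Biphasic unit-amplitude spike: one sine cycle (positive lobe first)."""
    n = max(4, int(round(width_ms / 1000.0 * fs)))
    t = np.arange(n) / n
    return np.sin(2.0 * np.pi * t)


def simulate_firing_trace(
    rate_hz: float,
    spike_amp_pA: float,
    drug_window: tuple[float, float],
    effect: str = "none",
    seed=0,
    duration: float | None = None,
    fs: float = 10_000.0,
    noise_sd: float | None = None,
    excite_factor: float = 3.2,
    inhibit_factor: float = 0.25,
    silent_lead_s: float = 10.0,
    jitter_frac: float = 0.1,
    amp_floor_frac: float = 0.35,
) -> TracePatch:
    """Simulate a cell-attached spiking trace with a drug-application epoch.

    The baseline is a near-regular spike train at ``rate_hz`` (inter-spike
    interval jittered by ``jitter_frac``).  During ``drug_window``:

    * ``excite`` — the rate is multiplied by ``excite_factor`` (default 3.2,
      a +220% frequency increase) and the spike amplitude decays
      exponentially toward a floor of ``amp_floor_frac`` of the baseline
      amplitude, emulating progressive sodium-channel inactivation under
      strong depolarization (spikes shrink but remain visible);
    * ``inhibit`` — the rate is multiplied by ``inhibit_factor`` (default
      0.25, a 75% block) with no amplitude change; a factor of 0 silences
      the cell completely;
    * ``inhibit_then_excite`` — a ``silent_lead_s`` silent period precedes
      the excitation;
    * ``none`` — statistics unchanged.

    Washout restores baseline statistics.  True spike times/amplitudes are
    stored in ``meta`` for detector validation.
    """
    if rate_hz < 0:
        raise ValueError("rate_hz must be >= 0")
    if effect not in ("none", "excite", "inhibit", "inhibit_then_excite"):
        raise ValueError(f"unknown effect {effect!r}")
    d0, d1 = float(drug_window[0]), float(drug_window[1])
    if duration is None:
        duration = d1 + d0  # symmetric washout by default
    if not (0 <= d0 < d1 <= duration):
        raise ValueError("drug_window must lie within the trace duration")
    if noise_sd is None:
        noise_sd = 0.05 * spike_amp_pA
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )

    # (start, end, rate, amplitude profile) epochs
    epochs: list[tuple[float, float, float, str]] = []
    if effect == "excite":
        epochs = [(0, d0, rate_hz, "flat"), (d0, d1, rate_hz * excite_factor, "decay"),
                  (d1, duration, rate_hz, "flat")]
    elif effect == "inhibit":
        epochs = [(0, d0, rate_hz, "flat"), (d0, d1, rate_hz * inhibit_factor, "flat"),
                  (d1, duration, rate_hz, "flat")]
    elif effect == "inhibit_then_excite":
        lead = min(silent_lead_s, d1 - d0)
        epochs = [(0, d0, rate_hz, "flat"), (d0, d0 + lead, 0.0, "flat"),
                  (d0 + lead, d1, rate_hz * excite_factor, "decay"),
                  (d1, duration, rate_hz, "flat")]
    else:
        epochs = [(0, duration, rate_hz, "flat")]

    spike_times: list[float] = []
    spike_amps: list[float] = []
    decay_tau = max((d1 - d0) / 2.0, 1e-6)
    for start, end, rate, profile in epochs:
        if rate <= 0 or end <= start:
            continue
        isi = 1.0 / rate
        n = int(np.floor((end - start) * rate))
        base_t = start + (np.arange(n) + 0.5) * isi
        t = base_t + rng.normal(0, jitter_frac * isi, size=n)
        t = np.sort(np.clip(t, start, end - 1e-9))
        for ti in t:
            if profile == "decay":
                frac = amp_floor_frac + (1.0 - amp_floor_frac) * float(
                    np.exp(-(ti - start) / decay_tau)
                )
                amp = spike_amp_pA * frac
            else:
                amp = spike_amp_pA
            spike_times.append(float(ti))
            spike_amps.append(amp)

    n_samples = int(round(fs * duration))
    trace = rng.normal(0.0, noise_sd, size=n_samples)
    wf = _spike_waveform(fs)
    for ti, amp in zip(spike_times, spike_amps):
        i0 = int(round(ti * fs))
        i1 = min(i0 + wf.size, n_samples)
        if i0 < n_samples:
            trace[i0:i1] += amp * wf[: i1 - i0]

    acq = AcquisitionSpec(fs=fs, fc=fs / 4.0, noise_sd=noise_sd, duration=duration, V=0.0)
    meta = {
        "kind": "firing",
        "effect": effect,
        "rate_hz": rate_hz,
        "spike_amp_pA": spike_amp_pA,
        "drug_window": (d0, d1),
        "true_spike_times": np.asarray(spike_times),
        "true_spike_amps": np.asarray(spike_amps),
    }
    return TracePatch(samples=trace, acquisition=acq, meta=meta)
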