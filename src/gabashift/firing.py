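"""Spike detection and drug-effect valence scoring for cell-attached firing traces.

A GABA-A agonist applied to a spontaneously firing Purkinje cell either
increases firing (when the GABA-A reversal potential is depolarized relative
to rest) or inhibits it (when hyperpolarized).  Each cell's response is
summarized as a valence: +1 for excitation, +0.5 for excitation preceded by
a brief inhibition, 0 for no effect, -1 for inhibition; cells silent at
baseline are excluded.  The mean valence per age bin traces the
developmental excitatory-to-inhibitory switch of GABAergic signalling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .synthetic_data import TracePatch

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "DrugEffect",
    "detect_spikes",
    "drug_effect",
    "assign_valence",
    "mean_valence_by_age",
]

VALENCES = (-1.0, 0.0, 0.5, 1.0)


@dataclass
class SpikeTrain:
    """Detected spikes: strictly increasing times (s) and amplitudes (pA)."""

    spike_times: np.ndarray
    spike_amplitudes: np.ndarray
    meta: dict = field(default_factory=dict)

    def rate_in(self, t0: float, t1: float) -> float:
        if t1 <= t0:
            raise ValueError("window must have positive length")
        n = int(np.sum((self.spike_times >= t0) & (self.spike_times < t1)))
        return n / (t1 - t0)


@dataclass
class DrugEffect:
    """Quantified drug effect on one cell's firing."""

    freq_change: float | None  # (rate_drug - rate_base)/rate_base; None if silent
    transient_inhibition: bool
    amp_trend: float  # fractional amplitude change per minute during drug
    reversible: bool
    silent_at_baseline: bool = False
    rates: dict = field(default_factory=dict)


def detect_spikes(trace: TracePatch, threshold_sd: float = 5.0) -> SpikeTrain:
    """Peak detection of action-potential capacitive spikes.

    Peaks above ``threshold_sd`` x a robust (MAD-based) noise estimate, with
    a 2 ms refractory distance; amplitude is the peak value minus the local
    baseline (median in a +/- 25 ms window).  Requires >= 10 s of trace.
    """
    x = trace.samples
    fs = trace.acquisition.fs
    if trace.duration < 10.0:
        raise ValueError("need at least 10 s of trace for spike statistics")
    top = np.max(np.abs(x))
    if top > 0 and np.mean(np.abs(x) >= 0.999 * top) > 0.01:
        raise ValueError("saturated trace")
    baseline = float(np.median(x))
    noise = float(1.4826 * np.median(np.abs(x - baseline)))
    if noise <= 0:
        noise = float(np.std(x)) or 1e-12
    height = threshold_sd * noise
    peaks, _ = signal.find_peaks(x - baseline, height=height,
                                 distance=max(1, int(round(0.002 * fs))))
    half_win = int(round(0.025 * fs))
    amps = np.empty(peaks.size)
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - half_win), min(x.size, p + half_win)
        local = float(np.median(x[lo:hi]))
        amps[j] = x[p] - local
    return SpikeTrain(
        spike_times=peaks / fs,
        spike_amplitudes=amps,
        meta={"threshold_pA": height, "noise_sd": noise, "baseline": baseline},
    )


def drug_effect(
    train: SpikeTrain,
    baseline_window: tuple[float, float],
    drug_window: tuple[float, float],
    washout_window: tuple[float, float],
) -> DrugEffect:
    """Quantify the agonist effect on firing frequency and spike amplitude.

    A cell whose baseline rate is below 0.05 Hz (fewer than ~3 events per
    minute, indistinguishable from detector false alarms) is returned as
    silent-at-baseline; no valence is assigned to it downstream.

    ``freq_change = (rate_drug - rate_base)/rate_base``; transient inhibition
    is flagged when the first 20% of the drug window runs below half the
    baseline rate while the remainder exceeds baseline; the effect is
    reversible when the washout rate is within 25% of baseline.  The
    amplitude trend is the fractional amplitude slope per minute during the
    drug.
    """
    wins = [tuple(map(float, w)) for w in (baseline_window, drug_window, washout_window)]
    for t0, t1 in wins:
        if t1 - t0 < 30.0:
            raise ValueError("each analysis window must be at least 30 s")
    for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
        if b0 < a1:
            raise ValueError("windows must be ordered and non-overlapping")
    (b0, b1), (d0, d1), (w0, w1) = wins

    rate_base = train.rate_in(b0, b1)
    rate_drug = train.rate_in(d0, d1)
    rate_wash = train.rate_in(w0, w1)
    rates = {"baseline": rate_base, "drug": rate_drug, "washout": rate_wash}

    if rate_base < 0.05:
        logger.info("cell silent at baseline; excluded from valence scoring")
        return DrugEffect(freq_change=None, transient_inhibition=False, amp_trend=0.0,
                          reversible=False, silent_at_baseline=True, rates=rates)

    freq_change = (rate_drug - rate_base) / rate_base
    split = d0 + 0.2 * (d1 - d0)
    early = train.rate_in(d0, split)
    late = train.rate_in(split, d1)
    transient = bool(early < 0.5 * rate_base and late > rate_base)
    reversible = bool(abs(rate_wash - rate_base) / rate_base <= 0.25)

    sel = (train.spike_times >= d0) & (train.spike_times < d1)
    amp_trend = 0.0
    if sel.sum() >= 3:
        base_sel = (train.spike_times >= b0) & (train.spike_times < b1)
        ref = float(np.mean(train.spike_amplitudes[base_sel])) if base_sel.any() else float(
            np.mean(train.spike_amplitudes[sel]))
        if ref > 0:
            lr = stats.linregress(train.spike_times[sel],
                                  train.spike_amplitudes[sel] / ref)
            amp_trend = float(lr.slope * 60.0)
    return DrugEffect(freq_change=float(freq_change), transient_inhibition=transient,
                      amp_trend=amp_trend, reversible=reversible, rates=rates)


def assign_valence(effect: DrugEffect, no_effect_band: float = 0.15) -> float | None:
    """Valence of the drug effect: +1 excite, +0.5 transient inhibition then
    excitation, 0 no effect, -1 inhibit; None for cells silent at baseline.

    ``no_effect_band`` is the fractional frequency-change magnitude treated
    as no effect (default +/-15%).
    """
    if effect.silent_at_baseline or effect.freq_change is None:
        return None
    fc = effect.freq_change
    if fc > no_effect_band:
        return 0.5 if effect.transient_inhibition else 1.0
    if fc < -no_effect_band:
        return -1.0
    return 0.0


def mean_valence_by_age(valence_records: pd.DataFrame, bins) -> pd.DataFrame:
    """Mean valence per age bin, separately by sex.

    ``valence_records`` needs ``age``, ``sex`` and ``valence`` columns
    (valence in {-1, 0, +0.5, +1}; rows with missing valence are dropped).
    Empty bins are omitted.  Returns columns
    ``sex, bin_lo, bin_hi, n, mean_valence``.
    """
    df = valence_records.dropna(subset=["valence"])
    bad = set(df["valence"].unique()) - set(VALENCES)
    if bad:
        raise ValueError(f"inadmissible valence values: {sorted(bad)}")
    rows = []
    for sex in sorted(df["sex"].unique()):
        sub = df[df["sex"] == sex]
        for lo, hi in bins:
            sel = (sub["age"] >= lo) & (sub["age"] <= hi)
            if not sel.any():
                continue
            vals = sub.loc[sel, "valence"].to_numpy(dtype=float)
            rows.append({"sex": sex, "bin_lo": int(lo), "bin_hi": int(hi),
                         "n": int(vals.size), "mean_valence": float(np.mean(vals))})
    return pd.DataFrame(rows, columns=["sex", "bin_lo", "bin_hi", "n", "mean_valence"])
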