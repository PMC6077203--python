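"""Single-channel trace idealization and amplitude-distribution decomposition.

A filtered cell-attached trace is reduced to an alternating sequence of
closed/open segments ("idealization") by half-amplitude thresholding: the
conductance levels present in the patch are located as peaks of the
all-points amplitude histogram, each sample is assigned to the nearest level
(the decision boundaries are the half-amplitude points between adjacent
levels), and sojourns shorter than the filter dead time are removed.  The
per-event amplitudes are then decomposed into Gaussian components, which is
how the two conductance classes of the GABA-A channel manifest in an
amplitude histogram.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, median_filter
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .synthetic_data import RISE_TIME_FC, TracePatch

logger = logging.getLogger(__name__)

__all__ = [
    "IdealizedEvents",
    "AmplitudeMixture",
    "estimate_baseline",
    "idealize_trace",
    "fit_amplitude_mixture",
    "test_double_opening",
]

# histogram binning: Freedman-Diaconis with a floor (pA)
_BIN_FLOOR = 0.02


@dataclass
class IdealizedEvents:
    """Idealization result: contiguous segments and the baseline level.

    ``segments`` is an ordered list of ``(start_s, end_s, state, amplitude_pA)``
    where ``state`` is ``"closed"`` or ``"open_k"`` (k = 1 for the lowest
    conducting level) and ``amplitude_pA`` is the mean within-segment current
    relative to baseline.
    """

    segments: list[tuple[float, float, str, float]]
    baseline: float
    low_confidence: bool = False
    meta: dict = field(default_factory=dict)

    def open_events(self) -> list[tuple[float, float, str, float]]:
        return [s for s in self.segments if s[2] != "closed"]

    def open_amplitudes(self) -> np.ndarray:
        return np.asarray([s[3] for s in self.segments if s[2] != "closed"])

    def open_fraction(self) -> float:
        tot = sum(e - s for s, e, _, _ in self.segments)
        if tot == 0:
            return 0.0
        op = sum(e - s for s, e, st, _ in self.segments if st != "closed")
        return op / tot

    def open_time_by_state(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, e, st, _ in self.segments:
            if st != "closed":
                out[st] = out.get(st, 0.0) + (e - s)
        return out


@dataclass
class AmplitudeMixture:
    """Gaussian decomposition of an amplitude (or conductance) sample.

    ``components`` is ordered by increasing peak; each entry is
    ``(peak, sd, weight)``.  ``goodness`` is the BIC of the selected model.
    """

    components: list[tuple[float, float, float]]
    k: int
    goodness: float

    @property
    def peaks(self) -> np.ndarray:
        return np.asarray([c[0] for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.asarray([c[2] for c in self.components])


def _samples_of(trace) -> np.ndarray:
    if isinstance(trace, TracePatch):
        return trace.samples
    return np.asarray(trace, dtype=float)


def _histogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-points histogram with Freedman-Diaconis binning, floored at 0.02 pA."""
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    h = 2.0 * iqr / x.size ** (1.0 / 3.0) if iqr > 0 else 0.0
    h = max(h, _BIN_FLOOR)
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bins = max(4, int(np.ceil((hi - lo) / h)))
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def estimate_baseline(trace) -> float:
    """Closed-channel current level: the mode of the all-points histogram.

    The dominant histogram peak is the closed level whenever the patch is
    open less than ~50% of the time.  The coarse mode is refined to the mean
    of the samples in a +/- 2-bin window around it.  An exact tie between two
    modes resolves to the level nearer zero (logged).
    """
    x = _samples_of(trace)
    if x.size == 0:
        raise ValueError("empty trace")
    counts, centers = _histogram(x)
    top = counts.max()
    modes = np.flatnonzero(counts == top)
    if modes.size > 1:
        logger.warning("tied histogram modes at %s; choosing level nearest zero",
                       centers[modes])
        mode_idx = modes[np.argmin(np.abs(centers[modes]))]
    else:
        mode_idx = int(modes[0])
    binw = centers[1] - centers[0] if centers.size > 1 else _BIN_FLOOR
    sel = np.abs(x - centers[mode_idx]) <= 2.0 * binw
    return float(np.mean(x[sel])) if sel.any() else float(centers[mode_idx])


def _noise_sd(x: np.ndarray, baseline: float) -> float:
    """Robust baseline noise SD from the sub-baseline half of the samples.

    Openings only deflect the trace toward positive driving force, so
    samples below baseline are pure noise; for a half-normal the SD is
    1.4826 * median(|x - baseline|).
    """
    below = x[x < baseline]
    if below.size < 10:
        return float(1.4826 * np.median(np.abs(x - baseline)))
    return float(1.4826 * np.median(baseline - below))


def _detect_levels(x: np.ndarray, baseline: float, noise: float) -> list[float]:
    """Open-level amplitudes (relative to baseline) from all-points histogram peaks."""
    counts, centers = _histogram(x)
    smoothed = gaussian_filter1d(counts, 1.0, mode="nearest")
    min_sep_bins = 1
    if centers.size > 1:
        binw = centers[1] - centers[0]
        min_sep_bins = max(1, int(round(2.0 * noise / binw)))
    peaks, _ = signal.find_peaks(
        smoothed,
        prominence=max(5.0, 0.002 * smoothed.max()),
        distance=min_sep_bins,
    )
    amps = centers[peaks] - baseline
    amps = sorted(a for a in amps if a > max(3.0 * noise, _BIN_FLOOR))
    return [float(a) for a in amps]


def idealize_trace(
    trace: TracePatch,
    min_dwell_ms: float | None = None,
    expected_amp: float | None = None,
) -> IdealizedEvents:
    """Half-amplitude threshold idealization of a filtered trace.

    When ``expected_amp`` is given, a single open level at that amplitude is
    assumed and a sample is open when it crosses ``baseline + expected_amp/2``.
    Otherwise all prominent open levels are located in the all-points
    histogram and each sample is assigned to the nearest level — the decision
    boundaries are the half-amplitude points between adjacent levels, which
    keeps simultaneous openings of two channels out of the single-level
    amplitude statistics.

    Sojourns shorter than ``min_dwell_ms`` (default 1.5 x the Gaussian-filter
    rise time ``0.3321/fc``) are unresolvable at the analysis bandwidth and
    are removed with a median filter on the state sequence.  Per-event
    amplitude is the mean of within-event samples (one rise time trimmed from
    each edge when the event is long enough) minus baseline.

    A trace with no threshold crossings yields an empty open-event list; an
    expected amplitude below twice the noise estimate flags the result
    low-confidence.
    """
    x = trace.samples
    fs = trace.acquisition.fs
    fc = trace.acquisition.fc
    if x.size == 0:
        raise ValueError("empty trace")
    if min_dwell_ms is None:
        min_dwell_ms = 1.5 * RISE_TIME_FC / fc * 1000.0

    baseline = estimate_baseline(x)
    noise = _noise_sd(x, baseline)

    if expected_amp is not None:
        if expected_amp <= 0:
            raise ValueError("expected_amp must be positive")
        levels = [float(expected_amp)]
    else:
        levels = _detect_levels(x, baseline, noise)

    low_conf = bool(levels) and (min(levels) < 2.0 * noise)
    if low_conf:
        logger.warning(
            "low SNR: smallest level %.3g pA < 2x noise estimate %.3g pA", min(levels), noise
        )

    if not levels:
        seg = [(0.0, x.size / fs, "closed", 0.0)]
        return IdealizedEvents(segments=seg, baseline=baseline, low_confidence=False,
                               meta={"levels": [], "noise_sd": noise})

    # nearest-level assignment via half-amplitude boundaries
    centers = np.concatenate([[0.0], np.asarray(levels)])
    boundaries = 0.5 * (centers[:-1] + centers[1:])
    state_idx = np.searchsorted(boundaries, x - baseline, side="right")

    min_samples = int(round(min_dwell_ms / 1000.0 * fs))
    if min_samples >= 3:
        k = min_samples if min_samples % 2 == 1 else min_samples + 1
        state_idx = median_filter(state_idx, size=k, mode="nearest")

    # run-length encode, then merge residual sub-dwell runs into neighbours
    change = np.flatnonzero(np.diff(state_idx)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [state_idx.size]])
    states = state_idx[starts]
    if min_samples >= 1 and starts.size > 1:
        keep_s, keep_e, keep_st = [int(starts[0])], [int(ends[0])], [int(states[0])]
        for s, e, st in zip(starts[1:], ends[1:], states[1:]):
            if e - s < min_samples:
                keep_e[-1] = int(e)  # absorb into previous segment
            elif st == keep_st[-1]:
                keep_e[-1] = int(e)
            else:
                keep_s.append(int(s))
                keep_e.append(int(e))
                keep_st.append(int(st))
        starts, ends, states = np.asarray(keep_s), np.asarray(keep_e), np.asarray(keep_st)

    trim = int(round(RISE_TIME_FC / fc * fs))
    segments: list[tuple[float, float, str, float]] = []
    for s, e, st in zip(starts, ends, states):
        if e - s > 3 * trim:
            seg_mean = float(np.mean(x[s + trim : e - trim]))
        else:
            seg_mean = float(np.mean(x[s:e]))
        name = "closed" if st == 0 else f"open_{int(st)}"
        segments.append((s / fs, e / fs, name, seg_mean - baseline))

    return IdealizedEvents(
        segments=segments,
        baseline=baseline,
        low_confidence=low_conf,
        meta={"levels": levels, "noise_sd": noise, "min_dwell_ms": min_dwell_ms},
    )


def _seeded_means(x: np.ndarray, k: int) -> np.ndarray:
    """Quantile-spread initial means (peak-seeded when the histogram allows)."""
    qs = (np.arange(k) + 0.5) / k
    return np.quantile(x, qs).reshape(-1, 1)


def fit_amplitude_mixture(
    amplitudes, k_max: int = 3, k: int | None = None, random_state: int = 0
) -> AmplitudeMixture:
    """Gaussian-mixture decomposition of event amplitudes (or conductances).

    Fits k = 1..k_max component mixtures with quantile-seeded means and
    selects k by BIC (ties resolve toward smaller k).  Pass ``k`` to force a
    fixed component count (used by the two-level conductance model).  The
    component count is capped so each component has at least 10 observations.

    Raises ``ValueError`` for fewer than 20 observations or a degenerate
    (zero-spread) sample.
    """
    x = np.asarray(amplitudes, dtype=float).ravel()
    if x.size < 20:
        raise ValueError(f"need >= 20 observations for a mixture fit, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite amplitudes")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate (constant) amplitude sample")

    cap = max(1, x.size // 10)
    if k is not None:
        ks = [min(int(k), cap)]
        if ks[0] < k:
            logger.warning("capping mixture components at %d (n=%d)", ks[0], x.size)
    else:
        ks = list(range(1, min(k_max, cap) + 1))

    X = x.reshape(-1, 1)
    best: tuple[float, GaussianMixture] | None = None
    import warnings

    for kk in ks:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=kk,
                means_init=_seeded_means(x, kk),
                random_state=random_state,
                reg_covar=1e-6,
                max_iter=500,
            ).fit(X)
        if not gm.converged_ and kk > 1:
            logger.warning("mixture with k=%d did not converge; skipping", kk)
            continue
        bic = gm.bic(X)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, gm)
    if best is None:
        raise RuntimeError("no mixture model converged")
    bic, gm = best
    order = np.argsort(gm.means_.ravel())
    comps = [
        (float(gm.means_.ravel()[i]), float(np.sqrt(gm.covariances_.ravel()[i])),
         float(gm.weights_[i]))
        for i in order
    ]
    return AmplitudeMixture(components=comps, k=len(comps), goodness=float(bic))


def test_double_opening(peak_low: float, peak_high: float, tol: float = 0.10) -> str:
    """Decide whether a higher amplitude peak is a distinct conductance level
    or the stacked simultaneous opening of two lower-level channels.

    Returns ``"stacked_openings"`` when the high peak is within ``tol``
    relative deviation of twice the low peak, else ``"distinct_level"``.
    """
    if peak_low <= 0 or peak_high <= 0:
        raise ValueError("peaks must be positive")
    if peak_high <= peak_low:
        raise ValueError("peak_high must exceed peak_low")
    dev = abs(peak_high - 2.0 * peak_low) / (2.0 * peak_low)
    return "stacked_openings" if dev <= tol else "distinct_level"
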