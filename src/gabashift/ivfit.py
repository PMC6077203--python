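"""Current-voltage regression: slope conductance and reversal potential.

Each conductance level in a patch yields one (V, i) point per command
potential — the open-level amplitude at that potential.  An ordinary
least-squares line through those points gives the slope conductance
``g = 1000 * slope`` (pA/mV -> pS) and the reversal potential as the
x-intercept ``Erev = -intercept/slope``, extrapolated beyond the sampled
potentials when necessary.  All potentials are relative to the resting
potential (RP); the absolute membrane potential is never needed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["ChannelFit", "fit_iv", "fit_iv_shared", "predict_current", "patch_dominant_channel"]


@dataclass
class ChannelFit:
    """I-V fit of one conductance level in one patch.

    points: the fitted (V mV relative to RP, i pA) pairs.
    g: slope conductance, pS.  erev: reversal potential, mV relative to RP.
    r2: coefficient of determination.  level_label: the idealization state
    this level corresponds to (assigned by the pipeline).
    """

    points: list[tuple[float, float]]
    g: float
    erev: float
    r2: float
    level_label: str | None = None
    g_se: float = np.nan
    erev_se: float = np.nan
    meta: dict = field(default_factory=dict)


def predict_current(g: float, erev: float, V):
    """Ohmic single-channel current ``i = g*(V - Erev)/1000`` in pA.

    ``g`` in pS, potentials in mV relative to RP.  Vectorized over ``V``.
    """
    if g <= 0:
        raise ValueError("conductance must be positive")
    V = np.asarray(V, dtype=float)
    out = g * (V - erev) / 1000.0
    return float(out) if out.ndim == 0 else out


def fit_iv(points) -> ChannelFit:
    """Ordinary least-squares I-V line through (V, i) points.

    Requires at least two distinct potentials and finite amplitudes.  A
    non-positive slope is rejected as non-physical for these recordings
    (channel current increases with driving force under the sign convention
    used here).
    """
    pts = [(float(v), float(i)) for v, i in points]
    v = np.asarray([p[0] for p in pts])
    i = np.asarray([p[1] for p in pts])
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(i))):
        raise ValueError("non-finite I-V points")
    if np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct potentials to fit an I-V line")
    res = stats.linregress(v, i)
    if res.slope <= 0:
        raise ValueError(f"non-physical I-V slope {res.slope:.4g} pA/mV (must be > 0)")
    g = 1000.0 * res.slope
    erev = -res.intercept / res.slope
    r2 = 1.0 if v.size == 2 else float(res.rvalue**2)
    g_se = 1000.0 * res.stderr if res.stderr is not None else np.nan
    # delta-method SE for the x-intercept
    if res.stderr and res.intercept_stderr and res.slope != 0:
        erev_se = float(
            abs(erev)
            * np.sqrt(
                (res.intercept_stderr / res.intercept) ** 2 + (res.stderr / res.slope) ** 2
            )
            if res.intercept != 0
            else res.intercept_stderr / res.slope
        )
    else:
        erev_se = np.nan
    return ChannelFit(points=pts, g=float(g), erev=float(erev), r2=r2,
                      g_se=float(g_se), erev_se=erev_se)


def fit_iv_shared(points_by_level) -> list[ChannelFit]:
    """Joint I-V fit of several levels constrained to a common reversal potential.

    Model: ``i_k = g_k * (V - e) / 1000`` with one shared ``e``.  For a fixed
    ``e`` the per-level conductances have a closed form, so the fit profiles
    the residual over ``e`` with a scalar minimizer.  Offered because two
    levels recorded in the same patch share ionic selectivity and may be
    fitted with a single reversal potential.
    """
    data = [
        (np.asarray([p[0] for p in pts], dtype=float),
         np.asarray([p[1] for p in pts], dtype=float))
        for pts in points_by_level
    ]
    if not data:
        raise ValueError("no levels to fit")
    for v, _ in data:
        if np.unique(v).size < 2:
            raise ValueError("each level needs at least 2 distinct potentials")

    def rss(e: float) -> float:
        total = 0.0
        for v, i in data:
            d = v - e
            denom = np.sum(d * d)
            slope = np.sum(i * d) / denom if denom > 0 else 0.0
            total += float(np.sum((i - slope * d) ** 2))
        return total

    v_all = np.concatenate([v for v, _ in data])
    lo, hi = float(v_all.min()) - 200.0, float(v_all.max()) + 200.0
    res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded")
    e = float(res.x)
    fits = []
    for (v, i), pts in zip(data, points_by_level):
        d = v - e
        slope = float(np.sum(i * d) / np.sum(d * d))
        if slope <= 0:
            raise ValueError("non-physical slope in shared-reversal fit")
        pred = slope * d
        ss_res = float(np.sum((i - pred) ** 2))
        ss_tot = float(np.sum((i - i.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fits.append(
            ChannelFit(points=[(float(a), float(b)) for a, b in pts], g=1000.0 * slope,
                       erev=e, r2=r2, meta={"shared_erev": True})
        )
    return fits


def patch_dominant_channel(channel_fits, events) -> ChannelFit:
    """The fit of the level carrying the largest total open time in the patch.

    ``events`` is an ``IdealizedEvents`` (or an iterable of them, one per
    potential); open time is summed per state and matched to each fit's
    ``level_label``.  An exact tie resolves to the larger conductance, with a
    warning.
    """
    fits = list(channel_fits)
    if not fits:
        raise ValueError("no channel fits")
    if len(fits) == 1:
        return fits[0]

    ev_list = events if isinstance(events, (list, tuple)) else [events]
    open_time: dict[str, float] = {}
    for ev in ev_list:
        for state, t in ev.open_time_by_state().items():
            open_time[state] = open_time.get(state, 0.0) + t

    def key(f: ChannelFit) -> tuple[float, float]:
        t = open_time.get(f.level_label, 0.0) if f.level_label else 0.0
        return (t, f.g)

    ranked = sorted(fits, key=key, reverse=True)
    best, second = ranked[0], ranked[1]
    t_best = open_time.get(best.level_label, 0.0) if best.level_label else 0.0
    t_second = open_time.get(second.level_label, 0.0) if second.level_label else 0.0
    if t_best == t_second:
        logger.warning(
            "tie in total open time (%.3g s); choosing larger conductance %.3g pS",
            t_best, best.g,
        )
    return best
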