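"""Two-level conductance classification of pooled GABA-A channels.

Pooled slope conductances across cells fall into two Gaussian classes: a
high-conductance "level 1" (~17-18 pS, dominant in newborns) and a
low-conductance "level 2" (~10-11 pS, dominant in young adults).  The
classification threshold is the point between the two fitted means where the
weighted component densities are equal (closed-form quadratic); operationally
channels with g >= 14 pS are level 1 and g < 14 pS are level 2.  The
developmental disappearance of level 1 is summarized as the percent of
level-1 channels per age bin, and the "drop age" is the first bin where that
percentage falls below 50%.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .idealize import fit_amplitude_mixture

logger = logging.getLogger(__name__)

__all__ = [
    "LevelModel",
    "DEFAULT_THRESHOLD_PS",
    "HIGH_CONDUCTANCE_CUTOFF_PS",
    "fit_level_model",
    "intersection_threshold",
    "classify_level",
    "percent_level1_by_age",
    "default_age_bins",
]

#: operational classification limit between levels 1 and 2, pS
DEFAULT_THRESHOLD_PS = 14.0
#: conductances above this belong to a rare third class and are excluded
#: from the two-component fit
HIGH_CONDUCTANCE_CUTOFF_PS = 22.0


@dataclass
class LevelModel:
    """Two-Gaussian conductance model with its classification threshold.

    ``level1``/``level2`` are (mean pS, sd pS) of the high and low class;
    ``weights`` are (w_level1, w_level2); ``threshold`` is the density
    intersection between the two means.  ``n_high`` counts excluded
    high-conductance (> 22 pS) outliers.
    """

    level1: tuple[float, float]
    level2: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    n_high: int = 0

    def __post_init__(self):
        if not (self.level1[0] > self.threshold > self.level2[0]):
            raise ValueError(
                f"threshold {self.threshold:.3g} pS not between the level means "
                f"{self.level2[0]:.3g} and {self.level1[0]:.3g}"
            )


def intersection_threshold(gauss1, gauss2) -> float:
    """Conductance where two weighted Gaussian densities are equal.

    ``gauss1``/``gauss2`` are ``(mean, sd)`` or ``(mean, sd, weight)``
    (weight defaults to 0.5).  Solves the quadratic obtained by equating the
    log densities and returns the root strictly between the two means; if no
    crossing lies between the means (extreme weight imbalance) a ValueError
    with diagnostics is raised.
    """
    m1, s1, w1 = (*gauss1, 0.5)[:3]
    m2, s2, w2 = (*gauss2, 0.5)[:3]
    if s1 <= 0 or s2 <= 0 or w1 <= 0 or w2 <= 0:
        raise ValueError("sds and weights must be positive")
    if m1 == m2:
        raise ValueError("identical means: no unique intersection")
    lo, hi = min(m1, m2), max(m1, m2)
    # log(w1) - log(s1) - (x-m1)^2/(2 s1^2) = log(w2) - log(s2) - (x-m2)^2/(2 s2^2)
    A = 1.0 / (2.0 * s2**2) - 1.0 / (2.0 * s1**2)
    B = m1 / s1**2 - m2 / s2**2
    C = (m2**2 / (2.0 * s2**2) - m1**2 / (2.0 * s1**2)
         + np.log(w1 / w2) + np.log(s2 / s1))
    if abs(A) < 1e-15:  # equal sds -> linear equation
        if abs(B) < 1e-15:
            raise ValueError("densities never cross between the means")
        roots = np.array([-C / B])
    else:
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise ValueError(
                f"no real crossing (means {m1:.3g}/{m2:.3g}, sds {s1:.3g}/{s2:.3g}, "
                f"weights {w1:.3g}/{w2:.3g})"
            )
        sq = np.sqrt(disc)
        roots = np.array([(-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)])
    inside = roots[(roots > lo) & (roots < hi)]
    if inside.size == 0:
        raise ValueError(
            f"no density crossing between the means {lo:.3g} and {hi:.3g} "
            f"(roots {roots}); check component weights"
        )
    return float(inside[0])


def fit_level_model(conductances) -> LevelModel:
    """Fit the two-component Gaussian model to pooled slope conductances.

    Conductances above 22 pS belong to a rarely occurring larger-conductance
    channel and are excluded from the fit (counted in ``n_high``).  The fit
    delegates to the amplitude-mixture machinery with k = 2; if the two
    fitted components are not separated (means closer than the larger
    component SD) the sample is effectively unimodal and an error advises a
    single-component description.
    """
    g = np.asarray(conductances, dtype=float).ravel()
    if g.size < 30:
        raise ValueError(f"need >= 30 pooled conductances, got {g.size}")
    if np.ptp(g) < 1e-12:
        raise ValueError("all conductance values equal")
    high = g > HIGH_CONDUCTANCE_CUTOFF_PS
    n_high = int(high.sum())
    if n_high:
        logger.info("excluding %d conductances > %.0f pS from the two-level fit",
                    n_high, HIGH_CONDUCTANCE_CUTOFF_PS)
    g = g[~high]

    mix = fit_amplitude_mixture(g, k=2)
    (m_lo, s_lo, w_lo), (m_hi, s_hi, w_hi) = mix.components
    # bimodality gate: the fitted mixture density must dip between the two
    # component means; a near-flat profile means the sample is unimodal
    from scipy.stats import norm

    xs = np.linspace(m_lo, m_hi, 512)
    dens = w_lo * norm.pdf(xs, m_lo, s_lo) + w_hi * norm.pdf(xs, m_hi, s_hi)
    dip = dens.min() / min(dens[0], dens[-1])
    if dip > 0.9:
        raise ValueError(
            "no density dip between the fitted components (means "
            f"{m_lo:.3g}/{m_hi:.3g} pS); the sample looks unimodal — use k=1"
        )
    thr = intersection_threshold((m_lo, s_lo, w_lo), (m_hi, s_hi, w_hi))
    return LevelModel(
        level1=(m_hi, s_hi),
        level2=(m_lo, s_lo),
        weights=(w_hi, w_lo),
        threshold=thr,
        n_high=n_high,
    )


def classify_level(g: float, threshold: float = DEFAULT_THRESHOLD_PS) -> str:
    """Classify a slope conductance: level 1 iff ``g >= threshold`` (14 pS)."""
    if g <= 0:
        raise ValueError("conductance must be positive")
    return "level1" if g >= threshold else "level2"


def default_age_bins() -> list[tuple[int, int]]:
    """Consecutive 3-day postnatal bins P5-P25 plus a terminal P26+ bin."""
    bins = [(lo, lo + 2) for lo in range(5, 26, 3)]
    bins.append((26, 45))
    return bins


def percent_level1_by_age(
    cell_records: pd.DataFrame,
    age_bins=None,
    threshold: float = DEFAULT_THRESHOLD_PS,
):
    """Percent of level-1 channels per age bin and the developmental drop age.

    ``cell_records`` needs ``age_days`` and ``g_pS`` columns (the level is
    re-derived from the conductance at ``threshold``).  Returns
    ``(table, drop_age)`` where the table has columns
    ``bin_lo, bin_hi, n, percent`` (percent is NaN for empty bins, which are
    excluded from the drop scan) and ``drop_age`` is the lower edge of the
    first bin with < 50% level-1 channels (None if never reached).
    """
    if age_bins is None:
        age_bins = default_age_bins()
    bins = [(int(lo), int(hi)) for lo, hi in age_bins]
    for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
        if hi >= lo2:
            raise ValueError("age bins must be ordered and non-overlapping")
    ages = cell_records["age_days"].to_numpy()
    g = cell_records["g_pS"].to_numpy(dtype=float)
    rows = []
    drop_age = None
    for lo, hi in bins:
        sel = (ages >= lo) & (ages <= hi)
        n = int(sel.sum())
        if n == 0:
            rows.append({"bin_lo": lo, "bin_hi": hi, "n": 0, "percent": np.nan})
            continue
        pct = 100.0 * float(np.mean(g[sel] >= threshold))
        rows.append({"bin_lo": lo, "bin_hi": hi, "n": n, "percent": pct})
        if drop_age is None and pct < 50.0:
            drop_age = lo
    return pd.DataFrame(rows), drop_age
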