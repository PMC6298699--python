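"""Helical-geometry model of the PAM-to-CpG gap dependence of methylation.

A tethered methyltransferase reaches its substrate CpG most easily when the
enzyme's fusion point and the CpG sit on the same face of the DNA double
helix, so methylation frequency oscillates with gap length at the helical
period.  This module maps gap lengths to angular positions around the helix
axis, combines per-strand frequencies into an "at least one strand" profile,
and extracts two observable summaries from a gap profile: the dominant
oscillation period (by circularised autocorrelation) and the support window
over which methylation exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import ConditionProfile, condition_profile

__all__ = [
    "AngleModel",
    "angle_of_gap",
    "combined_any_strand",
    "dominant_period",
    "methylation_support",
    "profile_series",
    "InsufficientDataError",
]

# canonical B-DNA twist; the observed methylation periodicity (11 bp) is a
# deliberately distinct default in the condition profiles
B_DNA_DEGREES_PER_BP = 360.0 / 10.5


class InsufficientDataError(ValueError):
    """Raised when a gap profile has too few observed points."""


@dataclass(frozen=True)
class AngleModel:
    """Angular position per base pair around the helix axis.

    The angle at gap g is ``(phase_deg + g * degrees_per_bp) mod 360``,
    viewed down the DNA axis from the CpG site towards the PAM.  The phase
    origin is configurable, not asserted.
    """

    degrees_per_bp: float = B_DNA_DEGREES_PER_BP
    phase_deg: float = 0.0

    def __post_init__(self):
        if self.degrees_per_bp <= 0:
            raise ValueError("degrees_per_bp must be > 0")


def angle_of_gap(gap: float, model: AngleModel = AngleModel()) -> float:
    """Helical angle (degrees in [0, 360)) at a given gap length."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return float(np.mod(model.phase_deg + gap * model.degrees_per_bp, 360.0))


def combined_any_strand(p_cis: float, p_trans: float) -> float:
    """Probability of methylation on at least one strand, assuming the two
    strands are methylated independently: 1 - (1 - p_cis)(1 - p_trans)."""
    for p in (p_cis, p_trans):
        if not 0.0 <= p <= 1.0:
            raise ValueError("strand frequencies must be in [0, 1]")
    return 1.0 - (1.0 - p_cis) * (1.0 - p_trans)


def profile_series(
    profile: ConditionProfile,
    gaps=range(2, 43),
) -> pd.DataFrame:
    """Evaluate a condition profile over a gap range (GapProfileSeries)."""
    gaps = np.asarray(list(gaps), dtype=int)
    fc = np.array([condition_profile(profile, g, "cis") for g in gaps])
    ft = np.array([condition_profile(profile, g, "trans") for g in gaps])
    fa = 1.0 - (1.0 - fc) * (1.0 - ft)
    return pd.DataFrame(
        {"gap": gaps, "freq_cis": fc, "freq_trans": ft, "freq_any": fa}
    )


def _combined_column(series: pd.DataFrame) -> np.ndarray:
    """Combined any-strand frequency per gap, NaN where both strands missing."""
    if "freq_any" in series.columns:
        return series["freq_any"].to_numpy(dtype=float)
    fc = series["freq_cis"].to_numpy(dtype=float)
    ft = series["freq_trans"].to_numpy(dtype=float)
    out = 1.0 - (1.0 - np.nan_to_num(fc)) * (1.0 - np.nan_to_num(ft))
    out[np.isnan(fc) & np.isnan(ft)] = np.nan
    return out


def dominant_period(series: pd.DataFrame, min_points: int = 8) -> int | None:
    """Dominant oscillation period (bp) of a gap profile, or None if flat.

    The combined any-strand profile is resampled onto the full integer gap
    grid (missing gaps mean-imputed), mean-centred, and the integer lag in
    [2, span/2] at the highest local maximum of the overlap-normalised
    autocorrelation is returned.  Autocorrelation (rather than a spectral
    estimate) is robust on short, possibly gapped series; the linear
    (non-circular) form avoids wrap artefacts when the series length is not
    a multiple of the period.
    """
    gaps = series["gap"].to_numpy(dtype=int)
    if np.any(np.diff(gaps) <= 0):
        raise ValueError("gaps must be strictly increasing")
    comb = _combined_column(series)
    observed = ~np.isnan(comb)
    if observed.sum() < min_points:
        raise InsufficientDataError(
            f"need >= {min_points} observed gaps, have {int(observed.sum())}"
        )
    grid = np.arange(gaps[0], gaps[-1] + 1)
    x = np.full(grid.size, np.nan)
    x[np.searchsorted(grid, gaps)] = comb
    mean = np.nanmean(x)
    x = np.where(np.isnan(x), mean, x)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return None
    span = int(gaps[-1] - gaps[0])
    max_lag = span // 2
    if max_lag < 2:
        raise InsufficientDataError("gap span too short for period estimation")
    lags = np.arange(1, max_lag + 1)
    ac = np.array([np.mean(x[:-k] * x[k:]) for k in lags])
    # the oscillation shows up as a local maximum of the autocorrelation; the
    # global maximum over small lags only reflects the smooth support window,
    # so pick the highest local maximum among lags >= 2
    cand = []
    for i in range(1, lags.size):  # lag >= 2
        left_ok = ac[i] > ac[i - 1]
        right_ok = i + 1 >= lags.size or ac[i] >= ac[i + 1]
        if left_ok and right_ok:
            cand.append(i)
    if not cand:
        return int(lags[1 + int(np.argmax(ac[1:]))])
    best = max(cand, key=lambda i: ac[i])
    return int(lags[best])


def methylation_support(
    series: pd.DataFrame, threshold: float = 0.02
) -> tuple[int, int] | None:
    """Smallest and largest gap whose combined any-strand frequency reaches
    ``threshold``; None if no gap qualifies."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    gaps = series["gap"].to_numpy(dtype=int)
    comb = _combined_column(series)
    qual = gaps[np.nan_to_num(comb, nan=-1.0) >= threshold]
    if qual.size == 0:
        return None
    return int(qual.min()), int(qual.max())
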