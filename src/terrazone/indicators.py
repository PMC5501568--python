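"""Microbial indicator calculations from raw assay values.

Microbial biomass C and N come from chloroform-fumigation extraction: the
fumigated-minus-nonfumigated extractable C (or N) difference divided by a
calibration factor (0.45 for MBC, 0.54 for MBN).  Carbon mineralization is
the per-day rate of cumulative headspace CO2 over a short incubation
(sampling days 1, 3, 7, 10 with venting after each), nitrogen
mineralization the change in extractable inorganic N over a 28-day
incubation, and "specific" rates are normalized per unit MBC.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

MBC_CALIBRATION = 0.45
MBN_CALIBRATION = 0.54


def microbial_biomass(
    fumigated, nonfumigated, calibration: float, return_flags: bool = False
):
    """Biomass pool (ug g-1 soil) = (fumigated - nonfumigated) / calibration.

    Negative differences are physically impossible for a biomass pool; they
    are floored at 0, flagged, and a warning is emitted.
    """
    if not 0 < calibration <= 1:
        raise ValueError("calibration factor must be in (0, 1]")
    diff = (np.asarray(fumigated, dtype=float) - np.asarray(nonfumigated, dtype=float))
    flags = diff < 0
    if np.any(flags):
        warnings.warn(
            f"{int(np.sum(flags))} negative fumigation difference(s) floored at 0"
        )
    out = np.where(flags, 0.0, diff) / calibration
    if out.ndim == 0:
        out = float(out)
    if return_flags:
        return out, flags
    return out


def c_mineralization_rate(co2_series) -> float:
    """OLS slope of cumulative CO2 against day (concentration per day).

    ``co2_series`` is a sequence of (day, increment) pairs, the increment
    being the CO2 accumulated since the previous venting; increments are
    summed into a cumulative curve before the regression, so every sampling
    day informs the rate.
    """
    series = [(float(d), float(v)) for d, v in co2_series]
    if len(series) < 2:
        raise ValueError("need at least two CO2 time points")
    days = np.array([d for d, _ in series])
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    cumulative = np.cumsum([v for _, v in series])
    return float(sps.linregress(days, cumulative).slope)


def n_mineralization(initial, final):
    """Net inorganic-N change over the 28-day incubation (ug N g-1).

    Negative values (net immobilization) are passed through unchanged.
    """
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if not (np.isfinite(initial).all() and np.isfinite(final).all()):
        raise ValueError("inputs must be finite")
    out = final - initial
    return float(out) if out.ndim == 0 else out


def specific_rate(rate, mbc):
    """Mass-specific rate: rate per unit microbial biomass carbon.

    Undefined (NaN) where mbc <= 0; such records are excluded from
    specific-rate statistics downstream.
    """
    rate = np.asarray(rate, dtype=float)
    mbc = np.asarray(mbc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mbc > 0, rate / np.where(mbc > 0, mbc, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out
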