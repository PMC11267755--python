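"""Isotopic-envelope titration quantification and photometric PVD assay.

The MALDI titration procedure for two co-produced PVD species (e.g. PVD-Ser
at m/z ~1320 vs PVD-Thr at ~1334): the intensities of the full isotopic
envelope of each main signal are summed together with the envelope of its
retro-Diels-Alder companion (~303 Da below), the ratio of the two sums is
taken, a response factor is calibrated by ordinary least squares against
known mixing ratios, and unknown mixtures are read off the calibration line.
A Beer-Lambert helper converts the A400 of culture supernatants into molar
PVD concentration (ε = 19,000 (mol·L)⁻¹·cm⁻¹ at 400 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .annotation import PeakList
from .mass_core import DEFAULT_CONSTANTS, MassConstants

__all__ = [
    "EnvelopeSum",
    "envelope_sum",
    "intensity_ratio",
    "TitrationFit",
    "fit_response",
    "estimate_ratio",
    "PhotometryConfig",
    "pvd_concentration",
]


@dataclass(frozen=True)
class EnvelopeSum:
    """Summed intensity of an isotopic envelope (optionally + RDA companion)."""

    mono_mz: float
    total: float
    n_isotopologues: int  # isotopologue positions with a matched peak
    includes_rda: bool
    absent: bool  # no peak within tolerance of the monoisotopic position
    label: str = ""


def _sum_envelope(
    obs: PeakList, root_mz: float, k_max: int, tol: float, spacing: float
) -> tuple[float, int, bool]:
    total = 0.0
    matched = 0
    mono_found = False
    for k in range(k_max + 1):
        target = root_mz + k * spacing
        peak = obs.nearest(target)
        if peak is not None and abs(peak.mz - target) <= tol:
            total += peak.intensity
            matched += 1
            if k == 0:
                mono_found = True
    return total, matched, mono_found


def envelope_sum(
    obs: PeakList,
    mono_mz: float,
    k_max: int = 4,
    tol: float = 0.3,
    rda: bool = False,
    constants: MassConstants = DEFAULT_CONSTANTS,
    label: str = "",
) -> EnvelopeSum:
    """Sum the isotopic envelope rooted at ``mono_mz``.

    Intensities of the nearest peak within ``tol`` of mono_mz + k·1.00335 for
    k = 0..k_max are summed; missing isotopologues contribute zero.  With
    ``rda`` the same sum rooted at mono_mz − rda_loss is added.  A species
    with no peak within tolerance of the monoisotopic position is returned
    with a zero-compatible total and flagged absent.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    total, matched, mono_found = _sum_envelope(
        obs, mono_mz, k_max, tol, constants.isotope_spacing
    )
    if rda:
        rda_total, rda_matched, _ = _sum_envelope(
            obs, mono_mz - constants.rda_loss, k_max, tol, constants.isotope_spacing
        )
        total += rda_total
        matched += rda_matched
    return EnvelopeSum(
        mono_mz=mono_mz,
        total=total,
        n_isotopologues=matched,
        includes_rda=rda,
        absent=not mono_found,
        label=label,
    )


def intensity_ratio(
    obs: PeakList,
    mono_a: float,
    mono_b: float,
    k_max: int = 4,
    tol: float = 0.3,
    rda: bool = True,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Envelope-sum intensity ratio of species A over species B."""
    a = envelope_sum(obs, mono_a, k_max, tol, rda, constants)
    b = envelope_sum(obs, mono_b, k_max, tol, rda, constants)
    if b.absent or b.total == 0:
        raise ValueError(
            f"reference species at m/z {mono_b:.2f} absent — ratio undefined"
        )
    return a.total / b.total


@dataclass(frozen=True)
class TitrationFit:
    """An OLS response-factor calibration: measured ratio vs known ratio."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("calibration needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R² outside [0, 1]")


def fit_response(
    known_ratios: Sequence[float],
    measured_ratios: Sequence[float],
    through_origin: bool = False,
) -> TitrationFit:
    """Calibrate the MS response factor by OLS of measured on known ratios.

    The default includes an intercept and reports the ordinary coefficient of
    determination.  With ``through_origin`` the line is forced through zero
    and R² uses the uncentered total sum of squares (so it stays in [0, 1]).
    """
    known = np.asarray(known_ratios, dtype=float)
    measured = np.asarray(measured_ratios, dtype=float)
    if known.shape != measured.shape:
        raise ValueError("known and measured ratio lists must have equal length")
    n = known.size
    if n < 2:
        raise ValueError("calibration needs at least 2 points")
    if np.ptp(known) == 0:
        raise ValueError("known ratios have zero variance — cannot calibrate")
    if through_origin:
        slope = float(known @ measured / (known @ known))
        intercept = 0.0
        resid = measured - slope * known
        ss_tot = float(measured @ measured)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(known, measured)
        slope, intercept = float(fit.slope), float(fit.intercept)
        resid = measured - (slope * known + intercept)
        r2 = float(fit.rvalue) ** 2
        if not np.isfinite(r2):
            # constant measured ratios: the flat line fits exactly
            r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    return TitrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n=n,
        residuals=tuple(float(r) for r in resid),
    )


def estimate_ratio(fit: TitrationFit, measured: float) -> float:
    """Invert the calibration line: concentration ratio from a measured ratio."""
    if fit.slope == 0:
        raise ValueError("calibration slope is zero — cannot invert")
    return (measured - fit.intercept) / fit.slope


@dataclass(frozen=True)
class PhotometryConfig:
    """Beer-Lambert parameters for PVD quantification at 400 nm."""

    epsilon: float = 19000.0  # (mol·L)⁻¹·cm⁻¹
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.path_cm <= 0:
            raise ValueError("path length must be positive")


def pvd_concentration(a400: float, config: PhotometryConfig = PhotometryConfig()) -> float:
    """PVD concentration (mol/L) from absorbance at 400 nm."""
    if a400 < 0 or math.isnan(a400):
        raise ValueError("absorbance must be non-negative")
    return a400 / (config.epsilon * config.path_cm)
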