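"""Wet-assay calculators: ACE-inhibition (% inhibition, IC50) and ABTS (TEAC).

ACE inhibition is read out fluorimetrically.  With FC the control
fluorescence (enzyme, no inhibitor), FB the substrate blank, FS the sample
fluorescence (enzyme + inhibitor) and FBs the sample blank:

    inhibition % = ((FC − FB) − (FS − FBs)) / (FC − FB) × 100

IC50 is the inhibitor concentration at 50 % inhibition.  The default
estimator interpolates % inhibition linearly against log10(concentration)
between the pair of points bracketing 50 % — assumption-free and
reproducible; a four-parameter logistic fit is available behind a flag.

The ABTS radical-scavenging capacity of a compound is expressed as TEAC, the
millimolar Trolox concentration with the same scavenging as 1 mM of the
compound.  With responses linear in concentration for both, TEAC is the
ratio of the sample's response slope to the Trolox calibration slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AssayPlate",
    "TroloxCalibration",
    "IC50Result",
    "InvalidAssayError",
    "NotEstimableError",
    "ace_inhibition_percent",
    "inhibition_curve",
    "ic50",
    "teac",
]


class InvalidAssayError(ValueError):
    """Control does not exceed blank: the assay carries no signal."""


class NotEstimableError(ValueError):
    """The dose–response points do not bracket 50 % inhibition."""


def ace_inhibition_percent(fc: float, fb: float, fs: float, fbs: float) -> float:
    """Percent ACE inhibition from the four fluorescence readings.

    May fall outside [0, 100] on noisy data; values are reported as-is.
    """
    if fc <= fb:
        raise InvalidAssayError(f"control ({fc}) must exceed blank ({fb})")
    return ((fc - fb) - (fs - fbs)) / (fc - fb) * 100.0


@dataclass(frozen=True)
class AssayPlate:
    """ACE-assay readings: control/blank plus per-concentration samples.

    ``readings`` holds (concentration µM, FS, FBs) tuples; replicates (same
    concentration) are averaged before the curve is computed.
    """

    fc: float
    fb: float
    readings: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.fc <= self.fb:
            raise InvalidAssayError("control fluorescence must exceed blank")
        if any(c <= 0 for c, _, _ in self.readings):
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "readings", tuple(tuple(r) for r in self.readings))


def inhibition_curve(plate: AssayPlate) -> List[Tuple[float, float]]:
    """Replicate-averaged (concentration, % inhibition), ascending concentration."""
    by_conc: Dict[float, List[float]] = {}
    for conc, fs, fbs in plate.readings:
        by_conc.setdefault(conc, []).append(
            ace_inhibition_percent(plate.fc, plate.fb, fs, fbs)
        )
    return [(c, mean(v)) for c, v in sorted(by_conc.items())]


class IC50Result(NamedTuple):
    value_uM: float
    method: str
    curve: Tuple[Tuple[float, float], ...]
    out_of_range_flag: bool  # any averaged inhibition outside [0, 100]


def _ic50_loglinear(curve: Sequence[Tuple[float, float]]) -> float:
    for conc, inh in curve:
        if inh == 50.0:
            return conc
    for (c_lo, i_lo), (c_hi, i_hi) in zip(curve, curve[1:]):
        if (i_lo - 50.0) * (i_hi - 50.0) < 0:
            t = (50.0 - i_lo) / (i_hi - i_lo)
            return 10 ** (np.log10(c_lo) + t * (np.log10(c_hi) - np.log10(c_lo)))
    observed = [i for _, i in curve]
    raise NotEstimableError(
        f"inhibition range [{min(observed):.1f}, {max(observed):.1f}] %% "
        "does not bracket 50 %"
    )


def _four_pl(conc, bottom, top, ic50_, hill):
    return bottom + (top - bottom) / (1.0 + (ic50_ / conc) ** hill)


def _ic50_4pl(curve: Sequence[Tuple[float, float]]) -> float:
    conc = np.array([c for c, _ in curve])
    inh = np.array([i for _, i in curve])
    p0 = (0.0, 100.0, float(np.exp(np.mean(np.log(conc)))), 1.0)
    popt, _ = optimize.curve_fit(
        _four_pl, conc, inh, p0=p0, maxfev=20000,
        bounds=([-50, 50, conc.min() / 1e3, 0.1], [50, 150, conc.max() * 1e3, 10]),
    )
    return float(popt[2])


def ic50(plate: AssayPlate, method: str = "loglinear") -> IC50Result:
    """Estimate IC50 (µM) from a dose–response plate.

    ``method`` is ``"loglinear"`` (default; interpolation between the
    bracketing pair on a log-concentration axis) or ``"4pl"`` (four-parameter
    logistic least-squares fit).  Raises :class:`NotEstimableError` when no
    pair of points brackets 50 %.
    """
    curve = inhibition_curve(plate)
    if len(curve) < 2 and not any(i == 50.0 for _, i in curve):
        raise NotEstimableError("need at least two concentrations")
    if method == "loglinear":
        value = _ic50_loglinear(curve)
    elif method == "4pl":
        value = _ic50_4pl(curve)
    else:
        raise ValueError(f"unknown method {method!r}")
    flag = any(not 0 <= i <= 100 for _, i in curve)
    return IC50Result(value_uM=value, method=method, curve=tuple(curve),
                      out_of_range_flag=flag)


# -- ABTS / TEAC ------------------------------------------------------------

@dataclass(frozen=True)
class TroloxCalibration:
    """Least-squares line through Trolox (mM, response) standards."""

    points: Tuple[Tuple[float, float], ...]
    slope: float = field(init=False)
    intercept: float = field(init=False)
    r_squared: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(tuple(p) for p in self.points))
        concs = {c for c, _ in self.points}
        if len(concs) < 2:
            raise ValueError("calibration needs >= 2 distinct concentrations")
        fit = stats.linregress([c for c, _ in self.points], [r for _, r in self.points])
        if fit.slope == 0:
            raise ValueError("calibration slope is zero")
        object.__setattr__(self, "slope", float(fit.slope))
        object.__setattr__(self, "intercept", float(fit.intercept))
        object.__setattr__(self, "r_squared", float(fit.rvalue) ** 2)

    @property
    def concentration_range(self) -> Tuple[float, float]:
        concs = [c for c, _ in self.points]
        return min(concs), max(concs)


def teac(
    calibration: TroloxCalibration,
    sample_points: Sequence[Tuple[float, float]],
    mode: str = "slope_ratio",
) -> float:
    """Trolox-equivalent antioxidant capacity of a sample.

    ``slope_ratio`` (default) fits a least-squares line through the sample
    (mM, response) points and returns sample slope / Trolox slope.
    ``single_point`` converts a single reading through the calibration line
    and divides by the sample concentration.  Sample concentrations outside
    the calibration range trigger an extrapolation warning.
    """
    if not sample_points:
        raise ValueError("no sample points")
    lo, hi = calibration.concentration_range
    # the calibration is in Trolox-equivalent mM; range check uses responses
    # mapped back through the line rather than raw sample concentrations
    equiv = [(r - calibration.intercept) / calibration.slope for _, r in sample_points]
    if any(e < lo - 1e-12 or e > hi + 1e-12 for e in equiv):
        warnings.warn("sample response outside calibration range; extrapolating",
                      stacklevel=2)
    if mode == "single_point":
        conc, _ = sample_points[0]
        return equiv[0] / conc
    if mode != "slope_ratio":
        raise ValueError(f"unknown mode {mode!r}")
    concs = [c for c, _ in sample_points]
    resps = [r for _, r in sample_points]
    if len(set(concs)) == 1:
        # degenerate single-concentration input: fall back to single point
        return equiv[0] / concs[0]
    fit = stats.linregress(concs, resps)
    return float(fit.slope) / calibration.slope
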