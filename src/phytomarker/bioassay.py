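"""Bioassay arithmetic: DPPH scavenging, FRAP equivalents, NO inhibition, IC50.

All core functions return *fractions*; the reporting layer multiplies by 100
when a percent is wanted. Keeping one scale in the core avoids silent ×100
bugs between stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, FitError


@dataclass(frozen=True)
class DPPHMeasurement:
    """Optical densities at 517 nm.

    A0: blank (sample without radical reagent), corrects sample colour;
    A1: negative control (radical, no sample);
    A2: test sample with radical.
    """

    A0: float
    A1: float
    A2: float

    def __post_init__(self) -> None:
        vals = (self.A0, self.A1, self.A2)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ConfigError("absorbances must be finite and >= 0")


def dpph_scavenging(m: DPPHMeasurement) -> float:
    """Radical scavenging fraction 1 − (A2 − A0)/A1 (1 = complete)."""
    if m.A1 <= 0:
        raise ConfigError("negative-control absorbance A1 must be > 0")
    return 1.0 - (m.A2 - m.A0) / m.A1


@dataclass(frozen=True)
class FRAPCalibration:
    """OLS calibration of 593-nm absorbance on Fe(II) standard concentration."""

    standard_concentrations: tuple
    standard_absorbances: tuple
    slope: float
    intercept: float
    r_squared: float


def fit_frap_calibration(
    concentrations: np.ndarray,
    absorbances: np.ndarray,
    r2_floor: float = 0.99,
) -> FRAPCalibration:
    """Fit the ferrous-sulfate calibration line (abs = slope·conc + intercept)."""
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if conc.size < 3 or ab.size != conc.size:
        raise ConfigError("calibration needs >= 3 (concentration, absorbance) pairs")
    if np.any(np.diff(conc) <= 0):
        raise ConfigError("standard concentrations must be strictly increasing")
    if np.ptp(ab) == 0:
        raise FitError("constant absorbances: singular calibration fit")
    res = stats.linregress(conc, ab)
    r2 = res.rvalue ** 2
    if res.slope <= 0:
        warnings.warn("calibration slope is non-positive; check standards")
    if r2 < r2_floor:
        warnings.warn(f"calibration r²={r2:.4f} below floor {r2_floor}")
    return FRAPCalibration(tuple(conc), tuple(ab),
                           float(res.slope), float(res.intercept), float(r2))


def frap_value(
    sample_abs: float,
    cal: FRAPCalibration,
    mass_g: float,
    dilution: float = 1.0,
) -> tuple[float, bool]:
    """Fe(II) equivalents of a sample, in µmol Fe(II)/g.

    ``dilution`` is the volume/dilution factor converting the calibrated
    concentration (µmol/L) into µmol in the assayed extract. Returns
    ``(value, below_blank)`` — a below-blank reading is returned negative
    with the flag set rather than clipped.
    """
    if mass_g <= 0:
        raise ConfigError("sample mass must be > 0")
    if cal.slope == 0:
        raise FitError("calibration slope is zero")
    value = (sample_abs - cal.intercept) / cal.slope * dilution / mass_g
    below = value < -1e-9  # tolerate rounding at the blank itself
    if below:
        warnings.warn("sample absorbance below calibration blank")
    return float(value), bool(below)


def trolox_equivalents(sample_slope: float, trolox_slope: float) -> float:
    """Antioxidant capacity as a ratio of dose-response calibration slopes.

    Expressed in mol Trolox per mol (or per g, depending on the dose units
    used for the two slopes). This ratio-of-slopes convention assumes both
    dose-responses are linear over the compared range.
    """
    if trolox_slope == 0:
        raise ConfigError("reference (Trolox) slope must be nonzero")
    return sample_slope / trolox_slope


def inhibition_rate(treated: float, stimulated: float, unstimulated: float
                    ) -> tuple[float, bool]:
    """NO-inhibition fraction (stimulated − treated)/(stimulated − unstimulated).

    1 means the treatment restored the unstimulated baseline, 0 means no
    effect. Values outside [0, 1] are clipped and flagged.
    """
    if stimulated <= unstimulated:
        raise ConfigError(
            "no induction: stimulated level must exceed unstimulated level")
    raw = (stimulated - treated) / (stimulated - unstimulated)
    clipped = min(max(raw, 0.0), 1.0)
    return clipped, bool(raw != clipped)


@dataclass
class DoseResponseResult:
    """IC50 summary of one inhibition dose-response curve."""

    concentrations: np.ndarray
    responses: np.ndarray
    ic50: float | None             # None when censored
    censored: str | None           # None, ">max" or "<min"
    interpolated: bool             # True when the 4PL fit was not used
    fit_params: dict | None        # lower, upper, hill, ic50

    @property
    def label(self) -> str:
        if self.censored == ">max":
            return f"IC50 > {self.concentrations.max():g}"
        if self.censored == "<min":
            return f"IC50 < {self.concentrations.min():g}"
        return f"IC50 = {self.ic50:g}"


def _four_pl(c, lower, upper, hill, ic50):
    return lower + (upper - lower) / (1.0 + (ic50 / c) ** hill)


def estimate_ic50(concentrations: np.ndarray,
                  responses: np.ndarray) -> DoseResponseResult:
    """Half-maximal inhibitory concentration from a dose-response curve.

    Responses are inhibition fractions. A four-parameter logistic is fit by
    nonlinear least squares; if the fit fails, the IC50 falls back to
    log-linear interpolation between the doses bracketing 0.5 (flagged).
    When 0.5 is never bracketed the result is censored, reported in the
    "> max dose" / "< min dose" style.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < 4 or resp.size != conc.size:
        raise ConfigError("need >= 4 matched dose levels")
    if np.any(conc <= 0):
        raise ConfigError("concentrations must be positive")
    if not np.all(np.isfinite(resp)):
        raise ConfigError("responses must be finite")
    order = np.argsort(conc)
    conc, resp = conc[order], resp[order]

    if resp.max() < 0.5:
        return DoseResponseResult(conc, resp, None, ">max", False, None)
    if resp.min() > 0.5:
        return DoseResponseResult(conc, resp, None, "<min", False, None)
    exact = np.flatnonzero(resp == 0.5)
    if exact.size:
        # a dose hitting 50% exactly is its own IC50 (interpolation fixed point)
        return DoseResponseResult(conc, resp, float(conc[exact[0]]),
                                  None, True, None)

    try:
        mid = np.interp(0.5, resp, conc) if np.all(np.diff(resp) >= 0) \
            else float(np.sqrt(conc[0] * conc[-1]))
        p0 = [max(resp.min(), 0.0), min(resp.max(), 1.0), 1.0, mid]
        popt, _ = optimize.curve_fit(
            _four_pl, conc, resp, p0=p0,
            bounds=([-0.5, 0.0, -10.0, conc.min() / 100.0],
                    [0.5, 1.5, 10.0, conc.max() * 100.0]),
            maxfev=20000)
        lower, upper, hill, ic50 = popt
        if not (lower < 0.5 < upper) or not np.isfinite(ic50):
            raise RuntimeError("4PL curve does not cross 50% inhibition")
        fit = {"lower": float(lower), "upper": float(upper),
               "hill": float(hill), "ic50": float(ic50)}
        if not (conc.min() <= ic50 <= conc.max()):
            # crossing outside the tested range: fall through to interpolation
            raise RuntimeError("4PL IC50 outside tested dose range")
        return DoseResponseResult(conc, resp, float(ic50), None, False, fit)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        pass

    # log-linear interpolation between the two doses bracketing 0.5
    above = np.flatnonzero(resp >= 0.5)
    below = np.flatnonzero(resp < 0.5)
    if above.size == 0 or below.size == 0:
        return DoseResponseResult(
            conc, resp, None, ">max" if above.size == 0 else "<min",
            False, None)
    i_hi = above[0]
    i_lo = i_hi - 1 if i_hi > 0 else above[0]
    if i_hi == 0:
        return DoseResponseResult(conc, resp, float(conc[0]), None, True, None)
    r_lo, r_hi = resp[i_lo], resp[i_hi]
    if r_hi == r_lo:
        ic50 = float(np.sqrt(conc[i_lo] * conc[i_hi]))
    else:
        frac = (0.5 - r_lo) / (r_hi - r_lo)
        ic50 = float(np.exp(np.log(conc[i_lo])
                            + frac * (np.log(conc[i_hi]) - np.log(conc[i_lo]))))
    return DoseResponseResult(conc, resp, ic50, None, True, None)
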