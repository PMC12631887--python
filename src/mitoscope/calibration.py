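"""Cuvette-level probe calibration: log-log fit and limit of detection.

A viscosity-sensitive probe's emission intensity I grows as a power law
of solvent viscosity eta, so ordinary least squares of log10(I) on
log10(eta) yields the calibration line; its slope k and the standard
deviation sigma of replicate blank measurements give the limit of
detection by the standard three-sigma criterion LOD = 3 sigma / |k|,
expressed on the calibration abscissa (the same units as eta when the
blank sd is taken on the fitted response scale).

Logs are base 10 by default; R^2 and the LOD formula are invariant to
the base for the definitions used here.  sigma uses the n-1 denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int


def fit_loglog(
    viscosity, intensity, log_base: float = 10.0
) -> CalibrationFit:
    """OLS fit of log(intensity) on log(viscosity).

    Requires n >= 3 pairs with at least two distinct viscosity levels;
    all values must be strictly positive (the log is undefined
    otherwise).  A two-point fit is allowed but warns: it is exactly
    determined and carries no goodness-of-fit information.
    """
    eta = np.asarray(viscosity, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if eta.size != inten.size or eta.size < 2:
        raise ValueError("need paired series with n >= 2")
    if (eta <= 0).any() or (inten <= 0).any():
        raise ValueError("viscosity and intensity must be strictly positive (log domain)")
    if np.unique(eta).size < 2:
        raise ValueError("all viscosity levels identical; fit is rank-deficient")
    if eta.size == 2:
        warnings.warn("two-point calibration is exactly determined (under-determined fit)")
    scale = math.log(log_base)
    x = np.log(eta) / scale
    y = np.log(inten) / scale
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(eta.size - 2, 1)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        residual_sd=math.sqrt(ss_res / dof),
        n=int(eta.size),
    )


def blank_sd(blanks) -> float:
    """Sample (n-1) standard deviation of replicate blank measurements."""
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank replicates")
    return float(blanks.std(ddof=1))


def compute_lod(sigma: float, slope: float) -> float:
    """Limit of detection 3*sigma/|k| from blank sd and calibration slope."""
    if sigma < 0:
        raise ValueError("blank sd must be non-negative")
    if slope == 0:
        raise ZeroDivisionError("calibration slope is zero; LOD undefined")
    return 3.0 * sigma / abs(slope)
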