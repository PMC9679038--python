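"""Standard-additions quantification and per-Hb normalisation.

In the method of standard additions, known increments of analyte are added
to the sample and the instrument response is regressed on the added amount:
I = s * (m0 + a).  The initial amount is the x-axis intercept magnitude
m0 = intercept / slope, with its standard error propagated from the
regression covariance (delta method), or by bootstrap on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "AdditionSeries",
    "QuantResult",
    "QuantificationError",
    "standard_additions",
    "normalize_per_hb",
]


class QuantificationError(ValueError):
    """Raised when an addition series cannot yield a valid quantification."""


@dataclass(frozen=True)
class AdditionSeries:
    """A standard-additions series: added amounts (umol) and intensities.

    The first addition must be 0 (the unspiked sample) and additions must
    be non-decreasing.  ``sample_hb_g`` optionally carries the Hb mass of
    the aliquot for later normalisation.
    """

    added_umol: tuple
    intensities: tuple
    sample_hb_g: Optional[float] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.added_umol, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if a.size != i.size:
            raise ValueError("added amounts and intensities must have equal length")
        if a.size < 3:
            raise ValueError("need at least 3 points for standard additions")
        if a[0] != 0:
            raise ValueError("first addition must be 0 (the unspiked sample)")
        if np.any(np.diff(a) < 0):
            raise ValueError("added amounts must be non-decreasing")


@dataclass(frozen=True)
class QuantResult:
    """Initial analyte amount with its standard error and fit summary."""

    m0_umol: float
    se_umol: float
    slope: float
    intercept: float
    r_squared: float


def standard_additions(
    series: AdditionSeries,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> QuantResult:
    """Initial analyte amount m0 (umol) from an addition series.

    Ordinary least squares of intensity on added amount; m0 is
    intercept/slope.  The standard error is first-order (delta-method)
    propagation from the coefficient covariance including the
    intercept-slope covariance; with ``bootstrap=True`` a residual
    bootstrap replaces the delta method.
    """
    a = np.asarray(series.added_umol, dtype=float)
    intens = np.asarray(series.intensities, dtype=float)

    X = sm.add_constant(a)
    fit = sm.OLS(intens, X).fit()
    intercept, slope = fit.params
    if slope <= 0:
        raise QuantificationError("regression slope must be positive: signal must grow with additions")
    m0 = intercept / slope

    cov = np.asarray(fit.cov_params())
    var_b0, var_b1 = cov[0, 0], cov[1, 1]
    cov_b0b1 = cov[0, 1]
    # delta method on m0 = b0/b1: grad = (1/b1, -b0/b1^2)
    var_m0 = (
        var_b0 / slope**2
        + intercept**2 * var_b1 / slope**4
        - 2.0 * intercept * cov_b0b1 / slope**3
    )
    se = float(np.sqrt(max(var_m0, 0.0)))

    if bootstrap:
        rng = np.random.default_rng(seed)
        resid = intens - fit.fittedvalues
        draws = []
        for _ in range(n_boot):
            y = fit.fittedvalues + rng.choice(resid, size=resid.size, replace=True)
            b0, b1 = np.linalg.lstsq(X, y, rcond=None)[0]
            if b1 > 0:
                draws.append(b0 / b1)
        if len(draws) >= 2:
            se = float(np.std(draws, ddof=1))

    return QuantResult(
        m0_umol=float(m0),
        se_umol=se,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(fit.rsquared) if intens.std() > 0 else 1.0,
    )


def normalize_per_hb(m0_umol: float, hb_g: float) -> float:
    """Normalise an absolute amount (umol) to umol per g Hb."""
    if hb_g <= 0:
        raise ValueError("Hb mass must be strictly positive")
    return m0_umol / hb_g
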