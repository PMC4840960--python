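"""Four-parameter logistic (4PL) dose-response model with relative EC50.

The model on log10 dose x is::

    y = bottom + (top - bottom) / (1 + 10^((log_ec50 - x) * hill))

EC50 is the *relative* EC50 — the inflection concentration of the fitted
curve — with bottom and top left free (no constraint to 0/100).  Fitting is
nonlinear least squares with a self-starting initialization (bottom = min
response, top = max response, log_ec50 = median log dose, hill = 1).

The model object follows the familiar fit-and-results idiom::

    res = FourParamLogistic(doses_uM, responses).fit()
    res.ec50_uM, res.r_squared, res.bse["log_ec50"]
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import NoFitError

PARAM_NAMES = ("bottom", "top", "log_ec50", "hill")


def four_param_logistic(
    dose: np.ndarray | float, bottom: float, top: float, log_ec50: float, hill: float
) -> np.ndarray | float:
    """Evaluate the 4PL curve at dose(s) in the same concentration units as EC50."""
    logd = np.log10(dose)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logd) * hill))


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with diagnostics."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    r_squared: float
    converged: bool
    n_points: int
    bse: dict[str, float] = field(default_factory=dict)

    @property
    def ec50_uM(self) -> float:
        return float(10.0 ** self.log_ec50)

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return four_param_logistic(dose, self.bottom, self.top, self.log_ec50, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 47,
            f"{'n points':<14}{self.n_points:>10d}",
            f"{'converged':<14}{str(self.converged):>10}",
            f"{'R-squared':<14}{self.r_squared:>10.4f}",
            "-" * 47,
            f"{'param':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name in PARAM_NAMES:
            est = getattr(self, name)
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<12}{est:>12.4g}{se:>12.3g}")
        lines.append("-" * 47)
        lines.append(f"{'EC50':<12}{self.ec50_uM:>12.4g}")
        return "\n".join(lines)


class FourParamLogistic:
    """4PL dose-response model for one compound.

    Parameters
    ----------
    dose : sequence of positive concentrations (any consistent unit; EC50 is
        reported in the same unit).
    response : matching responses (raw or %DAPT-normalized scores).
    """

    def __init__(self, dose: Sequence[float], response: Sequence[float]):
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        if dose.shape != response.shape or dose.ndim != 1:
            raise ValueError("dose and response must be matching 1-D sequences")
        if np.any(dose <= 0):
            raise ValueError("doses must be strictly positive")
        if len(np.unique(dose)) < 4:
            raise ValueError("need at least 4 distinct doses for a 4-parameter fit")
        self.dose = dose
        self.response = response

    def start_params(self) -> np.ndarray:
        return np.array(
            [
                float(self.response.min()),
                float(self.response.max()),
                float(np.median(np.log10(self.dose))),
                1.0,
            ]
        )

    def fit(
        self,
        init: Sequence[float] | None = None,
        bounds: tuple | None = None,
        maxfev: int = 20000,
    ) -> DoseResponseFit:
        """Least-squares 4PL fit; raises :class:`NoFitError` for flat responses."""
        y = self.response
        if np.ptp(y) == 0:
            raise NoFitError("all responses equal; no dose-response signal to fit")
        p0 = np.asarray(init, dtype=float) if init is not None else self.start_params()
        kwargs = {}
        if bounds is not None:
            kwargs["bounds"] = bounds
        converged = True
        try:
            popt, pcov = curve_fit(
                four_param_logistic, self.dose, y, p0=p0, maxfev=maxfev, **kwargs
            )
        except RuntimeError:
            converged = False
            popt, pcov = p0, np.full((4, 4), np.nan)
        resid = y - four_param_logistic(self.dose, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        if not np.all(np.isfinite(se)):
            se = np.full(4, np.nan)
        return DoseResponseFit(
            bottom=float(popt[0]),
            top=float(popt[1]),
            log_ec50=float(popt[2]),
            hill=float(popt[3]),
            r_squared=r2,
            converged=converged and np.all(np.isfinite(popt)),
            n_points=len(y),
            bse=dict(zip(PARAM_NAMES, (float(s) for s in se))),
        )
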