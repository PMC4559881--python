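"""Percent inhibition and four-parameter-logistic (4PL) dose–response fitting.

The 4PL sigmoid

    y = bottom + (top - bottom) / (1 + (x / midpoint)^hill)

is fitted by least squares on log10(x), which is the standard
parameterization for potency estimation (the midpoint is an IC50 when x
is a concentration and an ED50 when x is a dose).  The estimator follows
the scikit-learn API so it composes with pipelines and model selection;
:func:`fit_4pl` and :func:`ed50_from_study` are thin functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

LN10 = math.log(10.0)


class DoseResponseError(ValueError):
    pass


class ConvergenceError(DoseResponseError):
    """Fit failed to converge; carries the best parameters found so far."""

    def __init__(self, message: str, params: dict | None = None):
        super().__init__(message)
        self.params = params or {}


def percent_inhibition(treated_mean: float, reference_mean: float) -> float:
    """100 × (1 − treated/reference); negative values denote an increase."""
    if reference_mean <= 0:
        raise DoseResponseError("reference mean must be > 0")
    return 100.0 * (1.0 - treated_mean / reference_mean)


def _curve(logx: np.ndarray, bottom: float, top: float, logmid: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logmid)))


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with asymptotic standard errors."""

    bottom: float
    top: float
    midpoint: float        #: ED50/IC50, in the units of x
    hill: float
    se_midpoint: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    n: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _curve(np.log10(x), self.bottom, self.top, math.log10(self.midpoint), self.hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic regression of response on dose/concentration.

    Parameters
    ----------
    fix_bottom, fix_top : float or None
        Fix the corresponding asymptote instead of estimating it.  For
        in vivo ED50 estimation on the percent-inhibition scale the
        bottom is conventionally fixed at 0.
    max_nfev : int
        Function-evaluation budget for the trust-region solver.

    Attributes
    ----------
    bottom_, top_, midpoint_, hill_ : float
        Fitted curve parameters (note ``hill`` > 0 means the response
        decreases with x under this parameterization).
    se_midpoint_ : float
        Asymptotic (Jacobian-based) standard error of the midpoint.
    se_ : dict
        Standard errors of all free parameters.
    rss_, converged_, n_iter_ : fit diagnostics.
    """

    def __init__(self, fix_bottom: float | None = None, fix_top: float | None = None,
                 max_nfev: int = 10000):
        self.fix_bottom = fix_bottom
        self.fix_top = fix_top
        self.max_nfev = max_nfev

    # -- internals -------------------------------------------------------
    def _unpack(self, theta: np.ndarray) -> tuple[float, float, float, float]:
        i = 0
        if self.fix_bottom is None:
            bottom = theta[i]; i += 1
        else:
            bottom = self.fix_bottom
        if self.fix_top is None:
            top = theta[i]; i += 1
        else:
            top = self.fix_top
        logmid, hill = theta[i], theta[i + 1]
        return bottom, top, logmid, hill

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise DoseResponseError("X and y must have matching lengths")
        if np.any(x <= 0):
            raise DoseResponseError("doses/concentrations must be > 0 (fit on log x)")
        if np.unique(x).size < 4:
            raise DoseResponseError("need >= 4 distinct x values")
        logx = np.log10(x)

        # starting values: asymptotes at the data range, midpoint at the x
        # whose response is nearest half-range, hill = 1
        top0 = self.fix_top if self.fix_top is not None else float(np.max(y))
        bot0 = self.fix_bottom if self.fix_bottom is not None else float(np.min(y))
        half = (top0 + bot0) / 2.0
        logmid0 = float(logx[np.argmin(np.abs(y - half))])
        # hill > 0 gives a decreasing curve in this parameterization, so
        # start with the sign implied by the data trend
        trend = np.polyfit(logx, y, 1)[0] if np.ptp(y) > 0 else -1.0
        hill0 = 1.0 if trend < 0 else -1.0
        theta0 = []
        if self.fix_bottom is None:
            theta0.append(bot0)
        if self.fix_top is None:
            theta0.append(top0)
        theta0 += [logmid0, hill0]

        def resid(theta):
            bottom, top, logmid, hill = self._unpack(theta)
            return _curve(logx, bottom, top, logmid, hill) - y

        sol = least_squares(resid, np.asarray(theta0, dtype=float),
                            method="lm" if len(theta0) <= x.size else "trf",
                            max_nfev=self.max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        bottom, top, logmid, hill = self._unpack(sol.x)
        if not sol.success:
            raise ConvergenceError(
                f"4PL fit did not converge: {sol.message}",
                params={"bottom": bottom, "top": top,
                        "midpoint": 10.0 ** logmid, "hill": hill},
            )

        self.bottom_, self.top_ = float(bottom), float(top)
        self.midpoint_, self.hill_ = float(10.0 ** logmid), float(hill)
        self.rss_ = float(2.0 * sol.cost)
        self.n_iter_ = int(sol.nfev)
        self.converged_ = True

        # asymptotic covariance: s^2 (J'J)^-1
        names = []
        if self.fix_bottom is None:
            names.append("bottom")
        if self.fix_top is None:
            names.append("top")
        names += ["log10_midpoint", "hill"]
        dof = max(x.size - len(names), 1)
        s2 = self.rss_ / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((len(names), len(names)), np.nan)
            se = np.full(len(names), np.nan)
        self.cov_ = cov
        self.se_ = dict(zip(names, se))
        # delta method: se(mid) = ln(10) * mid * se(log10 mid)
        self.se_midpoint_ = float(LN10 * self.midpoint_ * self.se_["log10_midpoint"])
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return _curve(np.log10(x), self.bottom_, self.top_,
                      math.log10(self.midpoint_), self.hill_)

    def result(self) -> DoseResponseFit:
        se = dict(self.se_)
        se["midpoint"] = self.se_midpoint_
        return DoseResponseFit(
            bottom=self.bottom_, top=self.top_, midpoint=self.midpoint_,
            hill=self.hill_, se_midpoint=self.se_midpoint_, se=se,
            rss=self.rss_, n=self.n_iter_, converged=self.converged_,
        )


def fit_4pl(x, y, fix_bottom: float | None = None, fix_top: float | None = None) -> DoseResponseFit:
    """Least-squares 4PL fit; see :class:`FourParamLogistic`."""
    est = FourParamLogistic(fix_bottom=fix_bottom, fix_top=fix_top).fit(x, y)
    return est.result()


def ed50_from_study(
    dose_groups: Mapping[float, float],
    vehicle_mean: float,
    fix_top: float | None = None,
) -> DoseResponseFit:
    """In vivo ED50 from treated group means versus a vehicle group.

    Group means are converted to percent inhibition of the vehicle mean
    and fitted with the bottom asymptote fixed at 0 (inhibition scale);
    the vehicle group itself only enters through the normalization and
    is never a fitted point.  Requires at least 4 dose groups.

    Degenerate designs are flagged: an essentially flat response raises
    :class:`DoseResponseError` ("no response"); a response saturated at
    every dose returns a fit carrying the ``'unidentifiable_midpoint'``
    flag (the midpoint then lies below the tested dose range).
    """
    doses = np.asarray(sorted(dose_groups), dtype=float)
    if doses.size < 4:
        raise DoseResponseError("need >= 4 dose groups for ED50 estimation")
    inhib = np.array(
        [percent_inhibition(dose_groups[d], vehicle_mean) for d in doses]
    )
    if np.max(np.abs(inhib)) < 5.0:
        raise DoseResponseError("no response: all groups within 5 % of vehicle")
    flags = []
    if np.min(inhib) > 0.8 * np.max(inhib) and np.max(inhib) > 50.0:
        flags.append("unidentifiable_midpoint")
    try:
        fit = fit_4pl(doses, inhib, fix_bottom=0.0, fix_top=fix_top)
    except ConvergenceError as exc:
        if not flags:
            raise
        fit = DoseResponseFit(
            bottom=0.0, top=exc.params.get("top", float("nan")),
            midpoint=exc.params.get("midpoint", float("nan")),
            hill=exc.params.get("hill", float("nan")),
            se_midpoint=float("nan"), converged=False,
        )
    fit.flags.extend(flags)
    return fit
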