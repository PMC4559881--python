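"""Non-compartmental pharmacokinetic analysis and binding/transport arithmetic.

Model-free summaries of concentration–time data: Cmax/Tmax, linear
trapezoidal AUC with standard BLQ substitution, terminal log-linear
half-life, clearance / volume / oral bioavailability from a matched
i.v. + p.o. pair, unbound-exposure scaling by the free fraction, and the
transporter efflux ratio.

Unit conventions: doses in μmol/kg, concentrations in μM, times in
hours.  Clearance is reported in ml/min/kg and the terminal volume of
distribution in l/kg, the usual preclinical reporting units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import ConcentrationTimeProfile, ProfileError

LN2 = math.log(2.0)


class NCAError(ValueError):
    """An NCA precondition failed (e.g. no quantifiable data)."""


# ---------------------------------------------------------------------------
# binding / transport arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParams:
    """Nonspecific binding of drug to plasma proteins or brain homogenate.

    ``bound_percent`` is the percent bound measured by equilibrium
    dialysis; the free fraction is fu = 1 − bound/100.
    """

    bound_percent: float
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_percent < 100.0:
            raise NCAError("bound_percent must lie in [0, 100)")
        if self.matrix not in {"plasma", "brain_homogenate"}:
            raise NCAError(f"unknown binding matrix {self.matrix!r}")

    @property
    def free_fraction(self) -> float:
        return 1.0 - self.bound_percent / 100.0


def unbound_auc(auc_total: float, binding: BindingParams | float) -> float:
    """Scale a total AUC to unbound exposure by the free fraction.

    ``binding`` may be a :class:`BindingParams` or a bound-percent value.
    Raises when binding is 100 % (free exposure undefined).
    """
    if not isinstance(binding, BindingParams):
        binding = BindingParams(bound_percent=float(binding))
    if auc_total < 0:
        raise NCAError("auc_total must be >= 0")
    return auc_total * binding.free_fraction


def efflux_ratio(flux_ba: float, flux_ab: float) -> float:
    """Basolateral→apical over apical→basolateral flux ratio (MDR1-MDCK)."""
    if flux_ba <= 0 or flux_ab <= 0:
        raise NCAError("fluxes must be > 0")
    return flux_ba / flux_ab


# ---------------------------------------------------------------------------
# single-profile quantities
# ---------------------------------------------------------------------------

def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed post-dose concentration and its time.

    Ties are broken toward the earliest time.  Raises
    :class:`NCAError` if the profile has no quantifiable post-dose point.
    """
    m = profile.numeric_mask & profile.postdose_mask
    if not m.any():
        raise NCAError("no quantifiable concentration in profile")
    t = profile.times[m]
    c = profile.concentrations[m]
    i = int(np.argmax(c))  # argmax returns the first maximum -> earliest time
    return float(c[i]), float(t[i])


def auc_trapezoid(
    profile: ConcentrationTimeProfile, t_start: float, t_end: float
) -> float:
    """Linear trapezoidal AUC over ``[t_start, t_end]``.

    The grid is the observed sampling times restricted to the window,
    with window endpoints obtained by linear interpolation, which makes
    the area exactly additive over adjacent windows.  BLQ samples are
    substituted per :meth:`ConcentrationTimeProfile.auc_concentrations`.
    """
    if t_end <= t_start:
        raise NCAError("t_end must exceed t_start")
    t = profile.times
    c = profile.auc_concentrations()
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise NCAError(
            f"window [{t_start}, {t_end}] h extends beyond observed times "
            f"[{t[0]}, {t[-1]}] h"
        )
    inside = (t > t_start) & (t < t_end)
    grid = np.concatenate(([t_start], t[inside], [t_end]))
    vals = np.concatenate(
        ([np.interp(t_start, t, c)], c[inside], [np.interp(t_end, t, c)])
    )
    if grid.size < 2:
        raise NCAError("fewer than 2 points in AUC window")
    return float(np.trapezoid(vals, grid))


@dataclass(frozen=True)
class TerminalPhaseFit:
    """Log-linear terminal phase regression result."""

    lambda_z: float          #: terminal rate constant, 1/h
    intercept_log: float     #: intercept of ln C vs t regression
    n_points: int            #: points used in the regression
    r_squared_adj: float     #: adjusted R² of the regression
    t_last: float            #: last observed quantifiable time, h

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z

    @property
    def c_last_pred(self) -> float:
        """Regression-predicted concentration at the last observed time."""
        return math.exp(self.intercept_log - self.lambda_z * self.t_last)


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, np.log(c), 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((np.log(c) - pred) ** 2))
    ss_tot = float(np.sum((np.log(c) - np.log(c).mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def terminal_half_life(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> TerminalPhaseFit:
    """Terminal rate constant λz and half-life from log-linear regression.

    Candidate points are the quantifiable samples strictly after Tmax.
    The default selection starts with the last ``min_points`` samples and
    extends backwards while the adjusted R² of the regression improves.
    BLQ samples are excluded.  Raises if the fitted slope is
    non-negative (no measurable terminal decline).
    """
    _, tmax = cmax_tmax(profile)
    m = profile.numeric_mask & (profile.times > tmax)
    t = profile.times[m]
    c = profile.concentrations[m]
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < min_points:
        raise NCAError(
            f"need >= {min_points} quantifiable points after Tmax for the "
            f"terminal phase, found {t.size}"
        )

    def adj_r2(k: int) -> tuple[float, float, float]:
        slope, intercept, r2 = _loglinear(t[-k:], c[-k:])
        n = k
        return slope, intercept, 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    best_k = min_points
    slope, intercept, best = adj_r2(best_k)
    for k in range(min_points + 1, t.size + 1):
        s, i, a = adj_r2(k)
        if a > best + 1e-12:
            best_k, best, slope, intercept = k, a, s, i
        else:
            break
    if slope >= 0:
        raise NCAError("no measurable terminal decline (non-negative slope)")
    return TerminalPhaseFit(
        lambda_z=-slope,
        intercept_log=intercept,
        n_points=best_k,
        r_squared_adj=best,
        t_last=float(t[-1]),
    )


def auc_to_infinity(profile: ConcentrationTimeProfile) -> tuple[float, float, TerminalPhaseFit]:
    """AUC(0→∞) = AUC(0→tlast) + C_last_pred/λz.

    Returns (auc_inf, extrapolated_fraction, terminal_fit).  The
    extrapolated tail uses the regression-predicted last concentration.
    """
    term = terminal_half_life(profile)
    t0 = max(0.0, profile.times[0])
    auc_last = auc_trapezoid(profile, t0, term.t_last)
    tail = term.c_last_pred / term.lambda_z
    auc_inf = auc_last + tail
    return auc_inf, tail / auc_inf, term


@dataclass
class NCAResult:
    """Non-compartmental parameter set from a matched i.v./p.o. pair."""

    cmax: float              #: maximum oral concentration (profile units)
    tmax: float              #: time of Cmax, h
    auc_0_t: float           #: oral AUC over the observed range, conc·h
    auc_0_inf: float         #: oral AUC extrapolated to infinity, conc·h
    lambda_z: float          #: i.v. terminal rate constant, 1/h
    clearance: float         #: blood clearance, ml/min/kg
    vz: float                #: terminal volume of distribution, l/kg
    f_oral: float            #: absolute oral bioavailability, fraction
    warnings: list[str] = field(default_factory=list)

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z


def nca_summary(
    iv_profile: ConcentrationTimeProfile,
    po_profile: ConcentrationTimeProfile,
) -> NCAResult:
    """Clearance, Vz, half-life and oral bioavailability from an i.v./p.o. pair.

    CL = Dose_iv / AUC∞_iv (converted to ml/min/kg), Vz = CL/λz (l/kg),
    F = (AUC∞_po/Dose_po) / (AUC∞_iv/Dose_iv).  A warning is attached when
    more than 20 % of either AUC is extrapolated.
    """
    if iv_profile.dose <= 0 or po_profile.dose <= 0:
        raise NCAError("both profiles need a positive dose")
    warnings: list[str] = []
    auc_inf_iv, frac_iv, term_iv = auc_to_infinity(iv_profile)
    auc_inf_po, frac_po, _ = auc_to_infinity(po_profile)
    for label, frac in (("iv", frac_iv), ("po", frac_po)):
        if frac > 0.20:
            warnings.append(
                f"{label} AUC extrapolation fraction {frac:.1%} exceeds 20 %"
            )
    # dose μmol/kg over AUC μM·h = μmol/(μmol/l)/h/kg = l/h/kg
    cl_l_h_kg = iv_profile.dose / auc_inf_iv
    cl_ml_min_kg = cl_l_h_kg * 1000.0 / 60.0
    vz = cl_l_h_kg / term_iv.lambda_z
    f = (auc_inf_po / po_profile.dose) / (auc_inf_iv / iv_profile.dose)
    if not 0.0 <= f <= 1.05:
        warnings.append(f"oral bioavailability {f:.2f} outside [0, 1.05]")
    cmax, tmax = cmax_tmax(po_profile)
    t0 = max(0.0, po_profile.times[0])
    t_last_po = po_profile.times[po_profile.numeric_mask][-1]
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_trapezoid(po_profile, t0, float(t_last_po)),
        auc_0_inf=auc_inf_po,
        lambda_z=term_iv.lambda_z,
        clearance=cl_ml_min_kg,
        vz=vz,
        f_oral=f,
        warnings=warnings,
    )
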