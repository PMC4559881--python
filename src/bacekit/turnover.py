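"""Indirect-response (turnover) PK/PD model for biomarker suppression.

A synthesis inhibitor (here a BACE-1 inhibitor suppressing Aβ
production) acts on the production side of a turnover system:

    dR/dt = kin · (1 − Imax · C(t) / (IC50 + C(t))) − kout · R

where R is the biomarker (e.g. CSF Aβ40), kin its zero-order production
rate, kout its first-order clearance rate constant, and C(t) the blood
drug concentration.  At steady state the baseline is R0 = kin/kout; the
biomarker half-life is ln2/kout.  Under complete blockade (C ≫ IC50,
Imax = 1) the response decays as R0·e^(−kout·t), giving the closed-form
percent reduction 100·(1 − e^(−kout·t)).

The PK forcing is a one-compartment first-order absorption model
(Bateman function).  Fitting is sequential: the forcing is fitted to the
blood profile first, then (kout, IC50) are estimated from the response
series with kin constrained through the observed predose baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .profiles import ConcentrationTimeProfile

LN2 = math.log(2.0)


class TurnoverError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PK forcing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PkForcing:
    """One-compartment oral PK forcing function.

    ``dose_scaled`` is F·D/V (amount per volume, i.e. the concentration
    scale), ``ka`` and ``ke`` the absorption and elimination rate
    constants (1/h), ``lag`` an optional absorption lag (h).
    """

    dose_scaled: float
    ka: float
    ke: float
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_scaled < 0 or self.ka <= 0 or self.ke <= 0 or self.lag < 0:
            raise TurnoverError("rates must be > 0, dose_scaled and lag >= 0")
        if self.ka == self.ke:
            # flip-flop degenerate point of the Bateman closed form
            object.__setattr__(self, "ka", self.ka * (1.0 + 1e-9))

    def conc(self, t) -> np.ndarray:
        """Closed-form concentration C(t); 0 before the lag time."""
        t = np.asarray(t, dtype=float)
        dt = t - self.lag
        scale = self.dose_scaled * self.ka / (self.ka - self.ke)
        with np.errstate(over="ignore"):
            c = scale * (np.exp(-self.ke * dt) - np.exp(-self.ka * dt))
        return np.where(dt >= 0, c, 0.0)

    def __call__(self, t):
        return self.conc(t)


def simulate_pk_oral(
    forcing: PkForcing,
    times: Sequence[float],
    subject_id: str = "sim",
    matrix: str = "blood",
    dose: float = 0.0,
    unit: str = "uM",
) -> ConcentrationTimeProfile:
    """Sample the closed-form one-compartment oral profile at ``times``."""
    t = np.asarray(times, dtype=float)
    return ConcentrationTimeProfile(
        subject_id=subject_id,
        matrix=matrix,
        times=t,
        concentrations=forcing.conc(t),
        dose=dose,
        route="po",
        unit=unit,
    )


# ---------------------------------------------------------------------------
# turnover model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurnoverModel:
    """Indirect-response parameters.

    kin : production rate, response units/h.
    kout : clearance rate constant, 1/h (biomarker t½ = ln2/kout).
    ic50 : drug concentration giving half-maximal production inhibition, μM.
    imax : maximal fractional inhibition of production, in (0, 1].
    """

    kin: float
    kout: float
    ic50: float
    imax: float = 1.0

    def __post_init__(self) -> None:
        if self.kout <= 0 or self.kin <= 0:
            raise TurnoverError("kin and kout must be > 0")
        if self.ic50 <= 0:
            raise TurnoverError("ic50 must be > 0")
        if not 0.0 < self.imax <= 1.0:
            raise TurnoverError("imax must lie in (0, 1]")

    @property
    def baseline(self) -> float:
        """Steady-state response R0 = kin/kout."""
        return self.kin / self.kout

    @property
    def t_half(self) -> float:
        return LN2 / self.kout


def _as_conc_callable(conc) -> Callable[[np.ndarray], np.ndarray]:
    if callable(conc):
        return conc
    if isinstance(conc, ConcentrationTimeProfile):
        t, c = conc.times, conc.auc_concentrations()
    else:
        t, c = (np.asarray(a, dtype=float) for a in conc)
    return lambda x: np.clip(np.interp(x, t, c), 0.0, None)


def simulate_turnover(
    model: TurnoverModel,
    conc,
    times: Sequence[float],
    r0: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the indirect-response ODE and return R at ``times``.

    ``conc`` may be a callable C(t), a :class:`ConcentrationTimeProfile`
    (linearly interpolated), or a (times, values) pair.  The response is
    initialized at the steady state kin/kout unless ``r0`` is given.
    Times before 0 (predose) return the initial value.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise TurnoverError("times must be 1-d and strictly increasing")
    cfun = _as_conc_callable(conc)
    r_init = model.baseline if r0 is None else float(r0)

    def rhs(t, r):
        c = float(np.asarray(cfun(t)))
        inhib = model.imax * c / (model.ic50 + c)
        return model.kin * (1.0 - inhib) - model.kout * r[0]

    t_start = min(0.0, times[0])
    pre = times < t_start + 1e-15
    eval_times = times[~pre]
    out = np.empty_like(times)
    out[pre] = r_init
    if eval_times.size:
        sol = solve_ivp(
            rhs,
            (t_start, float(eval_times[-1])),
            [r_init],
            t_eval=eval_times,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise TurnoverError(f"ODE solver failed: {sol.message}")
        out[~pre] = sol.y[0]
    return out


def complete_blockade_reduction(kout: float, t: float) -> float:
    """Percent biomarker reduction after time t of complete production blockade.

    100 × (1 − e^(−kout·t)): with production fully inhibited the response
    decays mono-exponentially at its own clearance rate.
    """
    if kout <= 0:
        raise TurnoverError("kout must be > 0")
    if t < 0:
        raise TurnoverError("t must be >= 0")
    return 100.0 * (1.0 - math.exp(-kout * t))


def half_life_from_kout(kout: float) -> float:
    """Biomarker half-life ln2/kout (h)."""
    if kout <= 0:
        raise TurnoverError("kout must be > 0")
    return LN2 / kout


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_pk_forcing(profile: ConcentrationTimeProfile) -> PkForcing:
    """Least-squares fit of the one-compartment oral closed form to a blood profile."""
    m = profile.numeric_mask & profile.postdose_mask & (profile.times > 0)
    t = profile.times[m]
    c = profile.concentrations[m]
    if t.size < 4:
        raise TurnoverError("need >= 4 post-dose points to fit the PK forcing")
    cmax = float(c.max())
    tmax = float(t[np.argmax(c)])
    # heuristics: ke from the last points, ka a few-fold faster, scale near Cmax
    tail = c > 0
    ke0 = max(np.log(2) / max(t[tail][-1] / 3.0, tmax), 1e-3)
    if (c[tail][-1] > 0) and t[tail][-1] > tmax:
        ke0 = max(np.log(c[np.argmax(c)] / c[tail][-1]) / (t[tail][-1] - tmax), 1e-3)
    theta0 = np.log([max(cmax, 1e-9) * 1.5, max(3.0 * ke0, 0.5), ke0])

    def resid(theta):
        ds, ka, ke = np.exp(theta)
        f = PkForcing(dose_scaled=ds, ka=max(ka, ke * (1 + 1e-6)), ke=ke)
        return f.conc(t) - c

    sol = least_squares(resid, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=20000)
    ds, ka, ke = np.exp(sol.x)
    if ka < ke:  # report the conventional (absorption faster) branch
        ka, ke = ke, ka
    return PkForcing(dose_scaled=float(ds), ka=float(ka), ke=float(ke))


@dataclass
class TurnoverFit:
    """Result of the sequential PK-then-PD turnover fit."""

    model: TurnoverModel
    forcing: PkForcing
    r0: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = True
    message: str = ""


class TurnoverEstimator(BaseEstimator):
    """Sequential indirect-response fit as a scikit-learn style estimator.

    ``fit(X, y)`` takes X = response times (h, predose negative) and
    y = response values; the blood PK profile is a constructor argument
    (or a pre-fitted :class:`PkForcing`).  kin is constrained to
    kout·R0 with R0 the mean of the predose samples, so only
    (kout, IC50) are free; Imax is fixed (default 1: complete enzyme
    blockade at saturating concentration).

    Attributes: ``model_`` (:class:`TurnoverModel`), ``forcing_``,
    ``r0_``, ``se_`` (asymptotic SEs for kout and ic50), ``rss_``,
    ``converged_``.
    """

    def __init__(self, blood=None, imax: float = 1.0, rtol: float = 1e-7,
                 seed: int = 0):
        self.blood = blood
        self.imax = imax
        self.rtol = rtol
        self.seed = seed  # reserved for stochastic restarts; fit is deterministic

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=float).ravel()
        if t.shape != r.shape:
            raise TurnoverError("times and response must have equal length")
        order = np.argsort(t)
        t, r = t[order], r[order]
        pre = t < 0
        if not pre.any():
            raise TurnoverError("response series must include predose baseline samples")
        r0 = float(r[pre].mean())
        if r0 <= 0:
            raise TurnoverError("predose baseline must be > 0")
        if np.ptp(r) < 0.05 * r0:
            raise TurnoverError("unidentifiable fit: response is flat")

        if isinstance(self.blood, PkForcing):
            forcing = self.blood
        elif self.blood is not None:
            forcing = fit_pk_forcing(self.blood)
        else:
            raise TurnoverError("a blood profile or PkForcing is required")

        # initial values: kout from the recovery tail time-scale, ic50 a
        # tenth of the peak concentration
        kout0 = 0.2
        ic500 = max(float(forcing.conc(np.array([1.0, 2.0, 4.0])).max()) / 10.0, 1e-6)
        theta0 = np.log([kout0, ic500])
        post = ~pre

        t_post_unique, inv = np.unique(t[post], return_inverse=True)

        def resid(theta):
            kout, ic50 = np.exp(theta)
            model = TurnoverModel(kin=kout * r0, kout=kout, ic50=ic50,
                                  imax=self.imax)
            pred = simulate_turnover(model, forcing, t_post_unique, r0=r0,
                                     rtol=self.rtol, atol=self.rtol * r0 * 1e-3)[inv]
            return np.concatenate([(np.full(pre.sum(), r0) - r[pre]),
                                   pred - r[post]])

        sol = least_squares(resid, theta0, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            max_nfev=400)
        kout, ic50 = np.exp(sol.x)
        self.model_ = TurnoverModel(kin=float(kout * r0), kout=float(kout),
                                    ic50=float(ic50), imax=self.imax)
        self.forcing_ = forcing
        self.r0_ = r0
        self.rss_ = float(2.0 * sol.cost)
        self.converged_ = bool(sol.success)
        self.message_ = str(sol.message)

        dof = max(t.size - 2, 1)
        s2 = self.rss_ / dof
        try:
            cov_log = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
            # delta method back to the natural scale
            self.se_ = {"kout": float(kout * se_log[0]),
                        "ic50": float(ic50 * se_log[1])}
        except np.linalg.LinAlgError:
            self.se_ = {"kout": float("nan"), "ic50": float("nan")}
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel()
        return simulate_turnover(self.model_, self.forcing_, t, r0=self.r0_,
                                 rtol=self.rtol)

    def result(self) -> TurnoverFit:
        return TurnoverFit(model=self.model_, forcing=self.forcing_,
                           r0=self.r0_, se=self.se_, rss=self.rss_,
                           converged=self.converged_, message=self.message_)


def fit_turnover(
    blood: ConcentrationTimeProfile | PkForcing,
    response_times: Sequence[float],
    response_values: Sequence[float],
    imax: float = 1.0,
) -> TurnoverFit:
    """Sequential PK-then-PD fit; see :class:`TurnoverEstimator`."""
    est = TurnoverEstimator(blood=blood, imax=imax).fit(response_times, response_values)
    return est.result()
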