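"""Parametric survival laws used to extrapolate trial PFS and OS curves.

Six accelerated-failure-time families are supported: exponential, Weibull,
Gompertz, log-normal, log-logistic and (two-parameter) gamma.  Parameterizations
follow the Stata ``streg`` conventions, which is also how the published survival
parameters for the IMpower010 arms are scaled:

=============  ==================================  =========================
family         survivor function S(t)              parameters
=============  ==================================  =========================
exponential    exp(-lam*t)                         rate lam
weibull        exp(-lam*t**p)                      rate lam, shape p
gompertz       exp(-lam/a*(exp(a*t)-1))            rate lam, shape a (any real)
lognormal      1 - Phi((ln t - mu)/sigma)          meanlog mu, sdlog sigma
loglogistic    1/(1 + (lam*t)**(1/gamma))          rate lam, scale gamma
gamma          1 - GammaCDF(t; k, rate)            shape k, rate
=============  ==================================  =========================

Time is measured in months throughout.  A Gompertz law with negative shape is
defective: S(t) -> exp(lam/a) > 0 as t -> infinity, so its median may not exist.

Fitting is plain maximum likelihood for right-censored data (no covariates),
optimized by Nelder-Mead on log-transformed positive parameters with a small
fixed set of starting points; the exponential MLE is closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "SurvivalModel",
    "FitResult",
    "survival_at",
    "median_survival",
    "log_likelihood",
    "fit_parametric",
    "select_by_aic",
    "param_covariance",
    "ipd_frame",
    "read_ipd",
    "write_ipd",
]

#: Fixed family enumeration order; also the AIC tie-break order.
FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic", "gamma")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("rate", "shape"),
    "gompertz": ("rate", "shape"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("rate", "gamma"),
    "gamma": ("shape", "rate"),
}

_GOMPERTZ_SHAPE_EPS = 1e-12


def _validate_params(family: str, params: tuple[float, ...]) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}; expected one of {FAMILIES}")
    names = PARAM_NAMES[family]
    if len(params) != len(names):
        raise ValueError(
            f"{family} expects {len(names)} parameter(s) {names}, got {len(params)}"
        )
    for name, value in zip(names, params):
        if not np.isfinite(value):
            raise ValueError(f"{family} parameter {name}={value} is not finite")
        # Gompertz shape may take any real value (negative => defective law).
        if family == "gompertz" and name == "shape":
            continue
        if value <= 0:
            raise ValueError(f"{family} parameter {name}={value} must be strictly positive")


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric time-to-event law (family + parameters), time unit months."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        _validate_params(self.family, self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES[self.family], self.params))

    def _frozen(self):
        f, p = self.family, self.params
        if f == "exponential":
            return stats.expon(scale=1.0 / p[0])
        if f == "weibull":
            lam, shape = p
            return stats.weibull_min(shape, scale=lam ** (-1.0 / shape))
        if f == "lognormal":
            mu, sigma = p
            return stats.lognorm(sigma, scale=math.exp(mu))
        if f == "loglogistic":
            lam, gam = p
            return stats.fisk(1.0 / gam, scale=1.0 / lam)
        if f == "gamma":
            shape, rate = p
            return stats.gamma(shape, scale=1.0 / rate)
        raise AssertionError(f)

    # -- survivor function ------------------------------------------------
    def sf(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        if self.family == "gompertz":
            lam, a = self.params
            if abs(a) < _GOMPERTZ_SHAPE_EPS:
                out = np.exp(-lam * t)
            else:
                out = np.exp(-lam * np.expm1(a * t) / a)
        else:
            out = self._frozen().sf(t)
        return out if out.shape else float(out)

    def logsf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "gompertz":
            lam, a = self.params
            if abs(a) < _GOMPERTZ_SHAPE_EPS:
                out = -lam * t
            else:
                out = -lam * np.expm1(a * t) / a
        else:
            out = self._frozen().logsf(t)
        return out if out.shape else float(out)

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "gompertz":
            lam, a = self.params
            # hazard lam*exp(a*t) times survivor
            if abs(a) < _GOMPERTZ_SHAPE_EPS:
                out = math.log(lam) - lam * t
            else:
                out = math.log(lam) + a * t - lam * np.expm1(a * t) / a
        else:
            out = self._frozen().logpdf(t)
        return out if out.shape else float(out)

    def ppf(self, q):
        """Inverse CDF (event-time quantile)."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile level must lie in [0, 1]")
        if self.family == "gompertz":
            lam, a = self.params
            if abs(a) < _GOMPERTZ_SHAPE_EPS:
                out = -np.log1p(-q) / lam
            else:
                arg = a * (-np.log1p(-q)) / lam
                with np.errstate(invalid="ignore", divide="ignore"):
                    out = np.where(arg > -1.0, np.log1p(np.maximum(arg, -1.0 + 1e-300)) / a, np.inf)
        else:
            out = self._frozen().ppf(q)
        return out if out.shape else float(out)

    @property
    def sf_limit(self) -> float:
        """S(t) as t -> infinity (non-zero only for defective Gompertz)."""
        if self.family == "gompertz":
            lam, a = self.params
            if a < -_GOMPERTZ_SHAPE_EPS:
                return math.exp(lam / a)
        return 0.0


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit of one family: model, log-likelihood and AIC."""

    model: SurvivalModel
    loglik: float
    aic: float
    n: int
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        k = self.model.n_params
        expected = 2 * k - 2 * self.loglik
        if self.converged and abs(self.aic - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("aic inconsistent with 2k - 2*loglik")


def survival_at(model: SurvivalModel, t: float) -> float:
    """Survivor probability S(t); S(0) = 1, non-increasing in t."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(model.sf(t))


def median_survival(model: SurvivalModel) -> float:
    """Time at which S(t) = 0.5; ``inf`` when the law never reaches 0.5."""
    if model.sf_limit > 0.5:
        return math.inf
    f, p = model.family, model.params
    if f == "exponential":
        return math.log(2.0) / p[0]
    if f == "weibull":
        lam, shape = p
        return (math.log(2.0) / lam) ** (1.0 / shape)
    if f == "lognormal":
        return math.exp(p[0])
    if f == "loglogistic":
        return 1.0 / p[0]
    if f == "gompertz":
        lam, a = p
        if abs(a) < _GOMPERTZ_SHAPE_EPS:
            return math.log(2.0) / lam
        return math.log1p(a * math.log(2.0) / lam) / a
    return float(model._frozen().median())


# ---------------------------------------------------------------------------
# IPD container helpers (CSV dialect: header ``time,event``, months, 0/1)
# ---------------------------------------------------------------------------

def ipd_frame(times, events) -> pd.DataFrame:
    """Build a validated individual-patient-data frame (time in months, event 0/1)."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int)})
    if len(df) and (not np.all(np.isfinite(df["time"])) or (df["time"] < 0).any()):
        raise ValueError("times must be finite and non-negative")
    if len(df) and not df["event"].isin((0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return df


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return ipd_frame(df["time"], df["event"])


def write_ipd(df: pd.DataFrame, path) -> None:
    df[["time", "event"]].to_csv(path, index=False)


def log_likelihood(model: SurvivalModel, data: pd.DataFrame) -> float:
    """Right-censored log-likelihood: sum of log f over events, log S over censored."""
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy()
    ll = np.where(e == 1, model.logpdf(np.maximum(t, 1e-300)), model.logsf(t))
    if not np.all(np.isfinite(ll)):
        return -math.inf
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _start_values(family: str, t: np.ndarray, e: np.ndarray) -> tuple[float, ...]:
    d = max(int(e.sum()), 1)
    rate0 = d / max(float(t.sum()), 1e-12)
    if family == "exponential":
        return (rate0,)
    if family == "weibull":
        return (rate0, 1.0)
    if family == "gompertz":
        return (rate0, 1e-4)
    if family == "lognormal":
        logs = np.log(np.maximum(t[e == 1], 1e-12))
        if logs.size == 0:
            logs = np.log(np.maximum(t, 1e-12))
        return (float(np.mean(logs)), max(float(np.std(logs)), 0.1))
    if family == "loglogistic":
        med = max(float(np.median(t)), 1e-6)
        return (1.0 / med, 1.0)
    if family == "gamma":
        return (1.0, rate0)
    raise AssertionError(family)


def _to_unconstrained(family: str, params) -> np.ndarray:
    theta = []
    for name, v in zip(PARAM_NAMES[family], params):
        if family == "gompertz" and name == "shape":
            theta.append(v)
        elif family == "lognormal" and name == "meanlog":
            theta.append(v)
        else:
            theta.append(math.log(v))
    return np.asarray(theta, dtype=float)


def _from_unconstrained(family: str, theta) -> tuple[float, ...]:
    params = []
    for name, v in zip(PARAM_NAMES[family], theta):
        if (family == "gompertz" and name == "shape") or (
            family == "lognormal" and name == "meanlog"
        ):
            params.append(float(v))
        else:
            params.append(float(math.exp(np.clip(v, -700, 700))))
    return tuple(params)


def fit_parametric(data: pd.DataFrame, family: str) -> FitResult:
    """Maximum-likelihood fit of one AFT family to right-censored data.

    Requires at least 10 records with at least one event.  Non-convergence is
    reported through ``converged``/``message`` on the returned result rather
    than raised, so callers can still rank whatever did converge.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(data) < 10:
        raise ValueError("need at least 10 records to fit")
    t = data["time"].to_numpy(dtype=float)
    e = data["event"].to_numpy()
    if e.sum() < 1:
        raise ValueError("need at least one event to fit")
    n = len(data)

    if family == "exponential":
        # Closed-form MLE: rate = events / total follow-up time.
        rate = float(e.sum()) / float(t.sum())
        model = SurvivalModel("exponential", (rate,))
        ll = log_likelihood(model, data)
        return FitResult(model, ll, 2 * 1 - 2 * ll, n)

    def nll(theta: np.ndarray) -> float:
        try:
            model = SurvivalModel(family, _from_unconstrained(family, theta))
        except ValueError:
            return math.inf
        ll = log_likelihood(model, data)
        return -ll if math.isfinite(ll) else math.inf

    base = _start_values(family, t, e)
    starts = [base]
    if family == "gompertz":
        lam0, _ = base
        starts += [(lam0, 0.02), (lam0 * 0.5, -0.01)]
    elif family == "lognormal":
        mu0, s0 = base
        starts += [(mu0, s0 * 2.0), (mu0 + 1.0, s0)]
    else:
        starts += [tuple(p * 0.5 for p in base), tuple(p * 2.0 for p in base)]

    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            _to_unconstrained(family, s),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish from the incumbent
    res = optimize.minimize(
        nll, best.x, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 4000, "maxfev": 6000},
    )
    if res.fun < best.fun:
        best = res

    if not math.isfinite(best.fun):
        model = SurvivalModel(family, base)
        return FitResult(model, -math.inf, math.inf, n, converged=False,
                         message="optimizer failed to find a finite likelihood")

    model = SurvivalModel(family, _from_unconstrained(family, best.x))
    ll = -float(best.fun)
    converged = bool(best.success) or best.status == 0
    msg = "" if converged else str(best.message)
    return FitResult(model, ll, 2 * model.n_params - 2 * ll, n,
                     converged=converged, message=msg)


def fit_all_families(data: pd.DataFrame) -> list[FitResult]:
    """Fit every family in the fixed enumeration order."""
    return [fit_parametric(data, fam) for fam in FAMILIES]


def select_by_aic(fits: list[FitResult]) -> FitResult:
    """Minimum-AIC fit; ties broken by fewer parameters, then family order."""
    ok = [f for f in fits if f.converged and math.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fits to select from")
    return min(ok, key=lambda f: (f.aic, f.model.n_params, FAMILIES.index(f.model.family)))


def param_covariance(fit: FitResult, data: pd.DataFrame, rel_step: float = 1e-4) -> np.ndarray:
    """Asymptotic parameter covariance from the numerically observed information.

    Central finite differences of the log-likelihood at the MLE, on the natural
    parameter scale.  Used for standard-error based recovery checks.
    """
    model = fit.model
    p0 = np.asarray(model.params, dtype=float)
    k = p0.size
    h = np.maximum(np.abs(p0) * rel_step, 1e-8)

    def ll(p):
        try:
            return log_likelihood(SurvivalModel(model.family, tuple(p)), data)
        except ValueError:
            return -math.inf

    H = np.empty((k, k))
    f0 = ll(p0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (ll(p0 + ei) - 2 * f0 + ll(p0 - ei)) / (h[i] ** 2)
            else:
                val = (
                    ll(p0 + ei + ej) - ll(p0 + ei - ej)
                    - ll(p0 - ei + ej) + ll(p0 - ei - ej)
                ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return np.linalg.inv(-H)


def fit_report(fits: dict[tuple[str, str, str], list[FitResult]]) -> pd.DataFrame:
    """Tabulate fits keyed by (group, arm, endpoint) into a tidy frame.

    Columns: group, arm, endpoint, family, loglik, aic, params...
    """
    rows = []
    for (group, arm, endpoint), fit_list in fits.items():
        for f in fit_list:
            row = {
                "group": group, "arm": arm, "endpoint": endpoint,
                "family": f.model.family, "loglik": f.loglik, "aic": f.aic,
                "n": f.n, "converged": f.converged,
            }
            for name, value in f.model.param_dict.items():
                row[f"param_{name}"] = value
            rows.append(row)
    return pd.DataFrame(rows)
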