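"""Pseudo individual-patient-data reconstruction from digitized KM curves.

Published survival figures give only curve coordinates and numbers-at-risk.
The reconstruction here follows the iterative algorithm of Guyot and
colleagues: within each at-risk interval, a censoring count is guessed,
censor times are spread evenly, event counts at each digitized step are
back-solved from the survival ratios, and the censoring guess is adjusted
until the implied number at risk matches the published one at the next
interval boundary.  The output is a list of (time, event) records whose
Kaplan-Meier estimate tracks the input curve.

``km_estimate`` (product-limit estimator, via lifelines) closes the loop so
round trips simulate -> digitize -> reconstruct -> fit can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import ipd_frame

__all__ = [
    "KMCurve",
    "RiskTable",
    "km_estimate",
    "reconstruct_ipd",
    "read_km_curve",
    "write_km_curve",
    "read_risk_table",
    "write_risk_table",
]

_MAX_ADJUST_ITER = 40


@dataclass(frozen=True)
class KMCurve:
    """Digitized survivor-curve coordinates: strictly increasing times, S non-increasing."""

    times: np.ndarray
    survival: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.size != s.size or t.size == 0:
            raise ValueError("times and survival must be non-empty and equal length")
        problems = []
        bad_t = np.where(np.diff(t) <= 0)[0]
        if bad_t.size:
            problems.append(f"times not strictly increasing at rows {list(bad_t + 1)}")
        if np.any((s < 0) | (s > 1)):
            problems.append("survival values outside [0, 1]")
        rising = np.where(np.diff(s) > 1e-12)[0]
        if rising.size:
            problems.append(f"survival rising at rows {list(rising + 1)}")
        if t[0] < 0:
            problems.append("negative time")
        if problems:
            raise ValueError("invalid KM curve: " + "; ".join(problems))

    def eval(self, t: float) -> float:
        """Step-function value: survival at the last coordinate <= t (1.0 before the first)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at increasing calendar times (months)."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        problems = []
        if t.size == 0 or t.size != n.size:
            problems.append("times and n_at_risk must be non-empty and equal length")
        else:
            bad_t = np.where(np.diff(t) <= 0)[0]
            if bad_t.size:
                problems.append(f"times not strictly increasing at rows {list(bad_t + 1)}")
            inc = np.where(np.diff(n) > 0)[0]
            if inc.size:
                problems.append(f"n_at_risk increasing at rows {list(inc + 1)}")
            if np.any(n < 0):
                problems.append("negative n_at_risk")
        if problems:
            raise ValueError("invalid risk table: " + "; ".join(problems))


def km_estimate(data: pd.DataFrame, label: str = "") -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate as a step curve at event times."""
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    table = kmf.event_table
    drop_times = table.index[table["observed"] > 0].to_numpy(dtype=float)
    sf = kmf.survival_function_.iloc[:, 0]
    times = [0.0]
    surv = [1.0]
    for t in drop_times:
        if t <= 0:
            surv[0] = float(sf.loc[t])
            continue
        times.append(float(t))
        surv.append(float(sf.loc[t]))
    return KMCurve(np.asarray(times), np.asarray(surv), label=label)


def _interval_bounds(curve_times: np.ndarray, risk_times: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [lower, upper] of curve points inside each at-risk interval."""
    bounds = []
    n_int = risk_times.size
    for i in range(n_int):
        t_lo = risk_times[i]
        t_hi = risk_times[i + 1] if i + 1 < n_int else np.inf
        lower = int(np.searchsorted(curve_times, t_lo, side="left"))
        upper = int(np.searchsorted(curve_times, t_hi, side="left")) - 1
        bounds.append((lower, upper))
    return bounds


def reconstruct_ipd(
    curve: KMCurve,
    risk: RiskTable,
    total_events: int | None = None,
) -> pd.DataFrame:
    """Reconstruct pseudo patient records from a digitized curve and risk table.

    The number of returned records equals the initial number at risk; events
    plus censorings conserve patients in every interval.  When ``total_events``
    is given, censoring in the final interval is adjusted so the cumulative
    event count matches it; otherwise no censoring is assumed inside the final
    interval and all patients still at risk after the last digitized time are
    administratively censored there.
    """
    t = curve.times
    s = curve.survival
    if t[0] > 0:  # anchor the curve at (0, 1)
        t = np.concatenate(([0.0], t))
        s = np.concatenate(([1.0], s))
    if risk.times[0] < t[0] or risk.times[-1] > t[-1] + 1e-9:
        raise ValueError("curve must span the risk-table time range")
    n0 = int(risk.n_at_risk[0])
    if n0 <= 0:
        raise ValueError("initial number at risk must be positive")

    K = t.size
    d = np.zeros(K, dtype=int)          # events at each curve point
    c = np.zeros(K, dtype=int)          # censorings in (t_k, t_{k+1})
    cen_times: list[float] = []

    bounds = _interval_bounds(t, risk.times)
    n_hat = n0
    km_prev = 1.0  # reconstructed KM just before the current interval
    n_intervals = len(bounds)

    for i, (lower, upper) in enumerate(bounds):
        if upper < lower:
            continue
        last_interval = i == n_intervals - 1
        target_next = None if last_interval else int(risk.n_at_risk[i + 1])
        t_end = risk.times[i + 1] if not last_interval else t[-1]

        # initial censoring guess: expected at risk at the boundary under the
        # curve's survival ratio, minus the published count
        if last_interval:
            c_guess = 0
        else:
            s_lo = km_prev if km_prev > 0 else 1.0
            s_hi = s[upper]
            expected = n_hat * (s_hi / s_lo if s_lo > 0 else 0.0)
            c_guess = max(int(round(expected - target_next)), 0)

        for _ in range(_MAX_ADJUST_ITER):
            d_i = np.zeros(upper - lower + 1, dtype=int)
            c_i = np.zeros(upper - lower + 1, dtype=int)
            # spread censor times evenly over the interval
            if c_guess > 0:
                span_lo, span_hi = t[lower], t_end
                ct = span_lo + (np.arange(1, c_guess + 1) - 0.5) / c_guess * (span_hi - span_lo)
                idx = np.clip(np.searchsorted(t[lower : upper + 1], ct, side="right") - 1,
                              0, upper - lower)
                for j in idx:
                    c_i[j] += 1
            n_cur = n_hat
            km_run = km_prev
            for k in range(lower, upper + 1):
                if n_cur > 0 and km_run > 0:
                    dk = int(round(n_cur * (1.0 - s[k] / km_run)))
                else:
                    dk = 0
                dk = int(np.clip(dk, 0, n_cur))
                if dk > 0:
                    km_run *= 1.0 - dk / n_cur
                d_i[k - lower] = dk
                n_cur -= dk
                cens_here = min(c_i[k - lower], n_cur)
                c_i[k - lower] = cens_here
                n_cur -= cens_here
            if last_interval or n_cur == target_next:
                break
            c_new = max(c_guess + (n_cur - target_next), 0)
            if c_new == c_guess:
                break
            c_guess = c_new

        # final interval: honour total_events if supplied
        if last_interval and total_events is not None:
            for _ in range(_MAX_ADJUST_ITER):
                events_so_far = int(d[:lower].sum() + d_i.sum())
                gap = events_so_far - int(total_events)
                if gap == 0:
                    break
                c_new = max(c_guess + gap, 0)
                if c_new == c_guess:
                    break
                c_guess = c_new
                d_i = np.zeros(upper - lower + 1, dtype=int)
                c_i = np.zeros(upper - lower + 1, dtype=int)
                if c_guess > 0:
                    span_lo, span_hi = t[lower], t_end
                    ct = span_lo + (np.arange(1, c_guess + 1) - 0.5) / c_guess * (span_hi - span_lo)
                    idx = np.clip(np.searchsorted(t[lower : upper + 1], ct, side="right") - 1,
                                  0, upper - lower)
                    for j in idx:
                        c_i[j] += 1
                n_cur = n_hat
                km_run = km_prev
                for k in range(lower, upper + 1):
                    if n_cur > 0 and km_run > 0:
                        dk = int(round(n_cur * (1.0 - s[k] / km_run)))
                    else:
                        dk = 0
                    dk = int(np.clip(dk, 0, n_cur))
                    if dk > 0:
                        km_run *= 1.0 - dk / n_cur
                    d_i[k - lower] = dk
                    n_cur -= dk
                    cens_here = min(c_i[k - lower], n_cur)
                    c_i[k - lower] = cens_here
                    n_cur -= cens_here

        # commit the interval
        d[lower : upper + 1] = d_i
        c[lower : upper + 1] = c_i
        if c_guess > 0:
            span_lo, span_hi = t[lower], t_end
            committed = int(c_i.sum())
            if committed > 0:
                ct = span_lo + (np.arange(1, committed + 1) - 0.5) / committed * (span_hi - span_lo)
                cen_times.extend(float(x) for x in ct)
        km_prev = km_run if (upper >= lower) else km_prev
        n_hat = n_cur

    # administrative censoring of everyone still at risk at the curve's end
    times_out: list[float] = []
    events_out: list[int] = []
    for k in range(K):
        times_out.extend([float(t[k])] * d[k])
        events_out.extend([1] * d[k])
    times_out.extend(cen_times)
    events_out.extend([0] * len(cen_times))
    remaining = n0 - len(times_out)
    if remaining > 0:
        times_out.extend([float(t[-1])] * remaining)
        events_out.extend([0] * remaining)

    out = ipd_frame(times_out, events_out)
    assert len(out) == n0, "reconstruction must conserve patients"
    return out.sort_values(["time", "event"], ignore_index=True)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_km_curve(path, label: str = "") -> KMCurve:
    df = pd.read_csv(path)
    return KMCurve(df["time"].to_numpy(float), df["survival"].to_numpy(float), label=label)


def write_km_curve(curve: KMCurve, path) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(path, index=False)


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(df["time"].to_numpy(float), df["n_at_risk"].to_numpy(int))


def write_risk_table(risk: RiskTable, path) -> None:
    pd.DataFrame({"time": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(path, index=False)
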