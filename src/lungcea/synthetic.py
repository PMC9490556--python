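"""Synthetic trial data: simulated follow-up, emulated curve digitization.

The source study digitized published Kaplan-Meier figures; no patient data is
deposited anywhere.  This module generates everything needed to exercise the
reconstruction-and-fitting pipeline end to end from known ground truth:

* :func:`simulate_ipd` draws event times from a known survival law by inverse
  CDF, with administrative censoring at the end of follow-up (default 45
  months, roughly the trial's follow-up era);
* :func:`digitize` emulates reading coordinates off a KM figure - ``ideal``
  mode keeps every step point exactly, ``jitter`` mode rounds survival to
  0.001 and time to 0.05 months, mimicking graph-digitizer extraction error;
* :func:`make_fixture` bundles both arms of one analysis population (true
  models = the published parameters, 450 patients per arm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ipd import KMCurve, RiskTable, km_estimate
from .parameters import GroupSurvival, default_group_survival
from .survival import SurvivalModel, ipd_frame

__all__ = ["TrialFixture", "simulate_ipd", "digitize", "make_fixture"]

DEFAULT_N_PER_ARM = 450
DEFAULT_CENSOR_MONTHS = 45.0
RISK_INTERVAL_MONTHS = 6.0


def simulate_ipd(
    model: SurvivalModel,
    n: int,
    censor_time: float = DEFAULT_CENSOR_MONTHS,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` records from ``model`` with administrative censoring."""
    if n <= 0:
        raise ValueError("n must be positive")
    if censor_time <= 0:
        raise ValueError("censor time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    times = np.asarray(model.ppf(u), dtype=float)
    events = (times <= censor_time).astype(int)
    times = np.minimum(times, censor_time)
    return ipd_frame(times, events)


def _risk_table_from_ipd(data: pd.DataFrame, interval: float, t_max: float) -> RiskTable:
    marks = np.arange(0.0, t_max + 1e-9, interval)
    t = data["time"].to_numpy(float)
    n_at_risk = np.array([(t >= m).sum() for m in marks], dtype=int)
    keep = n_at_risk > 0
    keep[0] = True
    return RiskTable(marks[keep], n_at_risk[keep])


def digitize(
    curve: KMCurve,
    mode: str = "ideal",
    ipd: pd.DataFrame | None = None,
    risk_interval: float = RISK_INTERVAL_MONTHS,
) -> tuple[KMCurve, RiskTable]:
    """Emulate figure digitization of a KM curve plus its at-risk table.

    When the underlying records are supplied, at-risk counts are exact; without
    them, counts are approximated from the curve itself assuming no censoring
    before each mark (adequate for purely administratively censored designs).
    """
    if mode not in ("ideal", "jitter"):
        raise ValueError("mode must be 'ideal' or 'jitter'")
    t = curve.times.copy()
    s = curve.survival.copy()
    if mode == "jitter":
        t = np.round(t / 0.05) * 0.05
        s = np.round(s, 3)
        # rounding can break strict monotonicity; restore it
        keep = np.concatenate(([True], np.diff(t) > 0))
        t, s = t[keep], s[keep]
        s = np.minimum.accumulate(s)
    digitized = KMCurve(t, s, label=curve.label)

    t_max = float(curve.times[-1])
    if ipd is not None:
        risk = _risk_table_from_ipd(ipd, risk_interval, t_max)
    else:
        marks = np.arange(0.0, t_max + 1e-9, risk_interval)
        n0 = 100  # nominal cohort when true counts are unknown
        counts = np.array([max(int(round(n0 * curve.eval(m))), 0) for m in marks])
        keep = counts > 0
        keep[0] = True
        risk = RiskTable(marks[keep], counts[keep])
    return digitized, risk


@dataclass(frozen=True)
class TrialFixture:
    """Both arms of one analysis population, with digitized artifacts."""

    group: str
    n_per_arm: int
    censor_months: float
    true_models: GroupSurvival
    ipd: dict = field(default_factory=dict)        # (arm, endpoint) -> DataFrame
    curves: dict = field(default_factory=dict)     # (arm, endpoint) -> KMCurve
    risk_tables: dict = field(default_factory=dict)


def make_fixture(
    group: str,
    seed: int | np.random.SeedSequence = 0,
    n_per_arm: int = DEFAULT_N_PER_ARM,
    censor_months: float = DEFAULT_CENSOR_MONTHS,
    mode: str = "ideal",
) -> TrialFixture:
    """Simulate one trial-like population from the published survival laws."""
    groups = default_group_survival()
    if group not in groups:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(groups)}")
    truth = groups[group]
    models = {
        ("atezolizumab", "pfs"): truth.atezolizumab_pfs,
        ("atezolizumab", "os"): truth.atezolizumab_os,
        ("bsc", "pfs"): truth.bsc_pfs,
        ("bsc", "os"): truth.bsc_os,
    }
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(models))
    ipd, curves, risk_tables = {}, {}, {}
    for child, (key, model) in zip(children, models.items()):
        data = simulate_ipd(model, n_per_arm, censor_months, np.random.default_rng(child))
        curve = km_estimate(data, label=f"{group}:{key[0]}:{key[1]}")
        dig, risk = digitize(curve, mode=mode, ipd=data)
        ipd[key] = data
        curves[key] = dig
        risk_tables[key] = risk
    return TrialFixture(group, n_per_arm, censor_months, truth, ipd, curves, risk_tables)
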