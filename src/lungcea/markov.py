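"""Three-state cohort Markov engine (PFS, PD, Death) on 3-week cycles.

The whole cohort starts progression-free.  Each cycle the transition
probabilities are rebuilt from the fitted PFS and OS survivor curves:

* staying progression-free follows the PFS survival ratio
  ``S_pfs(t) / S_pfs(t - mu)`` (mu = cycle length);
* death directly from PFS equals background (natural) mortality;
* progression absorbs the remainder of the PFS row;
* whole-cohort survival follows the OS ratio ``S_os(t) / S_os(t - mu)``, and
  the PD->PD probability is back-calculated so that the PFS and PD rows
  together reproduce it:
  ``p_pd_pd = [(nPFS + nPD) * p_s_s - nPFS * p_pfs_pfs - nPFS * p_pfs_pd] / nPD``.

Two background-mortality conventions are provided.  In ``embedded`` mode
(default) the OS curve is taken as the complete account of deaths, so cohort
survival equals the OS curve exactly.  In ``additional`` mode background
mortality acts as an independent competing death on top of the OS curve, so
cohort survival is the OS curve times ``(1 - q_cycle)^k``.  Either way all
probabilities are clamped to [0, 1] after the back-calculation (the formula
can transiently leave the unit interval when fitted curves cross); clamping
events are counted on the returned trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .survival import SurvivalModel

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "ModelSettings",
    "StateVector",
    "TransitionSet",
    "cycle_transitions",
    "run_cohort",
    "life_years",
    "write_trace",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

_PD_EPS = 1e-12


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings: cycle length, horizon, discounting, WTP."""

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    annual_discount_rate: float = 0.05
    natural_mortality_annual: float = 0.00718
    half_cycle_correction: bool = False
    wtp: float = 27354.0
    mortality_mode: str = "embedded"     # or "additional"
    discount_timing: str = "start"       # or "end"

    def __post_init__(self) -> None:
        errors = []
        if self.cycle_length_days <= 0:
            errors.append("cycle_length_days must be positive")
        if self.horizon_years <= 0:
            errors.append("horizon_years must be positive")
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            errors.append("annual_discount_rate must lie in [0, 0.08]")
        if not 0.0 <= self.natural_mortality_annual < 1.0:
            errors.append("natural_mortality_annual must lie in [0, 1)")
        if self.mortality_mode not in ("embedded", "additional"):
            errors.append("mortality_mode must be 'embedded' or 'additional'")
        if self.discount_timing not in ("start", "end"):
            errors.append("discount_timing must be 'start' or 'end'")
        if self.wtp < 0:
            errors.append("wtp must be non-negative")
        if errors:
            raise ValueError("invalid settings: " + "; ".join(errors))

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        # 10 years / 3-week cycles = 173.93; the nearest whole number of
        # transitions (174) is used so the trace covers the full horizon.
        return int(round(self.horizon_years / self.cycle_years))

    @property
    def cycle_mortality(self) -> float:
        """Per-cycle background death probability, from the annual probability."""
        return 1.0 - (1.0 - self.natural_mortality_annual) ** self.cycle_years

    def discount_factors(self, n_cycles: int | None = None) -> np.ndarray:
        """Discount factor for cycles 1..n (annual rate applied continuously)."""
        n = self.n_cycles if n_cycles is None else n_cycles
        k = np.arange(1, n + 1, dtype=float)
        t_years = (k - 1.0) * self.cycle_years if self.discount_timing == "start" \
            else k * self.cycle_years
        return (1.0 + self.annual_discount_rate) ** (-t_years)


class StateVector(NamedTuple):
    n_pfs: float
    n_pd: float
    n_death: float


class TransitionSet(NamedTuple):
    p_pfs_pfs: float
    p_pfs_pd: float
    p_pfs_death: float
    p_pd_pd: float
    p_pd_death: float


def _survival_ratio(model: SurvivalModel, t: float, mu: float) -> float:
    s_prev = float(model.sf(max(t - mu, 0.0)))
    if s_prev <= 0.0:
        return 0.0
    return min(float(model.sf(t)) / s_prev, 1.0)


def cycle_transitions(
    t: float,
    prev: StateVector,
    pfs_model: SurvivalModel,
    os_model: SurvivalModel,
    settings: ModelSettings,
) -> tuple[TransitionSet, bool]:
    """One cycle's transition probabilities at elapsed time ``t`` (months).

    Returns the transition set and a flag saying whether the back-calculated
    PD->PD probability had to be clamped into [0, 1].
    """
    mu = settings.cycle_months
    if t < mu - 1e-9:
        raise ValueError("transitions are evaluated at t >= one cycle length")
    q = settings.cycle_mortality
    extra = 1.0 - q if settings.mortality_mode == "additional" else 1.0

    r_pfs = _survival_ratio(pfs_model, t, mu)
    r_os = _survival_ratio(os_model, t, mu)

    p_pfs_death = q
    p_pfs_pfs = min(r_pfs * extra, 1.0 - p_pfs_death)
    p_pfs_pd = 1.0 - p_pfs_death - p_pfs_pfs

    p_s_s = r_os * extra
    n_pfs, n_pd = prev.n_pfs, prev.n_pd
    clamped = False
    if n_pd < _PD_EPS:
        # degenerate case: nobody progressed yet, tie PD row to whole-cohort survival
        p_pd_pd = min(max(p_s_s, 0.0), 1.0)
    else:
        raw = ((n_pfs + n_pd) * p_s_s
               - n_pfs * p_pfs_pfs
               - n_pfs * p_pfs_pd) / n_pd
        p_pd_pd = min(max(raw, 0.0), 1.0)
        clamped = abs(p_pd_pd - raw) > 1e-12
    p_pd_death = 1.0 - p_pd_pd

    return TransitionSet(p_pfs_pfs, p_pfs_pd, p_pfs_death, p_pd_pd, p_pd_death), clamped


def run_cohort(
    pfs_model: SurvivalModel,
    os_model: SurvivalModel,
    settings: ModelSettings,
) -> pd.DataFrame:
    """Run the cohort for the full horizon; returns the per-cycle trace.

    Columns: ``cycle, t_months, n_pfs, n_pd, n_death, new_deaths``.  Row 0 is
    the initial all-PFS state.  ``df.attrs['clamp_cycles']`` lists cycles where
    the PD back-calculation was clamped.
    """
    n = settings.n_cycles
    mu = settings.cycle_months
    state = StateVector(1.0, 0.0, 0.0)
    rows = [(0, 0.0, 1.0, 0.0, 0.0, 0.0)]
    clamp_cycles: list[int] = []
    for k in range(1, n + 1):
        t = k * mu
        tr, clamped = cycle_transitions(t, state, pfs_model, os_model, settings)
        if clamped:
            clamp_cycles.append(k)
        n_pfs = state.n_pfs * tr.p_pfs_pfs
        n_pd = state.n_pfs * tr.p_pfs_pd + state.n_pd * tr.p_pd_pd
        n_death = state.n_death + state.n_pfs * tr.p_pfs_death + state.n_pd * tr.p_pd_death
        new_deaths = n_death - state.n_death
        state = StateVector(n_pfs, n_pd, n_death)
        rows.append((k, t, n_pfs, n_pd, n_death, new_deaths))
    df = pd.DataFrame(rows, columns=["cycle", "t_months", "n_pfs", "n_pd", "n_death", "new_deaths"])
    df.attrs["clamp_cycles"] = clamp_cycles
    df.attrs["settings"] = settings
    return df


def _alive_per_cycle(trace: pd.DataFrame, settings: ModelSettings) -> np.ndarray:
    alive = (trace["n_pfs"] + trace["n_pd"]).to_numpy(dtype=float)
    if settings.half_cycle_correction:
        return 0.5 * (alive[:-1] + alive[1:])
    return alive[1:]


def life_years(trace: pd.DataFrame, settings: ModelSettings, discounted: bool = True) -> float:
    """Life-years in the trace: alive occupancy x cycle length, optionally discounted."""
    alive = _alive_per_cycle(trace, settings)
    w = settings.discount_factors(alive.size) if discounted else np.ones(alive.size)
    return float((alive * w).sum() * settings.cycle_years)


def write_trace(trace: pd.DataFrame, path) -> None:
    """Trace export CSV (occupancy plus any accrual columns present)."""
    trace.to_csv(path, index=False)
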