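"""One-way (tornado) and probabilistic sensitivity analysis, plus the CEAC.

Parameter uncertainty follows the published table: costs vary over +/-25% of
baseline with lognormal (or triangular, for the transaminase management cost)
distributions; utilities and adverse-event incidences are beta; the discount
rate is varied 0-8% one-way but held fixed in the probabilistic analysis.

Distribution parameterization is method-of-moments: the (low, high) range is
read as a central 95% interval, so sd = (high - low) / (2 * 1.96), with the
baseline as the mean.  The triangular distribution uses (low, mode=base, high)
directly.  All draws flow from one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .economics import Comparison

__all__ = [
    "ParamSpec",
    "default_low_high",
    "one_way",
    "draw",
    "run_psa",
    "ceac",
    "wtp_at_probability",
]

_Z95 = 1.959963984540054

Evaluator = Callable[[dict], Comparison]


def default_low_high(base: float) -> tuple[float, float]:
    """The +/-25% default range around a baseline value."""
    return 0.75 * base, 1.25 * base


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: baseline, (low, high) range and distribution."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"  # lognormal | triangle | beta | fixed

    def __post_init__(self) -> None:
        if self.low is None or self.high is None:
            lo, hi = default_low_high(self.base)
            object.__setattr__(self, "low", lo if self.low is None else self.low)
            object.__setattr__(self, "high", hi if self.high is None else self.high)
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high, "
                             f"got ({self.low}, {self.base}, {self.high})")
        if self.distribution not in ("lognormal", "triangle", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta requires support within [0, 1]")
        # pre-compute moment-matched shape parameters
        sd = (self.high - self.low) / (2.0 * _Z95)
        if self.distribution == "lognormal":
            if self.base <= 0:
                raise ValueError(f"{self.name}: lognormal requires a positive mean")
            cv2 = (sd / self.base) ** 2
            sigma2 = math.log1p(cv2)
            object.__setattr__(self, "_mulog", math.log(self.base) - 0.5 * sigma2)
            object.__setattr__(self, "_sdlog", math.sqrt(sigma2))
        elif self.distribution == "beta":
            m = self.base
            if sd == 0.0:
                object.__setattr__(self, "_alpha", None)
                object.__setattr__(self, "_beta", None)
            else:
                nu = m * (1.0 - m) / sd**2 - 1.0
                if nu <= 0:
                    raise ValueError(f"{self.name}: beta moment match infeasible "
                                     f"(mean {m}, sd {sd})")
                object.__setattr__(self, "_alpha", m * nu)
                object.__setattr__(self, "_beta", (1.0 - m) * nu)

    def sample(self, rng: np.random.Generator) -> float:
        if self.distribution == "fixed" or self.high == self.low:
            return self.base
        if self.distribution == "lognormal":
            return float(rng.lognormal(self._mulog, self._sdlog))
        if self.distribution == "triangle":
            return float(rng.triangular(self.low, self.base, self.high))
        if self._alpha is None:
            return self.base
        return float(rng.beta(self._alpha, self._beta))


def one_way(specs: list[ParamSpec], evaluate: Evaluator) -> pd.DataFrame:
    """Tornado table: ICER with each parameter at its low/high bound, others at base.

    Rows are sorted by |ICER_high - ICER_low| descending.  A failed evaluation
    flags the row (``error`` column) instead of dropping it.
    """
    base_icer = evaluate({}).icer
    rows = []
    for spec in specs:
        row = {"parameter": spec.name, "base": spec.base,
               "low": spec.low, "high": spec.high,
               "base_icer": base_icer, "error": ""}
        try:
            row["low_icer"] = evaluate({spec.name: spec.low}).icer
            row["high_icer"] = evaluate({spec.name: spec.high}).icer
            row["spread"] = abs(row["high_icer"] - row["low_icer"])
        except Exception as exc:  # noqa: BLE001 - row is flagged, not dropped
            row["low_icer"] = row["high_icer"] = row["spread"] = math.nan
            row["error"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("spread", ascending=False, ignore_index=True)


def draw(specs: list[ParamSpec], rng: np.random.Generator) -> dict[str, float]:
    """One Monte-Carlo draw of every uncertain parameter."""
    return {spec.name: spec.sample(rng) for spec in specs}


def run_psa(
    specs: list[ParamSpec],
    evaluate: Evaluator,
    n: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: ``n`` full model re-runs.

    Returns one row per draw with the sampled parameter values and the
    resulting incremental cost and QALYs.  Failed evaluations are excluded and
    counted in ``df.attrs['n_failed']``.
    """
    rng = np.random.default_rng(seed)
    records = []
    n_failed = 0
    for i in range(n):
        params = draw(specs, rng)
        try:
            cmp_ = evaluate(params)
        except Exception:  # noqa: BLE001 - logged via the failure count
            n_failed += 1
            continue
        rec = {"draw": i, **params,
               "delta_cost": cmp_.delta_cost, "delta_qaly": cmp_.delta_qaly}
        records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["n_failed"] = n_failed
    return out


def ceac(samples: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Probability at each threshold = fraction of draws with positive incremental
    net monetary benefit, ``wtp * dQ - dC > 0``.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    dq = samples["delta_qaly"].to_numpy(float)
    dc = samples["delta_cost"].to_numpy(float)
    prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})


def wtp_at_probability(curve: pd.DataFrame, p: float = 0.5) -> float:
    """WTP where the CEAC first reaches probability ``p`` (linear interpolation).

    Returns NaN when the curve never crosses ``p``.
    """
    w = curve["wtp"].to_numpy(float)
    pr = curve["probability"].to_numpy(float)
    if pr[0] >= p:
        return float(w[0])
    above = np.where(pr >= p)[0]
    if above.size == 0:
        return math.nan
    j = int(above[0])
    w0, w1, p0, p1 = w[j - 1], w[j], pr[j - 1], pr[j]
    if p1 == p0:
        return float(w1)
    return float(w0 + (p - p0) / (p1 - p0) * (w1 - w0))
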