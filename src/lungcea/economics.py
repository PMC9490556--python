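"""Cost and utility accrual, treatment schedules, and incremental statistics.

Costing conventions (all configurable through the inputs below):

* drug cost (atezolizumab, 1200 mg every 3 weeks, at most 16 cycles) is charged
  to patients progression-free at the start of the cycle, on paid cycles only
  (the patient-assistance programme zeroes a subset of cycles);
* best-supportive-care cost is charged to the comparator arm's progression-free
  occupancy over the same 16-cycle treatment window;
* routine follow-up is charged to everyone alive, each cycle of the horizon;
* subsequent-line therapy is charged to progressed-disease occupancy each cycle;
* terminal (hospice) care is a one-off cost on each new death within the horizon;
* severe adverse-event management costs, and the pyrexia disutility, are charged
  once in the first cycle of the treated arm.

QALYs weight state occupancy by the PFS/PD utilities.  Everything is discounted
with the settings' annual rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import ModelSettings, run_cohort
from .survival import SurvivalModel

__all__ = [
    "CostInputs",
    "UtilityInputs",
    "AEProfile",
    "ArmSpec",
    "CEResult",
    "Comparison",
    "accrue",
    "compare",
    "apply_pap",
    "apply_price_fraction",
    "PAP_PAID_DEFAULT",
    "PAP_PAID_PAY2_FREE3",
]

#: Default patient-assistance schedule: pay cycles 1-8, cycles 9-16 free.
#: Chosen to match the published with-PAP drug spend (about eight discounted
#: cycle-costs below the no-PAP spend).
PAP_PAID_DEFAULT = frozenset(range(1, 9))

#: Literal reading of "pay two cycles, then three free", repeating.
PAP_PAID_PAY2_FREE3 = frozenset({1, 2, 6, 7, 11, 12, 16})


def _check_nonneg(obj, names):
    bad = [n for n in names if getattr(obj, n) < 0]
    if bad:
        raise ValueError(f"negative cost inputs: {bad}")


@dataclass(frozen=True)
class CostInputs:
    """Per-cycle and one-off unit costs in 2022 USD."""

    atezolizumab_per_cycle: float = 4218.61
    bsc_per_cycle: float = 299.47
    subsequent_therapy_per_cycle: float = 736.35
    followup_per_cycle: float = 76.05
    terminal_care_once: float = 2331.70
    pyrexia_treatment: float = 845.61
    alt_ast_treatment_per_cycle: float = 75.67
    neutropenia_treatment: float = 0.0  # incidence is tabulated without a unit cost

    def __post_init__(self) -> None:
        _check_nonneg(self, [f.name for f in self.__dataclass_fields__.values()])


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities (EQ-5D-5L scale) and the pyrexia disutility."""

    u_pfs: float = 0.827
    u_pd: float = 0.321
    u_death: float = 0.0
    disutility_pyrexia: float = 0.420

    def __post_init__(self) -> None:
        for name in ("u_pfs", "u_pd", "u_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.u_pfs <= self.u_pd:
            raise ValueError("u_pfs must exceed u_pd")
        if self.disutility_pyrexia < 0:
            raise ValueError("disutility must be non-negative")


@dataclass(frozen=True)
class AEProfile:
    """Grade >= 3 adverse-event incidences for one arm (fractions of the cohort)."""

    neutropenia: float = 0.01
    alt_increased: float = 0.02
    ast_increased: float = 0.01
    pyrexia: float = 0.01

    def __post_init__(self) -> None:
        for name in ("neutropenia", "alt_increased", "ast_increased", "pyrexia"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"AE incidence {name}={v} must lie in [0, 1]")

    @staticmethod
    def none() -> "AEProfile":
        return AEProfile(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: survival models, drug schedule and AE profile."""

    name: str
    pfs_model: SurvivalModel
    os_model: SurvivalModel
    drug_cost_per_cycle: float = 0.0       # atezolizumab unit cost; 0 for BSC arm
    bsc_cost_per_cycle: float = 0.0        # comparator supportive-care unit cost
    treatment_cycles: int = 16
    paid_cycles: frozenset[int] | None = None  # None => every treatment cycle paid
    price_multiplier: float = 1.0
    ae_profile: AEProfile = field(default_factory=AEProfile.none)
    bsc_cost_window: int | None = 16       # None => BSC charged on every PFS cycle

    def __post_init__(self) -> None:
        if self.paid_cycles is None:
            object.__setattr__(self, "paid_cycles",
                               frozenset(range(1, self.treatment_cycles + 1)))
        if not 0 < self.price_multiplier <= 1.0:
            raise ValueError("price multiplier must lie in (0, 1]")
        if self.treatment_cycles > 16:
            raise ValueError("treatment schedule is capped at 16 cycles")
        if not frozenset(self.paid_cycles) <= frozenset(range(1, self.treatment_cycles + 1)):
            raise ValueError("paid cycles must be a subset of the treatment schedule")


@dataclass(frozen=True)
class CEResult:
    """Per-arm totals: discounted cost, LYs and QALYs (plus undiscounted)."""

    arm: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    breakdown: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("total cost must be non-negative")
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class Comparison:
    """Incremental statistics of strategy A versus comparator B."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float          # signed Delta C / Delta Q; NaN when Delta Q == 0
    nmb: float           # wtp * Delta Q - Delta C
    wtp: float
    classification: str  # cost-effective | not cost-effective | dominant | dominated


def accrue(
    trace: pd.DataFrame,
    arm: ArmSpec,
    costs: CostInputs,
    utils: UtilityInputs,
    settings: ModelSettings,
    ae_costs_per_cycle: bool = False,
) -> CEResult:
    """Attach costs and utilities to a cohort trace and total them up.

    ``ae_costs_per_cycle`` switches the ALT/AST management cost from the default
    first-cycle lump to a per-treatment-cycle charge.
    """
    n = len(trace) - 1
    if arm.treatment_cycles > n:
        raise ValueError("treatment schedule longer than the model horizon")
    cy = settings.cycle_years
    df = settings.discount_factors(n)
    ones = np.ones(n)

    pfs_start = trace["n_pfs"].to_numpy(float)[:-1]    # occupancy when the cycle begins
    pfs_end = trace["n_pfs"].to_numpy(float)[1:]
    pd_end = trace["n_pd"].to_numpy(float)[1:]
    alive_end = pfs_end + pd_end
    new_deaths = trace["new_deaths"].to_numpy(float)[1:]
    k = np.arange(1, n + 1)

    ae = arm.ae_profile
    paid = np.array([c in arm.paid_cycles for c in k])
    on_treatment = k <= arm.treatment_cycles

    drug = (arm.drug_cost_per_cycle * arm.price_multiplier) * pfs_start * (paid & on_treatment)
    if arm.bsc_cost_window is None:
        bsc_window = ones.astype(bool)
    else:
        bsc_window = k <= arm.bsc_cost_window
    bsc = arm.bsc_cost_per_cycle * pfs_start * bsc_window
    followup = costs.followup_per_cycle * alive_end
    subsequent = costs.subsequent_therapy_per_cycle * pd_end
    terminal = costs.terminal_care_once * new_deaths

    ae_lump = np.zeros(n)
    alt_ast_inc = ae.alt_increased + ae.ast_increased
    sae_once = (ae.neutropenia * costs.neutropenia_treatment
                + ae.pyrexia * costs.pyrexia_treatment)
    if ae_costs_per_cycle:
        ae_percycle = costs.alt_ast_treatment_per_cycle * alt_ast_inc * pfs_start * on_treatment
        ae_lump[0] = sae_once
        ae_component = ae_percycle + ae_lump
    else:
        ae_lump[0] = sae_once + costs.alt_ast_treatment_per_cycle * alt_ast_inc
        ae_component = ae_lump

    components = {
        "drug": drug, "bsc": bsc, "followup": followup,
        "subsequent_therapy": subsequent, "terminal_care": terminal, "sae": ae_component,
    }
    cost_disc = sum(float((v * df).sum()) for v in components.values())
    cost_undisc = sum(float(v.sum()) for v in components.values())

    if settings.half_cycle_correction:
        pfs_occ = 0.5 * (trace["n_pfs"].to_numpy(float)[:-1] + pfs_end)
        pd_occ = 0.5 * (trace["n_pd"].to_numpy(float)[:-1] + pd_end)
    else:
        pfs_occ, pd_occ = pfs_end, pd_end
    alive_occ = pfs_occ + pd_occ

    qaly_cycle = (pfs_occ * utils.u_pfs + pd_occ * utils.u_pd) * cy
    qaly_cycle[0] -= ae.pyrexia * utils.disutility_pyrexia * cy
    ly_cycle = alive_occ * cy

    return CEResult(
        arm=arm.name,
        cost=cost_disc,
        ly=float((ly_cycle * df).sum()),
        qaly=float((qaly_cycle * df).sum()),
        cost_undiscounted=cost_undisc,
        ly_undiscounted=float(ly_cycle.sum()),
        qaly_undiscounted=float(qaly_cycle.sum()),
        breakdown={name: float((v * df).sum()) for name, v in components.items()},
    )


def compare(a: CEResult, b: CEResult, wtp: float) -> Comparison:
    """Incremental cost-effectiveness of strategy ``a`` versus comparator ``b``."""
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    dly = a.ly - b.ly
    nmb = wtp * dq - dc
    if dq == 0.0:
        icer = math.nan
        classification = "cost-effective" if dc < 0 else (
            "not cost-effective" if dc > 0 else "cost-effective")
    else:
        icer = dc / dq
        if dq > 0 and dc <= 0:
            classification = "dominant"
        elif dq < 0 and dc >= 0:
            classification = "dominated"
        elif dq > 0:
            classification = "cost-effective" if icer <= wtp else "not cost-effective"
        else:  # dq < 0, dc < 0: cost-saving with QALY loss
            classification = "cost-effective" if icer >= wtp else "not cost-effective"
    return Comparison(dc, dq, dly, icer, nmb, wtp, classification)


def apply_pap(arm: ArmSpec, paid_cycles: frozenset[int] = PAP_PAID_DEFAULT) -> ArmSpec:
    """Patient-assistance programme: zero the drug cost on free cycles."""
    return replace(arm, paid_cycles=frozenset(paid_cycles))


def apply_price_fraction(arm: ArmSpec, fraction: float) -> ArmSpec:
    """Scale the drug unit cost to ``fraction`` of the original price."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("price fraction must lie in (0, 1]")
    return replace(arm, price_multiplier=arm.price_multiplier * fraction)
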