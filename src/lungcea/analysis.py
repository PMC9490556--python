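"""High-level analysis drivers tying the stages into the three-group study.

Everything here is a thin orchestration layer over the survival, Markov,
economics and sensitivity modules: build both arms for a population, run the
cohort once per arm (survival inputs are fixed in the probabilistic analysis,
so traces are computed once and re-costed per draw), and emit tidy tables.

``run_full`` produces the complete artifact bundle - base case, scenario
sweep, tornado per group, PSA samples and CEAC curves, a synthetic-data
validation report - under one root seed, with a JSON run manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import replace as _replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .economics import (AEProfile, ArmSpec, CEResult, Comparison, accrue,
                        apply_pap, apply_price_fraction, compare)
from .markov import ModelSettings, run_cohort
from .sensitivity import ParamSpec, ceac, one_way, run_psa, wtp_at_probability
from .survival import fit_all_families, select_by_aic
from .synthetic import make_fixture
from .ipd import reconstruct_ipd

__all__ = [
    "build_arms",
    "run_group",
    "run_base_case",
    "psa_param_specs",
    "tornado_param_specs",
    "make_evaluator",
    "run_group_psa",
    "run_tornado",
    "convention_sweep",
    "run_full",
]

SCENARIO_BASE = "base"
SCENARIO_PAP = "pap"


def _scenario_names(config: AnalysisConfig) -> list[str]:
    return [SCENARIO_BASE, SCENARIO_PAP] + [f"price_{f:g}" for f in config.price_fractions]


def build_arms(config: AnalysisConfig, group: str,
               scenario: str = SCENARIO_BASE) -> tuple[ArmSpec, ArmSpec]:
    """The (atezolizumab, BSC) strategy pair for one population and scenario."""
    gs = config.survival[group]
    atezo = ArmSpec(
        name="atezolizumab",
        pfs_model=gs.atezolizumab_pfs,
        os_model=gs.atezolizumab_os,
        drug_cost_per_cycle=config.costs.atezolizumab_per_cycle,
        treatment_cycles=config.treatment_cycles,
        ae_profile=config.ae_atezolizumab,
        bsc_cost_window=config.bsc_cost_window,
    )
    bsc = ArmSpec(
        name="bsc",
        pfs_model=gs.bsc_pfs,
        os_model=gs.bsc_os,
        bsc_cost_per_cycle=config.costs.bsc_per_cycle,
        treatment_cycles=config.treatment_cycles,
        ae_profile=AEProfile.none(),
        bsc_cost_window=config.bsc_cost_window,
    )
    if scenario == SCENARIO_PAP:
        atezo = apply_pap(atezo, config.pap_paid_cycles)
    elif scenario.startswith("price_"):
        atezo = apply_price_fraction(atezo, float(scenario.split("_", 1)[1]))
    elif scenario != SCENARIO_BASE:
        raise ValueError(f"unknown scenario {scenario!r}")
    return atezo, bsc


def run_group(config: AnalysisConfig, group: str, scenario: str = SCENARIO_BASE,
              ) -> tuple[CEResult, CEResult, Comparison]:
    """Full deterministic run of one population under one scenario."""
    atezo, bsc = build_arms(config, group, scenario)
    s = config.settings
    res_a = accrue(run_cohort(atezo.pfs_model, atezo.os_model, s), atezo,
                   config.costs, config.utilities, s)
    res_b = accrue(run_cohort(bsc.pfs_model, bsc.os_model, s), bsc,
                   config.costs, config.utilities, s)
    return res_a, res_b, compare(res_a, res_b, s.wtp)


def run_base_case(config: AnalysisConfig) -> pd.DataFrame:
    """Base-case + scenario table: one row per group x scenario x arm.

    Columns mirror the published results table:
    ``scenario, group, arm, total_cost, ly, qaly, icer`` (ICER on the
    atezolizumab row, versus BSC).
    """
    config.validate()
    rows = []
    for scenario in _scenario_names(config):
        for group in config.survival:
            res_a, res_b, cmp_ = run_group(config, group, scenario)
            rows.append({"scenario": scenario, "group": group, "arm": res_a.arm,
                         "total_cost": res_a.cost, "ly": res_a.ly,
                         "qaly": res_a.qaly, "icer": cmp_.icer})
            rows.append({"scenario": scenario, "group": group, "arm": res_b.arm,
                         "total_cost": res_b.cost, "ly": res_b.ly,
                         "qaly": res_b.qaly, "icer": math.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity-analysis wiring
# ---------------------------------------------------------------------------

def psa_param_specs(config: AnalysisConfig) -> list[ParamSpec]:
    """Every tabulated parameter with a sampling distribution (discount fixed)."""
    c, u, ae = config.costs, config.utilities, config.ae_atezolizumab
    return [
        ParamSpec("cost_atezolizumab", c.atezolizumab_per_cycle, distribution="lognormal"),
        ParamSpec("cost_bsc", c.bsc_per_cycle, distribution="lognormal"),
        ParamSpec("cost_subsequent", c.subsequent_therapy_per_cycle, distribution="lognormal"),
        ParamSpec("cost_alt_ast", c.alt_ast_treatment_per_cycle, distribution="triangle"),
        ParamSpec("cost_followup", c.followup_per_cycle, distribution="lognormal"),
        ParamSpec("cost_terminal", c.terminal_care_once, distribution="lognormal"),
        ParamSpec("cost_pyrexia", c.pyrexia_treatment, distribution="lognormal"),
        ParamSpec("u_pfs", u.u_pfs, 0.620, 1.000, distribution="beta"),
        ParamSpec("u_pd", u.u_pd, 0.240, 0.401, distribution="beta"),
        ParamSpec("disutility_pyrexia", u.disutility_pyrexia, 0.315, 0.525,
                  distribution="beta"),
        ParamSpec("inc_neutropenia", ae.neutropenia, 0.007, 0.012, distribution="beta"),
        ParamSpec("inc_alt", ae.alt_increased, 0.015, 0.025, distribution="beta"),
        ParamSpec("inc_ast", ae.ast_increased, 0.007, 0.012, distribution="beta"),
        ParamSpec("inc_pyrexia", ae.pyrexia, distribution="beta"),
    ]


def tornado_param_specs(config: AnalysisConfig) -> list[ParamSpec]:
    """One-way ranges: the PSA set plus the 0-8% discount-rate band."""
    return psa_param_specs(config) + [
        ParamSpec("discount_rate", config.settings.annual_discount_rate,
                  0.0, 0.08, distribution="fixed"),
    ]


def make_evaluator(config: AnalysisConfig, group: str, scenario: str = SCENARIO_BASE):
    """Closure mapping a parameter-override dict to a :class:`Comparison`.

    Survival inputs are fixed, so both cohort traces are computed once and the
    accrual stage is re-run per call - a full model re-run for everything the
    sampled parameters can touch.
    """
    atezo, bsc = build_arms(config, group, scenario)
    s0 = config.settings
    trace_a = run_cohort(atezo.pfs_model, atezo.os_model, s0)
    trace_b = run_cohort(bsc.pfs_model, bsc.os_model, s0)

    def evaluate(params: dict) -> Comparison:
        c = _override_costs(config.costs, params)
        u = _override_utilities(config.utilities, params)
        ae = _override_ae(config.ae_atezolizumab, params)
        settings = s0
        if "discount_rate" in params:
            settings = _replace(s0, annual_discount_rate=params["discount_rate"])
        arm_a = _replace(atezo, drug_cost_per_cycle=c.atezolizumab_per_cycle,
                         ae_profile=ae)
        arm_b = _replace(bsc, bsc_cost_per_cycle=c.bsc_per_cycle)
        res_a = accrue(trace_a, arm_a, c, u, settings)
        res_b = accrue(trace_b, arm_b, c, u, settings)
        return compare(res_a, res_b, s0.wtp)

    return evaluate


def _override_costs(base, params: dict):
    mapping = {
        "cost_atezolizumab": "atezolizumab_per_cycle",
        "cost_bsc": "bsc_per_cycle",
        "cost_subsequent": "subsequent_therapy_per_cycle",
        "cost_alt_ast": "alt_ast_treatment_per_cycle",
        "cost_followup": "followup_per_cycle",
        "cost_terminal": "terminal_care_once",
        "cost_pyrexia": "pyrexia_treatment",
    }
    kwargs = {attr: params[key] for key, attr in mapping.items() if key in params}
    return _replace(base, **kwargs) if kwargs else base


def _override_utilities(base, params: dict):
    mapping = {"u_pfs": "u_pfs", "u_pd": "u_pd",
               "disutility_pyrexia": "disutility_pyrexia"}
    kwargs = {attr: params[key] for key, attr in mapping.items() if key in params}
    return _replace(base, **kwargs) if kwargs else base


def _override_ae(base, params: dict):
    mapping = {"inc_neutropenia": "neutropenia", "inc_alt": "alt_increased",
               "inc_ast": "ast_increased", "inc_pyrexia": "pyrexia"}
    kwargs = {attr: params[key] for key, attr in mapping.items() if key in params}
    return _replace(base, **kwargs) if kwargs else base


def run_tornado(config: AnalysisConfig, group: str,
                scenario: str = SCENARIO_BASE) -> pd.DataFrame:
    return one_way(tornado_param_specs(config), make_evaluator(config, group, scenario))


def run_group_psa(config: AnalysisConfig, group: str, scenario: str = SCENARIO_BASE,
                  n: int | None = None,
                  seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    n = config.psa.n_draws if n is None else n
    return run_psa(psa_param_specs(config), make_evaluator(config, group, scenario),
                   n=n, seed=seed)


def wtp_grid(config: AnalysisConfig) -> np.ndarray:
    return np.arange(0.0, config.psa.wtp_grid_max + config.psa.wtp_grid_step / 2,
                     config.psa.wtp_grid_step)


# ---------------------------------------------------------------------------
# Convention sweep (structural-assumption sensitivity)
# ---------------------------------------------------------------------------

def convention_sweep(config: AnalysisConfig, group: str = "pdl1") -> pd.DataFrame:
    """Per-arm LY/QALY under every documented modelling-convention combination.

    The option space: background-mortality mode (embedded in the OS curve vs
    additional), discount timing (cycle start vs end), half-cycle correction,
    and whether comparator supportive care is charged beyond the 16-cycle
    treatment window.  One row per combination per arm.
    """
    rows = []
    for mode in ("embedded", "additional"):
        for timing in ("start", "end"):
            for hcc in (False, True):
                for window in (16, None):
                    cfg = _replace(
                        config,
                        settings=_replace(config.settings, mortality_mode=mode,
                                          discount_timing=timing,
                                          half_cycle_correction=hcc),
                        bsc_cost_window=window,
                    )
                    res_a, res_b, cmp_ = run_group(cfg, group)
                    for res in (res_a, res_b):
                        rows.append({
                            "mortality_mode": mode, "discount_timing": timing,
                            "half_cycle_correction": hcc,
                            "bsc_cost_window": "16" if window == 16 else "all",
                            "arm": res.arm, "total_cost": res.cost,
                            "ly": res.ly, "qaly": res.qaly, "icer": cmp_.icer,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full artifact bundle
# ---------------------------------------------------------------------------

def synthetic_validation(config: AnalysisConfig, group: str = "pdl1",
                         seed: int | np.random.SeedSequence = 0,
                         n_per_arm: int = 450) -> pd.DataFrame:
    """Simulate -> digitize -> reconstruct -> fit, against known ground truth."""
    fixture = make_fixture(group, seed=seed, n_per_arm=n_per_arm)
    rows = []
    for (arm, endpoint), curve in fixture.curves.items():
        truth = fixture.ipd[(arm, endpoint)]
        recon = reconstruct_ipd(curve, fixture.risk_tables[(arm, endpoint)])
        fits = fit_all_families(recon)
        best = select_by_aic(fits)
        true_model = {
            ("atezolizumab", "pfs"): fixture.true_models.atezolizumab_pfs,
            ("atezolizumab", "os"): fixture.true_models.atezolizumab_os,
            ("bsc", "pfs"): fixture.true_models.bsc_pfs,
            ("bsc", "os"): fixture.true_models.bsc_os,
        }[(arm, endpoint)]
        rows.append({
            "group": group, "arm": arm, "endpoint": endpoint,
            "true_family": true_model.family,
            "true_params": list(true_model.params),
            "selected_family": best.model.family,
            "selected_params": list(best.model.params),
            "selected_aic": best.aic,
            "n_reconstructed": len(recon),
            "n_true": len(truth),
        })
    return pd.DataFrame(rows)


def run_full(config: AnalysisConfig, seed: int = 0, out_dir=".",
             psa_n: int | None = None) -> dict:
    """Run everything and write the artifact bundle; returns the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    seeds = {name: child for name, child
             in zip(["psa", "synthetic"], root.spawn(2))}

    base = run_base_case(config)
    base.to_csv(out / "base_case.csv", index=False)

    grid = wtp_grid(config)
    ceac_rows = []
    psa_files = []
    psa_children = seeds["psa"].spawn(2 * len(config.survival))
    i = 0
    for group in config.survival:
        for scenario in (SCENARIO_BASE, SCENARIO_PAP):
            samples = run_group_psa(config, group, scenario, n=psa_n,
                                    seed=psa_children[i]); i += 1
            fname = f"psa_{group}_{scenario}.csv"
            samples.to_csv(out / fname, index=False)
            psa_files.append(fname)
            curve = ceac(samples, grid)
            curve["group"] = group
            curve["scenario"] = scenario
            ceac_rows.append(curve)
    ceac_all = pd.concat(ceac_rows, ignore_index=True)
    ceac_all.to_csv(out / "ceac.csv", index=False)

    tornado_files = []
    for group in config.survival:
        tor = run_tornado(config, group)
        fname = f"tornado_{group}.csv"
        tor.to_csv(out / fname, index=False)
        tornado_files.append(fname)

    validation = synthetic_validation(config, seed=seeds["synthetic"])
    validation.to_csv(out / "synthetic_validation.csv", index=False)

    sweep = convention_sweep(config)
    sweep.to_csv(out / "convention_sweep.csv", index=False)

    manifest = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "files": ["base_case.csv", "ceac.csv", "synthetic_validation.csv",
                  "convention_sweep.csv"] + psa_files + tornado_files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
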