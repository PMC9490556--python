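"""Analysis configuration: the full published parameter block, YAML round trip.

The zero-argument default configuration reproduces the source study's analysis:
three populations x two arms x PFS/OS survival laws, all unit costs, utilities,
adverse-event risks, discounting, the WTP threshold, the patient-assistance
schedule and the price-reduction scenario grid.  Validation collects every
violation before raising, and unknown YAML keys are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .economics import (AEProfile, CostInputs, PAP_PAID_DEFAULT, UtilityInputs)
from .markov import ModelSettings
from .parameters import (EXCHANGE_RATE_NOTE, GROUP_LABELS, GroupSurvival,
                         default_group_survival)
from .survival import FAMILIES, PARAM_NAMES, SurvivalModel

__all__ = ["PSASettings", "AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every detected violation listed."""


@dataclass(frozen=True)
class PSASettings:
    n_draws: int = 10_000
    wtp_grid_max: float = 350_000.0
    wtp_grid_step: float = 1_000.0

    def violations(self) -> list[str]:
        out = []
        if self.n_draws <= 0:
            out.append("psa.n_draws must be positive")
        if self.wtp_grid_step <= 0 or self.wtp_grid_max <= 0:
            out.append("psa WTP grid must be positive")
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    settings: ModelSettings = field(default_factory=ModelSettings)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    ae_atezolizumab: AEProfile = field(default_factory=AEProfile)
    survival: dict[str, GroupSurvival] = field(default_factory=default_group_survival)
    treatment_cycles: int = 16
    pap_paid_cycles: frozenset[int] = PAP_PAID_DEFAULT
    bsc_cost_window: int | None = 16
    price_fractions: tuple[float, ...] = (0.7, 0.6, 0.5, 0.4, 0.3)
    psa: PSASettings = field(default_factory=PSASettings)
    exchange_rate_note: str = EXCHANGE_RATE_NOTE

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        if not 1 <= self.treatment_cycles <= 16:
            errors.append("treatment_cycles must lie in 1..16")
        if not frozenset(self.pap_paid_cycles) <= frozenset(range(1, self.treatment_cycles + 1)):
            errors.append("pap_paid_cycles must be a subset of the treatment schedule")
        if self.bsc_cost_window is not None and self.bsc_cost_window < 0:
            errors.append("bsc_cost_window must be non-negative or null")
        for f in self.price_fractions:
            if not 0.0 < f <= 1.0:
                errors.append(f"price fraction {f} must lie in (0, 1]")
        unknown = set(self.survival) - set(GROUP_LABELS)
        if unknown:
            errors.append(f"unknown analysis groups: {sorted(unknown)}")
        errors.extend(self.psa.violations())
        if errors:
            raise ConfigError("; ".join(errors))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def model_dict(m: SurvivalModel) -> dict:
            return {"family": m.family, **m.param_dict}

        return {
            "settings": asdict(self.settings),
            "costs": asdict(self.costs),
            "utilities": asdict(self.utilities),
            "ae_atezolizumab": asdict(self.ae_atezolizumab),
            "survival": {
                g: {
                    "atezolizumab": {"pfs": model_dict(gs.atezolizumab_pfs),
                                     "os": model_dict(gs.atezolizumab_os)},
                    "bsc": {"pfs": model_dict(gs.bsc_pfs),
                            "os": model_dict(gs.bsc_os)},
                }
                for g, gs in self.survival.items()
            },
            "treatment_cycles": self.treatment_cycles,
            "pap_paid_cycles": sorted(self.pap_paid_cycles),
            "bsc_cost_window": self.bsc_cost_window,
            "price_fractions": list(self.price_fractions),
            "psa": asdict(self.psa),
            "exchange_rate_note": self.exchange_rate_note,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {"settings", "costs", "utilities", "ae_atezolizumab", "survival",
                 "treatment_cycles", "pap_paid_cycles", "bsc_cost_window",
                 "price_fractions", "psa", "exchange_rate_note"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

        def parse_model(d: dict) -> SurvivalModel:
            d = dict(d)
            family = d.pop("family")
            if family not in FAMILIES:
                raise ConfigError(f"unknown survival family {family!r}")
            names = PARAM_NAMES[family]
            extra = set(d) - set(names)
            if extra:
                raise ConfigError(f"unknown {family} parameters: {sorted(extra)}")
            return SurvivalModel(family, tuple(d[n] for n in names))

        kwargs: dict = {}
        if "settings" in raw:
            kwargs["settings"] = ModelSettings(**raw["settings"])
        if "costs" in raw:
            kwargs["costs"] = CostInputs(**raw["costs"])
        if "utilities" in raw:
            kwargs["utilities"] = UtilityInputs(**raw["utilities"])
        if "ae_atezolizumab" in raw:
            kwargs["ae_atezolizumab"] = AEProfile(**raw["ae_atezolizumab"])
        if "survival" in raw:
            kwargs["survival"] = {
                g: GroupSurvival(
                    atezolizumab_pfs=parse_model(d["atezolizumab"]["pfs"]),
                    atezolizumab_os=parse_model(d["atezolizumab"]["os"]),
                    bsc_pfs=parse_model(d["bsc"]["pfs"]),
                    bsc_os=parse_model(d["bsc"]["os"]),
                )
                for g, d in raw["survival"].items()
            }
        for key in ("treatment_cycles", "bsc_cost_window", "exchange_rate_note"):
            if key in raw:
                kwargs[key] = raw[key]
        if "pap_paid_cycles" in raw:
            kwargs["pap_paid_cycles"] = frozenset(raw["pap_paid_cycles"])
        if "price_fractions" in raw:
            kwargs["price_fractions"] = tuple(raw["price_fractions"])
        if "psa" in raw:
            kwargs["psa"] = PSASettings(**raw["psa"])
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def config_hash(self) -> str:
        """Stable digest of the resolved configuration (for run manifests)."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
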