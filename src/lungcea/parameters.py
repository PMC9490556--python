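"""Published model inputs: survival parameters, unit costs, utilities, AE risks.

These are the baseline values, ranges and distributions from the source
cost-effectiveness study of adjuvant atezolizumab versus best supportive care
(BSC) after resection of stage IB-IIIA NSCLC, with one analysis population per
PD-L1/stage subgroup:

* ``pdl1``           - PD-L1 TC >= 1%, stage II-IIIA
* ``all_randomised`` - all randomised, stage II-IIIA
* ``itt``            - intention-to-treat, stage IB-IIIA

Note: the published table prints identical Weibull OS parameters for the BSC
all-randomised row and the atezolizumab ITT row, and identical lognormal PFS
parameters for the BSC all-randomised and BSC ITT rows - possibly transcription
duplication in the source.  They are reproduced exactly as printed; a warning
is emitted once when the defaults are first built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .survival import SurvivalModel

__all__ = ["GroupSurvival", "GROUP_LABELS", "default_group_survival",
           "EXCHANGE_RATE_NOTE", "WTP_DEFAULT"]

logger = logging.getLogger(__name__)

WTP_DEFAULT = 27_354.0  # 3x China 2022 per-capita GDP, USD/QALY

EXCHANGE_RATE_NOTE = "costs in 2022 USD, converted at 1 USD = 6.3 RMB"

GROUP_LABELS = {
    "pdl1": "PD-L1 TC >= 1% stage II-IIIA",
    "all_randomised": "all randomised stage II-IIIA",
    "itt": "intention-to-treat stage IB-IIIA",
}


@dataclass(frozen=True)
class GroupSurvival:
    """Fitted PFS/OS laws for both arms of one analysis population."""

    atezolizumab_pfs: SurvivalModel
    atezolizumab_os: SurvivalModel
    bsc_pfs: SurvivalModel
    bsc_os: SurvivalModel


_warned_duplicates = False


def default_group_survival() -> dict[str, GroupSurvival]:
    """The published survival parameters, exactly as printed."""
    global _warned_duplicates
    if not _warned_duplicates:
        logger.warning(
            "published survival table repeats two parameter rows verbatim "
            "(BSC all-randomised OS == atezolizumab ITT OS; BSC all-randomised "
            "PFS == BSC ITT PFS); reproduced as printed"
        )
        _warned_duplicates = True
    return {
        "pdl1": GroupSurvival(
            atezolizumab_pfs=SurvivalModel("exponential", (0.01373,)),
            atezolizumab_os=SurvivalModel("exponential", (0.00516,)),
            bsc_pfs=SurvivalModel("lognormal", (3.52507, 1.52190)),
            bsc_os=SurvivalModel("loglogistic", (0.01216, 0.65240)),
        ),
        "all_randomised": GroupSurvival(
            atezolizumab_pfs=SurvivalModel("exponential", (0.01593,)),
            atezolizumab_os=SurvivalModel("weibull", (0.00146, 1.40082)),
            bsc_pfs=SurvivalModel("lognormal", (3.64405, 1.50079)),
            bsc_os=SurvivalModel("weibull", (0.00222, 1.27815)),
        ),
        "itt": GroupSurvival(
            atezolizumab_pfs=SurvivalModel("exponential", (0.01502,)),
            atezolizumab_os=SurvivalModel("weibull", (0.00222, 1.27815)),
            bsc_pfs=SurvivalModel("lognormal", (3.64405, 1.50079)),
            bsc_os=SurvivalModel("loglogistic", (0.01018, 0.67737)),
        ),
    }
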