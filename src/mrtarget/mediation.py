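"""Mediation assessment by contrasting adjusted and unadjusted outcomes.

When a target affects both a primary disease (e.g. heart failure) and a
candidate mediator disease (e.g. coronary artery disease), the mediated
share can be probed by repeating the MR against an outcome GWAS that was
conditioned on the mediator (e.g. via mtCOJO, consumed here as an input):
if the effect survives adjustment essentially unchanged, there is no
evidence the mediator carries it.

The contrast supplies a formal z-test for the difference that the
informal "limited difference" criterion lacks. Its SE treats the two
estimates as independent, which is conservative when they share
instruments and exposure data; the report flags this assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .estimators import MREstimate

NO_EVIDENCE = "no_evidence_of_mediation"
ATTENUATION = "evidence_of_attenuation"


@dataclass
class MediationReport:
    estimate_primary: MREstimate
    estimate_mediator: Optional[MREstimate]
    estimate_primary_adjusted: MREstimate
    delta_theta: float
    delta_se: float
    delta_z: float
    delta_pvalue: float
    verdict: str
    se_assumption: str = "independent estimates (conservative when instruments are shared)"


def mediation_contrast(
    primary: MREstimate,
    mediator: Optional[MREstimate],
    primary_adjusted: MREstimate,
    alpha: float = 0.05,
    require_attenuation: bool = True,
) -> MediationReport:
    """Compare MR estimates on the unadjusted vs mediator-adjusted outcome.

    ``delta_theta = theta_primary - theta_adjusted`` with
    ``delta_se = sqrt(se_primary^2 + se_adjusted^2)``. The verdict is
    ``evidence_of_attenuation`` iff the difference is significant at
    ``alpha`` and (when ``require_attenuation``) the adjusted effect is
    smaller in magnitude; otherwise ``no_evidence_of_mediation``. All
    estimates must be expressed in the same per-unit direction.
    """
    directions = {primary.direction, primary_adjusted.direction}
    if mediator is not None:
        directions.add(mediator.direction)
    if len(directions) != 1:
        raise ValueError(
            f"estimates use mismatched reporting directions: {sorted(directions)}"
        )
    delta = primary.theta - primary_adjusted.theta
    delta_se = float(np.hypot(primary.se, primary_adjusted.se))
    z = delta / delta_se
    p = float(2 * stats.norm.sf(abs(z)))
    attenuated = abs(primary_adjusted.theta) < abs(primary.theta)
    significant = p < alpha
    if significant and (attenuated or not require_attenuation):
        verdict = ATTENUATION
    else:
        verdict = NO_EVIDENCE
    return MediationReport(
        estimate_primary=primary,
        estimate_mediator=mediator,
        estimate_primary_adjusted=primary_adjusted,
        delta_theta=float(delta),
        delta_se=delta_se,
        delta_z=float(z),
        delta_pvalue=p,
        verdict=verdict,
    )
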