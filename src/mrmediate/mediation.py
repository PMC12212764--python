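"""Product-of-coefficients mediation arithmetic for two-step MR.

With a total exposure->outcome effect beta_all, an exposure->mediator effect
beta1 and a mediator->outcome effect beta2, the mediated (indirect) effect is
beta1*beta2 and the mediated proportion is (beta1*beta2)/beta_all.  The
proportion may legitimately be negative (indirect and total effects of
opposite sign) or exceed 1; it is reported as computed, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedProportionError
from .estimators import Z95


@dataclass(frozen=True)
class MediationEstimate:
    """Two-step mediation result with delta-method uncertainty.

    The SE/CI of the proportion are an extension over the bare point estimate:
    a first-order delta method treating the three input estimates as
    independent (they come from non-overlapping GWAS samples).
    """

    beta_all: float
    se_all: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    proportion: float
    se_proportion: float
    ci_low: float
    ci_high: float


def mediation_proportion(beta_all: float, se_all: float,
                         beta1: float, se1: float,
                         beta2: float, se2: float) -> MediationEstimate:
    """Mediated proportion (beta1*beta2)/beta_all with delta-method SE.

    var(prop) ~= prop^2 [(se1/beta1)^2 + (se2/beta2)^2 + (se_all/beta_all)^2],
    computed in the algebraically identical expanded form
    var(indirect)/beta_all^2 + indirect^2 se_all^2 / beta_all^4 so the
    beta1 = 0 or beta2 = 0 limits need no special-casing.  SEs of zero are
    allowed (exact inputs).  Raises if beta_all is zero.
    """
    if beta_all == 0:
        raise UndefinedProportionError("total effect beta_all is zero")
    for name, se in (("se_all", se_all), ("se1", se1), ("se2", se2)):
        if se < 0:
            raise ValueError(f"{name} must be >= 0")
    indirect = beta1 * beta2
    var_indirect = beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2
    prop = indirect / beta_all
    var_prop = (var_indirect / beta_all ** 2
                + (indirect * se_all) ** 2 / beta_all ** 4)
    se_prop = float(np.sqrt(var_prop))
    return MediationEstimate(
        beta_all=float(beta_all), se_all=float(se_all), beta1=float(beta1),
        se1=float(se1), beta2=float(beta2), se2=float(se2),
        indirect=float(indirect), se_indirect=float(np.sqrt(var_indirect)),
        proportion=float(prop), se_proportion=se_prop,
        ci_low=float(prop - Z95 * se_prop), ci_high=float(prop + Z95 * se_prop),
    )
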