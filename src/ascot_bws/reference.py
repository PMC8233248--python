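"""Published Austrian S-MNL estimates for the ASCOT-Carer.

These are the level utilities, positioning effects and scale multipliers
estimated from the Austrian general-population valuation survey (n = 1001).
They serve two roles in this package: as the default data-generating values
of the synthetic-choice simulator, and as the worked-example input of the
preference-weight scorer.  All utilities are relative to 'space and time to
be yourself' at level 4 (pinned to 0); levels 1 and 2 of 'feeling supported
and encouraged' share one coefficient.
"""

from __future__ import annotations

import numpy as np

from .estimate import ParameterVector

# rows follow instrument domain order OCC, CTL, SELF, SAFE, SOC, STS, ENC;
# columns are levels 1..4
AUSTRIA_BETA = np.array(
    [
        [3.53, 3.38, 1.34, 0.36],  # Occupation
        [3.33, 3.08, 1.64, 0.37],  # Control over daily life
        [2.82, 2.75, 0.99, 0.43],  # Looking after yourself
        [2.56, 1.78, 1.10, 0.71],  # Personal safety
        [2.94, 2.58, 1.34, 0.45],  # Social participation and involvement
        [3.50, 3.39, 1.69, 0.00],  # Space and time to be yourself (L4 = reference)
        [2.71, 2.71, 1.20, 0.41],  # Feeling supported and encouraged (L1 = L2 joint)
    ]
)

# positioning effects on best-type picks, positions 1..7 (position 1 = 0)
AUSTRIA_DELTA = np.array([0.00, -0.10, -0.18, -0.27, -0.32, -0.36, -0.40])

# scale multipliers relative to the reference group (understood the tasks,
# under 35, completion time below the first quartile), whose scale is 1
AUSTRIA_LAMBDA_NOT_UNDERSTOOD = 0.70
AUSTRIA_LAMBDA_AGE_35_PLUS = 0.80
AUSTRIA_LAMBDA_SLOW = 1.66


def austria_reference_params() -> ParameterVector:
    """The Austrian estimates bundled as a :class:`ParameterVector`."""
    return ParameterVector(
        beta=AUSTRIA_BETA.copy(),
        delta=AUSTRIA_DELTA.copy(),
        lam_not_understood=AUSTRIA_LAMBDA_NOT_UNDERSTOOD,
        lam_age35=AUSTRIA_LAMBDA_AGE_35_PLUS,
        lam_slow=AUSTRIA_LAMBDA_SLOW,
    )
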