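"""One-parameter (Jukes–Cantor type) nucleotide distance utilities.

The equal-rates, equal-frequencies substitution model is used throughout the
package: it is the simplest model with a closed-form distance correction, and
every simulated sequence in :mod:`introdepth.simulate` evolves under it.

Conventions
-----------
* ``p`` is a raw (uncorrected) proportion of differing sites between two
  sequences, ``0 <= p < 3/4``.
* ``d`` is an expected number of substitutions per site.
"""

from __future__ import annotations

import numpy as np

#: Raw divergence at which the one-parameter correction diverges.
SATURATION_BOUND = 0.75


def jc_correct(p: float) -> float:
    """Correct a raw proportion of differences to substitutions per site.

    ``d = -(3/4) ln(1 - 4p/3)``. Returns ``nan`` for ``p >= 3/4`` (saturated;
    the correction has no finite value there) and 0.0 for ``p <= 0``.
    """
    if p <= 0.0:
        return 0.0
    if p >= SATURATION_BOUND:
        return float("nan")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def jc_expected_p(d: float) -> float:
    """Expected raw difference proportion after ``d`` substitutions per site.

    Inverse of :func:`jc_correct`: ``p = (3/4)(1 - exp(-4d/3))``.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    return float(0.75 * -np.expm1(-4.0 * d / 3.0))


def jc_identity_prob(d: float) -> float:
    """Probability a site is in its original state after ``d`` substitutions."""
    return 1.0 - jc_expected_p(d)
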