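"""Classical test-theory corrections and a two-sample power calculation.

Cronbach's alpha for composite reliability, the Spearman–Brown prophecy
formula and its inverse (back-calculating single-component reliability from
a k-component composite), disattenuation of correlations for measurement
unreliability, and the normal-approximation power of a two-independent-
samples mean comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm

__all__ = [
    "cronbach_alpha",
    "spearman_brown",
    "spearman_brown_inverse",
    "composite_reliability_two_parts",
    "disattenuate",
    "power_two_sample",
]


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of a persons x components score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum),
    with sample (n-1) variances on complete cases.  May be negative for
    badly behaved items; equals 1 for parallel items.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least 2 components")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 3:
        raise ValueError("need at least 3 complete cases")
    k = m.shape[1]
    total_var = np.var(m.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    item_var = np.var(m, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def spearman_brown(r: float, k: float) -> float:
    """Reliability of a composite of k parallel components, each of
    reliability r: k*r / (1 + (k-1)*r)."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"component reliability must be in (0, 1), got {r}")
    if k <= 0:
        raise ValueError(f"length factor must be positive, got {k}")
    return k * r / (1.0 + (k - 1.0) * r)


def spearman_brown_inverse(R: float, k: float) -> float:
    """Single-component reliability back-calculated from a k-component
    composite reliability R: r = R / (k - (k-1)*R)."""
    if not 0.0 < R < 1.0:
        raise ValueError(f"composite reliability must be in (0, 1), got {R}")
    if k <= 1:
        raise ValueError(f"length factor must exceed 1, got {k}")
    denom = k - (k - 1.0) * R
    if denom <= 0:
        raise ValueError("inverse Spearman-Brown undefined: non-positive denominator")
    return R / denom


def composite_reliability_two_parts(r1: float, r2: float) -> float:
    """Overall reliability of a two-part assessment from the parts'
    reliabilities: Spearman–Brown at k=2 on their mean."""
    for r in (r1, r2):
        if not 0.0 < r < 1.0:
            raise ValueError(f"component reliability must be in (0, 1), got {r}")
    return spearman_brown((r1 + r2) / 2.0, 2.0)


def disattenuate(r_xy: float, r_xx: float, r_yy: float) -> float:
    """Correlation corrected for unreliability: r_xy / sqrt(r_xx * r_yy).

    The corrected magnitude can exceed 1 when the observed correlation is
    close to the reliability ceiling; it is reported as computed, with a
    warning rather than clipping.
    """
    for r, label in ((r_xx, "r_xx"), (r_yy, "r_yy")):
        if not 0.0 < r <= 1.0:
            raise ValueError(f"reliability {label} must be in (0, 1], got {r}")
    if abs(r_xy) > 1.0:
        raise ValueError(f"|r_xy| must be <= 1, got {r_xy}")
    out = r_xy / np.sqrt(r_xx * r_yy)
    if abs(out) > 1.0:
        warnings.warn(
            f"disattenuated correlation {out:.3f} exceeds 1 in magnitude",
            stacklevel=2,
        )
    return float(out)


def power_two_sample(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 1
) -> float:
    """Normal-approximation power for a two-independent-samples mean test.

    The noncentrality is d * sqrt(n1*n2/(n1+n2)).  ``tails=1`` gives the
    directional test Phi(ncp - z_{1-alpha}); ``tails=2`` adds the opposite
    rejection region at alpha/2 per side.
    """
    if d < 0:
        raise ValueError("effect size d must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 1:
        return float(norm.cdf(ncp - norm.ppf(1.0 - alpha)))
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(ncp - z) + norm.cdf(-ncp - z))
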