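"""Zero-truncated Poisson (ZTP) utilities.

The number of plasmids taken up by a *transformed* yeast cell is modelled as
Poisson with mean ``lam`` conditioned on being at least one: untransformed
cells (zero plasmids) are invisible to the selection and never counted.
``lam`` is proportional to the amount of library DNA in the transformation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "ztp_pmf",
    "ztp_multi_fraction",
    "sample_ztp",
    "eq1_expectation",
    "lambda_from_dna_mass",
]


def ztp_pmf(k, lam: float):
    """P(m = k) for m ~ Poisson(lam) conditioned on m >= 1."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    k = np.asarray(k)
    p = stats.poisson.pmf(k, lam) / (-np.expm1(-lam))
    return np.where(k >= 1, p, 0.0)


def ztp_multi_fraction(lam: float) -> float:
    """Fraction of transformed cells carrying two or more plasmids.

    1 - P(m = 1 | m >= 1) = 1 - lam * exp(-lam) / (1 - exp(-lam)).
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    return 1.0 - lam * np.exp(-lam) / (-np.expm1(-lam))


def sample_ztp(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` ZTP(lam) multiplicities by inverse-CDF through the
    untruncated Poisson: u ~ U(P(0), 1), m = Poisson-quantile(u)."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    p0 = np.exp(-lam)
    u = p0 + rng.random(size) * (1.0 - p0)
    m = stats.poisson.ppf(u, lam).astype(np.int64)
    # floating-point guard at the truncation boundary
    return np.maximum(m, 1)


def eq1_expectation(lam: float, max_m: int = 200) -> float:
    """Exact expectation (as a fraction, not %) of the two-marker
    post-transformation estimator under ZTP multiplicity.

    A cell with m plasmids drawn from an equimolar two-marker pool shows on
    the double-selection plate with probability 1 - 2^(1-m), and the
    estimator's denominator equals the total transformant count exactly, so

        E[estimate] = sum_m P(m | m>=1) * 2 * (1 - 2^(1-m)).

    For m <= 2 this equals the multi-plasmid fraction (the 25/50/25
    composition assumption); cells with m >= 3 are over-counted, giving the
    estimator a positive bias reported by ``eq1_bias``.
    """
    m = np.arange(1, max_m + 1)
    return float(np.sum(ztp_pmf(m, lam) * 2.0 * (1.0 - 2.0 ** (1.0 - m))))


def eq1_bias(lam: float) -> float:
    """Positive bias of the post-transformation estimator caused by cells
    with three or more plasmids (as a fraction)."""
    return eq1_expectation(lam) - ztp_multi_fraction(lam)


def lambda_from_dna_mass(micrograms: float, k: float = 0.05) -> float:
    """Map transformed DNA mass to mean plasmid multiplicity, lam = k * ug.

    The double-transformant fraction grows linearly with DNA in the small-lam
    regime; the default constant puts lam(1 ug) = 0.05.
    """
    if micrograms <= 0:
        raise ValueError("DNA mass must be positive")
    return k * micrograms
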