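"""Two-state thermodynamic map from binding free energy to growth rate.

In a DHFR protein-fragment complementation assay the growth rate of a cell in
methotrexate (MTX) is a proxy for the concentration of the reconstituted
enzyme, which under a two-state model is proportional to the equilibrium
fraction of complex formed.  The map has three pieces:

1. fraction bound  f = 1 / (1 + exp(dG / RT))   (logistic in dG),
2. a linear rescaling of f to a growth rate,    r = r_min + (r_max - r_min) f,
3. a dose-dependent background floor r_bg(dose) from incomplete inhibition of
   the endogenous DHFR: cells never grow slower than the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["ThermoModel", "fraction_bound", "growth_rate_from_binding"]


@dataclass(frozen=True)
class ThermoModel:
    """Latent-parameter bundle for the binding-to-growth map.

    Parameters
    ----------
    rt : energy scale in kcal/mol (default 0.593, ~25 degC).
    r_min, r_max : growth rates (generations/hour) at fraction bound 0 and 1.
    r_bg0 : background growth rate at 1X MTX (200 ug/mL).
    bg_exponent : power-law exponent of the background dose response,
        r_bg(dose) = r_bg0 * dose**(-bg_exponent), clipped to [r_min, r_max].
        Dose 0 (DMSO, no selection) gives r_max: every cell grows at full
        rate when the endogenous DHFR is uninhibited.
    """

    rt: float = 0.593
    r_min: float = 0.0
    r_max: float = 0.23
    r_bg0: float = 0.016
    bg_exponent: float = 0.6

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("RT must be positive")
        if self.r_min > self.r_max:
            raise ValueError("r_min must not exceed r_max")

    def background_rate(self, dose):
        """Background growth rate r_bg(dose), non-increasing in dose.

        ``dose`` is a multiple of the 1X concentration (200 ug/mL).
        """
        dose = np.asarray(dose, dtype=float)
        if np.any(dose < 0):
            raise ValueError("MTX dose must be non-negative")
        with np.errstate(divide="ignore"):
            r = np.where(dose > 0, self.r_bg0 * dose ** (-self.bg_exponent), np.inf)
        r = np.clip(r, self.r_min, self.r_max)
        if np.ndim(dose) == 0:
            return float(r)
        return r


def fraction_bound(dg, model: ThermoModel):
    """Equilibrium fraction of complex, f = 1 / (1 + exp(dG / RT)).

    Strictly decreasing in dG; saturates numerically at 0 and 1.
    """
    dg = np.asarray(dg, dtype=float)
    f = expit(-dg / model.rt)
    if np.ndim(dg) == 0:
        return float(f)
    return f


def growth_rate_from_binding(f, dose, model: ThermoModel):
    """Growth rate implied by fraction bound ``f`` at MTX multiple ``dose``.

    r = max(r_bg(dose), r_min + (r_max - r_min) * f): linear in f above the
    dose-dependent background floor.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fraction bound must lie in [0, 1]")
    r = np.maximum(model.background_rate(dose), model.r_min + (model.r_max - model.r_min) * f)
    if np.ndim(f) == 0 and np.ndim(dose) == 0:
        return float(r)
    return r
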