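"""Distance-decay electron transfer and ensemble electrode currents.

Electron exchange between the electrode and the protein's entry site (the
distal iron–sulfur cluster, for a hydrogenase) is modeled as exponential
tunneling/hopping decay, k(r) = C·exp(−βr).  Averaging the rate over the
Boltzmann orientation ensemble gives a reference current density
J₀ = (1/a₀)·ΣᵢPᵢkᵢ, and the electrode current follows the Langmuir coverage:
J(Π) = A·χ(Π)·J₀, saturating at A·J₀ once a monolayer forms.

C (rate prefactor), a₀ (footprint of one adsorbed protein) and A (electrode
area) are unit-bearing free parameters kept at 1 in arbitrary units; they may
be used as adjustable parameters when fitting experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import coverage

__all__ = [
    "ETParams",
    "BETA_DEFAULT",
    "BETA_STEEP",
    "et_rate",
    "reference_current_density",
    "total_current",
    "isotherm",
]

#: Default tunneling decay constant, Å⁻¹ (hydrogenase-on-graphene estimate).
BETA_DEFAULT = 0.45

#: Steeper decay constant used elsewhere in the protein-ET literature, Å⁻¹.
BETA_STEEP = 1.4


@dataclass(frozen=True)
class ETParams:
    """Electron-transfer and geometry parameters.

    beta : decay constant, Å⁻¹.
    C : rate prefactor, AU (absorbs driving force, reorganization energy, T).
    a0 : area per adsorbed protein, AU.
    A : electrode area, AU.
    """

    beta: float = BETA_DEFAULT
    C: float = 1.0
    a0: float = 1.0
    A: float = 1.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if min(self.C, self.a0, self.A) <= 0:
            raise ValueError("C, a0 and A must be positive")

    @classmethod
    def steep(cls, **kwargs) -> "ETParams":
        """Alternative profile with the steeper decay β = 1.4 Å⁻¹."""
        kwargs.setdefault("beta", BETA_STEEP)
        return cls(**kwargs)


def et_rate(r, params: ETParams = ETParams()):
    """Electron-transfer rate k = C·exp(−β·r) in AU, for distance r in Å."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance must be non-negative")
    k = params.C * np.exp(-params.beta * r_arr)
    return float(k) if np.isscalar(r) or r_arr.ndim == 0 else k


def reference_current_density(
    probs, rates, params: ETParams = ETParams()
) -> float:
    """Probability-weighted mean ET rate per protein footprint, AU.

    J₀ = (1/a₀)·Σᵢ Pᵢ·kᵢ — independent of protein concentration and
    electrode area; sets the saturation current A·J₀.
    """
    p = np.asarray(probs, dtype=float)
    k = np.asarray(rates, dtype=float)
    if p.shape != k.shape:
        raise ValueError("probabilities and rates must have equal length")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("orientation probabilities must sum to 1")
    return float(np.sum(p * k) / params.a0)


def total_current(chi: float, j0: float, params: ETParams = ETParams()) -> float:
    """Electrode current J = A·χ·J₀ in AU for coverage 0 ≤ χ ≤ 1."""
    if not 0.0 <= chi <= 1.0 + 1e-12:
        raise ValueError("coverage must lie in [0, 1]")
    return float(params.A * chi * j0)


def isotherm(
    pi_grid, k_total: float, j0: float, params: ETParams = ETParams()
) -> pd.DataFrame:
    """Current–pressure isotherm: columns pi_au, chi, j_au.

    Combines the Langmuir coverage χ(Π) with J = A·χ·J₀ over a grid of
    osmotic pressures; J is nondecreasing in Π and plateaus at A·J₀.
    """
    pi_arr = np.asarray(pi_grid, dtype=float)
    chi = coverage(pi_arr, k_total)
    return pd.DataFrame(
        {"pi_au": pi_arr, "chi": chi, "j_au": params.A * chi * j0}
    )
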