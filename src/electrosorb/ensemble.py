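"""Boltzmann orientation statistics and Langmuir adsorption equilibria.

Per-orientation interaction energies ΔEᵢ map to occupation probabilities
Pᵢ ∝ exp(−ΔEᵢ/k_BT) and to orientation-resolved adsorption constants
Kᵢ = (1/M)·exp(−ΔEᵢ/k_BT); the 1/M prefactor accounts for the rotational
entropy lost when a protein in solution locks into one of M orientations.
The overall constant K = ΣKᵢ drives a Langmuir isotherm in the protein's
osmotic pressure Π: coverage χ = KΠ/(1 + KΠ).  K and Π carry arbitrary
units because the vibrational/reference-state prefactor is unknown and set
to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT_KJ

__all__ = [
    "EnsembleParams",
    "probabilities",
    "adsorption_constants",
    "coverage",
    "orientation_coverage",
]


@dataclass(frozen=True)
class EnsembleParams:
    """Parameters of the orientation ensemble.

    ``M`` is the number of sampled orientations; ``unit_prefactor`` is the
    (unknown) vibrational/reference-state factor in the adsorption constant,
    fixed to 1 so K and Π are reported in matching arbitrary units.
    """

    temperature: float = 298.15
    M: int = 1
    unit_prefactor: float = 1.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.unit_prefactor <= 0:
            raise ValueError("unit_prefactor must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_BT in kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature


def probabilities(energies, temperature: float = 298.15) -> np.ndarray:
    """Boltzmann probabilities Pᵢ = exp(−Eᵢ/k_BT)/Σⱼexp(−Eⱼ/k_BT).

    Computed with max-subtraction so that deeply bound orientations (tens of
    k_BT below the rest, as in salt-free conditions) do not overflow.
    Invariant to adding a constant to all energies, so interaction energies
    and total energies give identical probabilities.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("at least one orientation energy is required")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    kt = GAS_CONSTANT_KJ * temperature
    w = np.exp(-(e - e.min()) / kt)
    return w / w.sum()


def adsorption_constants(energies, params: EnsembleParams):
    """Orientation-resolved Langmuir constants and their sum, arbitrary units.

    Kᵢ = (unit_prefactor/M)·exp(−ΔEᵢ/k_BT); K_total = Σᵢ Kᵢ.  Unlike the
    probabilities, these are *not* shift-invariant: the absolute depth of the
    adsorption well sets how strongly the protein binds.

    Returns ``(K_i, K_total)``.
    """
    e = np.asarray(energies, dtype=float)
    if e.size != params.M:
        raise ValueError(
            f"got {e.size} energies for an ensemble with M={params.M}"
        )
    k_i = params.unit_prefactor / params.M * np.exp(-e / params.kT)
    return k_i, float(k_i.sum())


def coverage(pi, k_total: float):
    """Langmuir coverage χ = KΠ/(1 + KΠ) for osmotic pressure Π ≥ 0.

    Linear in Π for Π ≪ 1/K, ½ at Π = 1/K, saturating at 1 (monolayer)
    for Π ≫ 1/K.
    """
    pi_arr = np.asarray(pi, dtype=float)
    if np.any(pi_arr < 0):
        raise ValueError("osmotic pressure must be non-negative")
    chi = k_total * pi_arr / (1.0 + k_total * pi_arr)
    return float(chi) if np.isscalar(pi) or pi_arr.ndim == 0 else chi


def orientation_coverage(chi: float, probs) -> np.ndarray:
    """Split the overall coverage among orientations: χᵢ = Pᵢ·χ, Σχᵢ = χ."""
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("orientation probabilities must sum to 1")
    return p * chi
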