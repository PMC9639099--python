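"""Protein–electrode electrostatic interaction energies.

Two backends evaluate the per-orientation adsorption energy ΔE(θ, φ):

* The built-in **screened-Coulomb image-charge (SCIC)** model: the exact
  Green's-function solution of the linearized Poisson–Boltzmann (Debye–
  Hückel) equation in the half-space z > 0 bounded by a conductor held at a
  fixed potential φ_e.  Each protein charge q at height z interacts with the
  plane through (i) the decaying potential of the biased plane,
  φ_e·exp(−κz), and (ii) its own and every other charge's mirror image, a
  screened (Yukawa) attraction.  The construction satisfies the Dirichlet
  condition φ = φ_e on z = 0 exactly.  Charges sit directly in the screened
  solvent: there is no low-dielectric cavity and no ion-exclusion (Stern)
  layer, which is the price of a closed form.

* A **table backend** that ingests per-orientation total energies computed
  externally (e.g. by a boundary-element solver) and reduces them to
  interaction energies by subtracting the isolated-protein and isolated-
  electrode energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    COULOMB_KJ_MOL_ANGSTROM,
    COULOMB_VOLT_ANGSTROM,
    ELEMENTARY_CHARGE,
    FARADAY_KJ_MOL,
    VACUUM_PERMITTIVITY,
)
from .orientation import PlacedStructure
from .structure import Structure

__all__ = [
    "Environment",
    "EnergyBreakdown",
    "GeometryError",
    "ionic_strength",
    "debye_kappa",
    "coulomb_energy",
    "scic_interaction_energy",
    "scic_potential",
    "induced_charge",
    "table_interaction_energy",
]


class GeometryError(ValueError):
    """Raised when charges lie on or below the electrode plane."""


def ionic_strength(concentrations, charges) -> float:
    """Ionic strength I = ½ Σ cⱼ zⱼ² in mol/L.

    For a monovalent salt such as NaCl this coincides with the salt
    concentration.  Electroneutrality is not enforced; an imbalanced input is
    accepted with a warning.
    """
    c = np.asarray(concentrations, dtype=float)
    z = np.asarray(charges, dtype=float)
    if c.shape != z.shape:
        raise ValueError("concentrations and charges must have equal length")
    if c.size == 0:
        return 0.0
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if abs(float(np.sum(c * z))) > 1e-9:
        warnings.warn(
            "ion mixture is not electroneutral; proceeding anyway",
            stacklevel=2,
        )
    return float(0.5 * np.sum(c * z**2))


def debye_kappa(
    I: float, temperature: float = 298.15, eps_solvent: float = 80.0
) -> float:
    """Inverse Debye–Hückel screening length κ in Å⁻¹.

    κ² = 2 e² N_A (1000·I) / (ε₀ ε_s k_B T) with I in mol/L.  At I = 0.15 M,
    298.15 K and ε_s = 80 this gives κ ≈ 0.127 Å⁻¹ (screening length ≈ 8 Å).
    """
    if I < 0:
        raise ValueError("ionic strength must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kappa_sq_m = (
        2.0
        * ELEMENTARY_CHARGE**2
        * AVOGADRO
        * (1e3 * I)
        / (VACUUM_PERMITTIVITY * eps_solvent * BOLTZMANN * temperature)
    )
    return math.sqrt(kappa_sq_m) * 1e-10  # 1/m -> 1/Å


@dataclass(frozen=True)
class Environment:
    """Solvent, electrolyte and electrode parameters.

    Parameters
    ----------
    ionic_strength : mol/L (0.15 for a physiological NaCl solution, 0 for
        salt-free water).
    temperature : K.
    eps_in : protein-interior dielectric constant (used by the Coulomb
        self-energy and by table bookkeeping; the SCIC kernel has no cavity).
    eps_solvent : solvent dielectric constant.
    phi_e : electrode potential in volts, relative to zero at infinity.  The
        linearized treatment requires |e·φ_e| < k_BT, i.e. |φ_e| ≲ 0.025 V at
        room temperature; ±0.05 V is already at the edge of validity.
    gap : distance (Å) between the electrode plane and the van der Waals
        surface of the closest atom.
    stern : ion-exclusion layer thickness (Å).  Metadata only: it motivates
        the default gap (two 2.0 Å layers may not overlap) but does not enter
        the energy kernel.
    """

    ionic_strength: float = 0.15
    temperature: float = 298.15
    eps_in: float = 4.0
    eps_solvent: float = 80.0
    phi_e: float = 0.0
    gap: float = 4.1
    stern: float = 2.0

    @property
    def kappa(self) -> float:
        """Inverse screening length, Å⁻¹ (0 when salt-free)."""
        return debye_kappa(
            self.ionic_strength, self.temperature, self.eps_solvent
        )


@dataclass(frozen=True)
class EnergyBreakdown:
    """Interaction energy split into its two physical terms, kJ/mol.

    ``field_term``: work of the protein charges in the biased plane's decaying
    potential (zero at φ_e = 0).  ``image_term``: attraction to the induced
    surface charge (mirror images); never positive for a conductor.
    """

    field_term: float
    image_term: float

    @property
    def total(self) -> float:
        return self.field_term + self.image_term


def coulomb_energy(structure: Structure, eps_in: float = 4.0) -> float:
    """Intramolecular Coulomb energy ½ΣᵢΣⱼ≠ᵢ k_e qᵢqⱼ/(ε_in rᵢⱼ), kJ/mol.

    Orientation- and translation-invariant; a large but constant term that
    cancels out of orientation probabilities.
    """
    coords = structure.coordinates
    q = structure.charges
    if len(structure) < 2:
        return 0.0
    d = cdist(coords, coords)
    iu = np.triu_indices(len(structure), k=1)
    if np.any(d[iu] == 0.0):
        raise ValueError("coincident atoms: Coulomb energy is singular")
    qq = np.outer(q, q)
    return float(COULOMB_KJ_MOL_ANGSTROM / eps_in * np.sum(qq[iu] / d[iu]))


def _check_above_plane(placed: PlacedStructure) -> None:
    z = placed.structure.coordinates[:, 2]
    if np.any(z <= 0):
        raise GeometryError(
            "all charges must lie strictly above the electrode plane (z > 0)"
        )


def scic_interaction_energy(
    placed: PlacedStructure, env: Environment
) -> EnergyBreakdown:
    """Adsorption energy of a placed structure in the SCIC half-space model.

    field_term = F φ_e Σᵢ qᵢ exp(−κ zᵢ)

    image_term = −(k_e / 2 ε_s) Σᵢ Σⱼ qᵢ qⱼ exp(−κ d*ᵢⱼ)/d*ᵢⱼ

    where d*ᵢⱼ is the distance from charge i to the mirror image (through
    z = 0) of charge j; the i = j self-image term, d*ᵢᵢ = 2zᵢ, is included —
    it dominates the conductor attraction.  The global ½ reflects that the
    image charges are induced, not fixed.  Both terms vanish as the structure
    recedes from the plane, so the result is already an interaction energy
    (isolated references subtract to zero).
    """
    _check_above_plane(placed)
    kappa = env.kappa
    coords = placed.structure.coordinates
    q = placed.structure.charges

    field = FARADAY_KJ_MOL * env.phi_e * float(
        np.sum(q * np.exp(-kappa * coords[:, 2]))
    )

    mirror = coords * np.array([1.0, 1.0, -1.0])
    dstar = cdist(coords, mirror)  # diagonal = 2 z_i
    qq = np.outer(q, q)
    image = -(
        COULOMB_KJ_MOL_ANGSTROM / (2.0 * env.eps_solvent)
    ) * float(np.sum(qq * np.exp(-kappa * dstar) / dstar))
    return EnergyBreakdown(field_term=field, image_term=image)


def scic_potential(
    placed: PlacedStructure, env: Environment, points: np.ndarray
) -> np.ndarray:
    """Electrostatic potential (V) of the SCIC solution at given points.

    φ(r) = φ_e e^{−κz} + (k/ε_s) Σⱼ qⱼ [e^{−κ|r−rⱼ|}/|r−rⱼ| −
    e^{−κ|r−r*ⱼ|}/|r−r*ⱼ|].  On the plane z = 0 the Yukawa pair cancels
    exactly and φ = φ_e: the Dirichlet electrode condition holds by
    construction.  Valid for z ≥ 0, away from the charges themselves.
    """
    _check_above_plane(placed)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    kappa = env.kappa
    coords = placed.structure.coordinates
    q = placed.structure.charges
    mirror = coords * np.array([1.0, 1.0, -1.0])
    d = cdist(pts, coords)
    dm = cdist(pts, mirror)
    with np.errstate(divide="ignore"):
        yukawa = np.exp(-kappa * d) / d - np.exp(-kappa * dm) / dm
    phi = env.phi_e * np.exp(-kappa * pts[:, 2]) + (
        COULOMB_VOLT_ANGSTROM / env.eps_solvent
    ) * yukawa.dot(q)
    return phi


def _surface_charge_density(
    placed: PlacedStructure, env: Environment, xy: np.ndarray
) -> np.ndarray:
    """Induced surface charge density σ at points on z = 0, in e/Å²."""
    kappa = env.kappa
    coords = placed.structure.coordinates
    q = placed.structure.charges
    dx = xy[:, 0][:, None] - coords[:, 0][None, :]
    dy = xy[:, 1][:, None] - coords[:, 1][None, :]
    z = coords[:, 2][None, :]
    d = np.sqrt(dx**2 + dy**2 + z**2)
    # image part: independent of eps (Gauss's law); plane part from the
    # biased-plane profile phi_e * exp(-kappa z)
    sigma_img = -(q[None, :] * z * (kappa * d + 1.0) * np.exp(-kappa * d) / (
        2.0 * math.pi * d**3
    )).sum(axis=1)
    sigma_plane_si = (
        VACUUM_PERMITTIVITY * env.eps_solvent * (kappa * 1e10) * env.phi_e
    )  # C/m²
    sigma_plane = sigma_plane_si / ELEMENTARY_CHARGE * 1e-20  # e/Å²
    return sigma_img + sigma_plane


def induced_charge(
    placed: PlacedStructure,
    env: Environment,
    disc_radius: float,
    n_rings: int = 128,
    n_azimuth: int = 64,
) -> float:
    """Total induced charge (e) on a disc of the electrode of given radius.

    Numerically integrates the analytic surface charge density
    σ = −ε₀ε_s ∂φ/∂z|_{z=0} over a disc centered on the origin, with
    Gauss–Legendre nodes in radius and a uniform periodic rule in azimuth.

    In the unscreened, unbiased limit (κ = 0, φ_e = 0) the integral over an
    unbounded plane equals minus the protein's net charge (Gauss's law): the
    electrode neutralizes the adsorbate.  Screening localizes but also
    shares the compensation with the ion cloud; a bias adds a uniform
    background density proportional to the disc area.
    """
    _check_above_plane(placed)
    if disc_radius <= 0:
        raise ValueError("disc_radius must be positive")
    coords = placed.structure.coordinates
    lateral = float(np.hypot(coords[:, 0], coords[:, 1]).max())
    if disc_radius < lateral:
        warnings.warn(
            f"disc radius {disc_radius:.1f} Å is smaller than the structure's"
            f" lateral extent {lateral:.1f} Å; the integral will miss charge",
            stacklevel=2,
        )
    nodes, wts = np.polynomial.legendre.leggauss(n_rings)
    r = 0.5 * disc_radius * (nodes + 1.0)
    wr = 0.5 * disc_radius * wts
    ang = 2.0 * math.pi * np.arange(n_azimuth) / n_azimuth
    wa = 2.0 * math.pi / n_azimuth
    rr, aa = np.meshgrid(r, ang, indexing="ij")
    xy = np.column_stack(
        [(rr * np.cos(aa)).ravel(), (rr * np.sin(aa)).ravel()]
    )
    sigma = _surface_charge_density(placed, env, xy).reshape(n_rings, n_azimuth)
    return float(np.sum(sigma.sum(axis=1) * wa * r * wr))


def table_interaction_energy(
    e_total: float | None = None,
    e_protein: float = 0.0,
    e_electrode: float = 0.0,
    *,
    components: tuple[float, float, float] | None = None,
) -> float:
    """Interaction energy ΔE = E_total − E_protein − E_electrode, kJ/mol.

    ``e_total`` may be given directly, or assembled from the three externally
    computed contributions ``components = (E_coulomb, E_solvation,
    E_surface)``.  All energies must be in kJ/mol on a common reference.
    """
    if components is not None:
        if e_total is not None:
            raise ValueError("give either e_total or components, not both")
        e_total = float(sum(components))
    if e_total is None:
        raise ValueError(
            "missing total energy: supply e_total or its three components"
        )
    if e_protein is None or e_electrode is None:
        raise ValueError("isolated protein and electrode energies are required")
    return float(e_total - e_protein - e_electrode)
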