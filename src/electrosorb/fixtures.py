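"""Synthetic structures and energy tables with known ground truth.

Real prepared point-charge structures of a hydrogenase (with quantum-derived
cofactor charges) are not redistributable, so the test and example suite runs
on generated stand-ins: quasi-spherical clouds of point charges with a tuned
net charge (and optionally dipole), residue labels, and one interior atom
marked as the electron-transfer entry site.  Energy tables over an
orientation grid come with brute-force ensemble observables computed at
extended precision, so the analysis pipeline can be checked against an
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import GAS_CONSTANT_KJ
from .electron_transfer import ETParams
from .orientation import OrientationGrid
from .structure import Atom, Structure, dipole_moment

__all__ = [
    "FixtureSpec",
    "SyntheticEnergyTable",
    "toy_protein",
    "dipole_fixture",
    "single_well_landscape",
    "synthetic_energy_table",
]

# residue names cycled through by the generator; all canonical, so patch
# diagnostics treat toy structures like real amino-acid chains
_RESIDUE_CYCLE = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy point-charge protein.

    n_atoms point charges are placed uniformly in a ball of ``body_radius``
    Å; partial charges are drawn and then affinely shifted so the net charge
    hits ``net_charge_target`` exactly.  If ``dipole_target`` (e·Å) is given,
    a zero-sum charge pattern along z is added to reach that dipole modulus.
    Atoms are grouped into residues of three; the atom nearest the body
    center becomes the electron-transfer entry site.
    """

    n_atoms: int = 150
    body_radius: float = 18.0
    net_charge_target: float = -5.0
    dipole_target: Optional[float] = None
    atom_radius_range: tuple[float, float] = (1.2, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 2:
            raise ValueError("n_atoms must be >= 2")
        if self.body_radius <= 0:
            raise ValueError("body_radius must be positive")
        lo, hi = self.atom_radius_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid atom_radius_range")


def _ball_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def toy_protein(spec: FixtureSpec = FixtureSpec()) -> Structure:
    """Generate a reproducible quasi-spherical point-charge structure."""
    rng = np.random.default_rng(spec.seed)
    coords = _ball_points(rng, spec.n_atoms, spec.body_radius)
    lo, hi = spec.atom_radius_range
    radii = rng.uniform(lo, hi, spec.n_atoms)
    charges = rng.normal(0.0, 0.4, spec.n_atoms)
    charges += (spec.net_charge_target - charges.sum()) / spec.n_atoms

    def build(q: np.ndarray) -> Structure:
        atoms = []
        for i in range(spec.n_atoms):
            atoms.append(
                Atom(
                    serial=i + 1,
                    name=f"C{i % 4 + 1}",
                    residue_name=_RESIDUE_CYCLE[(i // 3) % len(_RESIDUE_CYCLE)],
                    chain="A",
                    residue_seq=i // 3 + 1,
                    position=coords[i],
                    charge=float(q[i]),
                    radius=float(radii[i]),
                )
            )
        entry = int(np.argmin(np.linalg.norm(coords, axis=1)))
        return Structure(
            atoms,
            et_entry_serial=entry + 1,
            label=f"toy-{spec.seed}",
        )

    if spec.dipole_target is not None:
        z = coords[:, 2]
        pattern = z - z.mean()  # zero-sum: preserves the net charge
        scale = float(np.sum(pattern**2))
        if scale < 1e-9:
            raise ValueError(
                "dipole_target infeasible: atoms have no spread along z"
            )

        def excess(a: float) -> float:
            return (
                dipole_moment(build(charges + a * pattern)).e_angstrom
                - spec.dipole_target
            )

        a_hi = 10.0 * (spec.dipole_target + 1.0) / scale
        for _ in range(60):
            if excess(a_hi) > 0:
                break
            a_hi *= 2.0
        else:
            raise ValueError("dipole_target infeasible for this geometry")
        if excess(0.0) >= 0.0:
            a = brentq(excess, -a_hi, 0.0) if excess(-a_hi) < 0 else 0.0
        else:
            a = brentq(excess, 0.0, a_hi)
        charges = charges + a * pattern

    return build(charges)


def dipole_fixture(separation: float) -> Structure:
    """Two atoms of charge ±1 e separated along z; net charge 0.

    Dipole modulus equals ``separation`` in e·Å (4.803·separation in debye).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    atoms = [
        Atom(1, "P", "GLY", "A", 1, np.array([0.0, 0.0, separation / 2]), 1.0, 1.0),
        Atom(2, "N", "GLY", "A", 2, np.array([0.0, 0.0, -separation / 2]), -1.0, 1.0),
    ]
    return Structure(atoms, label="dipole-fixture")


def single_well_landscape(
    theta0: float, phi0: float, depth: float, base: float = 0.0
) -> Callable[[float, float], float]:
    """Landscape that is ``base`` everywhere except one orientation, which
    sits ``depth`` kJ/mol lower.  Useful for planting a known minimum."""

    def landscape(theta: float, phi: float) -> float:
        if abs(theta - theta0) < 1e-9 and abs(phi - phi0) < 1e-9:
            return base - depth
        return base

    return landscape


@dataclass(frozen=True)
class SyntheticEnergyTable:
    """An external-backend energy table bundled with oracle observables.

    ``frame`` is the CSV dialect consumed by the table backend (columns
    theta_deg, phi_deg, e_total_kj_mol, r_angstrom).  ``probabilities``,
    ``k_total`` and ``j0`` are ground truth computed by direct brute-force
    summation at extended (long-double) precision, independent of the
    pipeline code path.
    """

    frame: pd.DataFrame
    probabilities: np.ndarray
    k_total: float
    j0: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _default_distance(theta: float, phi: float) -> float:
    # smooth, orientation-dependent entry-site distance in a plausible range
    t, p = math.radians(theta), math.radians(phi)
    return 25.0 + 15.0 * math.cos(t) + 5.0 * math.sin(t) * math.cos(p)


def synthetic_energy_table(
    grid: OrientationGrid,
    landscape: Callable[[float, float], float],
    noise: float = 0.0,
    seed: int = 0,
    distance: Callable[[float, float], float] = _default_distance,
    temperature: float = 298.15,
    et_params: ETParams = ETParams(),
) -> SyntheticEnergyTable:
    """Tabulate a parametric energy landscape over an orientation grid.

    ``landscape(theta_deg, phi_deg)`` gives the interaction energy in kJ/mol;
    Gaussian noise of the given standard deviation is added reproducibly.
    Ground-truth Boltzmann probabilities, the overall adsorption constant
    K = Σᵢ(1/M)exp(−Eᵢ/k_BT) and the reference current density
    J₀ = (1/a₀)ΣᵢPᵢC·exp(−β rᵢ) are evaluated by direct summation with
    ``numpy.longdouble`` accumulators.
    """
    rng = np.random.default_rng(seed)
    e = np.array(
        [landscape(t, p) for t, p in zip(grid.theta_deg, grid.phi_deg)],
        dtype=float,
    )
    if noise > 0:
        e = e + rng.normal(0.0, noise, grid.M)
    if not np.all(np.isfinite(e)):
        raise ValueError("landscape must be finite on the grid")
    r = np.array(
        [distance(t, p) for t, p in zip(grid.theta_deg, grid.phi_deg)],
        dtype=float,
    )
    frame = pd.DataFrame(
        {
            "theta_deg": grid.theta_deg,
            "phi_deg": grid.phi_deg,
            "e_total_kj_mol": e,
            "r_angstrom": r,
        }
    )

    # brute-force oracle at extended precision, independent of the ensemble
    # module's vectorized max-subtraction path
    kt = np.longdouble(GAS_CONSTANT_KJ) * np.longdouble(temperature)
    e_ld = e.astype(np.longdouble)
    shift = e_ld.min()  # keeps exp in range; exact cancellation in P
    boltz = np.array(
        [np.exp(-(ei - shift) / kt) for ei in e_ld], dtype=np.longdouble
    )
    norm = np.longdouble(0.0)
    for b in boltz:
        norm += b
    probs = boltz / norm
    k_total = np.longdouble(0.0)
    for ei in e_ld:
        k_total += np.exp(-ei / kt) / np.longdouble(grid.M)
    j0 = np.longdouble(0.0)
    for pi, ri in zip(probs, r.astype(np.longdouble)):
        j0 += (
            pi
            * np.longdouble(et_params.C)
            * np.exp(-np.longdouble(et_params.beta) * ri)
        )
    j0 /= np.longdouble(et_params.a0)
    return SyntheticEnergyTable(
        frame=frame,
        probabilities=probs.astype(float),
        k_total=float(k_total),
        j0=float(j0),
    )
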