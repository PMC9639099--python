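"""Orientation sampling and rigid placement above the electrode plane.

The electrode is the plane z = 0 with the electrolyte filling z > 0.  An
orientation of the protein is a tilt angle θ (0–180°) and an azimuth φ
(0–360°); the grid samples θ in even steps and φ with a θ-dependent step so
that samples are roughly uniform in solid angle, dφ = 360°/max{1, n_eq·sinθ}
with a single sample at each pole.

The absolute body frame (which protein axis corresponds to θ = 0) is a
convention: ensemble-level observables are insensitive to it on a fine enough
grid, per-orientation labels are not.  The convention used here centers the
coordinates on the unweighted centroid and rotates the body-frame direction
(θ, φ) onto the electrode normal, R = R_y(−θ)·R_z(−φ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "OrientationGrid",
    "PlacedStructure",
    "build_grid",
    "orient",
    "place",
    "pose",
    "et_distance",
]


@dataclass(frozen=True)
class OrientationGrid:
    """The (θ, φ) sample set with per-sample solid angles.

    ``weight_sr`` holds the solid angle (steradian) represented by each
    sample: the θ strip (or polar cap) divided evenly among its φ samples.
    Weights sum to 4π by construction.  Ensemble sums nevertheless weight
    orientations evenly by default, because the sampling rule already makes
    the per-sample solid angles roughly constant; the stored weights serve as
    diagnostics and as an opt-in alternative.
    """

    theta_deg: np.ndarray
    phi_deg: np.ndarray
    weight_sr: np.ndarray

    def __post_init__(self):
        for name in ("theta_deg", "phi_deg", "weight_sr"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if not (
            self.theta_deg.shape == self.phi_deg.shape == self.weight_sr.shape
        ):
            raise ValueError("grid arrays must have equal length")
        if np.any(self.weight_sr <= 0):
            raise ValueError("solid-angle weights must be positive")

    @property
    def M(self) -> int:
        """Number of sampled orientations."""
        return self.theta_deg.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_deg": self.theta_deg,
                "phi_deg": self.phi_deg,
                "weight_sr": self.weight_sr,
            }
        )


@dataclass(frozen=True)
class PlacedStructure:
    """A structure posed at (θ, φ) and resting at a fixed gap above z = 0.

    The gap is measured between the electrode plane and the van der Waals
    surface of the closest atom: min(zᵢ − radiusᵢ) = gap.
    """

    structure: Structure
    theta_deg: float
    phi_deg: float
    gap: float


def build_grid(
    dtheta: float = 10.0,
    equator_count: int = 36,
    rounding: str = "round",
) -> OrientationGrid:
    """Build the quasi-uniform (θ, φ) orientation grid.

    θ runs over {0, dθ, …, 180}; at each θ there are
    n(θ) = max{1, f(equator_count·sinθ)} azimuths, equally spaced from 0 over
    [0°, 360°), where f is ``round`` (default) or ``floor``.  Each sample is
    assigned the solid angle of its θ strip (polar caps of half-angle dθ/2 at
    the poles) split evenly over the strip's azimuths.

    Parameters
    ----------
    dtheta : tilt increment in degrees; must divide 180.
    equator_count : number of azimuth samples at θ = 90°.
    rounding : integerization of the azimuth count, ``"round"`` or ``"floor"``.
    """
    n_steps = 180.0 / dtheta
    if abs(n_steps - round(n_steps)) > 1e-9 or dtheta <= 0:
        raise ValueError(f"dtheta={dtheta} must be a positive divisor of 180")
    if equator_count < 1:
        raise ValueError("equator_count must be >= 1")
    if rounding not in ("round", "floor"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    if rounding == "round":
        integerize = round
    else:
        # epsilon guards exact multiples (36·sin 30° = 18) against float
        # representation error
        integerize = lambda x: math.floor(x + 1e-9)  # noqa: E731

    thetas = [i * dtheta for i in range(int(round(n_steps)) + 1)]
    half = math.radians(dtheta) / 2.0
    t_list, p_list, w_list = [], [], []
    for theta in thetas:
        t = math.radians(theta)
        n_phi = max(1, int(integerize(equator_count * math.sin(t))))
        if theta == 0.0:
            strip = 2.0 * math.pi * (1.0 - math.cos(half))
        elif theta == 180.0:
            strip = 2.0 * math.pi * (1.0 - math.cos(half))
        else:
            strip = 2.0 * math.pi * (math.cos(t - half) - math.cos(t + half))
        for k in range(n_phi):
            t_list.append(theta)
            p_list.append(360.0 * k / n_phi)
            w_list.append(strip / n_phi)
    return OrientationGrid(
        np.array(t_list), np.array(p_list), np.array(w_list)
    )


def _rotation(theta_deg: float, phi_deg: float) -> Rotation:
    """R(θ, φ) = R_y(−θ)·R_z(−φ): maps the body-frame direction
    u(θ, φ) = (sinθcosφ, sinθsinφ, cosθ) onto the electrode normal +z.

    This is the inverse of the frame rotation R_z(φ)·R_y(θ).  Applied to the
    body it makes both angles physically active: the z-profile of the atoms
    (which is all the planar model sees) is r·u(θ, φ), so scanning (θ, φ)
    over the sphere scans every distinct presentation of the protein to the
    electrode.  Applying R_z(φ)·R_y(θ) to the body instead would leave the
    z-coordinates independent of φ entirely.
    """
    # intrinsic "YZ" composes as R_y(a1) @ R_z(a2)
    return Rotation.from_euler("YZ", [-theta_deg, -phi_deg], degrees=True)


def orient(structure: Structure, theta_deg: float, phi_deg: float) -> Structure:
    """Center the structure on its centroid and rotate it to (θ, φ).

    The rotation is rigid — R = R_y(−θ)·R_z(−φ) acting on centered
    coordinates, bringing the body direction (θ, φ) onto the electrode
    normal — so all interatomic distances are preserved.
    """
    coords = structure.coordinates
    centered = coords - coords.mean(axis=0)
    rotated = _rotation(theta_deg, phi_deg).apply(centered)
    return structure.with_coordinates(rotated)


def place(
    structure: Structure,
    gap: float = 4.1,
    theta_deg: float = 0.0,
    phi_deg: float = 0.0,
) -> PlacedStructure:
    """Translate the structure along z so its van der Waals surface rests at
    ``gap`` Å above the electrode plane.

    Pure translation: min over atoms of (z − radius) becomes exactly ``gap``.
    θ and φ are carried along as labels for bookkeeping.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    coords = structure.coordinates
    lowest = float((coords[:, 2] - structure.radii).min())
    shifted = coords + np.array([0.0, 0.0, gap - lowest])
    return PlacedStructure(
        structure.with_coordinates(shifted), theta_deg, phi_deg, gap
    )


def pose(
    structure: Structure,
    theta_deg: float,
    phi_deg: float,
    gap: float = 4.1,
) -> PlacedStructure:
    """orient() then place(): the one-call path used by orientation scans."""
    return place(orient(structure, theta_deg, phi_deg), gap, theta_deg, phi_deg)


def et_distance(placed: PlacedStructure) -> float:
    """Perpendicular distance (Å) of the marked electron-transfer entry atom
    to the electrode plane, i.e. its z coordinate."""
    return float(placed.structure.entry_atom.position[2])
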