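"""Orientation scan → ensemble → current: the end-to-end analysis.

A scan poses the structure at every grid orientation, evaluates the
interaction energy (built-in SCIC model or an ingested external table),
measures the entry-site distance and patch diagnostics, and reduces the
per-orientation records to ensemble observables: Boltzmann probabilities,
adsorption constants Kᵢ and K, the reference current density J₀, and the
minimum-energy orientation summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import electron_transfer as et
from .energy import Environment, scic_interaction_energy, table_interaction_energy
from .ensemble import EnsembleParams, adsorption_constants, probabilities
from .orientation import OrientationGrid, build_grid, et_distance, pose
from .patches import nearest_residue, patch_charge
from .structure import Structure, mark_entry_atom, read_pqr

__all__ = [
    "ScanConfig",
    "EnsembleSummary",
    "ScanResult",
    "scan",
    "isotherm_report",
    "load_energy_table",
]

#: Columns of the per-orientation scan table, in output order.
RECORD_COLUMNS = [
    "theta_deg",
    "phi_deg",
    "delta_e_kj_mol",
    "probability",
    "r_angstrom",
    "k_et_au",
    "p_times_k_au",
    "nearest_residue",
    "q10_e",
]


@dataclass(frozen=True)
class ScanConfig:
    """Everything a scan needs.

    Exactly one energy backend is active: ``backend="scic"`` (built-in
    screened-Coulomb image-charge model) or ``backend="table"`` with
    ``table_path`` pointing at a per-orientation energy CSV and the isolated
    protein/electrode energies for the ΔE bookkeeping.
    """

    structure: Optional[Structure] = None
    structure_path: Optional[str] = None
    entry_selector: Optional[str] = None
    environment: Environment = field(default_factory=Environment)
    dtheta: float = 10.0
    equator_count: int = 36
    rounding: str = "round"
    backend: str = "scic"
    table_path: Optional[str] = None
    e_protein: float = 0.0
    e_electrode: float = 0.0
    et_params: et.ETParams = field(default_factory=et.ETParams)
    patch_size: int = 10
    standard_residues_only: bool = True
    label: str = ""

    def resolve_structure(self) -> Structure:
        if (self.structure is None) == (self.structure_path is None):
            raise ValueError(
                "provide exactly one of structure / structure_path"
            )
        s = (
            self.structure
            if self.structure is not None
            else read_pqr(self.structure_path)
        )
        if self.entry_selector:
            s = mark_entry_atom(s, self.entry_selector)
        if s.et_entry_serial is None:
            raise ValueError(
                "no electron-transfer entry atom: mark one or give "
                "entry_selector"
            )
        return s


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble observables plus the minimum-energy orientation row."""

    M: int
    k_i: np.ndarray
    k_total: float
    j0: float
    theta_min: float
    phi_min: float
    delta_e_min: float
    p_min: float
    r_min: float
    aa_min: Optional[tuple]
    q10_min: Optional[int]


@dataclass(frozen=True)
class ScanResult:
    records: pd.DataFrame
    summary: EnsembleSummary
    config: ScanConfig


def load_energy_table(path) -> pd.DataFrame:
    """Read an external per-orientation energy CSV.

    Requires theta_deg and phi_deg plus either e_total_kj_mol or the three
    components e_coulomb_kj_mol, e_solvation_kj_mol, e_surface_kj_mol (summed
    into a total).  Extra columns (e.g. r_angstrom) are carried through.
    """
    df = pd.read_csv(path)
    needed = {"theta_deg", "phi_deg"}
    if not needed.issubset(df.columns):
        raise ValueError(f"energy table must contain columns {sorted(needed)}")
    if "e_total_kj_mol" not in df.columns:
        comps = ["e_coulomb_kj_mol", "e_solvation_kj_mol", "e_surface_kj_mol"]
        if not set(comps).issubset(df.columns):
            raise ValueError(
                "energy table needs e_total_kj_mol or the three component "
                "columns " + ", ".join(comps)
            )
        df = df.copy()
        df["e_total_kj_mol"] = df[comps].sum(axis=1)
    return df


def _table_energies(
    config: ScanConfig, grid: OrientationGrid
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-grid-sample ΔE from the external table, plus the table's own
    entry-site distances when it carries an r_angstrom column (those override
    geometric distances, keeping energies and distances from one source)."""
    table = load_energy_table(config.table_path)
    has_r = "r_angstrom" in table.columns
    key = {}
    for _, row in table.iterrows():
        k = (round(float(row["theta_deg"]), 6), round(float(row["phi_deg"]), 6))
        key[k] = (
            float(row["e_total_kj_mol"]),
            float(row["r_angstrom"]) if has_r else None,
        )
    missing = []
    energies = np.empty(grid.M)
    r = np.empty(grid.M) if has_r else None
    for i, (t, p) in enumerate(zip(grid.theta_deg, grid.phi_deg)):
        k = (round(float(t), 6), round(float(p), 6))
        if k not in key:
            missing.append(k)
            continue
        e_tot, r_i = key[k]
        energies[i] = table_interaction_energy(
            e_tot, config.e_protein, config.e_electrode
        )
        if has_r:
            r[i] = r_i
    if missing:
        shown = ", ".join(f"({t:g}, {p:g})" for t, p in missing[:8])
        raise ValueError(
            f"energy table is missing {len(missing)} grid orientations: "
            f"{shown}{'…' if len(missing) > 8 else ''}"
        )
    return energies, r


def scan(config: ScanConfig) -> ScanResult:
    """Run the orientation scan and reduce it to ensemble observables.

    Returns one record per grid orientation (M rows; probabilities summing
    to 1) and a summary holding K, J₀ and the minimum-energy orientation in
    the per-orientation table schema (ΔE_min, P_min, r_min, AA_min, Q10_min).
    """
    structure = config.resolve_structure()
    grid = build_grid(config.dtheta, config.equator_count, config.rounding)
    env = config.environment

    placed_all = [
        pose(structure, float(t), float(p), env.gap)
        for t, p in zip(grid.theta_deg, grid.phi_deg)
    ]
    table_r = None
    if config.backend == "scic":
        energies = np.array(
            [scic_interaction_energy(pl, env).total for pl in placed_all]
        )
    elif config.backend == "table":
        if not config.table_path:
            raise ValueError("table backend requires table_path")
        energies, table_r = _table_energies(config, grid)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    if table_r is not None:
        r = table_r
    else:
        r = np.array([et_distance(pl) for pl in placed_all])
    rates = et.et_rate(r, config.et_params)
    probs = probabilities(energies, env.temperature)
    params = EnsembleParams(temperature=env.temperature, M=grid.M)
    k_i, k_total = adsorption_constants(energies, params)
    j0 = et.reference_current_density(probs, rates, config.et_params)

    aa, q10 = [], []
    for pl in placed_all:
        try:
            chain, resname, resseq = nearest_residue(
                pl, config.standard_residues_only
            )
            aa.append(f"{resname} {resseq}" + (f" ({chain})" if chain else ""))
            q10.append(
                patch_charge(pl, config.patch_size, config.standard_residues_only)
            )
        except ValueError:
            aa.append("")
            q10.append(np.nan)

    records = pd.DataFrame(
        {
            "theta_deg": grid.theta_deg,
            "phi_deg": grid.phi_deg,
            "delta_e_kj_mol": energies,
            "probability": probs,
            "r_angstrom": r,
            "k_et_au": rates,
            "p_times_k_au": probs * rates,
            "nearest_residue": aa,
            "q10_e": q10,
        },
        columns=RECORD_COLUMNS,
    )

    imin = int(np.argmin(energies))
    summary = EnsembleSummary(
        M=grid.M,
        k_i=k_i,
        k_total=k_total,
        j0=j0,
        theta_min=float(grid.theta_deg[imin]),
        phi_min=float(grid.phi_deg[imin]),
        delta_e_min=float(energies[imin]),
        p_min=float(probs[imin]),
        r_min=float(r[imin]),
        aa_min=aa[imin] or None,
        q10_min=None if np.isnan(q10[imin]) else int(q10[imin]),
    )
    return ScanResult(records=records, summary=summary, config=config)


def isotherm_report(
    summary: EnsembleSummary,
    pi_grid,
    params: Optional[et.ETParams] = None,
) -> pd.DataFrame:
    """Coverage and current curves χ(Π), J(Π) from a completed scan."""
    params = params or et.ETParams()
    return et.isotherm(pi_grid, summary.k_total, summary.j0, params)
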