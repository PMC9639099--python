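"""Surface-patch diagnostics: which residues face the electrode.

For each adsorbed orientation, the residue closest to the electrode and the
net charge of the patch formed by the n closest residues (n = 10 by default)
characterize the local "charge patch" that can steer adsorption independently
of the global dipole.  Residue-to-plane distance is the minimum over the
residue's atoms of (z − radius), consistent with the placement criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .orientation import PlacedStructure

__all__ = [
    "STANDARD_RESIDUES",
    "PatchReport",
    "residue_distances",
    "nearest_residue",
    "patch_charge",
    "patch_report",
]

# 20 canonical amino acids plus the alternate protonation-state names
# emitted by common PQR preparation tools.
STANDARD_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM", "ARN",
        "TYM",
    }
)


@dataclass(frozen=True)
class PatchReport:
    """Nearest residue and patch charge for one adsorbed orientation."""

    nearest_residue: tuple[str, str, int]  # (chain, residue_name, residue_seq)
    q10: int
    residue_distances: pd.DataFrame


def residue_distances(
    placed: PlacedStructure, standard_only: bool = True
) -> pd.DataFrame:
    """Per-residue distance to the electrode plane, sorted nearest-first.

    Distance is min over the residue's atoms of (z − radius), i.e. the gap
    between that residue's van der Waals surface and the plane.  Ties are
    broken by (chain, residue_seq) so ranking is deterministic.  With
    ``standard_only`` (default), cofactor/hetero groups are excluded from the
    ranking — the patch is a patch of amino acids.
    """
    rows = []
    for a in placed.structure.atoms:
        rows.append(
            (
                a.chain,
                a.residue_name,
                a.residue_seq,
                a.position[2] - a.radius,
                a.charge,
            )
        )
    df = pd.DataFrame(
        rows, columns=["chain", "residue_name", "residue_seq", "dz", "charge"]
    )
    if standard_only:
        df = df[df["residue_name"].str.upper().isin(STANDARD_RESIDUES)]
        if df.empty:
            raise ValueError(
                "structure has no standard amino-acid residues; "
                "pass standard_only=False to include hetero groups"
            )
    grouped = (
        df.groupby(["chain", "residue_name", "residue_seq"], sort=False)
        .agg(distance=("dz", "min"), charge=("charge", "sum"))
        .reset_index()
    )
    return grouped.sort_values(
        ["distance", "chain", "residue_seq"], kind="mergesort"
    ).reset_index(drop=True)


def nearest_residue(
    placed: PlacedStructure, standard_only: bool = True
) -> tuple[str, str, int]:
    """(chain, residue_name, residue_seq) of the residue closest to the plane."""
    if not any(a.residue_name for a in placed.structure.atoms):
        raise ValueError("structure has no residue labels")
    top = residue_distances(placed, standard_only).iloc[0]
    return (top["chain"], top["residue_name"], int(top["residue_seq"]))


def patch_charge(
    placed: PlacedStructure, n: int = 10, standard_only: bool = True
) -> int:
    """Net charge (rounded to integer e) of the n residues closest to the
    electrode, or of all residues if the structure has fewer than n."""
    if n < 1:
        raise ValueError("patch size must be >= 1")
    ranked = residue_distances(placed, standard_only)
    return int(round(ranked["charge"].head(n).sum()))


def patch_report(
    placed: PlacedStructure, n: int = 10, standard_only: bool = True
) -> PatchReport:
    """Bundle nearest residue, patch charge and the ranked distance table."""
    ranked = residue_distances(placed, standard_only)
    top = ranked.iloc[0]
    return PatchReport(
        nearest_residue=(top["chain"], top["residue_name"], int(top["residue_seq"])),
        q10=int(round(ranked["charge"].head(n).sum())),
        residue_distances=ranked,
    )
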