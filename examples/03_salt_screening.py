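"""Effect of dissolved salt on the adsorption energy.

Compares the orientation-resolved adsorption energies of the same protein in
salt-free water (κ = 0) and physiological saline (I = 0.15 M, κ ≈ 0.125 Å⁻¹).
Mobile ions screen the protein–electrode attraction, so every orientation
binds more weakly in saline — the central trend of the model.
"""

import numpy as np

from electrosorb import (
    Environment,
    FixtureSpec,
    build_grid,
    debye_kappa,
    pose,
    scic_interaction_energy,
    toy_protein,
)

structure = toy_protein(FixtureSpec(seed=7))
grid = build_grid(dtheta=10.0, equator_count=36)
env_free = Environment(ionic_strength=0.0)
env_salt = Environment(ionic_strength=0.15)

print(f"kappa(0.15 M) = {debye_kappa(0.15):.4f} 1/angstrom "
      f"(screening length {1/debye_kappa(0.15):.1f} angstrom)")

e_free, e_salt = [], []
for t, p in zip(grid.theta_deg, grid.phi_deg):
    pl = pose(structure, float(t), float(p))
    e_free.append(scic_interaction_energy(pl, env_free).total)
    e_salt.append(scic_interaction_energy(pl, env_salt).total)
e_free, e_salt = np.array(e_free), np.array(e_salt)

print(f"salt-free:  delta_E in [{e_free.min():.2f}, {e_free.max():.2f}] kJ/mol")
print(f"0.15 M:     delta_E in [{e_salt.min():.2f}, {e_salt.max():.2f}] kJ/mol")
ratio = np.abs(e_salt) / np.abs(e_free)
print(f"screening ratio |dE_salt|/|dE_free|: "
      f"max {ratio.max():.3f} over {grid.M} orientations (all < 1)")
# The attraction survives screening only at short range: in saline the
# interaction is confined to roughly one Debye length (~8 angstrom) of the
# contact patch, which is why adsorption weakens with ionic strength.
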