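# electrosorb

Orientation-ensemble electrostatics of redox enzymes adsorbed on planar
conducting electrodes.

## The problem

Wiring a redox enzyme — a [NiFe] hydrogenase, say — to an electrode only
works if electrons can tunnel between the electrode and the enzyme's entry
site (the distal iron–sulfur cluster). Tunneling rates fall off
exponentially with distance, so the *orientation* the enzyme adopts when it
physisorbs decides whether the electrode is active. Electrostatics dominates
that choice: the protein's charges interact with the conductor (image
attraction) and with any applied bias, screened by the electrolyte's mobile
ions.

`electrosorb` models this as an orientation ensemble. For a rigid
point-charge structure (PQR format) posed at every tilt/azimuth (θ, φ) on a
quasi-uniform spherical grid, resting a fixed gap above the plane `z = 0`,
it computes:

- **Adsorption energy** ΔE(θ, φ), either from the built-in
  screened-Coulomb image-charge (SCIC) model — the exact solution of the
  linearized Poisson–Boltzmann equation in a conductor-bounded half-space,

  ΔE = F φₑ Σᵢ qᵢ e^(−κzᵢ) − (k_e/2ε_s) Σᵢⱼ qᵢqⱼ e^(−κd*ᵢⱼ)/d*ᵢⱼ,

  with κ the inverse Debye length, κ² = 2e²N_A·10³I/(ε₀ε_s k_BT), and d*ᵢⱼ
  the distance to the mirror charge — or ingested from an external
  boundary-element solver as a per-orientation CSV table
  (ΔE = E_total − E_protein − E_electrode).
- **Boltzmann probabilities** Pᵢ = e^(−ΔEᵢ/k_BT)/Σⱼe^(−ΔEⱼ/k_BT).
- **Langmuir adsorption**: per-orientation constants
  Kᵢ = (1/M)e^(−ΔEᵢ/k_BT), overall K = ΣKᵢ, coverage χ = KΠ/(1+KΠ) in the
  protein osmotic pressure Π.
- **Electrode current**: electron-transfer rates k = C·e^(−βr) with r the
  entry-site–plane distance (β = 0.45 Å⁻¹ by default), reference current
  density J₀ = (1/a₀)ΣᵢPᵢkᵢ, and total current J = A·χ·J₀.
- **Patch diagnostics**: the residue closest to the electrode and the net
  charge of the 10 closest residues for each orientation.

A seeded generator of synthetic point-charge proteins and energy tables
(with extended-precision ground truth) supports testing and exploration
without any external structure files.

## Worked example

```python
from electrosorb import Environment, FixtureSpec, ScanConfig, scan, toy_protein

structure = toy_protein(FixtureSpec(seed=7))   # 150 charges, net −5 e
config = ScanConfig(
    structure=structure,
    environment=Environment(ionic_strength=0.15, phi_e=0.0),
)
s = scan(config).summary
print(s.M, s.delta_e_min, s.p_min, s.k_total, s.j0)
```

Running `python examples/02_orientation_scan.py` prints:

```
orientations sampled (M): 412
minimum-energy pose:      theta=110 deg, phi=275 deg
  delta_E_min:            -1.119 kJ/mol
  P_min:                  0.0034
  entry-site distance:    22.60 angstrom
  nearest residue:        CYS 45 (A)  (10-residue patch charge +4 e)
K  (adsorption, AU):      1.1351
J0 (current density, AU): 8.389e-05
```

Read: in 0.15 M saline the best orientation is bound by only ~1 kJ/mol and
holds 0.3% of the population — adsorption is a dynamic equilibrium over many
orientations, and the current J₀ is an ensemble average, not the rate of the
best pose. `examples/03_salt_screening.py` shows the same protein in
salt-free water binding 4–10× more strongly in every orientation, and
`examples/04_isotherm_and_current.py` sweeps the Langmuir isotherm to the
monolayer plateau J = A·J₀. The other examples cover structure descriptors
and the external-table backend.

A thin CLI wraps the same pipeline for shell use:

```bash
electrosorb fixtures --out toy.pqr --seed 7
electrosorb scan --config scan.cfg --out results/
electrosorb isotherm --config scan.cfg --out isotherm.csv
```

where `scan.cfg` is a flat `key: value` file (`structure_path`,
`ionic_strength`, `phi_e`, `dtheta`, `backend`, …).

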