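# Methods

## Physical model

The enzyme is rigid: a fixed set of point charges qᵢ at positions rᵢ with
van der Waals radii, read from a PQR file (protonation state, and hence pH
dependence, is baked into the charges upstream — the package consumes
prepared structures and never assigns protonation). The electrode is the
plane z = 0, a conductor held at potential φₑ relative to zero at infinity;
the electrolyte fills z > 0 and is treated at the Debye–Hückel level, valid
for |eφ| < k_BT, so |φₑ| beyond a few tens of mV is outside the model.

An orientation is the pair (θ, φ): the body-frame direction
u(θ, φ) = (sinθcosφ, sinθsinφ, cosθ) is rotated onto the electrode normal
(R = R_y(−θ)·R_z(−φ) on centroid-centered coordinates), after which the
structure is translated so the lowest point of its van der Waals surface
sits a fixed gap above the plane. The gap defaults to 4.1 Å — two 2.0 Å
ion-exclusion (Stern) layers that must not overlap; the Stern thickness
itself is carried as metadata only and does not enter the energy kernel.
With this convention both angles genuinely change the presentation of the
protein to the plane (the atom z-profile is rᵢ·u(θ, φ)); the absolute body
frame remains a convention, so per-orientation labels are comparable only
within one run, while ensemble observables (K, J₀) are frame-robust — a
property the test suite checks by pre-rotating the input (≤0.7% change at
dθ = 10°).

### Orientation grid

θ runs from 0° to 180° in steps of dθ (default 10°); at each θ there are
n(θ) = max{1, round(n_eq·sinθ)} equally spaced azimuths (n_eq = 36 at the
equator, a single sample at each pole), making per-sample solid angles
roughly constant. `floor` integerization is available as an option (with a
1e-9 guard so exact multiples like 36·sin30° = 18 are not truncated by
floating-point representation). The defaults give M = 412 samples (408 with
floor); M is always reported, never assumed. Each sample carries the solid
angle of its θ strip (polar caps at the poles) split over its azimuths —
these weights sum to 4π exactly and are exported for diagnostics, but
ensemble sums weight orientations evenly, consistent with the
near-constant-solid-angle design of the grid.

### Adsorption energy: the SCIC backend

The built-in energy model is the exact Green's-function solution of the
linearized PB equation in the conductor-bounded half-space ("screened-
Coulomb image charge", SCIC). Each charge interacts with (i) the decaying
potential of the biased plane, φ(z) = φₑe^(−κz), giving
F·φₑ·Σqᵢe^(−κzᵢ), and (ii) the screened Coulomb field of every mirror
charge:

E_image = −(k_e/2ε_s)·ΣᵢΣⱼ qᵢqⱼ e^(−κd*ᵢⱼ)/d*ᵢⱼ,  d*ᵢⱼ = |rᵢ − r*ⱼ|,

including the i = j self-image term (d*ᵢᵢ = 2zᵢ), which dominates the
conductor attraction; the global ½ is the induced-charge (not fixed-charge)
energy factor. The construction satisfies φ = φₑ on the plane identically
(the Yukawa pair cancels there), which the tests assert to 1e-10 relative
at random plane points.

What the closed form gives up relative to a boundary-element solve: there is
no low-dielectric protein cavity (ε_in plays no role in the kernel; charges
sit directly in the ε_s = 80 screened solvent), no solvent-excluded surface,
no Stern layers, and no finite-electrode edge effects. Consequently absolute
energies are a model of the same physics at reduced fidelity — the
screening, image-attraction, bias and distance trends are exact for this
geometry, and full-fidelity energies can be supplied through the table
backend (CSV of per-orientation totals, reduced by subtracting the isolated
protein and electrode energies). When such a table carries its own
entry-site distances (`r_angstrom`), those override geometric distances so
energies and distances come from one source.

The induced surface charge density of the same analytic solution,
σ = −ε₀ε_s∂φ/∂z|₀, is integrated over a finite disc (Gauss–Legendre in
radius, uniform in azimuth) to expose the neutralization property: with
κ = 0 and φₑ = 0 the plane's induced charge converges to minus the protein's
net charge (Gauss's law), verified to 2% on a disc 50× the charge height.
Physical constants (k_e = 1389.35 kJ mol⁻¹ Å e⁻², F = 96.485 kJ mol⁻¹ V⁻¹,
1 e·Å = 4.8032 D, k_BT = 2.479 kJ/mol at 298.15 K) are derived from CODATA
values via `scipy.constants` at import time, not typed in.

### Ensemble, isotherm, current

Boltzmann probabilities use max-subtraction (salt-free wells reach tens of
k_BT, so naive exponentiation can overflow) and are shift-invariant, so
interaction and total energies give identical populations. Adsorption
constants Kᵢ = (1/M)e^(−ΔEᵢ/k_BT) carry the 1/M rotational-entropy penalty;
the unknown vibrational/reference-state prefactor is fixed at one, so K and
the osmotic pressure Π are in matching arbitrary units. Coverage follows
the Langmuir isotherm (no protein–protein interactions, monolayer only);
the identity Σᵢ KᵢΠ/(1+KΠ) = χ(K) ties the per-orientation and overall
descriptions together and is asserted numerically. Electron transfer decays
exponentially with the entry atom's perpendicular distance to the plane,
β = 0.45 Å⁻¹ by default with a steeper 1.4 Å⁻¹ named profile
(`ETParams.steep()`); C, a₀ and A stay at 1 AU and are the natural free
parameters when fitting experiments.

"Room temperature" is 298.15 K throughout.

## Dipole convention

For a charged molecule the dipole depends on the pole. The pole used is the
center of *absolute* charge, Σ|qᵢ|rᵢ/Σ|qᵢ| (centroid fallback when
Σ|q| ≤ 1e-6 e). The signed-charge-weighted mean is not usable here: about
that point the dipole of any net-charged distribution vanishes identically,
which would make the descriptor vacuous. The |q|-weighted pole is
translation/rotation-covariant, reduces to the midpoint for a ± pair, and
to the charge position (zero dipole) for a single charge.

## Synthetic fixtures

`toy_protein` generates N point charges uniformly in a ball — by default
150 atoms in an 18 Å ball with radii 1.2–2.0 Å, a desk-scale stand-in for a
globular ~90 kDa enzyme; net charge −5 e by default, the moderately
negative regime typical of such an enzyme near neutral pH. Charges are
drawn from a Gaussian and affinely shifted so Σq hits the target exactly;
an optional dipole target is met by adding a zero-sum charge pattern along
z (root-found with Brent's method; infeasible geometries raise). Residues
are assigned in consecutive triples cycling through the 20 canonical amino
acids, so patch diagnostics behave as on real chains; the atom nearest the
body center is the electron-transfer entry site, mimicking a buried
cofactor. Everything is reproducible from the seed.

What the generator does *not* emulate: realistic folds and side-chain
charge clustering (so patch charges are statistical, not structural), the
strongly anisotropic dipole of a real hydrogenase, excluded-volume packing,
and solvent-excluded-surface geometry. Tests passing on these fixtures
validate the machinery — energies, sums, equilibria, currents — not the
biology of any particular enzyme; conclusions about a real system require
its prepared PQR (and ideally external BEM energies via the table backend).

`synthetic_energy_table` tabulates an arbitrary landscape over a grid with
seeded Gaussian noise and bundles ground-truth P, K and J₀ computed by
direct long-double (80-bit) summation — an oracle independent of the
pipeline's vectorized path, which the tests require to agree to 1e-10
(observed ~1e-15).

## Numerical choices and degenerate inputs

- PQR parsing is whitespace-based and accepts both the 10-field and
  11-field (chain) dialects per line; malformed lines report their line
  number; empty structures are rejected everywhere.
- Coincident atoms make the Coulomb self-energy singular and raise; charges
  on or below the plane raise a geometry error in the SCIC kernel.
- Residue ranking ties break deterministically by (chain, residue_seq);
  patch charges are rounded to integers (force-field residue charges are
  near-integers by construction).
- Quadrature for the induced charge: Gauss–Legendre radial nodes ×
  uniform azimuth; refinement is monotone and the default (128 rings × 64
  angles) reaches ~1% on the neutralization check.
- Scan problem sizes used in the shipped tests and acceptance script — the
  default 412-orientation grid with 150-atom fixtures for single scans, a
  26-orientation grid with 30-atom fixtures for repeated-scan oracle
  studies — keep every check comfortably within interactive runtimes while
  leaving the trends (screening, saturation, frame robustness) well
  resolved.

## Known limitations

- The SCIC backend's absolute energies underestimate structure in real
  systems (no dielectric cavity or SES); use the table backend for
  solver-grade energies.
- Charge regulation (pKₐ shifts near the charged surface) is excluded: the
  PQR's protonation state is fixed regardless of orientation or distance.
- The Langmuir treatment ignores protein–protein interactions and
  multilayers; currents are relative (AU) until C, a₀, A are fitted.
- Absolute (θ, φ) labels are body-frame conventions; only frame-robust
  ensemble observables should be compared across differently prepared
  inputs.
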