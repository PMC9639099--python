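"""Debye screening, Coulomb self-energy and the SCIC half-space model."""

import numpy as np
import pytest

from electrosorb import (
    Environment,
    coulomb_energy,
    debye_kappa,
    induced_charge,
    ionic_strength,
    net_charge,
    pose,
    scic_interaction_energy,
    scic_potential,
    table_interaction_energy,
)
from electrosorb.constants import COULOMB_KJ_MOL_ANGSTROM, FARADAY_KJ_MOL
from electrosorb.energy import GeometryError
from electrosorb.orientation import PlacedStructure

from conftest import make_structure


def placed_point_charges(positions, charges, radii=None):
    return PlacedStructure(
        make_structure(positions, charges, radii), 0.0, 0.0, 4.1
    )


class TestIonicStrengthAndKappa:
    def test_monovalent_salt(self):
        assert ionic_strength([0.15, 0.15], [1, -1]) == pytest.approx(0.15)

    def test_empty_is_zero(self):
        assert ionic_strength([], []) == 0.0

    def test_divalent_salt(self):
        assert ionic_strength([0.1, 0.1], [2, -2]) == pytest.approx(0.4)

    def test_imbalanced_input_warns_but_computes(self):
        with pytest.warns(UserWarning, match="electroneutral"):
            assert ionic_strength([0.1], [1]) == pytest.approx(0.05)

    def test_physiological_kappa(self):
        assert debye_kappa(0.15, 298.15, 80.0) == pytest.approx(0.125, rel=0.02)

    def test_zero_salt_means_no_screening(self):
        assert debye_kappa(0.0) == 0.0

    def test_sqrt_scaling(self):
        assert debye_kappa(0.6) == pytest.approx(2 * debye_kappa(0.15), rel=1e-12)


class TestCoulombEnergy:
    def test_two_unit_charges_at_one_angstrom(self):
        s = make_structure([[0, 0, 0], [1, 0, 0]], [1.0, 1.0])
        assert coulomb_energy(s, 4.0) == pytest.approx(
            COULOMB_KJ_MOL_ANGSTROM / 4.0, rel=1e-12
        )

    def test_single_atom_zero(self):
        assert coulomb_energy(make_structure([[0, 0, 0]], [1.0])) == 0.0

    def test_even_in_charge_sign(self, toy):
        flipped = toy.with_coordinates(toy.coordinates)
        flipped = make_structure(
            toy.coordinates, -toy.charges, radii=toy.radii
        )
        assert coulomb_energy(flipped) == pytest.approx(
            coulomb_energy(toy), rel=1e-12
        )

    def test_rigid_motion_invariant(self, toy):
        moved = toy.with_coordinates(toy.coordinates + [10.0, 0.0, 3.0])
        assert coulomb_energy(moved) == pytest.approx(
            coulomb_energy(toy), rel=1e-12
        )

    def test_coincident_atoms_rejected(self):
        s = make_structure([[0, 0, 0], [0, 0, 0]], [1.0, 1.0])
        with pytest.raises(ValueError, match="oincident"):
            coulomb_energy(s)


class TestSCICInteraction:
    def test_classical_image_formula_single_charge(self):
        """+1 e at height h above a grounded plane in a dielectric:
        E = −k_e/(2ε·2h)."""
        pl = placed_point_charges([[0, 0, 5.0]], [1.0])
        env = Environment(ionic_strength=0.0, phi_e=0.0)
        br = scic_interaction_energy(pl, env)
        assert br.field_term == 0.0
        assert br.total == pytest.approx(
            -COULOMB_KJ_MOL_ANGSTROM / (80.0 * 2 * 10.0), rel=1e-12
        )
        assert br.total == pytest.approx(-0.868, abs=5e-4)

    def test_image_term_even_in_charge(self):
        env = Environment(ionic_strength=0.0, phi_e=0.0)
        plus = placed_point_charges([[0, 0, 5.0]], [1.0])
        minus = placed_point_charges([[0, 0, 5.0]], [-1.0])
        assert scic_interaction_energy(plus, env).total == pytest.approx(
            scic_interaction_energy(minus, env).total, rel=1e-12
        )

    def test_field_term_is_faraday_times_potential(self):
        pl = placed_point_charges([[0, 0, 5.0]], [1.0])
        env = Environment(ionic_strength=0.0, phi_e=0.05)
        br = scic_interaction_energy(pl, env)
        assert br.field_term == pytest.approx(FARADAY_KJ_MOL * 0.05, rel=1e-12)
        assert br.field_term == pytest.approx(4.824, abs=5e-4)

    def test_total_is_sum_of_terms(self, toy, saline_env):
        br = scic_interaction_energy(pose(toy, 40.0, 80.0), saline_env)
        assert br.total == br.field_term + br.image_term

    def test_image_term_always_attractive(self, toy, small_grid, saline_env):
        for t, p in zip(small_grid.theta_deg, small_grid.phi_deg):
            br = scic_interaction_energy(pose(toy, float(t), float(p)), saline_env)
            assert br.image_term < 0

    def test_image_magnitude_decays_with_gap(self, toy, saline_env):
        pl = pose(toy, 30.0, 60.0, gap=4.1)
        values = []
        for extra in (0.0, 2.0, 5.0, 10.0, 30.0):
            shifted = pl.structure.with_coordinates(
                pl.structure.coordinates + [0, 0, extra]
            )
            far = PlacedStructure(shifted, 30.0, 60.0, 4.1 + extra)
            values.append(abs(scic_interaction_energy(far, saline_env).image_term))
        assert np.all(np.diff(values) < 0)

    def test_salt_screens_the_attraction(self, toy):
        pl = pose(toy, 70.0, 120.0)
        e_freshwater = scic_interaction_energy(
            pl, Environment(ionic_strength=0.0)
        ).image_term
        e_saline = scic_interaction_energy(
            pl, Environment(ionic_strength=0.15)
        ).image_term
        e_brine = scic_interaction_energy(
            pl, Environment(ionic_strength=0.6)
        ).image_term
        assert abs(e_freshwater) > abs(e_saline) > abs(e_brine)

    def test_charge_below_plane_rejected(self, saline_env):
        pl = placed_point_charges([[0, 0, -1.0]], [1.0])
        with pytest.raises(GeometryError):
            scic_interaction_energy(pl, saline_env)


class TestBoundaryCondition:
    @pytest.mark.parametrize("I,phi_e", [(0.0, 0.0), (0.15, 0.05), (0.15, -0.05)])
    def test_potential_on_plane_equals_electrode_potential(self, toy, I, phi_e):
        env = Environment(ionic_strength=I, phi_e=phi_e)
        pl = pose(toy, 55.0, 210.0, env.gap)
        rng = np.random.default_rng(42)
        pts = np.column_stack(
            [rng.uniform(-30, 30, 100), rng.uniform(-30, 30, 100), np.zeros(100)]
        )
        phi = scic_potential(pl, env, pts)
        scale = max(abs(phi_e), 1e-3)
        assert np.max(np.abs(phi - phi_e)) / scale < 1e-10


class TestInducedCharge:
    def test_grounded_plane_neutralizes_protein(self, toy):
        env = Environment(ionic_strength=0.0, phi_e=0.0)
        pl = pose(toy, 20.0, 30.0, env.gap)
        radius = 50.0 * float(pl.structure.coordinates[:, 2].max())
        q_ind = induced_charge(pl, env, disc_radius=radius, n_rings=256)
        assert q_ind == pytest.approx(-net_charge(toy), rel=0.02)

    def test_bias_alone_gives_area_proportional_charge(self):
        env = Environment(ionic_strength=0.15, phi_e=0.05)
        # a single negligible charge far away stands in for "no protein"
        pl = placed_point_charges([[0, 0, 1e4]], [1e-12])
        q1 = induced_charge(pl, env, disc_radius=50.0)
        q2 = induced_charge(pl, env, disc_radius=100.0)
        assert q1 > 0
        assert q2 / q1 == pytest.approx(4.0, rel=1e-6)

    def test_quadrature_converges(self, toy):
        env = Environment(ionic_strength=0.0, phi_e=0.0)
        pl = pose(toy, 20.0, 30.0, env.gap)
        vals = {
            n: induced_charge(pl, env, disc_radius=400.0, n_rings=n)
            for n in (16, 32, 64)
        }
        assert abs(vals[64] - vals[32]) < abs(vals[32] - vals[16]) + 1e-12

    def test_small_disc_warns(self, toy, saline_env):
        pl = pose(toy, 20.0, 30.0)
        with pytest.warns(UserWarning, match="lateral extent"):
            induced_charge(pl, saline_env, disc_radius=1.0, n_rings=8)


class TestTableBookkeeping:
    def test_subtracts_isolated_references(self):
        assert table_interaction_energy(-100.0, -80.0, -12.0) == pytest.approx(-8.0)

    def test_components_are_assembled_first(self):
        assert table_interaction_energy(
            e_protein=-82.0, e_electrode=-10.0, components=(-50.0, -40.0, -10.0)
        ) == pytest.approx(-8.0)

    def test_reference_against_itself_is_zero(self):
        assert table_interaction_energy(-92.0, -92.0, 0.0) == 0.0

    def test_missing_total_is_an_error(self):
        with pytest.raises(ValueError, match="missing total"):
            table_interaction_energy(None, 0.0, 0.0)
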