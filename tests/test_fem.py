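"""FEM solver: assembly identities, montage presets, oracle agreement,
linearity and reciprocity."""

import math

import numpy as np
import pytest

import ctdcsim as c
from ctdcsim.fem import (
    FemSystem,
    Montage,
    TissueModel,
    assemble_system,
    local_stiffness,
    make_montage_preset,
    neumann_load,
    solve_potential,
)
from ctdcsim.oracle import potential_multishell
from ctdcsim.phantom import ElectrodeSpec

R = 92.0


def _bipolar(radius=R, current=1.0, disc_cm=0.5):
    a = ElectrodeSpec("a", (0.0, 0.0, radius), "disc", (disc_cm,))
    b = ElectrodeSpec("b", (0.0, 0.0, -radius), "disc", (disc_cm,))
    return Montage([(a, current), (b, -current)], name="antipodal")


class TestPresets:
    def test_celnik_pads_and_current(self):
        m = make_montage_preset("celnik", scalp_radius=R)
        currents = sorted(cur for _, cur in m.electrodes)
        assert currents == [-2.0, 2.0]
        for e, _ in m.electrodes:
            assert e.area_cm2 == pytest.approx(25.0)

    def test_manto_shares_anode_with_celnik(self):
        celnik = make_montage_preset("celnik", scalp_radius=R)
        manto = make_montage_preset("manto", scalp_radius=R)
        anode_c = next(e for e, cur in celnik.electrodes if cur > 0)
        anode_m = next(e for e, cur in manto.electrodes if cur > 0)
        assert anode_c.center == anode_m.center  # same cerebellar anode
        assert {e.id for e, _ in manto.electrodes} == {"cb_anode", "supraorbital"}
        assert {e.id for e, _ in celnik.electrodes} == {"cb_anode", "buccinator"}

    def test_hd4x1_currents_and_anode_area(self):
        m = make_montage_preset("hd4x1", scalp_radius=R)
        anode = [(e, cur) for e, cur in m.electrodes if cur > 0]
        cathodes = [(e, cur) for e, cur in m.electrodes if cur < 0]
        assert len(anode) == 1 and anode[0][1] == 1.0
        assert anode[0][0].area_cm2 == pytest.approx(3.14, abs=0.005)
        assert [cur for _, cur in cathodes] == [-0.25] * 4

    @pytest.mark.parametrize("name", ["celnik", "manto", "hd4x1"])
    def test_preset_currents_balance_exactly(self, name):
        m = make_montage_preset(name, scalp_radius=R)
        assert sum(cur for _, cur in m.electrodes) == 0.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_montage_preset("tdcs9000", scalp_radius=R)

    def test_unbalanced_montage_rejected(self):
        a = ElectrodeSpec("a", (0, 0, R), "disc", (0.5,))
        b = ElectrodeSpec("b", (0, 0, -R), "disc", (0.5,))
        with pytest.raises(ValueError, match="sum to 0"):
            Montage([(a, 1.0), (b, -0.5)])


class TestAssembly:
    def test_local_stiffness_matches_hand_assembly(self):
        """Reference tetra (unit right-corner): shape-function gradients are
        grad(l0) = (-1,-1,-1), grad(li) = e_i (in 1/mm); with sigma = 1 and
        volume 1/6 mm^3 the local matrix follows directly."""
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        k = local_stiffness(pts, sigma=1.0)
        grads_mm = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        # volume in m^3 = 1/6 * 1e-9; gradients in 1/m = 1e3 * per-mm values
        expected = (1e-9 / 6.0) * (grads_mm * 1e3) @ (grads_mm * 1e3).T
        assert np.allclose(k, expected, rtol=1e-12)

    def test_conductivity_scaling_scales_operator(self, sphere_mesh):
        k1 = assemble_system(sphere_mesh, TissueModel({1: 1.0}))
        k3 = assemble_system(sphere_mesh, TissueModel({1: 3.0}))
        diff = (k3 - 3.0 * k1)
        assert abs(diff).max() < 1e-12 * abs(k1).max()

    def test_constant_vector_in_nullspace(self, sphere_system):
        ones = np.ones(sphere_system.K.shape[0])
        out = sphere_system.K @ ones
        assert np.abs(out).max() < 1e-10 * sphere_system.K.diagonal().max()

    def test_operator_symmetric(self, sphere_system):
        K = sphere_system.K
        asym = abs(K - K.T).max()
        assert asym < 1e-12 * abs(K).max()

    def test_missing_label_rejected_by_name(self, sphere_mesh):
        with pytest.raises(ValueError, match=r"\[1\]"):
            TissueModel({2: 1.0}).for_mesh(sphere_mesh)


class TestSolve:
    def test_zero_current_montage_gives_zero_fields(self, sphere_system):
        m = Montage(
            [(ElectrodeSpec("a", (0, 0, R), "disc", (0.5,)), 0.0),
             (ElectrodeSpec("b", (0, 0, -R), "disc", (0.5,)), 0.0)]
        )
        sol = sphere_system.solve(m)
        assert np.all(sol.node_potentials == 0.0)
        assert np.all(sol.element_field == 0.0)

    def test_neumann_load_sums_to_zero(self, sphere_mesh):
        f = neumann_load(sphere_mesh, _bipolar())
        assert abs(f.sum()) < 1e-15

    def test_swapping_electrodes_negates_potential(self, sphere_system):
        m = _bipolar()
        sol = sphere_system.solve(m)
        swapped = sphere_system.solve(m.swapped())
        scale = np.abs(sol.node_potentials).max()
        assert np.allclose(
            swapped.node_potentials, -sol.node_potentials, rtol=0, atol=1e-10 * scale
        )

    def test_doubling_currents_doubles_fields(self, sphere_system):
        sol1 = sphere_system.solve(_bipolar(current=1.0))
        sol2 = sphere_system.solve(_bipolar(current=2.0))
        scale = np.abs(sol1.element_field).max()
        assert np.allclose(
            sol2.element_field, 2.0 * sol1.element_field, rtol=0, atol=1e-10 * scale
        )

    def test_linear_potential_has_exact_uniform_gradient(self, sphere_system):
        """Phi = x (in mm) imposed at the nodes gives E = -grad(Phi) =
        (-1000, 0, 0) V/m in every element, exactly."""
        phi = sphere_system.mesh.nodes[:, 0] * 1e-3  # volts, linear in x
        E = sphere_system.element_field(phi)
        # d(phi)/dx = 1e-3 V/mm = 1 V/m, so Ex = -1 V/m in every element
        assert np.allclose(E[:, 0], -1.0, atol=1e-9)
        assert np.abs(E[:, 1:]).max() < 1e-9

    def test_enorm_definition(self):
        E = np.array([[1.0, 1.0, 1.0]])
        assert np.linalg.norm(E, axis=1)[0] == pytest.approx(math.sqrt(3.0))

    def test_gauge_zero_mean_over_scalp_nodes(self, sphere_system):
        sol = sphere_system.solve(_bipolar())
        scalp_mean = sol.node_potentials[sphere_system.scalp_nodes].mean()
        assert abs(scalp_mean) < 1e-12 * np.abs(sol.node_potentials).max()

    def test_cg_matches_direct(self, sphere_system):
        m = _bipolar()
        direct = sphere_system.solve(m, method="direct")
        cg = sphere_system.solve(m, method="cg", tol=1e-10)
        scale = np.abs(direct.node_potentials).max()
        assert np.allclose(
            cg.node_potentials, direct.node_potentials, rtol=0, atol=1e-6 * scale
        )
        assert cg.diagnostics["iterations"] > 0

    def test_reciprocity_of_potential_differences(self, sphere_system):
        """Drive pair A and measure the (patch-averaged) potential difference
        across pair B; equals driving B and measuring across A.  The
        measurement functional is the same area-weighted patch distribution
        used for injection, f_B . phi_A = f_A . phi_B by operator symmetry."""
        mesh = sphere_system.mesh

        def montage_at(u1, u2):
            e1 = ElectrodeSpec("p", tuple(R * np.asarray(u1, dtype=float)), "disc", (0.5,))
            e2 = ElectrodeSpec("q", tuple(R * np.asarray(u2, dtype=float)), "disc", (0.5,))
            return Montage([(e1, 1.0), (e2, -1.0)])

        mon_a = montage_at((0, 0, 1), (0, 0, -1))
        mon_b = montage_at((1, 0, 0), (0, 1, 0))
        sol_a = sphere_system.solve(mon_a)
        sol_b = sphere_system.solve(mon_b)
        f_a = neumann_load(mesh, mon_a)
        f_b = neumann_load(mesh, mon_b)
        v_b_under_a = float(f_b @ sol_a.node_potentials)
        v_a_under_b = float(f_a @ sol_b.node_potentials)
        assert v_b_under_a == pytest.approx(v_a_under_b, rel=1e-8)

    def test_unbalanced_currents_rejected_at_solve(self, sphere_mesh, homog_shells):
        # bypass Montage validation to hit the solver-level check
        m = _bipolar()
        m.electrodes[1] = (m.electrodes[1][0], -0.5)
        with pytest.raises(ValueError):
            solve_potential(sphere_mesh, TissueModel.from_shells(homog_shells), Montage(m.electrodes))


class TestOracleAgreement:
    def _relative_error(self, resolution, homog_shells):
        mesh = c.build_shell_phantom(homog_shells, resolution=resolution, seed=1)
        system = FemSystem(mesh, TissueModel.from_shells(homog_shells))
        sol = system.solve(_bipolar())
        rn = np.linalg.norm(mesh.nodes, axis=1)
        pts = mesh.nodes[rn <= R - 20.0]  # >= one electrode diameter inside
        phi_o = potential_multishell(
            homog_shells, ((0, 0, R), 1.0), ((0, 0, -R), -1.0), pts, n_terms=300
        )
        phi_f = sol.node_potentials[rn <= R - 20.0]
        phi_f = phi_f - phi_f.mean() + phi_o.mean()  # align gauges
        return np.linalg.norm(phi_f - phi_o) / np.linalg.norm(phi_o)

    def test_interior_potentials_match_series_oracle(self, homog_shells):
        """Antipodal 1 cm discs at +-1 mA on the homogeneous sphere: interior
        relative L2 error < 5% at the default resolution and decreasing
        monotonically across three refinement levels."""
        errors = [self._relative_error(res, homog_shells) for res in (12.0, 9.0, 6.0)]
        assert errors[1] < 0.05  # within the gate near the default resolution
        assert errors[0] > errors[1] > errors[2]
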