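"""Constitutive law, element stiffness and solver unit checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import block_labels
from orbitmech.elasticity import (
    ElasticSystem,
    LoadCase,
    MaterialModel,
    assemble_and_solve,
    assemble_stiffness,
    element_stiffness,
    elastic_matrix,
    hooke_stress,
)
from orbitmech.errors import (
    DegenerateElementError,
    SolverError,
    ValidationError,
)
from orbitmech.meshing import voxels_to_tetmesh
from orbitmech.volumes import Tissue

UNIT_TET = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


class TestHookeLaw:
    def test_zero_strain_gives_zero_stress(self):
        np.testing.assert_array_equal(
            hooke_stress(np.zeros((3, 3)), MaterialModel()), np.zeros((3, 3))
        )

    def test_poisson_zero_reduces_to_scalar_law(self):
        eps = np.diag([0.01, 0.0, 0.0])
        sigma = hooke_stress(eps, MaterialModel(E=1.0, nu=0.0))
        np.testing.assert_allclose(sigma, eps)

    def test_calibrated_poisson_example(self):
        """Independent scalar evaluation at the calibrated nu = 0.1:
        sigma_11 = (1/1.1)(0.01 + 0.125*0.01), sigma_22 = sigma_33 =
        (1/1.1)(0.125*0.01)."""
        eps = np.diag([0.01, 0.0, 0.0])
        sigma = hooke_stress(eps, MaterialModel(E=1.0, nu=0.1))
        assert sigma[0, 0] == pytest.approx((0.01 + 0.125 * 0.01) / 1.1)
        assert sigma[1, 1] == pytest.approx(0.125 * 0.01 / 1.1)
        assert sigma[2, 2] == pytest.approx(sigma[1, 1])
        assert abs(sigma - np.diag(np.diag(sigma))).max() == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_stress_linear_in_strain(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        eps = 0.01 * (a + a.T)
        mat = MaterialModel(E=2.0, nu=0.25)
        np.testing.assert_allclose(
            hooke_stress(scale * eps, mat), scale * hooke_stress(eps, mat), rtol=1e-12
        )

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValidationError):
            MaterialModel(nu=0.5)


class TestElementStiffness:
    def test_symmetric_with_rigid_translation_nullspace(self):
        k = element_stiffness(UNIT_TET, MaterialModel(E=1.0, nu=0.2))
        np.testing.assert_allclose(k, k.T, atol=1e-14)
        for comp in range(3):
            u = np.zeros(12)
            u[comp::3] = 1.0  # rigid translation
            np.testing.assert_allclose(k @ u, 0.0, atol=1e-12)

    def test_matches_numerical_quadrature_oracle(self):
        """Independent oracle: integrate B^T D B over the tet with
        finite-difference shape-function gradients and 4-point Gauss
        quadrature of the virtual-work integral."""
        coords = UNIT_TET + np.random.default_rng(5).normal(scale=0.1, size=(4, 3))
        mat = MaterialModel(E=1.0, nu=0.0)

        def shape(x):
            m = np.vstack([np.ones(4), coords.T])
            return np.linalg.solve(m, np.array([1.0, *x]))

        def grad_shape(x, h=1e-5):
            g = np.zeros((4, 3))
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                g[:, j] = (shape(x + e) - shape(x - e)) / (2 * h)
            return g

        def b_matrix(g):
            b = np.zeros((6, 12))
            for i in range(4):
                gx, gy, gz = g[i]
                c = 3 * i
                b[0, c] = gx
                b[1, c + 1] = gy
                b[2, c + 2] = gz
                b[3, c], b[3, c + 1] = gy, gx
                b[4, c + 1], b[4, c + 2] = gz, gy
                b[5, c], b[5, c + 2] = gz, gx
            return b

        # 4-point Gauss rule on the tetrahedron (degree 2, ample here)
        a, bq = 0.58541020, 0.13819660
        bary = np.full((4, 4), bq)
        np.fill_diagonal(bary, a)
        vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
        d = elastic_matrix(1.0, 0.0)
        k_oracle = np.zeros((12, 12))
        for w in bary:
            x = w @ coords
            b = b_matrix(grad_shape(x))
            k_oracle += 0.25 * vol * b.T @ d @ b
        k = element_stiffness(coords, mat)
        np.testing.assert_allclose(k, k_oracle, atol=1e-8)

    def test_degenerate_tet_raises(self):
        flat = UNIT_TET.copy()
        flat[3] = flat[0]
        with pytest.raises(DegenerateElementError):
            element_stiffness(flat, MaterialModel())


@pytest.fixture(scope="module")
def block():
    mesh = voxels_to_tetmesh(block_labels(3, 3, 3))
    tags = mesh.boundary_tags.copy()
    top = mesh.boundary_normals[:, 2] > 0.5
    bottom = mesh.boundary_normals[:, 2] < -0.5
    tags[:] = "opening"
    tags[top] = "l1"
    tags[bottom] = "intact_bone"
    mesh.boundary_tags = tags
    return mesh


class TestSolver:
    def test_zero_traction_gives_zero_displacement(self, block):
        u = assemble_and_solve(
            block, MaterialModel(), LoadCase(tractions={"l1": 0.0}), {"l1"}
        )
        np.testing.assert_allclose(u.u, 0.0, atol=1e-14)

    def test_displacement_linear_in_load_and_inverse_in_modulus(self, block):
        u1 = assemble_and_solve(
            block, MaterialModel(E=1.0), LoadCase(tractions={"l1": 0.01}), {"l1"}
        )
        u2 = assemble_and_solve(
            block, MaterialModel(E=1.0), LoadCase(tractions={"l1": 0.02}), {"l1"}
        )
        u3 = assemble_and_solve(
            block, MaterialModel(E=2.0), LoadCase(tractions={"l1": 0.01}), {"l1"}
        )
        np.testing.assert_allclose(u2.u, 2 * u1.u, atol=1e-12)
        np.testing.assert_allclose(u3.u, u1.u / 2, atol=1e-12)

    def test_unconstrained_system_raises(self, block):
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2))
        mesh.boundary_tags = np.full_like(mesh.boundary_tags, "opening")
        with pytest.raises(SolverError, match="Dirichlet"):
            ElasticSystem(mesh, MaterialModel(), set())

    def test_global_stiffness_symmetric_positive_semidefinite(self):
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2))
        k = assemble_stiffness(mesh, MaterialModel(E=1.0, nu=0.3)).toarray()
        np.testing.assert_allclose(k, k.T, atol=1e-12)
        w = np.linalg.eigvalsh(k)
        assert w.min() > -1e-10

    def test_element_fields_recover_uniform_strain(self):
        """An affine displacement field yields the same constant strain in
        every element, and stresses equal the constitutive law applied
        to it (scaled per tissue)."""
        from orbitmech.elasticity import (
            DisplacementField,
            element_strains,
            element_stresses,
        )

        mesh = voxels_to_tetmesh(block_labels(2, 2, 2, tissue=Tissue.MUSCLE))
        a = np.array([[0.01, 0.002, 0.0], [0.002, -0.004, 0.0], [0.0, 0.0, 0.006]])
        field = DisplacementField(mesh.nodes @ a.T)
        eps = element_strains(mesh, field)
        np.testing.assert_allclose(eps, np.broadcast_to(a, eps.shape), atol=1e-12)
        mat = MaterialModel(E=1.0, nu=0.2, multipliers={int(Tissue.MUSCLE): 5.0})
        sig = element_stresses(mesh, field, mat)
        expected = 5.0 * hooke_stress(a, MaterialModel(E=1.0, nu=0.2))
        np.testing.assert_allclose(sig, np.broadcast_to(expected, sig.shape), atol=1e-12)

    def test_per_tissue_multiplier_scales_stiffness(self):
        mesh = voxels_to_tetmesh(block_labels(2, 2, 2, tissue=Tissue.MUSCLE))
        base = MaterialModel(multipliers={int(Tissue.MUSCLE): 1.0})
        stiff = MaterialModel(multipliers={int(Tissue.MUSCLE): 5.0})
        k1 = assemble_stiffness(mesh, base)
        k5 = assemble_stiffness(mesh, stiff)
        np.testing.assert_allclose(k5.toarray(), 5 * k1.toarray(), rtol=1e-12)
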