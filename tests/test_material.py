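"""Constitutive-model tests: elasticity, strain criteria, damage law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonefem.material import (
    DamageLaw,
    ElasticConstants,
    PointState,
    StrainCriterion,
    consistent_tangent,
    criterion_strain,
    damage_from_kappa,
    equivalent_strain,
    material_update,
    min_principal_strain,
    stiffness_matrix,
    strain_to_voigt,
    voigt_to_stress,
)
from conftest import random_rotation, random_symmetric


class TestStiffnessMatrix:
    def test_uniaxial_slopes_match_measured_moduli(self, constants):
        """Compliance along/across the osteon axis reproduces E_L and E_T."""
        S = np.linalg.inv(stiffness_matrix(constants))
        assert 1.0 / S[2, 2] == pytest.approx(13498.0, rel=1e-9)
        assert 1.0 / S[0, 0] == pytest.approx(11025.0, rel=1e-9)
        assert 1.0 / S[1, 1] == pytest.approx(11025.0, rel=1e-9)

    def test_lateral_over_axial_strain_ratio_is_poisson(self, constants):
        S = np.linalg.inv(stiffness_matrix(constants))
        # uniaxial stress along z: eps_x / eps_z = S13 / S33 = -nu_LT
        assert -S[0, 2] / S[2, 2] == pytest.approx(0.3, rel=1e-9)

    def test_isotropic_limit_matches_closed_form(self):
        E, nu = 10000.0, 0.25
        c = ElasticConstants(E_L=E, E_T=E, nu_LT=nu, nu_TT=nu, G_LT=E / (2 * (1 + nu)))
        C = stiffness_matrix(c)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        expected = np.diag([2 * mu] * 3 + [mu] * 3).astype(float)
        expected[:3, :3] += lam
        np.testing.assert_allclose(C, expected, rtol=1e-10, atol=1e-6)

    def test_symmetric_positive_definite(self, constants):
        C = stiffness_matrix(constants)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_material_axis_permutation(self, constants):
        """Longitudinal axis along x: axial slope appears in the 11 slot."""
        S = np.linalg.inv(stiffness_matrix(constants, axis=0))
        assert 1.0 / S[0, 0] == pytest.approx(13498.0, rel=1e-9)
        assert 1.0 / S[2, 2] == pytest.approx(11025.0, rel=1e-9)

    def test_inadmissible_constants_rejected(self):
        with pytest.raises(ValueError, match="admissible|positive|range"):
            ElasticConstants(E_L=100.0, E_T=10000.0, nu_LT=0.49)

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            ElasticConstants(E_L=-1.0)


class TestStrainScalars:
    def test_min_principal_diagonal(self):
        eps = np.diag([-0.05, 0.015, 0.015])
        assert min_principal_strain(eps) == pytest.approx(-0.05)

    def test_min_principal_pure_shear(self):
        eps = np.zeros((3, 3))
        eps[0, 1] = eps[1, 0] = 0.01
        assert min_principal_strain(eps) == pytest.approx(-0.01)

    def test_min_principal_matches_characteristic_polynomial(self):
        """Independent oracle: roots of det(eps - lam I) = 0."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            eps = random_symmetric(rng)
            # characteristic polynomial via invariants
            i1 = np.trace(eps)
            i2 = 0.5 * (i1**2 - np.trace(eps @ eps))
            i3 = np.linalg.det(eps)
            roots = np.roots([1.0, -i1, i2, -i3])
            assert min_principal_strain(eps) == pytest.approx(
                float(np.min(roots.real)), abs=1e-10
            )

    def test_equivalent_uniaxial_strain(self):
        eps = np.diag([-0.03, 0.0, 0.0])
        assert equivalent_strain(eps) == pytest.approx(0.02, rel=1e-12)

    def test_equivalent_volumetric_is_zero(self):
        assert equivalent_strain(0.01 * np.eye(3)) == pytest.approx(0.0, abs=1e-15)

    def test_equivalent_pure_shear(self):
        gamma = 0.02
        eps = np.zeros((3, 3))
        eps[0, 1] = eps[1, 0] = gamma / 2.0
        assert equivalent_strain(eps) == pytest.approx(gamma / np.sqrt(3.0), rel=1e-12)

    def test_criterion_compressive_magnitude(self):
        eps = np.diag([-0.05, 0.015, 0.015])
        assert criterion_strain(eps, StrainCriterion.MIN_PRINCIPAL) == pytest.approx(0.05)

    def test_criterion_tensile_state_drives_nothing(self):
        eps = np.diag([0.05, 0.0, 0.0])
        assert criterion_strain(eps, StrainCriterion.MIN_PRINCIPAL) == 0.0

    def test_criterion_equivalent_matches_deviatoric_norm(self):
        eps = np.diag([-0.05, 0.015, 0.015])
        dev = eps - np.trace(eps) / 3.0 * np.eye(3)
        expected = np.sqrt(2.0 / 3.0 * (dev * dev).sum())
        assert criterion_strain(eps, "equivalent") == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        """Both criterion strains are objective under rotations."""
        rng = np.random.default_rng(seed)
        eps = random_symmetric(rng)
        R = random_rotation(rng)
        rotated = R @ eps @ R.T
        for crit in StrainCriterion:
            assert criterion_strain(rotated, crit) == pytest.approx(
                criterion_strain(eps, crit), abs=1e-12
            )


class TestDamageLaw:
    def test_zero_at_threshold(self, law):
        assert damage_from_kappa(0.043, law) == 0.0

    def test_value_at_twice_threshold(self, law):
        assert damage_from_kappa(2 * 0.043, law) == pytest.approx(
            1.0 - np.exp(-1.0), rel=1e-12
        )

    def test_cap_crossing_point(self, law):
        kappa_cap = 0.043 * (1.0 + np.log(10.0))
        assert kappa_cap == pytest.approx(law.kappa_at_cap, rel=1e-12)
        assert damage_from_kappa(kappa_cap, law) == pytest.approx(0.9, rel=1e-12)
        assert damage_from_kappa(10 * kappa_cap, law) == 0.9

    def test_continuity_at_threshold(self, law):
        eps = 1e-12
        below = damage_from_kappa(0.043 - eps, law)
        above = damage_from_kappa(0.043 + eps, law)
        assert below == 0.0
        assert above == pytest.approx(0.0, abs=1e-9)

    def test_monotone_nondecreasing(self, law):
        kappas = np.linspace(0.0, 0.3, 500)
        D = damage_from_kappa(kappas, law)
        assert (np.diff(D) >= 0.0).all()
        assert (D >= 0.0).all() and (D <= 0.9).all()

    def test_residual_fraction_consistency_enforced(self):
        with pytest.raises(ValueError, match="residual_fraction"):
            DamageLaw(residual_fraction=0.2)
        assert DamageLaw(residual_fraction=0.1).residual_fraction == pytest.approx(0.1)


class TestMaterialUpdate:
    def test_undamaged_elasticity(self, constants, law):
        eps = np.diag([0.001, -0.002, 0.0005])
        stress, state, secant = material_update(
            eps, PointState(), constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        C = stiffness_matrix(constants)
        np.testing.assert_allclose(
            stress, voigt_to_stress(C @ strain_to_voigt(eps)), rtol=1e-12
        )
        assert state.D == 0.0 and not state.failed

    def test_irreversibility_on_unloading(self, constants, law):
        """Damage from a deep excursion persists at small strain."""
        big = np.diag([0.0, 0.0, -2 * 0.043])
        small = np.diag([0.0, 0.0, -0.01])
        _, s1, _ = material_update(
            big, PointState(), constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        stress, s2, secant = material_update(
            small, s1, constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        D_expected = 1.0 - np.exp(-1.0)
        assert s1.D == pytest.approx(D_expected, rel=1e-12)
        assert s2.D == pytest.approx(D_expected, rel=1e-12)
        C = stiffness_matrix(constants)
        np.testing.assert_allclose(
            stress,
            (1 - D_expected) * voigt_to_stress(C @ strain_to_voigt(small)),
            rtol=1e-10,
        )

    def test_secant_consistency(self, constants, law):
        rng = np.random.default_rng(3)
        state = PointState()
        for _ in range(20):
            eps = random_symmetric(rng, scale=0.03)
            stress, state, secant = material_update(
                eps, state, constants, law, StrainCriterion.EQUIVALENT
            )
            np.testing.assert_allclose(
                strain_to_voigt(stress)[:3],
                (secant @ strain_to_voigt(eps))[:3],
                rtol=1e-9,
                atol=1e-12,
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_damage_bounded_and_monotone_along_paths(self, seed):
        """D stays in [0, 0.9] and never decreases over random strain paths."""
        constants, law = ElasticConstants(), DamageLaw()
        rng = np.random.default_rng(seed)
        state = PointState()
        crit = StrainCriterion.MIN_PRINCIPAL if seed % 2 else StrainCriterion.EQUIVALENT
        prev_D = 0.0
        for _ in range(15):
            eps = random_symmetric(rng, scale=0.04)
            _, state, _ = material_update(eps, state, constants, law, crit)
            assert 0.0 <= state.D <= 0.9
            assert state.D >= prev_D
            prev_D = state.D
        assert state.failed == (state.D >= 0.9 - 1e-12)

    def test_stress_continuous_across_damage_initiation(self, constants, law):
        """No stress jump as the criterion strain crosses the threshold."""
        h = 1e-8
        below = np.diag([0.0, 0.0, -(0.043 - h)])
        above = np.diag([0.0, 0.0, -(0.043 + h)])
        s_b, _, _ = material_update(
            below, PointState(), constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        s_a, _, _ = material_update(
            above, PointState(), constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        assert abs(s_a[2, 2] - s_b[2, 2]) < 1e-3  # MPa


class TestConsistentTangent:
    @pytest.mark.parametrize("crit", list(StrainCriterion))
    def test_matches_finite_difference_of_stress(self, constants, law, crit):
        """The softening tangent agrees with numerical differentiation."""
        base = np.diag([0.005, 0.005, -0.06])  # actively damaging state
        state0 = PointState()
        T = consistent_tangent(base, state0, constants, law, crit)
        h = 1e-8
        fd = np.zeros((6, 6))
        pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        for col, (i, j) in enumerate(pairs):
            d = np.zeros((3, 3))
            if i == j:
                d[i, j] = h  # gamma increment h -> tensor h/2 off-diagonal
            else:
                d[i, j] = d[j, i] = h / 2.0
            sp, _, _ = material_update(base + d, state0, constants, law, crit)
            sm, _, _ = material_update(base - d, state0, constants, law, crit)
            fd[:, col] = (strain_to_voigt(sp) - strain_to_voigt(sm)) / (2 * h)
            fd[3:, col] /= 2.0  # stress Voigt carries single shear components
        np.testing.assert_allclose(T, fd, rtol=5e-4, atol=1e-2)

    def test_reduces_to_secant_on_elastic_branch(self, constants, law):
        eps = np.diag([0.0, 0.0, -0.01])
        T = consistent_tangent(
            eps, PointState(), constants, law, StrainCriterion.MIN_PRINCIPAL
        )
        np.testing.assert_allclose(T, stiffness_matrix(constants), rtol=1e-12)
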