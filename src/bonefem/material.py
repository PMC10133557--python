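"""Point-level constitutive model for cortical bone damage.

Cortical bone is treated as a transversely isotropic elastic continuum whose
stiff axis follows the osteons (the longitudinal / loading axis).  Damage is
the scalar continuum-damage-mechanics kind: a single variable ``D`` degrades
the whole stiffness tensor,

    sigma = (1 - D) * C : eps

and grows with an exponential softening law once a scalar *criterion strain*
exceeds the critical compressive failure strain ``eps_f``:

    D = 0                        kappa <= eps_f
    D = 1 - exp(1 - kappa/eps_f) kappa >  eps_f    (capped at D_max)

``kappa`` is the largest criterion strain the point has ever experienced,
which makes damage irreversible.  Two criterion strains are supported: the
magnitude of the minimum (most compressive) principal strain, and the von
Mises equivalent strain of the total strain tensor.

Units: MPa for moduli and stress, dimensionless strain.  Strain tensors use
tensorial shear components; Voigt vectors (order 11, 22, 33, 12, 13, 23) use
engineering shear and appear only at the stiffness-matrix boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticConstants",
    "DamageLaw",
    "PointState",
    "StrainCriterion",
    "stiffness_matrix",
    "compliance_matrix",
    "min_principal_strain",
    "equivalent_strain",
    "criterion_strain",
    "damage_from_kappa",
    "material_update",
    "consistent_tangent",
    "strain_to_voigt",
    "voigt_to_stress",
]

#: Voigt component order used throughout: 11, 22, 33, 12, 13, 23.
_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


class StrainCriterion(str, enum.Enum):
    """Which scalar strain drives damage."""

    MIN_PRINCIPAL = "min_principal"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class ElasticConstants:
    """Transversely isotropic engineering constants.

    Defaults are nanoindentation-derived rat femoral cortical bone values:
    longitudinal modulus 13,498 MPa, transverse modulus 11,025 MPa,
    Poisson ratio 0.3.  The remaining constants are not measured for this
    material; ``nu_TT`` defaults to ``nu_LT`` and ``G_LT`` to the isotropic
    relation ``E_L / (2 (1 + nu_LT))``.

    Parameters
    ----------
    E_L : float
        Young's modulus along the osteon (longitudinal) axis, MPa.
    E_T : float
        Young's modulus in the transverse plane, MPa.
    nu_LT : float
        Poisson ratio coupling longitudinal loading to transverse strain.
    nu_TT : float
        In-plane transverse Poisson ratio.
    G_LT : float
        Longitudinal-transverse shear modulus, MPa.
    """

    E_L: float = 13498.0
    E_T: float = 11025.0
    nu_LT: float = 0.3
    nu_TT: float | None = None
    G_LT: float | None = None

    def __post_init__(self) -> None:
        if self.nu_TT is None:
            object.__setattr__(self, "nu_TT", self.nu_LT)
        if self.G_LT is None:
            object.__setattr__(self, "G_LT", self.E_L / (2.0 * (1.0 + self.nu_LT)))
        if self.E_L <= 0 or self.E_T <= 0 or self.G_LT <= 0:
            raise ValueError("all moduli must be positive")
        for name in ("nu_LT", "nu_TT"):
            nu = getattr(self, name)
            if not -1.0 < nu < 0.5:
                raise ValueError(f"{name}={nu} outside the admissible range (-1, 0.5)")
        # thermodynamic admissibility: full check via the assembled matrix
        stiffness_matrix(self)

    @property
    def G_TT(self) -> float:
        """In-plane shear modulus, fixed by transverse isotropy."""
        return self.E_T / (2.0 * (1.0 + self.nu_TT))


@dataclass(frozen=True)
class DamageLaw:
    """Exponential softening law with a damage cap.

    ``residual_fraction`` (the modulus fraction at which an element counts
    as failed) is tied to the cap by ``residual_fraction = 1 - D_max``; a
    value passed explicitly must satisfy that identity.
    """

    epsilon_f: float = 0.043
    D_max: float = 0.9
    residual_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon_f < 1.0:
            raise ValueError(f"epsilon_f={self.epsilon_f} must lie in (0, 1)")
        if not 0.0 < self.D_max < 1.0:
            raise ValueError(f"D_max={self.D_max} must lie in (0, 1)")
        expected = 1.0 - self.D_max
        if self.residual_fraction is None:
            object.__setattr__(self, "residual_fraction", expected)
        elif not math.isclose(self.residual_fraction, expected, rel_tol=1e-9):
            raise ValueError(
                f"residual_fraction={self.residual_fraction} inconsistent with "
                f"1 - D_max = {expected}"
            )

    @property
    def kappa_at_cap(self) -> float:
        """Criterion strain at which D reaches D_max: eps_f * (1 - ln(1 - D_max))."""
        return self.epsilon_f * (1.0 - math.log(1.0 - self.D_max))


@dataclass(frozen=True)
class PointState:
    """State carried by one material point (one element centroid)."""

    strain: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    D: float = 0.0
    kappa: float = 0.0
    failed: bool = False


def _voigt_index(i: int, j: int) -> int:
    lo, hi = min(i, j), max(i, j)
    return _VOIGT_PAIRS.index((lo, hi))


def compliance_matrix(constants: ElasticConstants, axis: int = 2) -> np.ndarray:
    """6x6 compliance matrix with the longitudinal material axis along `axis`."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    t1, t2 = [a for a in range(3) if a != axis]
    c = constants
    S = np.zeros((6, 6))
    S[_voigt_index(axis, axis), _voigt_index(axis, axis)] = 1.0 / c.E_L
    for t in (t1, t2):
        S[_voigt_index(t, t), _voigt_index(t, t)] = 1.0 / c.E_T
        iv, jv = _voigt_index(t, t), _voigt_index(axis, axis)
        S[iv, jv] = S[jv, iv] = -c.nu_LT / c.E_L
        k = _voigt_index(axis, t)
        S[k, k] = 1.0 / c.G_LT
    iv, jv = _voigt_index(t1, t1), _voigt_index(t2, t2)
    S[iv, jv] = S[jv, iv] = -c.nu_TT / c.E_T
    k = _voigt_index(t1, t2)
    S[k, k] = 1.0 / c.G_TT
    return S


def stiffness_matrix(constants: ElasticConstants, axis: int = 2) -> np.ndarray:
    """Assemble the 6x6 stiffness matrix C (Voigt order 11,22,33,12,13,23; MPa).

    Raises ``ValueError`` if the constants are thermodynamically inadmissible
    (the matrix is not positive definite), naming the offending eigenvalue.
    """
    S = compliance_matrix(constants, axis=axis)
    eig = np.linalg.eigvalsh(S)
    if eig[0] <= 0:
        raise ValueError(
            "inadmissible elastic constants: compliance matrix has a "
            f"non-positive eigenvalue {eig[0]:.4g} (stiffness not positive "
            "definite); check the Poisson ratios against the modulus ratio"
        )
    C = np.linalg.inv(S)
    return 0.5 * (C + C.T)


def strain_to_voigt(strain: np.ndarray) -> np.ndarray:
    """Symmetric strain tensor -> Voigt vector with engineering shear."""
    e = np.asarray(strain, dtype=float)
    return np.array(
        [e[0, 0], e[1, 1], e[2, 2], 2.0 * e[0, 1], 2.0 * e[0, 2], 2.0 * e[1, 2]]
    )


def voigt_to_stress(v: np.ndarray) -> np.ndarray:
    """Voigt stress vector -> symmetric 3x3 stress tensor."""
    return np.array(
        [
            [v[0], v[3], v[4]],
            [v[3], v[1], v[5]],
            [v[4], v[5], v[2]],
        ]
    )


def min_principal_strain(strain: np.ndarray) -> float:
    """Most-negative principal strain (smallest eigenvalue), signed."""
    return float(np.linalg.eigvalsh(np.asarray(strain, dtype=float))[0])


def equivalent_strain(strain: np.ndarray) -> float:
    """Von Mises equivalent strain sqrt(2/3 * e:e) of the deviator e."""
    e = np.asarray(strain, dtype=float)
    dev = e - np.trace(e) / 3.0 * np.eye(3)
    return float(np.sqrt(2.0 / 3.0 * np.tensordot(dev, dev)))


def criterion_strain(strain: np.ndarray, criterion: StrainCriterion) -> float:
    """Non-negative scalar driving strain for the chosen criterion.

    For the minimum-principal criterion, only compression drives damage: the
    result is the magnitude of the most-negative principal strain, or zero
    for tensile-dominated states.
    """
    criterion = StrainCriterion(criterion)
    if criterion is StrainCriterion.MIN_PRINCIPAL:
        return max(0.0, -min_principal_strain(strain))
    return equivalent_strain(strain)


def damage_from_kappa(kappa, law: DamageLaw):
    """Damage variable for a history strain kappa (scalar or array).

    Zero up to and including eps_f (the threshold comparison is strict),
    then ``1 - exp(1 - kappa/eps_f)``, capped at ``D_max``.
    """
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(over="ignore"):
        grown = 1.0 - np.exp(1.0 - kappa / law.epsilon_f)
    D = np.where(kappa <= law.epsilon_f, 0.0, np.minimum(law.D_max, grown))
    return float(D) if D.ndim == 0 else D


def material_update(
    strain: np.ndarray,
    state: PointState,
    constants: ElasticConstants,
    law: DamageLaw,
    criterion: StrainCriterion,
) -> tuple[np.ndarray, PointState, np.ndarray]:
    """UMAT-style update: strain in, (stress, new state, secant matrix) out.

    The history variable is the running maximum of the criterion strain, so
    damage never heals on unloading.  The returned secant matrix is
    ``(1 - D) C``; the consistent tangent with the softening term is
    available separately via :func:`consistent_tangent`.
    """
    strain = np.asarray(strain, dtype=float)
    kappa_new = max(state.kappa, criterion_strain(strain, criterion))
    D_new = max(state.D, damage_from_kappa(kappa_new, law))
    failed = state.failed or D_new >= law.D_max - 1e-12
    C = stiffness_matrix(constants)
    secant = (1.0 - D_new) * C
    stress = voigt_to_stress(secant @ strain_to_voigt(strain))
    new_state = PointState(strain=strain.copy(), D=D_new, kappa=kappa_new, failed=failed)
    return stress, new_state, secant


def _criterion_gradient(
    strain: np.ndarray, criterion: StrainCriterion
) -> np.ndarray:
    """d(kappa)/d(strain) as a symmetric 3x3 tensor (zero if inactive)."""
    criterion = StrainCriterion(criterion)
    e = np.asarray(strain, dtype=float)
    if criterion is StrainCriterion.MIN_PRINCIPAL:
        w, V = np.linalg.eigh(e)
        if w[0] >= 0.0:
            return np.zeros((3, 3))
        n = V[:, 0]
        return -np.outer(n, n)
    eps_eq = equivalent_strain(e)
    if eps_eq == 0.0:
        return np.zeros((3, 3))
    dev = e - np.trace(e) / 3.0 * np.eye(3)
    return (2.0 / 3.0) * dev / eps_eq


def consistent_tangent(
    strain: np.ndarray,
    state: PointState,
    constants: ElasticConstants,
    law: DamageLaw,
    criterion: StrainCriterion,
) -> np.ndarray:
    """Full algorithmic tangent d(sigma)/d(eps) including the softening term.

    Equals the secant ``(1 - D) C`` minus the rank-one contribution
    ``(C eps) (dD/deps)^T`` while damage is actively growing; equals the
    secant alone on the elastic branch, at the cap, or under unloading
    (kappa below its historical maximum).  Provided for verification; the
    solver uses the secant.
    """
    strain = np.asarray(strain, dtype=float)
    C = stiffness_matrix(constants)
    kappa = criterion_strain(strain, criterion)
    kappa_new = max(state.kappa, kappa)
    D = max(state.D, damage_from_kappa(kappa_new, law))
    secant = (1.0 - D) * C
    # softening term active only when this strain state drives kappa upward
    if kappa <= max(law.epsilon_f, state.kappa) or D >= law.D_max - 1e-12:
        return secant
    dD_dkappa = (law.epsilon_f ** -1) * math.exp(1.0 - kappa / law.epsilon_f)
    grad = _criterion_gradient(strain, criterion)
    # Voigt gradient wrt engineering strain components: off-diagonal tensor
    # entries map one-to-one to gamma derivatives
    g = np.array(
        [grad[0, 0], grad[1, 1], grad[2, 2], grad[0, 1], grad[0, 2], grad[1, 2]]
    )
    sigma_eff = C @ strain_to_voigt(strain)
    return secant - dD_dkappa * np.outer(sigma_eff, g)
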