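"""Small-displacement hexahedral finite-element machinery.

Trilinear 8-node hexahedra with full 2x2x2 Gauss integration for the
stiffness and a single centroid evaluation point for strain recovery.
Because every element of a voxel mesh is the same cube and shares the same
undamaged stiffness tensor, the global matrix is assembled from one
reference element matrix scaled by a per-element stiffness factor
(1 - D, or the floor value for failed elements).

Platen boundary conditions replace the rigid plates and contact of the
physical test: the bottom platen is frictionless (axial displacement fixed,
lateral free), the top platen either sticks (lateral fixed — a stand-in
for penalty friction that transmits shear into the specimen) or is
frictionless (for analytic verification).  With two frictionless platens
the in-plane rigid-body modes are pinned at two bottom nodes chosen so the
pins carry no force in a uniform-strain state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .specimen import HexMesh

__all__ = [
    "BoundaryConditions",
    "CompressionSolver",
    "element_stiffness",
    "reference_cube_stiffness",
    "assemble_and_solve",
    "recover_centroid_strains",
]

# local node coordinates in (-1,1)^3, matching the mesh corner ordering
_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


@dataclass(frozen=True)
class BoundaryConditions:
    """Platen boundary conditions for axial compression.

    ``applied_axial_displacement`` is the displacement of the top platen in
    mm; negative values compress the specimen.
    """

    applied_axial_displacement: float
    top_mode: str = "stick_platen"
    bottom_mode: str = "frictionless_platen"

    def __post_init__(self) -> None:
        if self.top_mode not in ("stick_platen", "frictionless_platen"):
            raise ValueError(f"unknown top_mode {self.top_mode!r}")
        if self.bottom_mode != "frictionless_platen":
            raise ValueError(f"unknown bottom_mode {self.bottom_mode!r}")


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """(8, 3) gradients of the trilinear shape functions at local point xi."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _XI[a]
        g[a, 0] = sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8.0
        g[a, 1] = (1 + sx * xi[0]) * sy * (1 + sz * xi[2]) / 8.0
        g[a, 2] = (1 + sx * xi[0]) * (1 + sy * xi[1]) * sz / 8.0
    return g


def _b_matrix(dN_dx: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix (Voigt 11,22,33,12,13,23, eng. shear)."""
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dN_dx[a]
        c = 3 * a
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c] = bz
        B[4, c + 2] = bx
        B[5, c + 1] = bz
        B[5, c + 2] = by
    return B


def element_stiffness(
    node_coords: np.ndarray, C: np.ndarray, element_id: int | None = None
) -> np.ndarray:
    """24x24 stiffness of one trilinear hex (2x2x2 Gauss), N/mm.

    Raises ``ValueError`` for an inverted element (non-positive Jacobian).
    """
    X = np.asarray(node_coords, dtype=float)
    K = np.zeros((24, 24))
    for gx in _GP:
        for gy in _GP:
            for gz in _GP:
                dN_dxi = _shape_gradients(np.array([gx, gy, gz]))
                J = dN_dxi.T @ X  # (3,3): dx/dxi
                detJ = np.linalg.det(J)
                if detJ <= 0:
                    which = "" if element_id is None else f" (element {element_id})"
                    raise ValueError(f"inverted hex element{which}: det J = {detJ:.3g}")
                dN_dx = dN_dxi @ np.linalg.inv(J)
                B = _b_matrix(dN_dx)
                K += B.T @ C @ B * detJ
    return 0.5 * (K + K.T)


def reference_cube_stiffness(edge: float, C: np.ndarray) -> np.ndarray:
    """Stiffness of an axis-aligned cube of the given edge length."""
    corners = (_XI + 1.0) / 2.0 * edge
    return element_stiffness(corners, C)


def centroid_b_matrix(edge: float) -> np.ndarray:
    """6x24 strain-displacement matrix at the centroid of an edge-length cube."""
    dN_dxi = _shape_gradients(np.zeros(3))
    return _b_matrix(dN_dxi * (2.0 / edge))


def _constraints(mesh: HexMesh, bcs: BoundaryConditions) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet (dof index, value) arrays implementing the platens."""
    top = mesh.node_sets["top_surface"]
    bottom = mesh.node_sets["bottom_surface"]
    dofs: list[int] = []
    vals: list[float] = []
    dofs += (3 * bottom + 2).tolist()
    vals += [0.0] * len(bottom)
    dofs += (3 * top + 2).tolist()
    vals += [bcs.applied_axial_displacement] * len(top)
    if bcs.top_mode == "stick_platen":
        for d in (0, 1):
            dofs += (3 * top + d).tolist()
            vals += [0.0] * len(top)
    else:
        # pin in-plane rigid modes at two bottom nodes: full lateral pin at A,
        # y-pin at a node B sharing A's y-coordinate (zero-force pins under
        # any uniform-strain field centred on A)
        coords = mesh.node_coords[bottom]
        a = 0
        same_y = np.nonzero(
            (np.abs(coords[:, 1] - coords[a, 1]) < 1e-12)
            & (np.abs(coords[:, 0] - coords[a, 0]) > 1e-12)
        )[0]
        if len(same_y) == 0:
            raise ValueError("cannot pin rigid modes: degenerate bottom surface")
        b = int(same_y[0])
        dofs += [3 * bottom[a], 3 * bottom[a] + 1, 3 * bottom[b] + 1]
        vals += [0.0, 0.0, 0.0]
    return np.asarray(dofs, dtype=np.int64), np.asarray(vals, dtype=float)


def assemble_global_stiffness(
    mesh: HexMesh, C: np.ndarray, element_factors: np.ndarray
) -> sp.csr_matrix:
    """Sparse global stiffness from the scaled reference-cube element matrix."""
    K0 = reference_cube_stiffness(mesh.spacing, C)
    edofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
    rows = np.repeat(edofs, 24, axis=1).ravel()
    cols = np.tile(edofs, (1, 24)).ravel()
    data = (element_factors[:, None] * K0.ravel()[None, :]).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return K


class CompressionSolver:
    """Repeated-solve context for one mesh and platen configuration.

    The staggered damage iteration solves the same sparse system many
    times with slowly changing element stiffness factors.  This class
    caches the last direct factorization and answers subsequent solves by
    conjugate gradients preconditioned with it, refactorizing only when
    the damage field has drifted too far for the preconditioner to work.
    """

    #: CG iteration budget before giving up and refactorizing
    _CG_MAXITER = 30

    def __init__(
        self,
        mesh: HexMesh,
        C: np.ndarray,
        top_mode: str = "stick_platen",
        bottom_mode: str = "frictionless_platen",
    ) -> None:
        self.mesh = mesh
        self.C = np.asarray(C, dtype=float)
        self.top_mode = top_mode
        self.K0 = reference_cube_stiffness(mesh.spacing, C)
        edofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._rows = np.repeat(edofs, 24, axis=1).ravel()
        self._cols = np.tile(edofs, (1, 24)).ravel()
        self._n = 3 * mesh.n_nodes
        # unit-displacement constraint pattern; scaled by the applied value
        bcs = BoundaryConditions(1.0, top_mode=top_mode, bottom_mode=bottom_mode)
        self._cdofs, self._cunit = _constraints(mesh, bcs)
        is_c = np.zeros(self._n, dtype=bool)
        is_c[self._cdofs] = True
        self._free = np.nonzero(~is_c)[0]
        self._top_z = 3 * mesh.node_sets["top_surface"] + 2
        self._bot_z = 3 * mesh.node_sets["bottom_surface"] + 2
        self._lu = None
        self._lu_factors: np.ndarray | None = None

    def _assemble(self, factors: np.ndarray) -> sp.csr_matrix:
        data = (factors[:, None] * self.K0.ravel()[None, :]).ravel()
        return sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self._n, self._n)
        ).tocsr()

    def _factorize(self, Kff: sp.csc_matrix):
        try:
            return spla.splu(
                Kff, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True}
            )
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise RuntimeError(
                "singular stiffness system: check for isolated voxels or a "
                "stiffness floor of zero"
            ) from exc

    def solve(
        self, element_factors: np.ndarray, applied_axial_displacement: float
    ) -> tuple[np.ndarray, float]:
        """Solve for one displacement level; return (displacements, reaction).

        ``element_factors`` scales each element's stiffness (1 intact,
        1 - D damaged, the configured floor once failed).  The reaction is
        the axial force on the top platen, positive in compression; top
        and bottom reactions are checked to balance.
        """
        factors = np.asarray(element_factors, dtype=float)
        if factors.shape != (self.mesh.n_elements,):
            raise ValueError("element_factors must have one entry per element")
        K = self._assemble(factors)
        cvals = self._cunit * applied_axial_displacement
        free = self._free
        rhs = -(K[free][:, self._cdofs] @ cvals)
        Kff = K[free][:, free].tocsc()

        x = None
        if self._lu is not None and np.array_equal(factors, self._lu_factors):
            x = self._lu.solve(rhs)
        elif self._lu is not None:
            M = spla.LinearOperator(Kff.shape, self._lu.solve)
            x, info = spla.cg(
                Kff, rhs, M=M, rtol=1e-13, atol=0.0, maxiter=self._CG_MAXITER
            )
            if info != 0:
                x = None
        if x is None:
            self._lu = self._factorize(Kff)
            self._lu_factors = factors.copy()
            x = self._lu.solve(rhs)

        u = np.zeros(self._n)
        u[self._cdofs] = cvals
        u[free] = x

        f = K @ u  # constraint forces at Dirichlet dofs, ~0 elsewhere
        f_top = f[self._top_z].sum()
        f_bot = f[self._bot_z].sum()
        scale = max(abs(f_top), abs(f_bot), 1.0)
        residual = np.abs(Kff @ x - rhs).max()
        if residual > 1e-8 * scale:
            raise RuntimeError(
                f"equilibrium residual {residual:.3g} exceeds tolerance"
            )
        if not np.isclose(f_top + f_bot, 0.0, atol=1e-6 * scale):
            raise RuntimeError("top and bottom platen reactions do not balance")
        return u.reshape(-1, 3), float(-f_top)  # positive in compression


def assemble_and_solve(
    mesh: HexMesh,
    C: np.ndarray,
    element_factors: np.ndarray,
    bcs: BoundaryConditions,
) -> tuple[np.ndarray, float]:
    """One-shot solve of the constrained system; see :class:`CompressionSolver`."""
    solver = CompressionSolver(
        mesh, C, top_mode=bcs.top_mode, bottom_mode=bcs.bottom_mode
    )
    return solver.solve(element_factors, bcs.applied_axial_displacement)


def recover_centroid_strains(mesh: HexMesh, displacements: np.ndarray) -> np.ndarray:
    """(E, 3, 3) symmetric strain tensors at each element centroid.

    The strain is the symmetric gradient of the trilinear interpolant
    evaluated at the cube centre; shear components are tensorial.
    """
    u = np.asarray(displacements, dtype=float).reshape(-1, 3)
    Bc = centroid_b_matrix(mesh.spacing)
    ue = u[mesh.elements].reshape(mesh.n_elements, 24)
    v = ue @ Bc.T  # (E, 6) Voigt, engineering shear
    E = np.zeros((mesh.n_elements, 3, 3))
    E[:, 0, 0] = v[:, 0]
    E[:, 1, 1] = v[:, 1]
    E[:, 2, 2] = v[:, 2]
    E[:, 0, 1] = E[:, 1, 0] = v[:, 3] / 2.0
    E[:, 0, 2] = E[:, 2, 0] = v[:, 4] / 2.0
    E[:, 1, 2] = E[:, 2, 1] = v[:, 5] / 2.0
    return E
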