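"""Synthetic cortical-bone specimen geometry and voxel hex meshing.

The diaphysis segment of a rat femur is, at desk scale, a hollow,
roughly tubular shell of cortical bone.  This module generates such
specimens as boolean voxel grids (standing in for a segmented micro-CT
scan), reads/writes real segmentations in MetaImage or NRRD form, and
converts any voxel mask into a conforming 8-node hexahedral mesh with one
element per occupied voxel.

Conventions: the k (third) grid axis is the loading axis and coincides
with the longitudinal (osteon) material axis.  Lengths are in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "VoxelSpecimen",
    "HexMesh",
    "generate_hollow_cylinder",
    "read_voxel_mask",
    "write_voxel_mask",
    "voxels_to_mesh",
]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelSpecimen:
    """Boolean occupancy grid on a cubic lattice.

    ``occupancy[i, j, k]`` is True where bone is present; ``spacing`` is the
    voxel edge length in mm; ``origin`` locates the corner of voxel (0,0,0).
    """

    occupancy: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if occ.ndim != 3 or not occ.any():
            raise ValueError("occupancy must be a non-empty 3-D boolean grid")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def height(self) -> float:
        """Extent along the loading (k) axis, mm."""
        ks = np.nonzero(self.occupancy.any(axis=(0, 1)))[0]
        return float((ks.max() - ks.min() + 1) * self.spacing)


@dataclass(frozen=True)
class HexMesh:
    """Conforming mesh of identical cube-shaped 8-node hexahedra.

    ``elements[e]`` lists the 8 node indices of element ``e`` in the usual
    trilinear-hex ordering (bottom quad counter-clockwise, then top quad),
    which makes every element Jacobian positive.  ``node_sets`` holds the
    ``top_surface`` / ``bottom_surface`` node index arrays used for platen
    boundary conditions.  ``element_to_voxel`` maps each element back to its
    (i, j, k) voxel so damage fields can be analysed on the grid.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    spacing: float
    node_sets: dict[str, np.ndarray]
    element_to_voxel: np.ndarray
    voxel_shape: tuple[int, int, int]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def element_volume(self) -> np.ndarray:
        """Volume of each element, mm^3 (all voxels are cubes)."""
        return np.full(self.n_elements, self.spacing**3)

    def element_centroids(self) -> np.ndarray:
        """(E, 3) array of element centroid coordinates, mm."""
        return self.node_coords[self.elements].mean(axis=1)

    def geometry_hash(self) -> str:
        """Content hash of the mesh for run provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.node_coords))
        h.update(np.ascontiguousarray(self.elements))
        return h.hexdigest()[:16]


def _largest_component(occ: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the largest 26-connected component; return (mask, n_discarded)."""
    labels, n = ndimage.label(occ, structure=_STRUCT_26)
    if n <= 1:
        return occ, 0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    mask = labels == keep
    return mask, int(occ.sum() - mask.sum())


def generate_hollow_cylinder(
    outer_diameter: float = 3.5,
    wall_thickness: float = 0.5,
    height: float = 5.0,
    voxel_size: float = 0.08,
    eccentricity: float = 0.0,
    thickness_noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelSpecimen:
    """Generate a voxelized hollow-cylinder specimen.

    The default 3.5 mm outer diameter / 0.5 mm wall are plausible rat
    femoral mid-diaphysis dimensions; the 5 mm height matches the specimen
    preparation protocol.  ``eccentricity`` shifts the medullary cavity off
    centre by that fraction of the wall thickness, and
    ``thickness_noise_sd`` (mm) adds smooth perturbations to the inner and
    outer surfaces that vary around the circumference and slowly along the
    shaft, emulating the irregular cortex of a real bone (a femoral
    diaphysis is neither axisymmetric nor prismatic).  Both default to
    zero for analytic verification; the run configuration enables them for
    fracture studies so that failure has a physical place to localize.

    Deterministic for a given seed.
    """
    if not outer_diameter > 2.0 * wall_thickness > 0.0:
        raise ValueError("need outer_diameter > 2*wall_thickness > 0")
    if voxel_size > wall_thickness / 2.0:
        raise ValueError(
            f"voxel_size={voxel_size} mm too coarse to resolve the "
            f"{wall_thickness} mm wall (need <= wall_thickness/2)"
        )
    if height < voxel_size:
        raise ValueError("height must be at least one voxel")

    rng = np.random.default_rng(seed)
    r_out = outer_diameter / 2.0
    r_in = r_out - wall_thickness
    margin = 3.0 * thickness_noise_sd
    half = r_out + margin + voxel_size
    n_xy = int(np.ceil(2.0 * half / voxel_size))
    n_z = max(1, int(round(height / voxel_size)))

    # voxel centre coordinates relative to the cylinder axis
    c = (np.arange(n_xy) + 0.5) * voxel_size - half
    X, Y = np.meshgrid(c, c, indexing="ij")
    theta = np.arctan2(Y, X)[:, :, None]
    z = ((np.arange(n_z) + 0.5) / n_z)[None, None, :]  # normalized height

    # smooth surface noise: low-order Fourier harmonics around the
    # circumference modulated by low-order modes along the shaft, so the
    # wall is neither axisymmetric nor prismatic
    def surface_noise() -> np.ndarray:
        if thickness_noise_sd == 0.0:
            return np.zeros((1, 1, 1))
        harmonics = (1, 2, 3)
        axial_modes = (0.0, 1.0, 2.0)
        out = np.zeros((n_xy, n_xy, n_z))
        for m in harmonics:
            for p in axial_modes:
                a, b, ph = rng.normal(0.0, 1.0, size=3)
                axial = np.cos(np.pi * p * z + ph)
                out += (a * np.cos(m * theta) + b * np.sin(m * theta)) * axial
        # normalize so the pointwise sd is thickness_noise_sd
        out *= thickness_noise_sd / np.sqrt(len(harmonics) * len(axial_modes))
        return out

    dr_out = surface_noise()
    dr_in = surface_noise()
    offset = eccentricity * wall_thickness

    r2_outer = (X**2 + Y**2)[:, :, None]
    r2_inner = ((X - offset) ** 2 + Y**2)[:, :, None]
    occ = (r2_outer <= (r_out + dr_out) ** 2) & (r2_inner >= (r_in + dr_in) ** 2)
    occ = np.broadcast_to(occ, (n_xy, n_xy, n_z)).copy()
    occ, n_discarded = _largest_component(occ)
    if n_discarded:
        logger.warning("discarded %d voxels outside the main component", n_discarded)
    if not occ.any():
        raise ValueError("generated geometry is empty; check the parameters")
    return VoxelSpecimen(occupancy=occ, spacing=voxel_size, origin=np.array([-half, -half, 0.0]))


def write_voxel_mask(spec: VoxelSpecimen, path: str) -> None:
    """Write a specimen as a MetaImage (.mhd/.raw) or NRRD mask."""
    arr = spec.occupancy.transpose(2, 1, 0).astype(np.uint8)  # sitk is (z,y,x)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing((spec.spacing,) * 3)
    img.SetOrigin(tuple(spec.origin))
    sitk.WriteImage(img, str(path))


def read_voxel_mask(path: str) -> VoxelSpecimen:
    """Read a segmented voxel mask (MetaImage or NRRD) as a VoxelSpecimen.

    Nonzero voxels are treated as bone.  Only the largest 26-connected
    component is kept (isolated voxels would make the stiffness matrix
    singular); the number of discarded voxels is logged.  Anisotropic
    spacing is rejected because cube-voxel meshing assumes it.
    """
    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError(f"anisotropic voxel spacing {tuple(spacing)} not supported")
    arr = sitk.GetArrayFromImage(img)
    occ = (arr != 0).transpose(2, 1, 0)
    if not occ.any():
        raise ValueError(f"voxel mask {path} contains no occupied voxels")
    occ, n_discarded = _largest_component(occ)
    if n_discarded:
        logger.warning(
            "%s: discarded %d voxels outside the largest connected component",
            path,
            n_discarded,
        )
    return VoxelSpecimen(
        occupancy=occ, spacing=float(spacing[0]), origin=np.asarray(img.GetOrigin())
    )


# local corner offsets in trilinear-hex node order (positive Jacobian)
_CORNERS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)


def voxels_to_mesh(spec: VoxelSpecimen) -> HexMesh:
    """Convert a voxel mask into a conforming hexahedral mesh.

    One cube element per occupied voxel.  Coincident corner nodes are
    merged exactly by integer lattice index (no floating-point tolerance),
    so shared faces reference identical node indices.  ``top_surface`` /
    ``bottom_surface`` node sets collect the nodes on the highest / lowest
    lattice plane along the loading axis.
    """
    occ = spec.occupancy
    ni, nj, nk = occ.shape
    vox = np.argwhere(occ)  # (E, 3) lattice indices, C-order sorted

    # lattice node ids: corner (i,j,k) -> i*(nj+1)*(nk+1) + j*(nk+1) + k
    corner_idx = vox[:, None, :] + _CORNERS[None, :, :]  # (E, 8, 3)
    flat = (
        corner_idx[..., 0] * (nj + 1) * (nk + 1)
        + corner_idx[..., 1] * (nk + 1)
        + corner_idx[..., 2]
    )
    used, elements = np.unique(flat, return_inverse=True)
    elements = elements.reshape(-1, 8).astype(np.int64)

    # decode lattice index -> coordinates
    k_lat = used % (nk + 1)
    j_lat = (used // (nk + 1)) % (nj + 1)
    i_lat = used // ((nj + 1) * (nk + 1))
    node_coords = (
        np.stack([i_lat, j_lat, k_lat], axis=1).astype(float) * spec.spacing
        + spec.origin
    )

    k_max = int(vox[:, 2].max()) + 1
    k_min = int(vox[:, 2].min())
    node_sets = {
        "top_surface": np.nonzero(k_lat == k_max)[0],
        "bottom_surface": np.nonzero(k_lat == k_min)[0],
    }
    return HexMesh(
        node_coords=node_coords,
        elements=elements,
        spacing=spec.spacing,
        node_sets=node_sets,
        element_to_voxel=vox,
        voxel_shape=(ni, nj, nk),
    )
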