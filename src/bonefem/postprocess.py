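"""Fracture-parameter extraction and comparison studies.

Derives the quantities used to compare simulations with the physical
compression test: fracture load (peak reaction), fracture displacement and
time (at the quasi-static 1 mm/min rate), apparent stiffness (least-squares
slope of the early load-displacement curve), and the crack orientation
class obtained by fitting a plane to the failed-element cloud.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

from .fracture import SimulationConfig, SimulationResult, run_compression
from .material import DamageLaw, ElasticConstants, StrainCriterion
from .solver import BoundaryConditions
from .specimen import HexMesh, generate_hollow_cylinder, voxels_to_mesh

__all__ = [
    "FractureSummary",
    "summarize",
    "fit_crack_plane",
    "mesh_sensitivity_study",
    "compare_criteria",
]

logger = logging.getLogger(__name__)

#: quasi-static loading rate of the physical test, mm/min
LOADING_RATE_MM_PER_MIN = 1.0

#: crack-plane angle (degrees, from the loading axis) separating the
#: transverse from the oblique class
TRANSVERSE_ANGLE_DEG = 15.0


@dataclass(frozen=True)
class FractureSummary:
    """Scalar fracture parameters of one run.

    ``fracture_*`` fields are None when no element failed (purely elastic
    run); the apparent stiffness is always reported.
    """

    fracture_load: float | None
    fracture_displacement: float | None
    fracture_time: float | None
    apparent_stiffness: float
    crack_angle: float | None
    crack_class: str | None
    termination_reason: str
    criterion: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "fracture_load_N": self.fracture_load,
            "fracture_displacement_mm": self.fracture_displacement,
            "fracture_time_s": self.fracture_time,
            "apparent_stiffness_N_per_mm": self.apparent_stiffness,
            "crack_angle_deg": self.crack_angle,
            "crack_class": self.crack_class,
            "termination_reason": self.termination_reason,
            "criterion": self.criterion,
        }


def _stiffness_fit(
    displacement: np.ndarray, reaction: np.ndarray, window: tuple[float, float]
) -> float:
    """Least-squares slope of the curve restricted to a peak-fraction window.

    Only the rising branch (up to the peak) enters the fit, so post-peak
    softening points that re-enter the load window are excluded.
    """
    i_peak = int(np.argmax(reaction))
    displacement = displacement[: i_peak + 1]
    reaction = reaction[: i_peak + 1]
    peak = reaction.max()
    lo, hi = window
    sel = (reaction >= lo * peak) & (reaction <= hi * peak) & (displacement > 0)
    if sel.sum() < 2:  # tiny runs: fall back to the whole rising branch
        sel = (displacement > 0) & (reaction > 0)
    if sel.sum() < 2:
        return 0.0
    slope, _ = np.polyfit(displacement[sel], reaction[sel], 1)
    return float(slope)


def fit_crack_plane(mesh: HexMesh, failed: np.ndarray) -> tuple[float, str] | None:
    """Fit a plane to the failed-element region; return (angle, class).

    Only the largest face-connected failed cluster is used, so scattered
    failed elements do not contaminate the fit.  The plane normal is the
    direction of smallest spread of the cluster centroids (principal-axis
    analysis); the angle is measured between that normal and the loading
    (k) axis.  Returns None when no element failed.
    """
    failed = np.asarray(failed, dtype=bool)
    if not failed.any():
        return None
    grid = np.zeros(mesh.voxel_shape, dtype=bool)
    vox = mesh.element_to_voxel
    grid[vox[:, 0], vox[:, 1], vox[:, 2]] = failed
    labels, n = ndimage.label(grid)  # face connectivity
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts.argmax()
    in_cluster = labels[vox[:, 0], vox[:, 1], vox[:, 2]] == keep
    pts = mesh.element_centroids()[failed & in_cluster]
    centred = pts - pts.mean(axis=0)
    if len(pts) == 1:
        normal = np.array([0.0, 0.0, 1.0])
    else:
        cov = centred.T @ centred / len(pts)
        w, V = np.linalg.eigh(cov)
        normal = V[:, 0]  # smallest-spread direction
    angle = float(np.degrees(np.arccos(min(1.0, abs(normal[2])))))
    crack_class = "transverse" if angle <= TRANSVERSE_ANGLE_DEG else "oblique"
    return angle, crack_class


def summarize(
    result: SimulationResult,
    mesh: HexMesh,
    stiffness_window: tuple[float, float] = (0.1, 0.4),
) -> FractureSummary:
    """Derive the fracture parameters from a finished run.

    Fracture load is the peak reaction; fracture displacement the
    displacement at that peak; fracture time follows from the quasi-static
    rate (1 mm/min).  Apparent stiffness is the least-squares slope of the
    load-displacement curve over the ``stiffness_window`` fraction of the
    peak load (default 10-40%).
    """
    rec = result.records
    if len(rec) < 3:
        raise ValueError("need at least 3 increments to summarize a run")
    disp = rec["displacement"].to_numpy()
    reac = rec["reaction"].to_numpy()
    stiffness = _stiffness_fit(disp, reac, stiffness_window)

    if not result.failed.any():
        return FractureSummary(
            fracture_load=None,
            fracture_displacement=None,
            fracture_time=None,
            apparent_stiffness=stiffness,
            crack_angle=None,
            crack_class=None,
            termination_reason=result.termination_reason,
            criterion=result.criterion.value,
        )

    i_peak = int(np.argmax(reac))
    fracture_load = float(reac[i_peak])
    fracture_displacement = float(disp[i_peak])
    rate_mm_per_s = LOADING_RATE_MM_PER_MIN / 60.0
    fracture_time = fracture_displacement / rate_mm_per_s
    plane = fit_crack_plane(mesh, result.failed)
    angle, crack_class = plane if plane is not None else (None, None)
    return FractureSummary(
        fracture_load=fracture_load,
        fracture_displacement=fracture_displacement,
        fracture_time=fracture_time,
        apparent_stiffness=stiffness,
        crack_angle=angle,
        crack_class=crack_class,
        termination_reason=result.termination_reason,
        criterion=result.criterion.value,
    )


def _build_mesh(geometry: dict[str, Any], voxel_size: float, seed: int) -> HexMesh:
    spec = generate_hollow_cylinder(
        outer_diameter=geometry.get("outer_diameter", 3.5),
        wall_thickness=geometry.get("wall_thickness", 0.5),
        height=geometry.get("height", 5.0),
        voxel_size=voxel_size,
        eccentricity=geometry.get("eccentricity", 0.0),
        thickness_noise_sd=geometry.get("thickness_noise_sd", 0.0),
        seed=seed,
    )
    return voxels_to_mesh(spec)


def mesh_sensitivity_study(
    geometry: dict[str, Any],
    sizes_um: list[float],
    constants: ElasticConstants,
    law: DamageLaw,
    config: SimulationConfig,
    bcs: BoundaryConditions | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One full fracture run per element size; table of fracture parameters.

    ``sizes_um`` are element edge lengths in micrometres.  Duplicates are
    dropped with a warning; a size too coarse for the cortical wall yields
    a row flagged ``ok=False`` instead of aborting the study.  The table is
    sorted by element size.
    """
    if len(sizes_um) < 1:
        raise ValueError("need at least one element size")
    uniq = sorted(set(float(s) for s in sizes_um))
    if len(uniq) < len(sizes_um):
        _warnings.warn("duplicate element sizes dropped", stacklevel=2)
    rows = []
    for size_um in uniq:
        voxel_mm = size_um / 1000.0
        try:
            mesh = _build_mesh(geometry, voxel_mm, seed)
            result = run_compression(mesh, constants, law, None, config, bcs)
            summ = summarize(result, mesh)
            rows.append(
                {
                    "element_size_um": size_um,
                    "element_count": mesh.n_elements,
                    "fracture_load_N": summ.fracture_load,
                    "apparent_stiffness_N_per_mm": summ.apparent_stiffness,
                    "ok": True,
                    "note": "",
                }
            )
        except ValueError as exc:
            logger.warning("size %g um skipped: %s", size_um, exc)
            rows.append(
                {
                    "element_size_um": size_um,
                    "element_count": 0,
                    "fracture_load_N": None,
                    "apparent_stiffness_N_per_mm": None,
                    "ok": False,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows).sort_values("element_size_um", ignore_index=True)


def compare_criteria(
    geometry: dict[str, Any],
    voxel_size: float,
    constants: ElasticConstants,
    law: DamageLaw,
    config: SimulationConfig,
    bcs: BoundaryConditions | None = None,
    seed: int = 0,
) -> dict[str, Any]:
    """Run both strain criteria on the same specimen and compare.

    Returns both fracture summaries, the load and displacement-at-failure
    ratios (equivalent over min-principal), and the maximum relative
    reaction difference over the shared damage-free increments (the early
    elastic branches must coincide because the moduli are identical).
    """
    mesh = _build_mesh(geometry, voxel_size, seed)
    runs: dict[str, SimulationResult] = {}
    summaries: dict[str, FractureSummary] = {}
    for crit in (StrainCriterion.MIN_PRINCIPAL, StrainCriterion.EQUIVALENT):
        res = run_compression(mesh, constants, law, crit, config, bcs)
        runs[crit.value] = res
        summaries[crit.value] = summarize(res, mesh)

    a = runs[StrainCriterion.MIN_PRINCIPAL.value].records
    b = runs[StrainCriterion.EQUIVALENT.value].records
    n = min(len(a), len(b))
    both_elastic = (
        (a["n_damaged"].to_numpy()[:n] == 0)
        & (b["n_damaged"].to_numpy()[:n] == 0)
        & (a["displacement"].to_numpy()[:n] == b["displacement"].to_numpy()[:n])
    )
    ra = a["reaction"].to_numpy()[:n][both_elastic]
    rb = b["reaction"].to_numpy()[:n][both_elastic]
    nonzero = ra > 0
    coincidence = (
        float(np.abs(ra[nonzero] - rb[nonzero]).max() / ra[nonzero].max())
        if nonzero.any()
        else 0.0
    )

    s_mp = summaries[StrainCriterion.MIN_PRINCIPAL.value]
    s_eq = summaries[StrainCriterion.EQUIVALENT.value]

    def _ratio(x: float | None, y: float | None) -> float | None:
        if x is None or y is None or y == 0:
            return None
        return x / y

    return {
        "summaries": {k: v.to_dict() for k, v in summaries.items()},
        "results": runs,
        "fracture_load_ratio_eq_over_mp": _ratio(s_eq.fracture_load, s_mp.fracture_load),
        "fracture_displacement_ratio_eq_over_mp": _ratio(
            s_eq.fracture_displacement, s_mp.fracture_displacement
        ),
        "crack_classes": {
            "min_principal": s_mp.crack_class,
            "equivalent": s_eq.crack_class,
        },
        "elastic_branch_max_rel_diff": coincidence,
        "n_elements": mesh.n_elements,
    }
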