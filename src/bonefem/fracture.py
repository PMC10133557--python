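"""Progressive-failure driver for axial compression.

The load is applied as a monotone displacement ramp.  Each increment is
solved with a staggered (operator-split) scheme: solve the linear system
with the current per-element secant stiffness, recover centroid strains,
update the damage field from the running-maximum criterion strain, and
repeat until the damage field stops changing.  Elements whose stiffness
fraction drops to the residual value are flagged failed and floored at a
small stiffness factor instead of being deleted, which keeps the system
non-singular while removing their load-bearing capacity.

An increment in which a large burst of elements fails is bisected and
re-run at half the step, so brutal softening is traversed in smaller
steps.  The run stops at full displacement, when the reaction has dropped
a set fraction below its peak, or when the failed elements percolate
across the specimen (a face-connected failed surface separates the intact
top from the intact bottom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

from .material import (
    DamageLaw,
    ElasticConstants,
    StrainCriterion,
    damage_from_kappa,
    stiffness_matrix,
)
from .solver import BoundaryConditions, CompressionSolver, recover_centroid_strains
from .specimen import HexMesh

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_compression",
    "check_percolation",
    "criterion_strain_field",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Loading protocol and solver controls.

    Defaults follow the physical test: 0.5 mm total axial compression in
    100 equal increments.  ``stiffness_floor`` is the stiffness factor
    retained by failed elements; results must be insensitive to it within
    the 1e-3..1e-5 range.  ``bisection_fraction`` triggers sub-stepping
    when more than that fraction of elements fails in one increment.
    """

    total_displacement: float = 0.5
    n_increments: int = 100
    criterion: StrainCriterion = StrainCriterion.MIN_PRINCIPAL
    stagger_tolerance: float = 1e-3
    max_stagger_iterations: int = 25
    stiffness_floor: float = 1e-4
    load_drop_fraction: float | None = 0.2
    percolation: bool = True
    bisection_fraction: float = 0.05
    max_bisection_depth: int = 6

    def __post_init__(self) -> None:
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        if self.total_displacement <= 0:
            raise ValueError("total_displacement must be positive (magnitude)")
        if not 0.0 < self.stiffness_floor < 1.0:
            raise ValueError("stiffness_floor must lie in (0, 1)")
        object.__setattr__(self, "criterion", StrainCriterion(self.criterion))


@dataclass
class SimulationResult:
    """History and final state of one compression run."""

    records: pd.DataFrame
    kappa: np.ndarray
    D: np.ndarray
    failed: np.ndarray
    termination_reason: str
    criterion: StrainCriterion
    config: SimulationConfig
    provenance: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def displacement(self) -> np.ndarray:
        return self.records["displacement"].to_numpy()

    @property
    def reaction(self) -> np.ndarray:
        return self.records["reaction"].to_numpy()


def criterion_strain_field(
    strains: np.ndarray, criterion: StrainCriterion
) -> np.ndarray:
    """Vectorized criterion strain for an (E, 3, 3) strain-tensor array."""
    criterion = StrainCriterion(criterion)
    if criterion is StrainCriterion.MIN_PRINCIPAL:
        lam_min = np.linalg.eigvalsh(strains)[:, 0]
        return np.maximum(0.0, -lam_min)
    tr = np.trace(strains, axis1=1, axis2=2)
    dev = strains - tr[:, None, None] / 3.0 * np.eye(3)
    return np.sqrt(2.0 / 3.0 * np.einsum("eij,eij->e", dev, dev))


def check_percolation(mesh: HexMesh, failed: np.ndarray) -> bool:
    """True when failed elements separate the intact top from the bottom.

    Works on the voxel grid: intact (non-failed) voxels are labelled with
    face connectivity; if no intact component reaches both the topmost and
    bottommost occupied voxel layers, a failed surface crosses the whole
    specimen.
    """
    failed = np.asarray(failed, dtype=bool)
    if not failed.any():
        return False
    grid = np.zeros(mesh.voxel_shape, dtype=bool)
    vox = mesh.element_to_voxel
    grid[vox[:, 0], vox[:, 1], vox[:, 2]] = ~failed
    k_top = int(vox[:, 2].max())
    k_bot = int(vox[:, 2].min())
    labels, n = ndimage.label(grid)  # 6-connectivity
    if n == 0:
        return True
    top_labels = np.unique(labels[:, :, k_top])
    bot_labels = np.unique(labels[:, :, k_bot])
    common = np.intersect1d(top_labels, bot_labels)
    return not bool((common > 0).any())


def _stagger(
    solver: CompressionSolver,
    mesh: HexMesh,
    kappa: np.ndarray,
    D: np.ndarray,
    failed: np.ndarray,
    d: float,
    law: DamageLaw,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """Fixed-point iteration on the damage field at frozen displacement d."""
    kappa_t = kappa.copy()
    D_t = D.copy()
    failed_t = failed.copy()
    reaction = 0.0
    converged = False
    it = 0
    for it in range(1, cfg.max_stagger_iterations + 1):
        factors = np.where(failed_t, cfg.stiffness_floor, 1.0 - D_t)
        u, reaction = solver.solve(factors, -d)
        strains = recover_centroid_strains(mesh, u)
        kappa_t = np.maximum(kappa_t, criterion_strain_field(strains, cfg.criterion))
        D_new = np.maximum(D_t, damage_from_kappa(kappa_t, law))
        delta = float(np.abs(D_new - D_t).max())
        D_t = D_new
        failed_t = failed_t | (D_t >= law.D_max - 1e-12)
        if delta <= cfg.stagger_tolerance:
            converged = True
            break
    return kappa_t, D_t, failed_t, reaction, converged, it


def run_compression(
    mesh: HexMesh,
    constants: ElasticConstants,
    law: DamageLaw,
    criterion: StrainCriterion | str | None = None,
    config: SimulationConfig | None = None,
    bcs: BoundaryConditions | None = None,
) -> SimulationResult:
    """Run the incremental compression simulation to termination.

    ``criterion`` overrides the one in ``config`` when given.  ``bcs``
    supplies the platen modes only; the displacement magnitude and ramp
    come from ``config``.
    """
    config = config or SimulationConfig()
    if criterion is not None:
        config = replace(config, criterion=StrainCriterion(criterion))
    top_mode, bottom_mode = (
        (bcs.top_mode, bcs.bottom_mode)
        if bcs is not None
        else ("stick_platen", "frictionless_platen")
    )
    C = stiffness_matrix(constants)
    solver = CompressionSolver(mesh, C, top_mode=top_mode, bottom_mode=bottom_mode)
    E = mesh.n_elements
    kappa = np.zeros(E)
    D = np.zeros(E)
    failed = np.zeros(E, dtype=bool)

    rows: list[dict[str, Any]] = [
        {
            "displacement": 0.0,
            "reaction": 0.0,
            "n_damaged": 0,
            "n_failed": 0,
            "max_D": 0.0,
            "stagger_converged": True,
        }
    ]
    warnings: list[str] = []
    termination = "full_displacement"

    step = config.total_displacement / config.n_increments
    targets = list(np.arange(1, config.n_increments + 1) * step)
    d_prev = 0.0
    peak = 0.0
    stop = False

    # stack-based adaptive stepping: bisect an increment when a large burst
    # of elements fails at once
    pending = [(d, 0) for d in reversed(targets)]
    while pending and not stop:
        d, depth = pending.pop()
        kappa_t, D_t, failed_t, reaction, converged, iters = _stagger(
            solver, mesh, kappa, D, failed, d, law, config
        )
        n_new_failed = int(failed_t.sum() - failed.sum())
        if (
            n_new_failed > config.bisection_fraction * E
            and depth < config.max_bisection_depth
            and d - d_prev > 1e-12
        ):
            mid = 0.5 * (d_prev + d)
            pending.append((d, depth + 1))
            pending.append((mid, depth + 1))
            continue
        if not converged:
            msg = (
                f"stagger iteration did not converge at displacement {d:.6g} mm "
                f"({iters} iterations); increment accepted"
            )
            warnings.append(msg)
            logger.warning(msg)
        kappa, D, failed = kappa_t, D_t, failed_t
        d_prev = d
        rows.append(
            {
                "displacement": d,
                "reaction": reaction,
                "n_damaged": int((D > 0).sum()),
                "n_failed": int(failed.sum()),
                "max_D": float(D.max()),
                "stagger_converged": converged,
            }
        )
        peak = max(peak, reaction)
        if (
            config.load_drop_fraction is not None
            and failed.any()
            and reaction < (1.0 - config.load_drop_fraction) * peak
        ):
            termination = "load_drop"
            stop = True
        elif config.percolation and check_percolation(mesh, failed):
            termination = "percolation"
            stop = True

    records = pd.DataFrame(rows)
    return SimulationResult(
        records=records,
        kappa=kappa,
        D=D,
        failed=failed,
        termination_reason=termination,
        criterion=config.criterion,
        config=config,
        provenance={"geometry_hash": mesh.geometry_hash(), "n_elements": E},
        warnings=warnings,
    )
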