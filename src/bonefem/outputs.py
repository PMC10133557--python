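"""Writers for run artifacts: curve CSV, VTU damage field, JSON summary.

Every output directory is self-describing: the summary embeds the fully
resolved configuration, its content hash, the package version and the
mesh geometry hash.  Outputs are byte-identical across reruns of the same
configuration and seed (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .fracture import SimulationResult
from .postprocess import FractureSummary
from .specimen import HexMesh

__all__ = ["write_outputs", "write_vtu", "check_writable"]

_CSV_HEADER = (
    "# load-displacement curve; units: displacement mm, reaction N\n"
    "displacement,reaction,n_damaged,n_failed,max_D\n"
)


def check_writable(out_dir: str | Path) -> Path:
    """Create the output directory early and fail before any computation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    probe.unlink()
    return out


def write_curve_csv(result: SimulationResult, path: Path) -> None:
    rows = [
        f"{r.displacement:.9g},{r.reaction:.9g},{int(r.n_damaged)},"
        f"{int(r.n_failed)},{r.max_D:.9g}"
        for r in result.records.itertuples()
    ]
    path.write_text(_CSV_HEADER + "\n".join(rows) + "\n")


def write_vtu(mesh: HexMesh, cell_data: dict[str, np.ndarray], path: Path) -> None:
    """Write the mesh with per-element scalar fields as an ASCII VTU file.

    Plain XML unstructured-grid format (hexahedron cell type), openable in
    ParaView and other standard viewers.
    """
    pts = mesh.node_coords
    conn = mesh.elements
    n_pts, n_cells = len(pts), len(conn)
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join("          " + " ".join(f"{x:.9g}" for x in p) for p in pts),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join("          " + " ".join(str(i) for i in c) for c in conn),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(str(8 * (i + 1)) for i in range(n_cells)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + " ".join("12" for _ in range(n_cells)),
        "        </DataArray>",
        "      </Cells>",
        "      <CellData>",
    ]
    for name, values in cell_data.items():
        arr = np.asarray(values)
        vtype = "Float64" if np.issubdtype(arr.dtype, np.floating) else "Int32"
        parts += [
            f'        <DataArray type="{vtype}" Name="{name}" format="ascii">',
            "          " + " ".join(f"{v:.9g}" if vtype == "Float64" else str(int(v)) for v in arr),
            "        </DataArray>",
        ]
    parts += [
        "      </CellData>",
        "    </Piece>",
        "  </UnstructuredGrid>",
        "</VTKFile>",
        "",
    ]
    path.write_text("\n".join(parts))


def write_outputs(
    result: SimulationResult,
    summary: FractureSummary,
    mesh: HexMesh,
    out_dir: str | Path,
    config_echo: dict[str, Any] | None = None,
    config_hash: str | None = None,
    write_field: bool = True,
) -> dict[str, Path]:
    """Write curve.csv, field.vtu, summary.json and run.log to out_dir."""
    out = check_writable(out_dir)
    files: dict[str, Path] = {}

    files["curve"] = out / "curve.csv"
    write_curve_csv(result, files["curve"])

    if write_field:
        files["field"] = out / "field.vtu"
        write_vtu(
            mesh,
            {"damage": result.D, "failed": result.failed.astype(np.int32)},
            files["field"],
        )

    payload = {
        "units": {"length": "mm", "force": "N", "modulus": "MPa"},
        "package_version": __version__,
        "summary": summary.to_dict(),
        "termination_reason": result.termination_reason,
        "stagger_warnings": result.warnings,
        "provenance": dict(result.provenance),
        "config": config_echo,
        "config_hash": config_hash,
        "boundary_note": (
            "rigid platen contact approximated by nodal constraints: "
            "bottom frictionless, top per boundary.top_mode (stick stands in "
            "for the penalty-friction platen)"
        ),
    }
    files["summary"] = out / "summary.json"
    files["summary"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    log_lines = [
        f"increment displacement={r.displacement:.6g} mm reaction={r.reaction:.6g} N "
        f"n_damaged={int(r.n_damaged)} n_failed={int(r.n_failed)} max_D={r.max_D:.4g} "
        f"converged={bool(r.stagger_converged)}"
        for r in result.records.itertuples()
    ]
    files["log"] = out / "run.log"
    files["log"].write_text("\n".join(log_lines) + "\n")
    return files
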