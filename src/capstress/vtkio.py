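"""Minimal legacy-ASCII VTK writer for quadratic-quad unstructured grids."""

from __future__ import annotations

import numpy as np

VTK_QUADRATIC_QUAD = 23


def write_vtk(
    path,
    nodes: np.ndarray,
    elements: np.ndarray,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "capstress",
) -> None:
    """Write a Q8 mesh with optional per-cell / per-point fields.

    ``nodes`` is (N, 2) in mm (z set to 0); ``elements`` is (E, 8) node
    indices in the corner-then-midside order that VTK's quadratic quad uses
    natively. String-valued cell data is encoded as integer codes with the
    lookup written into the array name.
    """
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    for x, y in nodes:
        lines.append(f"{x:.12g} {y:.12g} 0")
    lines.append(f"CELLS {len(elements)} {len(elements) * 9}")
    for conn in elements:
        lines.append("8 " + " ".join(str(i) for i in conn))
    lines.append(f"CELL_TYPES {len(elements)}")
    lines.extend([str(VTK_QUADRATIC_QUAD)] * len(elements))

    def emit(block: dict[str, np.ndarray], n: int, header: str) -> None:
        lines.append(f"{header} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in "US":
                labels = sorted(set(arr.tolist()))
                codes = {lab: i for i, lab in enumerate(labels)}
                tag = "|".join(f"{codes[lab]}={lab}" for lab in labels)
                arr = np.array([codes[v] for v in arr], dtype=int)
                name = f"{name}({tag})"
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.12g}" for v in arr.astype(float))
            else:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    vals = list(row.astype(float)) + [0.0] * (3 - arr.shape[1])
                    lines.append(" ".join(f"{v:.12g}" for v in vals))

    if cell_data:
        emit(cell_data, len(elements), "CELL_DATA")
    if point_data:
        emit(point_data, len(nodes), "POINT_DATA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
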