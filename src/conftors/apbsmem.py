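"""Grid-parameter generation for membrane Poisson–Boltzmann runs (APBSmem).

Only the configuration is produced here — the focusing grid hierarchy,
ion species, and the membrane z-scan plan; running the electrostatics
solver itself is out of scope. The conventions:

* fine grid x/y extents come from the solver input template for the
  protein; the fine z extent is ``-2 * z_min + 40`` A, where ``z_min`` is
  the smallest z coordinate in the PQR file, so the whole protein stays
  inside the fine grid even when the membrane is scanned over +/- 20 A;
* medium grid = 2 x fine, coarse grid = 5 x fine (componentwise);
* grid dimension is 161 points per axis;
* mobile ions are 150 mM Na+ (radius 0.95 A) and Cl- (radius 1.81 A).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import ParseError

__all__ = ["GridSpec", "IonSpecies", "grid_from_pqr", "emit_scan_plan", "write_template"]

GRID_DIMENSION = 161
MEDIUM_FACTOR = 2.0
COARSE_FACTOR = 5.0
Z_SCAN_RANGE = 20.0  # A, membrane displacement scanned symmetrically about OPM placement
FINE_Z_PADDING = 40.0  # A, added to -2*z_min

DEFAULT_IONS = (
    (+1.0, 0.95, 150.0),   # Na+
    (-1.0, 1.81, 150.0),   # Cl-
)


@dataclass(frozen=True)
class IonSpecies:
    charge: float
    radius: float          # A
    concentration: float   # mM


@dataclass
class GridSpec:
    fine: tuple[float, float, float]
    medium: tuple[float, float, float]
    coarse: tuple[float, float, float]
    dimension: int
    membrane_thickness: float
    z_scan_range: float
    ion_species: list[IonSpecies] = field(default_factory=list)

    def __post_init__(self):
        for f, m, c in zip(self.fine, self.medium, self.coarse):
            if abs(m - MEDIUM_FACTOR * f) > 1e-9 or abs(c - COARSE_FACTOR * f) > 1e-9:
                raise ValueError("grid extents must keep the 1:2:5 fine:medium:coarse ratio")

    def to_dict(self) -> dict:
        return {
            "fine": list(self.fine),
            "medium": list(self.medium),
            "coarse": list(self.coarse),
            "dimension": self.dimension,
            "membrane_thickness": self.membrane_thickness,
            "z_scan_range": self.z_scan_range,
            "ion_species": [
                {"charge": i.charge, "radius": i.radius, "concentration_mM": i.concentration}
                for i in self.ion_species
            ],
        }


def read_pqr_coordinates(path) -> np.ndarray:
    """Coordinates (n, 3) from a PQR file (whitespace-separated PDB variant)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such PQR file: {path}")
    coords = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            # ... name res [chain] resnum x y z charge radius
            try:
                x, y, z = (float(v) for v in fields[-5:-2])
            except (ValueError, IndexError):
                raise ParseError(f"{path}:{lineno}: unparseable PQR atom line") from None
            coords.append((x, y, z))
    if not coords:
        raise ParseError(f"{path}: no atoms found")
    return np.asarray(coords)


def grid_from_pqr(pqr, fine_xy: tuple[float, float], membrane_thickness: float) -> GridSpec:
    """Build the focusing-grid specification for one protein.

    ``fine_xy`` is the fine-grid x/y extent taken from the solver input
    template; ``membrane_thickness`` normally comes from the OPM membrane
    model of the same structure.
    """
    coords = read_pqr_coordinates(pqr)
    z_min = float(coords[:, 2].min())
    fine_z = -2.0 * z_min + FINE_Z_PADDING
    fine = (float(fine_xy[0]), float(fine_xy[1]), fine_z)
    return GridSpec(
        fine=fine,
        medium=tuple(MEDIUM_FACTOR * f for f in fine),
        coarse=tuple(COARSE_FACTOR * f for f in fine),
        dimension=GRID_DIMENSION,
        membrane_thickness=float(membrane_thickness),
        z_scan_range=Z_SCAN_RANGE,
        ion_species=[IonSpecies(*ion) for ion in DEFAULT_IONS],
    )


def emit_scan_plan(grid: GridSpec, step: float = 1.0) -> np.ndarray:
    """Membrane z positions to scan: -range .. +range inclusive, 1 A default.

    Zero is the reference (OPM) bilayer placement.
    """
    if step <= 0:
        raise ValueError("scan step must be positive")
    r = grid.z_scan_range
    n = int(round(r / step))
    return np.arange(-n, n + 1) * step


def write_template(grid: GridSpec, out_prefix) -> tuple[Path, Path]:
    """Write a key-value solver template and a JSON grid spec side-car."""
    out_prefix = Path(out_prefix)
    tmpl = out_prefix.with_suffix(".in")
    lines = [
        f"dime {grid.dimension} {grid.dimension} {grid.dimension}",
        "glen_fine {:.3f} {:.3f} {:.3f}".format(*grid.fine),
        "glen_medium {:.3f} {:.3f} {:.3f}".format(*grid.medium),
        "glen_coarse {:.3f} {:.3f} {:.3f}".format(*grid.coarse),
        f"membrane_thickness {grid.membrane_thickness:.3f}",
        "membrane_fill flooding",
        f"z_scan_range {grid.z_scan_range:.1f}",
    ]
    for ion in grid.ion_species:
        lines.append(f"ion {ion.charge:+.0f} {ion.radius:.2f} {ion.concentration:.0f}")
    tmpl.write_text("\n".join(lines) + "\n")
    js = out_prefix.with_suffix(".json")
    js.write_text(json.dumps(grid.to_dict(), indent=2) + "\n")
    return tmpl, js
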