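"""Protein tilt, membrane insertion offsets, and placement comparison.

The protein's principal axis is the bisector of the THX1 and THX2
conftors (the two crossover TM-helix-pair vectors); tilt is the angle
between that axis and the membrane normal, folded into [0, 90] degrees
since an axis has no sign. Membrane placements from different sources
(energy minimisation, geometric fitting, coarse-grained simulation) are
compared as tilt and membrane-center differences against a reference
source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import GeometryError, MembraneError
from .conftor import compute_conftor, registry_by_name
from .geometry import center_of_geometry, vector_angle
from .structure_io import MembraneModel, RegionAnnotation, Structure

__all__ = [
    "PlacementComparison",
    "principal_axis",
    "tilt_angle",
    "membrane_from_leaflets",
    "membrane_z_offset",
    "tm_cog_offset",
    "compare_placements",
]


@dataclass(frozen=True)
class PlacementComparison:
    structure_id: str
    source: str
    tilt_delta: float  # degrees, non-negative magnitude
    z_delta: float     # A, signed along the reference normal


def principal_axis(
    structure: Structure,
    annotation: RegionAnnotation,
    membrane: MembraneModel | None = None,
    registry=None,
    model_index: int = 0,
) -> np.ndarray:
    """Unit bisector of the normalized THX1 and THX2 conftor vectors."""
    specs = registry_by_name(registry)
    v1 = compute_conftor(structure, annotation, specs["THX1"], membrane, model_index).vector
    v2 = compute_conftor(structure, annotation, specs["THX2"], membrane, model_index).vector
    u1 = v1 / np.linalg.norm(v1)
    u2 = v2 / np.linalg.norm(v2)
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm < 1e-9:
        raise GeometryError("THX1 and THX2 are antiparallel; bisector undefined")
    return bisector / norm


def tilt_angle(
    structure: Structure,
    annotation: RegionAnnotation,
    membrane: MembraneModel,
    registry=None,
    model_index: int = 0,
) -> float:
    """Angle between the protein principal axis and the membrane normal.

    Folded into [0, 90] degrees.
    """
    axis = principal_axis(structure, annotation, membrane, registry, model_index)
    angle = vector_angle(axis, membrane.normal)
    return min(angle, 180.0 - angle)


def membrane_from_leaflets(upper_points, lower_points) -> MembraneModel:
    """Membrane model from two leaflet bead point sets (e.g. PO4/NC3 beads).

    normal = unit(COG_upper - COG_lower); center = midpoint of the COGs;
    thickness = |COG_upper - COG_lower|.
    """
    upper = np.asarray(upper_points, dtype=float).reshape(-1, 3)
    lower = np.asarray(lower_points, dtype=float).reshape(-1, 3)
    if upper.size == 0 or lower.size == 0:
        raise MembraneError("both leaflet bead sets must be non-empty")
    cog_u = center_of_geometry(upper)
    cog_l = center_of_geometry(lower)
    sep = cog_u - cog_l
    thickness = float(np.linalg.norm(sep))
    if thickness < 1e-9:
        raise MembraneError("leaflet centres coincide; membrane normal undefined")
    return MembraneModel(center=(cog_u + cog_l) / 2, normal=sep / thickness, thickness=thickness)


def membrane_z_offset(candidate: MembraneModel, reference: MembraneModel) -> float:
    """Signed distance between membrane centers along the reference normal (A).

    Both models must already be in one coordinate frame (superpose the
    structures first). Positive = candidate center lies toward the
    extracellular side of the reference center.
    """
    return float(np.dot(candidate.center - reference.center, reference.normal))


def tm_cog_offset(
    structure: Structure,
    annotation: RegionAnnotation,
    membrane: MembraneModel,
    model_index: int = 0,
) -> float:
    """Signed offset of the TM-helix Cα COG from the membrane center (A).

    Measured along the membrane normal; a well-placed bilayer gives values
    near zero for a symmetric transporter.
    """
    model = structure.models[model_index]
    pts = []
    for name in annotation.region_names():
        if not name.startswith("TH"):
            continue
        entry = annotation.get(name)
        atoms = model.ca_range(entry.chain_id, entry.start_residue, entry.end_residue)
        pts.extend(a.position for a in atoms)
    if not pts:
        raise MembraneError("no annotated TM helices with resolved Cα")
    cog = center_of_geometry(pts)
    return float(np.dot(cog - membrane.center, membrane.normal))


def compare_placements(
    structure_id: str,
    placements: dict[str, tuple[float, float]],
    reference_source: str = "OPM",
) -> list[PlacementComparison]:
    """Tilt/z deltas of each placement source versus a reference source.

    ``placements`` maps source name -> (tilt degrees, membrane-center z A).
    Tilt deltas are reported as non-negative magnitudes, z deltas signed.
    """
    if reference_source not in placements:
        raise MembraneError(f"reference source {reference_source!r} not among placements")
    ref_tilt, ref_z = placements[reference_source]
    rows = []
    for source in sorted(placements, key=lambda s: (s != reference_source, s)):
        tilt, z = placements[source]
        rows.append(
            PlacementComparison(
                structure_id=structure_id,
                source=source,
                tilt_delta=abs(tilt - ref_tilt),
                z_delta=z - ref_z,
            )
        )
    return rows
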