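"""Per-helix geometry and 2D helix-end projections.

Helix bending/twist/rise follow the HELANAL scheme: local helix axes are
fitted to every four consecutive Cα (Sugeta–Miyazawa construction, via
:mod:`MDAnalysis.analysis.helix_analysis`), and a bending angle is assigned
to each 9-residue sliding window as the angle between the local axes of the
window's first and last four residues. A straight helix gives near-zero
bending everywhere; a broken or kinked helix produces a contiguous peak of
bending angles at the windows spanning the break, which is how aberrant
TM helices (e.g. broken helices in low-resolution structures) are flagged.

Helix-end projections drop the intracellular and extracellular end anchors
of each TM helix onto the membrane plane, giving the 2D helix-arrangement
maps used to compare helix packing across structures (after superposing
every structure onto a common reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from MDAnalysis.analysis import helix_analysis as _hel

from ._errors import GeometryError, MembraneError
from .conftor import AnchorTarget
from .conftor import _helix_end_point  # shared end-anchor resolution
from .geometry import kabsch_superpose, vector_angle
from .structure_io import MembraneModel, RegionAnnotation, Structure

__all__ = [
    "HelixGeometry",
    "EndProjection",
    "helanal_geometry",
    "detect_breaks",
    "project_helix_ends",
    "compare_end_projections",
]

WINDOW = 9  # residues per sliding window; local axes come from 4-Cα fits


@dataclass
class HelixGeometry:
    helix_name: str
    window_axes: np.ndarray        # (n-8, 3) unit vectors
    bending_angles: np.ndarray     # (n-8,) degrees, one per window
    max_bending: float
    overall_axis: np.ndarray       # unit vector
    twist_per_residue: float       # degrees
    rise_per_residue: float        # A

    @property
    def n_windows(self) -> int:
        return len(self.window_axes)


@dataclass(frozen=True)
class EndProjection:
    helix_name: str
    side: str            # intracellular | extracellular
    xy: np.ndarray       # A, coordinates in the membrane plane


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length axis")
    return v / n


def helanal_geometry(ca_coords, helix_name: str = "") -> HelixGeometry:
    """HELANAL-style helix geometry from an ordered Cα trace (n >= 9).

    Local axes are Sugeta–Miyazawa fits to 4 consecutive Cα. Window ``i``
    (residues ``i .. i+8``) gets the mean of its six local axes as its
    window axis and the angle between its first and last local axis
    (residues ``i..i+3`` vs ``i+5..i+8``) as its bending angle.
    """
    ca = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    n = ca.shape[0]
    if n < WINDOW:
        raise GeometryError(f"helix analysis needs >= {WINDOW} residues, got {n}")
    out = _hel.helix_analysis(ca)
    local_axes = np.asarray(out["local_axes"])            # (n-3, 3)
    n_win = n - WINDOW + 1
    window_axes = np.empty((n_win, 3))
    bending = np.empty(n_win)
    for i in range(n_win):
        window_axes[i] = _unit(local_axes[i : i + 6].mean(axis=0))
        bending[i] = vector_angle(local_axes[i], local_axes[i + 5])
    # overall axis: principal direction of the window axes, signed toward
    # their mean so it points the same way as the helix
    mean_axis = window_axes.mean(axis=0)
    _, _, vt = np.linalg.svd(window_axes, full_matrices=False)
    overall = vt[0] if np.dot(vt[0], mean_axis) >= 0 else -vt[0]
    return HelixGeometry(
        helix_name=helix_name,
        window_axes=window_axes,
        bending_angles=bending,
        max_bending=float(bending.max()),
        overall_axis=_unit(overall),
        twist_per_residue=float(np.mean(out["local_twists"])),
        rise_per_residue=float(np.mean(out["local_heights"])),
    )


def detect_breaks(geometry: HelixGeometry, threshold: float = 20.0):
    """Windows whose bending exceeds ``threshold`` degrees, worst first."""
    hits = [
        (int(i), float(b))
        for i, b in enumerate(geometry.bending_angles)
        if b > threshold
    ]
    hits.sort(key=lambda t: -t[1])
    return hits


# --- end projections ---------------------------------------------------------


def _plane_basis(membrane: MembraneModel) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (e1, e2) with e2 = n x e1."""
    n = membrane.normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = _unit(seed - np.dot(seed, n) * n)
    e2 = np.cross(n, e1)
    return e1, e2


def _shared_annotated_ca(structure, annotation, regions):
    pts = []
    for name in regions:
        entry = annotation.get(name)
        atoms = structure.model.ca_range(entry.chain_id, entry.start_residue, entry.end_residue)
        pts.extend(a.position for a in atoms)
    return np.asarray(pts)


def project_helix_ends(
    structure: Structure,
    annotation: RegionAnnotation,
    membrane: MembraneModel,
    reference: Structure | None = None,
    reference_annotation: RegionAnnotation | None = None,
    window: int = 1,
) -> list[EndProjection]:
    """Project the TM-helix end anchors onto the membrane plane.

    When a ``reference`` structure is given, the structure is first
    superposed onto it over the shared annotated TM Cα so that projections
    from different structures share one coordinate frame; the membrane
    model must then be the reference's. Returns one 2D point per annotated
    TM helix and side.
    """
    if membrane is None:
        raise MembraneError("helix-end projection needs a membrane model")
    th_regions = [r for r in annotation.region_names() if r.startswith("TH")]
    model = structure.models[0]
    transform = None
    if reference is not None:
        ref_ann = reference_annotation or annotation
        ref_regions = [r for r in ref_ann.region_names() if r.startswith("TH")]
        shared = sorted(set(th_regions) & set(ref_regions))
        mob = _shared_annotated_ca(structure, annotation, shared)
        ref = _shared_annotated_ca(reference, ref_ann, shared)
        if mob.shape != ref.shape:
            raise GeometryError(
                "structure and reference resolve different Cα counts over shared TM helices"
            )
        transform, _ = kabsch_superpose(mob, ref)
    e1, e2 = _plane_basis(membrane)
    out = []
    for region in th_regions:
        for side in ("intracellular", "extracellular"):
            p = _helix_end_point(model, annotation, AnchorTarget(region, side, window), membrane)
            if transform is not None:
                p = transform.apply(p)
            rel = p - membrane.center
            out.append(
                EndProjection(
                    helix_name=region,
                    side=side,
                    xy=np.array([np.dot(rel, e1), np.dot(rel, e2)]),
                )
            )
    return out


def compare_end_projections(
    a: list[EndProjection],
    b: list[EndProjection],
    outlier_threshold: float = 5.0,
):
    """Per-helix in-plane displacement between two projection sets.

    Both sets must cover the same (helix, side) keys and be expressed in a
    common reference frame. Returns (helix, side, displacement A, outlier)
    rows; displacements above ``outlier_threshold`` are flagged — the tool
    for spotting a relocated helix among otherwise similar structures.
    """
    amap = {(p.helix_name, p.side): p.xy for p in a}
    bmap = {(p.helix_name, p.side): p.xy for p in b}
    if set(amap) != set(bmap):
        only_a = sorted(set(amap) - set(bmap))
        only_b = sorted(set(bmap) - set(amap))
        raise GeometryError(f"projection key mismatch: only-in-a={only_a}, only-in-b={only_b}")
    rows = []
    for key in sorted(amap):
        d = float(np.linalg.norm(amap[key] - bmap[key]))
        rows.append((key[0], key[1], d, d > outlier_threshold))
    return rows
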