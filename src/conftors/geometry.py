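"""Rigid-body and vector primitives.

Superposition follows the Kabsch algorithm (proper rotations only), done
through :class:`scipy.spatial.transform.Rotation`, which handles the
reflection case of the underlying SVD. Angles are computed on clipped
normalized dot products so floating-point overshoot never leaks NaNs out
of ``arccos``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._errors import GeometryError
from .structure_io import RegionAnnotation, Structure

__all__ = [
    "RigidTransform",
    "center_of_geometry",
    "vector_angle",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
]


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation


def center_of_geometry(points) -> np.ndarray:
    """Unweighted arithmetic mean of a non-empty set of 3D points."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise GeometryError("center_of_geometry of an empty point set")
    return points.reshape(-1, 3).mean(axis=0)


def vector_angle(a, b) -> float:
    """Angle between two non-zero vectors, degrees in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise GeometryError("angle with a zero-length vector is undefined")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _check_not_collinear(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError(f"{label} point set is (near-)collinear; superposition underdetermined")


def kabsch_superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rigid transform and the minimized RMSD (A).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"point-count mismatch: mobile {mobile.shape[0]} vs reference {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    _check_not_collinear(mobile, "mobile")
    _check_not_collinear(reference, "reference")
    cog_m = mobile.mean(axis=0)
    cog_r = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cog_r, mobile - cog_m)
    rmat = rot.as_matrix()
    transform = RigidTransform(rotation=rmat, translation=cog_r - rmat @ cog_m)
    # recompute the residual from the transformed coordinates: the solver's
    # reported rssd loses precision to cancellation near-zero
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def _selection_ca(structure: Structure, annotation: RegionAnnotation, regions) -> np.ndarray:
    coords = []
    for name in regions:
        entry = annotation.get(name)
        atoms = structure.model.ca_range(entry.chain_id, entry.start_residue, entry.end_residue)
        coords.extend(a.position for a in atoms)
    return np.asarray(coords, dtype=float)


def pairwise_rmsd_matrix(
    structures: list[Structure],
    annotation: RegionAnnotation | list[RegionAnnotation],
    selection: list[str] | None = None,
) -> np.ndarray:
    """Symmetric matrix of superposed Cα RMSD over an annotated core.

    ``selection`` defaults to the TM helices (TH1-TH12 where annotated);
    every structure must resolve the same number of Cα for the selection.
    A single annotation may be shared, or one given per structure.
    """
    if isinstance(annotation, RegionAnnotation):
        annotations = [annotation] * len(structures)
    else:
        annotations = list(annotation)
    if selection is None:
        selection = [r for r in annotations[0].region_names() if r.startswith("TH")]
    sets = [_selection_ca(s, a, selection) for s, a in zip(structures, annotations)]
    lengths = {pts.shape[0] for pts in sets}
    if len(lengths) > 1:
        bad = ", ".join(
            f"{s.identifier}({pts.shape[0]})" for s, pts in zip(structures, sets)
        )
        raise GeometryError(f"selection resolves to unequal Cα counts: {bad}")
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rmsd = kabsch_superpose(sets[i], sets[j])
            mat[i, j] = mat[j, i] = rmsd
    return mat
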