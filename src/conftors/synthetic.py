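"""Ground-truth synthetic fixtures.

Everything the metric engine measures can be generated here with exactly
known geometry: ideal and kinked α-helices, OPM-style DUMMY membrane
layers, leaflet bead sheets, and a parameterized "toy transporter" — a
12-pseudo-helix Cα assembly whose conftor angles, NBD distances and
membrane tilt are set analytically by construction.

Exactness trick: anchor helices come in phase-opposed pairs (two parallel
ideal helices whose helical phases differ by 180°), so the COG of any
residue pair sits exactly on the central axis; single anchor helices use
residue counts for which the helical phase completes full turns
(19 residues at 100°/residue for end-to-end vectors, 18 for whole-helix
COGs), so end anchors and COG anchors land exactly on prescribed points.
The fixtures are Cα-only geometric traces, not chemically valid proteins;
every implemented metric consumes Cα coordinates only, so nothing more is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._errors import GeometryError
from .conftor import classify_conformation
from .structure_io import (
    AtomRecord,
    MembraneModel,
    Model,
    RegionAnnotation,
    RegionEntry,
    Structure,
)

__all__ = [
    "ToyTransporterParams",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_opm_dummy_layers",
    "make_leaflet_beads",
    "make_toy_transporter",
    "make_closing_trajectory",
]

HELIX_RADIUS = 2.3   # A, Cα radius about the helix axis
HELIX_RISE = 1.5     # A / residue
HELIX_TWIST = 100.0  # deg / residue
STRAND_RISE = 3.3    # A / residue, straight pseudo-strand

MEMBRANE_HALF = 15.0
N_TM = 19            # 18 * 100 deg = 5 full turns: end-to-end runs along the axis
N_COG = 18           # 18 * 100 deg = 5 full turns: Cα COG sits on the axis


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero vector")
    return v / n


def _frame(axis):
    """Deterministic orthonormal (u, v) perpendicular to ``axis``."""
    axis = _unit(axis)
    seed = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    u = _unit(seed - np.dot(seed, axis) * axis)
    v = np.cross(axis, u)
    return u, v


def make_ideal_helix(
    n_res: int,
    axis=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
    phase: float = 0.0,
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix, first residue nearest ``origin``."""
    if n_res < 4:
        raise GeometryError("an ideal helix needs at least 4 residues")
    axis = _unit(axis)
    origin = np.asarray(origin, dtype=float)
    u, v = _frame(axis)
    k = np.arange(n_res)
    ang = np.deg2rad(phase + k * twist)
    return (
        origin[None, :]
        + np.outer(k * rise, axis)
        + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def make_kinked_helix(
    n1: int,
    n2: int,
    kink_angle: float,
    axis=(0.0, 0.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
) -> np.ndarray:
    """Two ideal arms whose axes enclose ``kink_angle`` at the junction."""
    if n1 < 9 or n2 < 9:
        raise GeometryError("each arm of a kinked helix needs >= 9 residues")
    if not 0.0 <= kink_angle < 180.0:
        raise GeometryError("kink angle must be in [0, 180) degrees")
    axis = _unit(axis)
    origin = np.asarray(origin, dtype=float)
    u, _ = _frame(axis)
    arm1 = make_ideal_helix(n1, axis, origin, rise, twist, radius)
    rot = Rotation.from_rotvec(np.deg2rad(kink_angle) * u)
    axis2 = rot.apply(axis)
    # continue the chain: next axis point one rise along the new axis
    axis_end = origin + (n1 - 1) * rise * axis
    origin2 = axis_end + rise * axis2
    arm2 = make_ideal_helix(n2, axis2, origin2, rise, twist, radius, phase=n1 * twist)
    # keep arm2's helical frame coherent with arm1's by rotating its lateral
    # offsets with the kink
    k = np.arange(n2)
    ang = np.deg2rad(n1 * twist + k * twist)
    u1, v1 = _frame(axis)
    lateral = radius * (np.outer(np.cos(ang), u1) + np.outer(np.sin(ang), v1))
    arm2 = origin2[None, :] + np.outer(k * rise, axis2) + rot.apply(lateral)
    return np.vstack([arm1, arm2])


def make_opm_dummy_layers(
    center=(0.0, 0.0, 0.0),
    half_thickness: float = MEMBRANE_HALF,
    extent: float = 14.0,
    spacing: float = 4.0,
) -> list[AtomRecord]:
    """OPM-style DUM pseudo-atom grids on the two membrane boundary planes."""
    center = np.asarray(center, dtype=float)
    xs = np.arange(-extent, extent + 1e-9, spacing)
    atoms = []
    resnum = 9000
    for sign in (+1.0, -1.0):
        for x in xs:
            for y in xs:
                resnum += 1
                atoms.append(
                    AtomRecord(
                        chain_id="M",
                        residue_number=resnum,
                        insertion_code="",
                        residue_name="DUM",
                        atom_name="O",
                        position=center + np.array([x, y, sign * half_thickness]),
                    )
                )
    return atoms


def make_leaflet_beads(
    center=(0.0, 0.0, 0.0),
    normal=(0.0, 0.0, 1.0),
    thickness: float = 40.0,
    extent: float = 20.0,
    spacing: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two planar leaflet bead sheets (upper, lower) about ``center``."""
    center = np.asarray(center, dtype=float)
    normal = _unit(normal)
    u, v = _frame(normal)
    xs = np.arange(-extent, extent + 1e-9, spacing)
    grid = np.array([[x, y] for x in xs for y in xs])
    plane = grid[:, :1] * u[None, :] + grid[:, 1:] * v[None, :]
    upper = center + plane + (thickness / 2) * normal
    lower = center + plane - (thickness / 2) * normal
    return upper, lower


# --- toy transporter ---------------------------------------------------------


@dataclass(frozen=True)
class ToyTransporterParams:
    thx_angle: float = 40.0       # deg, THX1^THX2
    icv_angle: float = 45.0       # deg, ICV1^ICV2
    nbd_int_distance: float = 60.0  # A, S9-tip separation
    nbd_ext_distance: float = 45.0  # A, coupling-helix COG separation
    tilt: float = 0.0             # deg, protein axis vs membrane normal
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.thx_angle < 170.0:
            raise GeometryError("thx_angle must be in (0, 170) degrees")
        if not 0.0 < self.icv_angle < 170.0:
            raise GeometryError("icv_angle must be in (0, 170) degrees")
        if self.nbd_int_distance <= 0 or self.nbd_ext_distance <= 0:
            raise GeometryError("NBD distances must be positive")
        if not 0.0 <= self.tilt < 60.0:
            raise GeometryError("tilt must be in [0, 60) degrees")


def _helix_records(coords, chain, start_resnum, resname="ALA"):
    return [
        AtomRecord(chain, start_resnum + i, "", resname, "CA", coords[i])
        for i in range(len(coords))
    ]


def _strand(first_point, direction, n_res):
    first_point = np.asarray(first_point, dtype=float)
    d = _unit(direction)
    return first_point[None, :] + np.outer(np.arange(n_res) * STRAND_RISE, d)


def _phase_pair(bottom, direction, n_res, offset_dir, offset=4.0):
    """Two parallel ideal helices whose per-residue Cα COG is the central axis.

    ``bottom`` is the exact central-axis start point; returns (helix_a,
    helix_b) with opposite helical phases and lateral offsets ±offset.
    """
    direction = _unit(direction)
    u, v = _frame(direction)
    off = offset * _unit(offset_dir)
    k = np.arange(n_res)
    ang = np.deg2rad(k * HELIX_TWIST)
    lateral = HELIX_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    axis_pts = np.asarray(bottom, dtype=float)[None, :] + np.outer(k * HELIX_RISE, direction)
    return axis_pts + off + lateral, axis_pts - off - lateral


# fixed residue-number layout of the toy transporter (chain A)
_LAYOUT = {
    **{f"TH{i}": (100 * i + 1, 100 * i + N_TM) for i in range(1, 13)},
    **{f"ICD{i}": (1300 + 100 * (i - 1) + 1, 1300 + 100 * (i - 1) + N_TM) for i in range(1, 5)},
    **{f"CH{i}": (2000 + 100 * i + 1, 2000 + 100 * i + 12) for i in range(1, 5)},
    "WAH1": (3101, 3100 + N_COG),
    "WAH2": (3201, 3200 + N_COG),
    "SIG1": (3301, 3310),
    "SIG2": (3401, 3410),
    "S6_1": (3501, 3508),
    "S6_2": (3601, 3608),
    "S9_1": (3701, 3705),
    "S9_2": (3801, 3805),
}


def toy_annotation() -> RegionAnnotation:
    return RegionAnnotation(
        entries=[RegionEntry(name, "A", lo, hi) for name, (lo, hi) in sorted(_LAYOUT.items())]
    )


def _toy_atoms(params: ToyTransporterParams) -> tuple[list[AtomRecord], dict]:
    """Protein Cα records (untilted frame) plus exact anchor ground truth."""
    a = np.deg2rad(params.thx_angle / 2.0)
    d1 = np.array([np.sin(a), 0.0, np.cos(a)])     # THX1 direction
    d2 = np.array([-np.sin(a), 0.0, np.cos(a)])    # THX2 direction
    b = np.deg2rad(params.icv_angle / 2.0)
    g1 = np.array([-np.sin(b), 0.0, -np.cos(b)])   # ICV1 direction (into cytosol)
    g2 = np.array([np.sin(b), 0.0, -np.cos(b)])    # ICV2 direction
    span = (N_TM - 1) * HELIX_RISE                 # 27 A

    atoms: list[AtomRecord] = []
    yhat = np.array([0.0, 1.0, 0.0])

    # THX pairs: central axes cross the membrane center
    p1 = -span / 2 * d1   # THX1 origin (intracellular end of the pair axis)
    p2 = -span / 2 * d2
    th4, th5 = _phase_pair(p1, d1, N_TM, yhat)
    th10, th11 = _phase_pair(p2, d2, N_TM, yhat)
    atoms += _helix_records(th4, "A", _LAYOUT["TH4"][0])
    atoms += _helix_records(th5, "A", _LAYOUT["TH5"][0])
    atoms += _helix_records(th10, "A", _LAYOUT["TH10"][0])
    atoms += _helix_records(th11, "A", _LAYOUT["TH11"][0])

    # remaining TM helices: vertical decorations on a circle
    rng = np.random.default_rng(params.seed)
    decor = [i for i in range(1, 13) if i not in (4, 5, 10, 11)]
    for idx, i in enumerate(decor):
        ang = 2 * np.pi * idx / len(decor)
        base = np.array([12.0 * np.cos(ang), 12.0 * np.sin(ang), -span / 2])
        coords = make_ideal_helix(
            N_TM, (0, 0, 1), base, phase=float(rng.uniform(0, 360))
        )
        atoms += _helix_records(coords, "A", _LAYOUT[f"TH{i}"][0])

    # intracellular continuations, hanging below the TM pairs
    icd_span = (N_TM - 1) * HELIX_RISE
    q1, q2 = p1, p2
    icd1, icd2 = _phase_pair(q1, g1, N_TM, yhat)   # residue 0 at the membrane end
    icd3, icd4 = _phase_pair(q2, g2, N_TM, yhat)
    atoms += _helix_records(icd1, "A", _LAYOUT["ICD1"][0])
    atoms += _helix_records(icd2, "A", _LAYOUT["ICD2"][0])
    atoms += _helix_records(icd3, "A", _LAYOUT["ICD3"][0])
    atoms += _helix_records(icd4, "A", _LAYOUT["ICD4"][0])

    # coupling-helix clusters: pair COG exactly at c1 / c2
    ext = params.nbd_ext_distance
    c1 = np.array([-ext / 2, 0.0, -19.0])
    c2 = np.array([ext / 2, 0.0, -19.0])
    ch_len = 12
    xhat = np.array([1.0, 0.0, 0.0])
    ch1, ch4 = _phase_pair(c1 - (ch_len - 1) / 2 * HELIX_RISE * yhat, yhat, ch_len, xhat, 3.0)
    ch2, ch3 = _phase_pair(c2 - (ch_len - 1) / 2 * HELIX_RISE * yhat, yhat, ch_len, xhat, 3.0)
    atoms += _helix_records(ch1, "A", _LAYOUT["CH1"][0])
    atoms += _helix_records(ch2, "A", _LAYOUT["CH2"][0])
    atoms += _helix_records(ch3, "A", _LAYOUT["CH3"][0])
    atoms += _helix_records(ch4, "A", _LAYOUT["CH4"][0])

    # S9 strands: first residue exactly at s1 / s2 (NBD bottoms)
    internal = params.nbd_int_distance
    s1 = np.array([-internal / 2, 0.0, -42.0])
    s2 = np.array([internal / 2, 0.0, -42.0])
    atoms += _helix_records(_strand(s1, (0.2, 0.9, -0.37), 5), "A", _LAYOUT["S9_1"][0])
    atoms += _helix_records(_strand(s2, (-0.2, 0.9, -0.37), 5), "A", _LAYOUT["S9_2"][0])

    # Walker A helices: 18 residues -> COG exactly at the axis midpoint
    w1 = np.array([-14.0, 6.0, -35.0])
    w2 = np.array([14.0, 6.0, -35.0])
    wah_half = (N_COG - 1) / 2 * HELIX_RISE
    atoms += _helix_records(
        make_ideal_helix(N_COG, yhat, w1 - wah_half * yhat), "A", _LAYOUT["WAH1"][0]
    )
    atoms += _helix_records(
        make_ideal_helix(N_COG, yhat, w2 - wah_half * yhat), "A", _LAYOUT["WAH2"][0]
    )

    # signature motifs and S6 strands: straight segments, midpoint = COG
    sig1_mid = np.array([-14.0, -6.0, -35.0])
    sig2_mid = np.array([14.0, -6.0, -35.0])
    for name, mid, n in (("SIG1", sig1_mid, 10), ("SIG2", sig2_mid, 10)):
        d = yhat
        first = mid - (n - 1) / 2 * STRAND_RISE * d
        atoms += _helix_records(_strand(first, d, n), "A", _LAYOUT[name][0])
    s6_1_mid = np.array([-8.0, 0.0, -30.0])
    s6_2_mid = np.array([8.0, 0.0, -30.0])
    for name, mid in (("S6_1", s6_1_mid), ("S6_2", s6_2_mid)):
        first = mid - 3.5 * STRAND_RISE * yhat
        atoms += _helix_records(_strand(first, yhat, 8), "A", _LAYOUT[name][0])

    anchors = {
        "thx1": (p1, p1 + span * d1),
        "thx2": (p2, p2 + span * d2),
        "icv1": (q1, q1 + icd_span * g1),
        "icv2": (q2, q2 + icd_span * g2),
        "c1": c1, "c2": c2, "s1": s1, "s2": s2,
        "w1": w1, "w2": w2, "sig1": sig1_mid, "sig2": sig2_mid,
        "s6_1": s6_1_mid, "s6_2": s6_2_mid,
    }
    return atoms, anchors


def make_toy_transporter(
    params: ToyTransporterParams,
) -> tuple[Structure, RegionAnnotation, MembraneModel, dict]:
    """Toy two-pseudo-domain transporter with exactly known metrics.

    Returns (structure, annotation, membrane, ground_truth). Ground-truth
    keys use the metric-request grammar of
    :func:`conftors.conftor.trajectory_metrics` plus ``tilt_deg`` and the
    expected classification label under ``class``.
    """
    atoms, anchors = _toy_atoms(params)
    rot = Rotation.from_rotvec(np.deg2rad(params.tilt) * np.array([1.0, 0.0, 0.0]))
    atoms = [
        AtomRecord(a.chain_id, a.residue_number, a.insertion_code, a.residue_name,
                   a.atom_name, rot.apply(a.position))
        for a in atoms
    ]
    dum = make_opm_dummy_layers()
    structure = Structure(
        identifier=f"toy_thx{params.thx_angle:g}_icv{params.icv_angle:g}_t{params.tilt:g}",
        models=[Model(atoms, dum)],
    )
    membrane = MembraneModel(
        center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), thickness=2 * MEMBRANE_HALF
    )

    gt = {
        "angle:THX1,THX2": params.thx_angle,
        "angle:THV1,THV2": params.thx_angle,
        "angle:ICV1,ICV2": params.icv_angle,
        "angle:ICX1,ICX2": params.icv_angle,
        "length:NBDX:ext": params.nbd_ext_distance,
        "length:NBDX:int": params.nbd_int_distance,
        "length:THX1:span": float((N_TM - 1) * HELIX_RISE),
        "length:WAH:span": float(np.linalg.norm(anchors["w2"] - anchors["w1"])),
        "length:S6:span": float(np.linalg.norm(anchors["s6_2"] - anchors["s6_1"])),
        "length:WAH1_SIG2:span": float(np.linalg.norm(anchors["sig2"] - anchors["w1"])),
        "length:WAH2_SIG1:span": float(np.linalg.norm(anchors["sig1"] - anchors["w2"])),
        "tilt_deg": params.tilt,
    }
    gt["class"] = classify_conformation(
        {
            "THX": params.thx_angle,
            "ICV": params.icv_angle,
            "NBDX_ext": params.nbd_ext_distance,
        }
    ).label
    return structure, toy_annotation(), membrane, gt


def make_closing_trajectory(
    start_params: ToyTransporterParams,
    end_params: ToyTransporterParams,
    n_frames: int,
) -> tuple[Structure, RegionAnnotation, MembraneModel, dict]:
    """Multi-model toy trajectory interpolating the parameters linearly.

    Ground truth maps each metric key to its per-frame value list.
    """
    if n_frames < 2:
        raise GeometryError("a trajectory needs at least 2 frames")
    fractions = np.linspace(0.0, 1.0, n_frames)
    models = []
    gt_frames = []
    for f in fractions:
        params = ToyTransporterParams(
            thx_angle=(1 - f) * start_params.thx_angle + f * end_params.thx_angle,
            icv_angle=(1 - f) * start_params.icv_angle + f * end_params.icv_angle,
            nbd_int_distance=(1 - f) * start_params.nbd_int_distance + f * end_params.nbd_int_distance,
            nbd_ext_distance=(1 - f) * start_params.nbd_ext_distance + f * end_params.nbd_ext_distance,
            tilt=(1 - f) * start_params.tilt + f * end_params.tilt,
            seed=start_params.seed,
        )
        frame, _, membrane, gt = make_toy_transporter(params)
        models.append(frame.models[0])
        gt_frames.append(gt)
    structure = Structure(identifier="toy_trajectory", models=models)
    series_gt = {
        key: [g[key] for g in gt_frames]
        for key in gt_frames[0]
        if key not in ("class",)
    }
    return structure, toy_annotation(), membrane, series_gt
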