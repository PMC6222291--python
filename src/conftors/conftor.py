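"""Conformational vectors ("conftors") for ABC Type I exporters.

A conftor is a directed segment between two anchor points of a structure —
a single Cα or the centre of geometry (COG) of a Cα set — chosen so that
its direction tracks the orientation of a domain. Angles between conftors
and distances between their endpoints quantify differences between
transporter conformations that a global RMSD blurs together:

* ``THV1/THV2``   — single TM-helix vectors (membrane-embedded parts),
  pointing from the intracellular to the extracellular helix end.
* ``THX1/THX2``   — like THV but anchored on the COG of the end Cα of the
  two helix pairs TH4–TH5 and TH10–TH11, the helices that cross over from
  one TM domain to the opposite nucleotide binding domain (NBD). The
  THX1^THX2 angle separates the four canonical conformation classes.
* ``ICV1/ICV2, ICX1/ICX2`` — the intracellular continuations of the same
  helices; the ICV1^ICV2 angle separates inward-facing, outward-facing
  and occluded states.
* ``NBDV1/NBDV2, NBDX1/NBDX2`` — from coupling-helix COGs to the first
  residue of strand S9, the last NBD strand. The distance between the two
  NBDX origins ("ext", the TMD/NBD interface separation) and between the
  two tips ("int", the NBD bottom separation) track NBD opening/closure.
* ``S6, WAH, WAH1_SIG2, WAH2_SIG1`` — inter-NBD vectors between opposite
  S6 strands, Walker A helices, and Walker-A-to-signature motif pairs
  (the two composite ATP sites).

Angles between conftors of one structure are invariant under rigid-body
motion, so no prior superposition to a reference is required for any
metric computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import AnchorError, AnnotationError
from .geometry import center_of_geometry, vector_angle
from .structure_io import MembraneModel, Model, RegionAnnotation, Structure, resolve_ca

__all__ = [
    "AnchorTarget",
    "AnchorSpec",
    "ConftorSpec",
    "Conftor",
    "ConformationClass",
    "MetricSeries",
    "CLASS_PROTOTYPES",
    "builtin_conftor_registry",
    "compute_conftor",
    "conftor_angle_metric",
    "conftor_length_metric",
    "classify_conformation",
    "trajectory_metrics",
]

MIN_CONFTOR_LENGTH = 0.5  # A; anchors closer than this give no usable direction

WHICH_END = ("intracellular", "extracellular", "whole", "first", "last")


@dataclass(frozen=True)
class AnchorTarget:
    region_name: str
    which_end: str = "whole"
    window: int = 1

    def __post_init__(self):
        if self.which_end not in WHICH_END:
            raise ValueError(f"which_end must be one of {WHICH_END}, got {self.which_end!r}")
        if self.window < 1:
            raise ValueError("window must be >= 1 residue")


@dataclass(frozen=True)
class AnchorSpec:
    """How one conftor endpoint is derived from annotated regions.

    kinds
    -----
    ``single_ca``         one Cα (first/last residue of one region)
    ``cog_of_residues``   COG of all Cα across the target regions
    ``cog_of_helix_ends`` COG of the terminal-window Cα of each target
                          region's intracellular or extracellular end
    """

    kind: str
    targets: tuple[AnchorTarget, ...]

    def __post_init__(self):
        if self.kind not in ("single_ca", "cog_of_residues", "cog_of_helix_ends"):
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.kind == "single_ca" and len(self.targets) != 1:
            raise ValueError("single_ca anchor takes exactly one target")
        if not self.targets:
            raise ValueError("anchor needs at least one target")

    def region_names(self) -> list[str]:
        return [t.region_name for t in self.targets]


@dataclass(frozen=True)
class ConftorSpec:
    name: str
    origin: AnchorSpec
    tip: AnchorSpec
    # orient="along_normal": the vector must point intracellular -> extracellular
    # (checked against the membrane normal when one is available)
    orient: str | None = None


@dataclass(frozen=True)
class Conftor:
    name: str
    origin_point: np.ndarray
    tip_point: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.tip_point - self.origin_point

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class ConformationClass:
    label: str
    prototype_angles: dict[str, float]
    distances: dict[str, float]
    ambiguity_flag: bool


@dataclass
class MetricSeries:
    metric_name: str
    frame_indices: list[int]
    values: list[float]
    units: str = ""

    def __post_init__(self):
        if len(self.frame_indices) != len(self.values):
            raise ValueError("frame_indices and values must have equal length")


# Class-average angle signatures (degrees) of the four conformation classes,
# as measured on the curated exporter structure set. THX = THX1^THX2 angle,
# ICV = ICV1^ICV2 angle. THV (THV1^THV2) only isolates the occluded class
# (23 deg vs 36-40 deg for everything else) and is not used for assignment.
CLASS_PROTOTYPES: dict[str, dict[str, float]] = {
    "bottom_open_inward_facing": {"THX": 46.0, "ICV": 43.0},
    "bottom_closed_inward_facing": {"THX": 39.0, "ICV": 38.0},
    "bottom_closed_outward_facing": {"THX": 35.0, "ICV": 60.0},
    "occluded": {"THX": 26.0, "ICV": 53.0},
}

THV_OCCLUDED_MEAN = 23.0
THV_OTHER_RANGE = (36.0, 40.0)

# Inward-facing sub-class boundary on the NBDX "ext" distance (coupling-helix
# interface separation, A): bottom-open structures splay the NBDs apart,
# bottom-closed ones keep the interfaces near contact.
NBD_EXT_OPEN_BOUNDARY = 40.0


def builtin_conftor_registry() -> list[ConftorSpec]:
    """The standard ABC Type I exporter conftor set.

    Region names follow the annotation vocabulary (TH1-12, ICD1-4, CH1-4,
    WAH1/2, SIG1/2, S6_1/2, S9_1/2). Which coupling helices feed NBDX1
    versus NBDX2 follows the domain-swapped architecture and is remapped
    simply by renaming regions in the annotation file.
    """

    def end(region, side, window=1):
        return AnchorSpec("cog_of_helix_ends", (AnchorTarget(region, side, window),))

    def ends(regions, side, window=1):
        return AnchorSpec(
            "cog_of_helix_ends", tuple(AnchorTarget(r, side, window) for r in regions)
        )

    def cog(*regions):
        return AnchorSpec("cog_of_residues", tuple(AnchorTarget(r, "whole") for r in regions))

    def first_ca(region):
        return AnchorSpec("single_ca", (AnchorTarget(region, "first"),))

    specs = [
        # membrane-embedded TM vectors: intracellular -> extracellular
        ConftorSpec("THV1", end("TH4", "intracellular"), end("TH4", "extracellular"), "along_normal"),
        ConftorSpec("THV2", end("TH10", "intracellular"), end("TH10", "extracellular"), "along_normal"),
        ConftorSpec(
            "THX1",
            ends(("TH4", "TH5"), "intracellular"),
            ends(("TH4", "TH5"), "extracellular"),
            "along_normal",
        ),
        ConftorSpec(
            "THX2",
            ends(("TH10", "TH11"), "intracellular"),
            ends(("TH10", "TH11"), "extracellular"),
            "along_normal",
        ),
        # intracellular continuations: membrane-proximal end -> cytosolic end
        ConftorSpec("ICV1", end("ICD1", "extracellular"), end("ICD1", "intracellular")),
        ConftorSpec("ICV2", end("ICD3", "extracellular"), end("ICD3", "intracellular")),
        ConftorSpec(
            "ICX1",
            ends(("ICD1", "ICD2"), "extracellular"),
            ends(("ICD1", "ICD2"), "intracellular"),
        ),
        ConftorSpec(
            "ICX2",
            ends(("ICD3", "ICD4"), "extracellular"),
            ends(("ICD3", "ICD4"), "intracellular"),
        ),
        # NBD vectors: coupling-helix COG -> first residue of strand S9
        ConftorSpec("NBDV1", cog("CH1"), first_ca("S9_1")),
        ConftorSpec("NBDV2", cog("CH3"), first_ca("S9_2")),
        ConftorSpec("NBDX1", cog("CH1", "CH4"), first_ca("S9_1")),
        ConftorSpec("NBDX2", cog("CH2", "CH3"), first_ca("S9_2")),
        # inter-NBD vectors
        ConftorSpec("S6", cog("S6_1"), cog("S6_2")),
        ConftorSpec("WAH", cog("WAH1"), cog("WAH2")),
        ConftorSpec("WAH1_SIG2", cog("WAH1"), cog("SIG2")),
        ConftorSpec("WAH2_SIG1", cog("WAH2"), cog("SIG1")),
    ]
    return specs


def registry_by_name(registry=None) -> dict[str, ConftorSpec]:
    registry = registry if registry is not None else builtin_conftor_registry()
    return {s.name: s for s in registry}


# --- anchor resolution -------------------------------------------------------


def _region_cas(model: Model, annotation: RegionAnnotation, region_name: str):
    entry = annotation.get(region_name)
    atoms = model.ca_range(entry.chain_id, entry.start_residue, entry.end_residue)
    if not atoms:
        raise AnchorError(f"region {region_name}: no resolved Cα in annotated range")
    return entry, atoms


def _nbd_proxy_cog(model: Model, annotation: RegionAnnotation) -> np.ndarray | None:
    """COG of NBD-motif Cα, used to orient helix ends when no membrane is given."""
    pts = []
    for name in ("WAH1", "WAH2", "SIG1", "SIG2", "S9_1", "S9_2"):
        if annotation.has(name):
            try:
                _, atoms = _region_cas(model, annotation, name)
            except AnchorError:
                continue
            pts.extend(a.position for a in atoms)
    return center_of_geometry(pts) if pts else None


def _helix_end_point(
    model: Model,
    annotation: RegionAnnotation,
    target: AnchorTarget,
    membrane: MembraneModel | None,
) -> np.ndarray:
    entry, atoms = _region_cas(model, annotation, target.region_name)
    w = min(target.window, len(atoms))
    first = center_of_geometry([a.position for a in atoms[:w]])
    last = center_of_geometry([a.position for a in atoms[-w:]])
    side = target.which_end
    if side == "first":
        return first
    if side == "last":
        return last
    if side == "whole":
        return center_of_geometry([a.position for a in atoms])
    if membrane is not None:
        z_first = float(np.dot(first - membrane.center, membrane.normal))
        z_last = float(np.dot(last - membrane.center, membrane.normal))
        intracellular_is_first = z_first < z_last
    else:
        nbd = _nbd_proxy_cog(model, annotation)
        if nbd is None:
            raise AnchorError(
                f"region {target.region_name}: cannot orient helix ends without a "
                "membrane model or annotated NBD motifs"
            )
        intracellular_is_first = np.linalg.norm(first - nbd) < np.linalg.norm(last - nbd)
    if side == "intracellular":
        return first if intracellular_is_first else last
    return last if intracellular_is_first else first


def _resolve_anchor(
    model: Model,
    annotation: RegionAnnotation,
    anchor: AnchorSpec,
    membrane: MembraneModel | None,
) -> np.ndarray:
    if anchor.kind == "single_ca":
        target = anchor.targets[0]
        entry = annotation.get(target.region_name)
        residue = entry.start_residue if target.which_end in ("first", "whole") else entry.end_residue
        if target.which_end in ("intracellular", "extracellular"):
            return _helix_end_point(model, annotation, target, membrane)
        return resolve_ca(model, entry.chain_id, residue).position
    if anchor.kind == "cog_of_residues":
        pts = []
        for target in anchor.targets:
            _, atoms = _region_cas(model, annotation, target.region_name)
            pts.extend(a.position for a in atoms)
        return center_of_geometry(pts)
    # cog_of_helix_ends
    pts = [_helix_end_point(model, annotation, t, membrane) for t in anchor.targets]
    return center_of_geometry(pts)


def compute_conftor(
    structure: Structure,
    annotation: RegionAnnotation,
    spec: ConftorSpec,
    membrane: MembraneModel | None = None,
    model_index: int = 0,
) -> Conftor:
    """Resolve a conftor's anchors on one model of a structure.

    TM-class conftors (``orient="along_normal"``) are checked against the
    membrane normal when a membrane model is available and flipped (with a
    warning) if they point extracellular -> intracellular.
    """
    annotation.require(set(spec.origin.region_names()) | set(spec.tip.region_names()))
    model = structure.models[model_index]
    origin = _resolve_anchor(model, annotation, spec.origin, membrane)
    tip = _resolve_anchor(model, annotation, spec.tip, membrane)
    vec = tip - origin
    if np.linalg.norm(vec) <= MIN_CONFTOR_LENGTH:
        raise AnchorError(
            f"conftor {spec.name}: origin and tip anchors coincide "
            f"(separation {np.linalg.norm(vec):.3f} A)"
        )
    if spec.orient == "along_normal" and membrane is not None:
        if float(np.dot(vec, membrane.normal)) < 0:
            warnings.warn(
                f"conftor {spec.name} pointed against the membrane normal; "
                "flipping to the intracellular->extracellular convention",
                stacklevel=2,
            )
            origin, tip = tip, origin
    return Conftor(name=spec.name, origin_point=origin, tip_point=tip)


# --- scalar metrics ----------------------------------------------------------


def conftor_angle_metric(
    structure: Structure,
    annotation: RegionAnnotation,
    name_a: str,
    name_b: str,
    membrane: MembraneModel | None = None,
    registry=None,
    model_index: int = 0,
) -> float:
    """Angle (degrees) between two named conftors of one structure."""
    specs = registry_by_name(registry)
    for name in (name_a, name_b):
        if name not in specs:
            raise AnnotationError(f"unknown conftor {name!r}")
    ca = compute_conftor(structure, annotation, specs[name_a], membrane, model_index)
    cb = compute_conftor(structure, annotation, specs[name_b], membrane, model_index)
    return vector_angle(ca.vector, cb.vector)


def conftor_length_metric(
    structure: Structure,
    annotation: RegionAnnotation,
    name: str,
    endpoint_pair: str = "span",
    membrane: MembraneModel | None = None,
    registry=None,
    model_index: int = 0,
) -> float:
    """Length metric (A) on a conftor or a ``1``/``2`` conftor pair.

    ``span``: |tip - origin| of the conftor ``name``.
    ``ext``:  distance between the origin anchors of ``name+"1"`` and
              ``name+"2"`` (for NBDX: the TMD/NBD interface separation).
    ``int``:  distance between the tip anchors of the pair (for NBDX: the
              separation of the NBD bottoms).
    """
    specs = registry_by_name(registry)
    if endpoint_pair == "span":
        if name not in specs:
            raise AnnotationError(f"unknown conftor {name!r}")
        return compute_conftor(structure, annotation, specs[name], membrane, model_index).length
    if endpoint_pair not in ("ext", "int"):
        raise ValueError("endpoint_pair must be one of span/ext/int")
    n1, n2 = f"{name}1", f"{name}2"
    for n in (n1, n2):
        if n not in specs:
            raise AnnotationError(f"unknown conftor {n!r} (needed for {endpoint_pair})")
    c1 = compute_conftor(structure, annotation, specs[n1], membrane, model_index)
    c2 = compute_conftor(structure, annotation, specs[n2], membrane, model_index)
    if endpoint_pair == "ext":
        return float(np.linalg.norm(c1.origin_point - c2.origin_point))
    return float(np.linalg.norm(c1.tip_point - c2.tip_point))


def classify_conformation(
    metrics: dict[str, float],
    ambiguity_margin: float = 5.0,
    nbd_ext_boundary: float = NBD_EXT_OPEN_BOUNDARY,
) -> ConformationClass:
    """Assign the nearest conformation class in (THX, ICV) angle space.

    ``metrics`` must contain ``"THX"`` and ``"ICV"`` (degrees); an optional
    ``"NBDX_ext"`` (A) breaks ties between the two inward-facing classes.
    The ambiguity flag is raised when the two best classes lie within
    ``ambiguity_margin`` degrees of each other in total distance.
    """
    for key in ("THX", "ICV"):
        if key not in metrics:
            raise AnnotationError(f"classification requires metric {key!r}")
    point = np.array([metrics["THX"], metrics["ICV"]], dtype=float)
    distances = {
        label: float(np.linalg.norm(point - np.array([proto["THX"], proto["ICV"]])))
        for label, proto in CLASS_PROTOTYPES.items()
    }
    ranked = sorted(distances, key=distances.get)
    best, second = ranked[0], ranked[1]
    ambiguous = distances[second] - distances[best] < ambiguity_margin
    inward = {"bottom_open_inward_facing", "bottom_closed_inward_facing"}
    if ambiguous and {best, second} == inward and "NBDX_ext" in metrics:
        best = (
            "bottom_open_inward_facing"
            if metrics["NBDX_ext"] > nbd_ext_boundary
            else "bottom_closed_inward_facing"
        )
        ambiguous = False
    return ConformationClass(
        label=best,
        prototype_angles=dict(CLASS_PROTOTYPES[best]),
        distances=distances,
        ambiguity_flag=ambiguous,
    )


# --- trajectory metrics ------------------------------------------------------


def parse_metric_request(request: str) -> tuple[str, tuple, str]:
    """Parse ``"angle:A,B"`` / ``"length:NAME:ext|int|span"`` into a plan.

    Returns (kind, args, units).
    """
    parts = request.split(":")
    if parts[0] == "angle" and len(parts) == 2 and "," in parts[1]:
        a, b = (p.strip() for p in parts[1].split(",", 1))
        return "angle", (a, b), "deg"
    if parts[0] == "length" and len(parts) == 3 and parts[2] in ("ext", "int", "span"):
        return "length", (parts[1].strip(), parts[2]), "A"
    raise ValueError(
        f"bad metric request {request!r}; use 'angle:A,B' or 'length:NAME:ext|int|span'"
    )


def trajectory_metrics(
    frames: Structure,
    annotation: RegionAnnotation,
    metrics: list[str],
    membrane: MembraneModel | None = None,
    registry=None,
) -> list[MetricSeries]:
    """Evaluate scalar conftor metrics on every model of a frame series."""
    series = []
    for request in metrics:
        kind, args, units = parse_metric_request(request)
        values = []
        for fi in range(frames.n_models):
            try:
                if kind == "angle":
                    v = conftor_angle_metric(
                        frames, annotation, *args, membrane=membrane,
                        registry=registry, model_index=fi,
                    )
                else:
                    name, pair = args
                    v = conftor_length_metric(
                        frames, annotation, name, pair, membrane=membrane,
                        registry=registry, model_index=fi,
                    )
            except (AnchorError, AnnotationError) as exc:
                raise AnchorError(f"frame {fi}: {exc}") from exc
            values.append(v)
        series.append(
            MetricSeries(
                metric_name=request,
                frame_indices=list(range(frames.n_models)),
                values=values,
                units=units,
            )
        )
    return series
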