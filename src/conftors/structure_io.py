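"""Structure and annotation I/O.

Structures are read from PDB or mmCIF through gemmi. Protein ATOM records
and HETATM records (lipids, OPM DUMMY membrane pseudo-atoms) are kept in
separate pools per model, and every model of a multi-model file is exposed
so that coordinate-frame series (multi-model PDB trajectories) can be
analysed frame by frame.

Region annotations name residue ranges (author numbering, inclusive) per
chain: transmembrane helices TH1-TH12, intracellular domains ICD1-ICD4,
coupling helices CH1-CH4, Walker A helices WAH1/WAH2, signature motifs
SIG1/SIG2 and the NBD strands S6/S9 of each half. They are carried in a
plain TSV so that per-structure residue selections can be curated by hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import AnnotationError, MembraneError, ParseError

__all__ = [
    "AtomRecord",
    "Structure",
    "RegionAnnotation",
    "MembraneModel",
    "parse_structure",
    "parse_opm_membrane",
    "load_annotation",
    "write_structure",
]

REGION_VOCABULARY = (
    tuple(f"TH{i}" for i in range(1, 13))
    + tuple(f"ICD{i}" for i in range(1, 5))
    + tuple(f"CH{i}" for i in range(1, 5))
    + ("WAH1", "WAH2", "SIG1", "SIG2", "S6_1", "S6_2", "S9_1", "S9_2")
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: author chain/residue identifiers plus Cartesian position (A)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ParseError(
                f"non-finite/ill-shaped position for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_number}"
            )
        object.__setattr__(self, "position", pos)


class Model:
    """Atoms of one coordinate frame, with fast Cα lookup."""

    def __init__(self, atoms: list[AtomRecord], het_atoms: list[AtomRecord]):
        self.atoms = atoms
        self.het_atoms = het_atoms
        self._ca: dict[tuple[str, int, str], AtomRecord] = {}
        for a in atoms:
            if a.atom_name == "CA":
                self._ca[(a.chain_id, a.residue_number, a.insertion_code)] = a

    def __len__(self) -> int:
        return len(self.atoms) + len(self.het_atoms)

    def ca(self, chain_id: str, residue_number: int, insertion_code: str = "") -> AtomRecord | None:
        return self._ca.get((chain_id, residue_number, insertion_code))

    def ca_range(self, chain_id: str, start: int, end: int) -> list[AtomRecord]:
        """All resolved Cα in [start, end] of a chain, in residue order.

        Insertion-coded residues sort after their base number.
        """
        hits = [
            a
            for (ch, num, _ic), a in self._ca.items()
            if ch == chain_id and start <= num <= end
        ]
        hits.sort(key=lambda a: (a.residue_number, a.insertion_code))
        return hits


@dataclass
class Structure:
    identifier: str
    models: list[Model]
    source_path: str = ""

    def __post_init__(self):
        if not self.models or any(len(m) == 0 for m in self.models):
            raise ParseError(f"{self.identifier}: structure must have >=1 non-empty model")

    @property
    def model(self) -> Model:
        """First (or only) model."""
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class RegionEntry:
    region_name: str
    chain_id: str
    start_residue: int
    end_residue: int


@dataclass
class RegionAnnotation:
    entries: list[RegionEntry] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.start_residue > e.end_residue:
                raise AnnotationError(
                    f"region {e.region_name}/{e.chain_id}: start {e.start_residue} "
                    f"> end {e.end_residue}"
                )
            key = (e.region_name, e.chain_id)
            if key in seen:
                raise AnnotationError(f"duplicate region {e.region_name} for chain {e.chain_id}")
            seen.add(key)
        self._by_name = {}
        for e in self.entries:
            self._by_name.setdefault(e.region_name, []).append(e)

    def get(self, region_name: str) -> RegionEntry:
        hits = self._by_name.get(region_name)
        if not hits:
            raise AnnotationError(f"region {region_name!r} not annotated")
        if len(hits) > 1:
            raise AnnotationError(f"region {region_name!r} ambiguous across chains")
        return hits[0]

    def has(self, region_name: str) -> bool:
        return region_name in self._by_name

    def region_names(self) -> list[str]:
        return sorted(self._by_name)

    def require(self, region_names) -> None:
        missing = [r for r in region_names if not self.has(r)]
        if missing:
            raise AnnotationError(f"missing annotated regions: {', '.join(missing)}")


@dataclass
class MembraneModel:
    """Planar membrane: center point, unit normal, optional thickness (A)."""

    center: np.ndarray
    normal: np.ndarray
    thickness: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise MembraneError("membrane normal must be non-zero")
        self.normal = n / norm
        if self.thickness is not None and self.thickness <= 0:
            raise MembraneError("membrane thickness must be positive")


# --- reading ---------------------------------------------------------------

_HET_WATER = {"HOH", "WAT"}


def _validate_pdb_coordinates(path: Path) -> None:
    """Fail early, naming the line, where gemmi would silently zero a field."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric coordinate field {fieldtxt!r}"
                        ) from None


def _pick_altloc(group: list) -> "gemmi.Atom":  # noqa: F821
    # highest occupancy wins; ties resolved toward blank/'A' altloc
    return sorted(group, key=lambda a: (-a.occ, a.altloc))[0]


def parse_structure(path, model_index: int | None = None, identifier: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    HETATM records (lipid beads, OPM DUMMY atoms, ions) are kept in a
    separate per-model pool; waters are dropped. Alternate conformers are
    reduced to the highest-occupancy one (ties go to altloc 'A').

    Parameters
    ----------
    model_index : optional 0-based model to keep; default keeps all models.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if path.suffix.lower() in {".pdb", ".ent"}:
        _validate_pdb_coordinates(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()

    models: list[Model] = []
    for gm in st:
        atoms: list[AtomRecord] = []
        hets: list[AtomRecord] = []
        for chain in gm:
            for res in chain:
                if res.name in _HET_WATER:
                    continue
                groups: dict[str, list] = {}
                for atom in res:
                    groups.setdefault(atom.name, []).append(atom)
                is_het = res.het_flag == "H"
                for name, group in groups.items():
                    atom = _pick_altloc(group)
                    rec = AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        atom_name=name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                    (hets if is_het else atoms).append(rec)
        if atoms or hets:
            models.append(Model(atoms, hets))

    if not models:
        raise ParseError(f"{path}: no atoms found")
    if model_index is not None:
        if not 0 <= model_index < len(models):
            raise ParseError(
                f"{path}: model {model_index} requested but file has {len(models)} model(s)"
            )
        models = [models[model_index]]
    return Structure(identifier=identifier or path.stem, models=models, source_path=str(path))


def parse_opm_membrane(structure: Structure, model_index: int = 0) -> MembraneModel:
    """Membrane model from OPM DUMMY pseudo-atoms (residue name DUM).

    OPM marks the two hydrophobic boundary planes with layers of DUM
    atoms. The membrane center is the centre of geometry of all DUM atoms;
    the layers are split by the sign of their coordinate along the
    best-fit plane normal after centering, the normal is oriented toward
    the layer with the greater mean projection, and the thickness is the
    distance between the two layer planes.
    """
    model = structure.models[model_index]
    dum = np.array([a.position for a in model.het_atoms if a.residue_name == "DUM"])
    if dum.size == 0:
        raise MembraneError(f"{structure.identifier}: no membrane annotation (no DUM atoms)")
    center = dum.mean(axis=0)
    centered = dum - center
    # plane-pair normal = direction of largest spread orthogonal to the
    # in-plane lattice: smallest principal axis of each layer's plane, but for
    # two parallel planes the normal is the top singular direction of the
    # *projections*; use SVD and take the axis separating the two layers.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    # the layer-separating axis is the principal direction along which the
    # points split into two clusters with a gap at zero
    best = None
    for axis in vt:
        proj = centered @ axis
        if np.all(np.abs(proj) > 1e-6):  # no point on the center plane
            spread = proj.std()
            if best is None or spread > best[0]:
                best = (spread, axis, proj)
    if best is None:
        raise MembraneError(f"{structure.identifier}: DUM atoms form a single layer")
    _, axis, proj = best
    upper = proj > 0
    if not upper.any() or upper.all():
        raise MembraneError(f"{structure.identifier}: DUM atoms form a single layer")
    thickness = float(proj[upper].mean() - proj[~upper].mean())
    # each boundary layer must be planar: within-layer spread along the split
    # axis stays tiny compared to the layer separation
    if max(proj[upper].std(), proj[~upper].std()) > 0.05 * thickness:
        raise MembraneError(
            f"{structure.identifier}: DUM atoms do not form two planar layers"
        )
    # orient the normal toward the layer with the greater mean z
    mean_z_upper = dum[upper][:, 2].mean()
    mean_z_lower = dum[~upper][:, 2].mean()
    normal = axis if mean_z_upper >= mean_z_lower else -axis
    return MembraneModel(center=center, normal=normal, thickness=thickness)


def load_annotation(path) -> RegionAnnotation:
    """Load a region-annotation TSV with header region_name/chain/start/end."""
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such annotation file: {path}")
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["region_name", "chain", "start", "end"]
        if header != expected:
            raise AnnotationError(
                f"{path}: unknown columns {header!r}; expected {expected!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            name, chain, start, end = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer residue bound") from None
            if start_i > end_i:
                raise AnnotationError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            entries.append(RegionEntry(name, chain, start_i, end_i))
    return RegionAnnotation(entries=entries)


def write_annotation(annotation: RegionAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("region_name\tchain\tstart\tend\n")
        for e in annotation.entries:
            fh.write(f"{e.region_name}\t{e.chain_id}\t{e.start_residue}\t{e.end_residue}\n")


# --- writing ---------------------------------------------------------------

def write_structure(structure: Structure, path) -> None:
    """Write all models back to a (minimal) PDB file."""
    lines = []
    multi = structure.n_models > 1
    for mi, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for pool, record in ((model.atoms, "ATOM  "), (model.het_atoms, "HETATM")):
            for a in pool:
                x, y, z = a.position
                lines.append(
                    f"{record}{serial % 100000:5d} {a.atom_name:^4s}{a.residue_name:>4s} "
                    f"{a.chain_id[:1]}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def resolve_ca(
    model: Model, chain_id: str, residue_number: int, max_substitution: int = 2
) -> AtomRecord:
    """Cα of a residue, substituting the nearest resolved neighbour.

    Annotated range ends are sometimes unresolved in cryo-EM maps; the
    nearest resolved residue within ``max_substitution`` positions is used
    instead (with a warning). Further than that is an error.
    """
    atom = model.ca(chain_id, residue_number)
    if atom is not None:
        return atom
    for offset in range(1, max_substitution + 1):
        for cand in (residue_number + offset, residue_number - offset):
            atom = model.ca(chain_id, cand)
            if atom is not None:
                warnings.warn(
                    f"Cα {chain_id}/{residue_number} unresolved; substituting "
                    f"residue {cand}",
                    stacklevel=2,
                )
                return atom
    raise AnnotationError(
        f"no resolved Cα within {max_substitution} residues of {chain_id}/{residue_number}"
    )
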