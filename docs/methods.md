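# Methods

## The problem

ABC Type I exporters (P-glycoprotein-like transporters: two transmembrane
domains of six helices each, two cytosolic nucleotide binding domains, and
intracellular domains with coupling helices linking the two) cycle through
conformations conventionally called bottom-open inward-facing, bottom-closed
inward-facing, bottom-closed outward-facing, and occluded. Global RMSD mixes
all of these differences into one number; two structures in the same RMSD
cluster can still differ in functionally decisive inter-domain arrangements.
This package implements a set of *conformational vectors* (conftors):
directed segments between anchor points — a single Cα or the centre of
geometry (COG) of a Cα set — chosen so that angles between them and
distances between their endpoints isolate specific inter-domain degrees of
freedom.

## Conftor definitions and anchors

An anchor is resolved from a region annotation (named residue ranges per
chain, author numbering, inclusive) in one of three ways: a single Cα
(first or last residue of a region), the COG of all Cα in one or more
regions, or the COG of the terminal-window Cα of one or more helix ends.
The helix "end" anchor defaults to the single terminal Cα of the annotated
range (window = 1); widening the window averages the last *w* residues,
which damps the effect of frayed termini but slightly shortens the vector.

Which terminal is "intracellular" is decided by projecting both ends onto
the membrane normal (lower projection = intracellular). Without a membrane
model, the end nearer the COG of the annotated NBD motifs (Walker A,
signature, S9) is taken as intracellular. TM-class conftors additionally
verify their direction against the membrane normal and are flipped (with a
warning) if a mis-ordered annotation made them point outward-in.

The built-in registry covers: THV1/THV2 (single TM helices TH4 and TH10),
THX1/THX2 (end-COGs of the crossover pairs TH4–TH5 and TH10–TH11),
ICV1/ICV2 and ICX1/ICX2 (the intracellular continuations, ICD1/ICD3 and
the ICD1–ICD2 / ICD3–ICD4 pairs), NBDV and NBDX (coupling-helix COG → first
residue of strand S9; NBDX1 groups CH1+CH4, NBDX2 groups CH2+CH3 — the
grouping is effectively carried by the annotation file, so renaming regions
remaps it), and the inter-NBD vectors S6, WAH, WAH1_SIG2, WAH2_SIG1.

All conftor angles and lengths are functions of one structure's internal
geometry, so they are rigid-body invariant; no superposition to a reference
is needed (the invariance suite checks this to 1e-9 over random rigid
transforms). Superposition (Kabsch, proper rotations only) is used only for
pairwise RMSD matrices and to bring helix-end projections from several
structures into one frame.

## Conformation classification

Class prototypes are the class-average angle signatures measured on the
curated Type I exporter set: THX1^THX2 = 46° / 39° / 35° / 26° and
ICV1^ICV2 = 43° / 38° / 60° / 53° for bottom-open inward-facing,
bottom-closed inward-facing, bottom-closed outward-facing, and occluded
respectively (THV1^THV2 only isolates the occluded class, 23° against
36–40° for everything else, and is not used for assignment). Assignment is
nearest prototype in the (THX, ICV) plane by Euclidean distance. The source
measurements report separability of the classes but no decision rule, so
the rule is this package's choice; the ambiguity flag is raised when the
two best classes differ by less than 5° in total distance, roughly the
scatter between the two inward-facing signatures.

When the two best classes are the two inward-facing ones and an NBDX "ext"
length (the separation of the two coupling-helix interface COGs) is
supplied, it breaks the tie: above 40 Å the NBDs are splayed
(bottom-open), below they are near contact (bottom-closed). The 40 Å
boundary is a package convention — the underlying measurements state only
that this length separates the two sub-classes, without printing values —
and it is a keyword argument for users with a calibrated set.

## Helix geometry

Bending, twist and rise follow the HELANAL scheme. Local helix axes are
Sugeta–Miyazawa fits to every 4 consecutive Cα (computed through
MDAnalysis). Each 9-residue sliding window (n − 8 windows for n residues)
gets (i) a window axis, the unit mean of its six local axes, and (ii) a
bending angle, the angle between the local axes of its first and last four
residues — two non-overlapping 4-residue segments 5 residues apart. This
windowed construction is what makes a sharp kink legible: a window whose
leading segment lies entirely in one arm and trailing segment entirely in
the other reports the full inter-arm angle, whereas angles between
*successive* overlapping window axes would smear a 30° kink into ~4° steps.
`detect_breaks` simply thresholds the per-window bending (default 20°),
which flags broken TM helices as a contiguous peak of windows.

On ideal helices (rise 1.5 Å, twist 100°/residue) the implementation
returns max bending < 1°, rise 1.5 ± 0.05 Å and twist 100 ± 1°/residue;
engineered two-arm kinks are recovered within 3°.

## Membrane models, tilt and insertion

OPM-style files carry DUM pseudo-atom grids on the two hydrophobic
boundary planes. The membrane center is the COG of all DUM atoms; the two
layers are separated along the principal direction in which the points
split into two planar clusters (a generalisation of splitting by the sign
of z that also handles tilted synthetic membranes), the normal points
toward the layer with greater mean z, and the thickness is the distance
between the layer planes. A planarity guard (within-layer spread < 5% of
thickness along the split axis) rejects single-layer or degenerate inputs.
Coarse-grained bilayers are summarised from two leaflet bead sets as
normal = unit(COG_upper − COG_lower), center = midpoint, thickness =
|COG_upper − COG_lower|.

The protein principal axis is the bisector of the normalized THX1 and THX2
vectors; tilt is its angle to the membrane normal folded into [0°, 90°]
(an axis has no sign). Insertion is reported two ways: the signed distance
between two membrane centers along the reference normal (structures must
be superposed first; positive = toward the extracellular side of the
reference), and the signed offset of the TM-helix Cα COG from a membrane
center. Placement tables from different sources are compared against a
reference source (default OPM) as |Δtilt| and signed Δz.

## Membrane-PB grid configuration

For membrane Poisson–Boltzmann runs the package emits the grid hierarchy
only (no solver execution): fine x/y extents come from the protein's
solver template, fine z = −2·z_min + 40 Å with z_min the smallest z in the
PQR file (keeps the protein inside the fine grid across the whole membrane
scan), medium = 2× fine, coarse = 5× fine, 161 grid points per axis,
150 mM Na+/Cl− (radii 0.95/1.81 Å), and a membrane z-scan of ±20 Å in 1 Å
steps (41 positions, zero = the reference OPM placement). The template
records the flooding membrane-fill method as a field for the external
solver.

## Synthetic fixtures: what they emulate and what they do not

The toy transporter is a Cα-only geometric assembly: 12 pseudo-TM helices,
four ICD helices, four coupling helices, Walker A/signature/S6/S9 motifs
and an OPM-style DUM membrane, parameterized by the THX angle, ICV angle,
NBD int/ext distances and tilt. Anchor-bearing helices are built so the
anchors land exactly on prescribed points: phase-opposed helix pairs make
every per-residue pair COG sit on the central axis, and single anchor
helices use residue counts completing whole helical turns (19 residues at
100°/residue for exact end-to-end vectors, 18 for exact whole-helix COGs).
Ground-truth metrics are therefore exact to machine precision, and the
parameter-recovery suite demands agreement to 1e-6 over a grid of THX
{20–50°} × ICV {35–60°} × tilt {0–12°}.

These fixtures are geometry oracles, not proteins: no side chains, no
physical packing, no annotation noise, no unresolved residues beyond what
tests inject deliberately. Passing them shows the measurement machinery is
correct and invariant; it does not validate the biological calibration of
the class prototypes, which requires curated experimental structures and
per-structure annotations (`scripts/validate_structures.py` performs that
comparison when such files are supplied).

Default toy parameters (THX 40°, ICV 45°, NBD int 60 Å / ext 45 Å, tilt
0°, membrane thickness 30 Å) sit in the realistic range spanned by the
transporter conformation classes; trajectory fixtures interpolate
parameters linearly between two endpoint states, emulating the NBD-closure
course seen in simulations of inward-facing transporters.

## Numerical choices

* Dot products are clipped to [−1, 1] before arccos.
* Kabsch superposition runs through `scipy.spatial.transform.Rotation`
  (reflections excluded); the returned RMSD is recomputed from the
  transformed coordinates because the solver's internal residual loses
  precision to cancellation near zero. Collinear point sets (second
  singular value < 1e-8 of the first) are rejected as underdetermined.
* Conftor anchors closer than 0.5 Å are rejected (no usable direction).
* Alternate conformers keep the highest occupancy, ties resolved toward
  altloc 'A'. A missing Cα at an annotated range end is substituted by the
  nearest resolved residue within 2 positions (with a warning); farther
  gaps are errors.
* Reports are sorted by (structure, metric/conftor) so identical inputs
  give byte-identical files.
* Test and acceptance problem sizes (30-residue helices, 8-point Kabsch
  sets, 60-cell recovery grids, 100 rigid transforms) were chosen as the
  smallest sizes at which each property is non-trivially exercised.

## Known limitations

* Region annotation quality is the dominant error source on real
  structures; the package validates ranges but cannot detect a
  biologically wrong helix assignment.
* The conftor registry targets Type I exporters; Type II (ABCG-like)
  architectures lack the ICD/coupling-helix topology these vectors assume.
* PDB round-trips are limited by the format's 1e-3 Å coordinate precision.
* The classification prototypes are fixed class means; they are not
  re-fitted from user data.
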