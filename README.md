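# conftors

Quantitative, standardized conformational metrics for ABC Type I exporter
structures — and, more generally, for any annotated membrane-protein
structure or multi-model coordinate series.

Comparing transporter conformations by global RMSD hides exactly the
inter-domain rearrangements that matter for function. This package measures
them directly with *conformational vectors* (conftors): directed segments
between anchor points (a single Cα or the centre of geometry of a Cα set)
whose relative angles and endpoint distances isolate individual degrees of
freedom — TM-helix splay, intracellular-domain opening, nucleotide binding
domain (NBD) separation and rotation. On top of the conftor engine it
provides:

* **Conformation classification** into the four canonical Type I exporter
  classes from the THX1^THX2 and ICV1^ICV2 angles (class signatures
  46/39/35/26° and 43/38/60/53°), with an NBD-interface-distance tie-break
  between the two inward-facing sub-classes.
* **Membrane placement metrics**: protein tilt (angle between the
  THX-bisector principal axis and the membrane normal), membrane models
  from OPM DUMMY atoms or coarse-grained leaflet beads, signed insertion
  offsets, and placement comparison across sources (OPM / PDBTM / CG).
* **Helix geometry** (HELANAL-style bending, twist, rise per 9-residue
  window), break detection, and 2D projection of TM-helix end positions
  onto the membrane plane for cross-structure helix-packing comparison.
* **Trajectory analysis**: any conftor angle/length evaluated per frame of
  a multi-model PDB.
* **Membrane Poisson–Boltzmann grid configuration** (APBSmem-style focusing
  grids, ion species, membrane z-scan plan) from a PQR file — configuration
  only, no solver execution.
* **Synthetic ground-truth fixtures**: ideal/kinked helices, OPM-style
  membranes, and a parameterized toy transporter whose metrics are exact by
  construction, used throughout the test suite.

Structures are read from PDB/mmCIF (gemmi); region annotations (TM helices
TH1–TH12, intracellular domains ICD1–4, coupling helices CH1–4, Walker A /
signature motifs, strands S6/S9) come from a plain TSV with columns
`region_name  chain  start  end`.

## Worked example

Generate a toy transporter built with a 46° THX angle, 43° ICV angle and a
12° membrane tilt, then measure it back:

```sh
$ conftor fixtures --thx 46 --icv 43 --tilt 12 --out-prefix toy
wrote toy.pdb / .tsv / .json

$ conftor compute --structure toy.pdb --annotation toy.tsv \
    --metric "angle:THX1,THX2" --metric "angle:ICV1,ICV2" \
    --metric "length:NBDX:ext" --metric "length:NBDX:int" --out conftors.tsv
wrote 16 conftors to conftors.tsv
structure_id          metric     value units
         toy angle:ICV1,ICV2 42.996854   deg
         toy angle:THX1,THX2 46.001981   deg
         toy length:NBDX:ext 45.000000     A
         toy length:NBDX:int 60.000000     A
```

The THX/ICV angles return the generator's 46°/43° (the few-millidegree
residue comes from the 10⁻³ Å coordinate precision of the PDB format; the
in-memory API is exact to ~10⁻¹⁴). `length:NBDX:ext` is the distance
between the two coupling-helix interface COGs and `length:NBDX:int` the
distance between the NBD bottoms (the S9 anchors). Classification:

```sh
$ conftor classify --structure toy.pdb --annotation toy.tsv
{
  "ambiguity_flag": false,
  "label": "bottom_open_inward_facing",
  "metrics": { "ICV": 42.997, "NBDX_ext": 45.0, "THX": 46.002 },
  ...
}
```

(46°, 43°) lies on the bottom-open inward-facing class signature, so the
structure is assigned that label with near-zero prototype distance and no
ambiguity. Other subcommands: `conftor traj` (per-frame metric series),
`conftor project` (helix-end 2D maps), `conftor membrane` (OPM membrane
model + tilt), `conftor apbsmem-config` (PB grid templates). The same
functionality is available as a library, e.g.
`conftors.conftor_angle_metric(structure, annotation, "THX1", "THX2")`.

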