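#!/usr/bin/env python
"""Class-signature validation against curated experimental structures.

Given a directory of OPM-oriented PDB files (with DUM membrane atoms), a
directory of matching region-annotation TSVs, and a label table assigning
each structure to a conformation class, this script computes the THX1^THX2,
ICV1^ICV2 and THV1^THV2 angles of every structure and reports class
averages next to the reference signatures (THX 46/39/35/26 deg,
ICV 43/38/60/53 deg, THV occluded 23 deg).

This needs externally obtained coordinate files and hand-curated residue
annotations; it is not part of the offline test suite.

Usage:
  python scripts/validate_structures.py \\
      --structures dir/of/pdbs --annotations dir/of/tsvs \\
      --labels labels.tsv            # columns: structure_id <TAB> class
"""

import argparse
from collections import defaultdict
from pathlib import Path

from conftors.conftor import CLASS_PROTOTYPES, THV_OCCLUDED_MEAN, conftor_angle_metric
from conftors.structure_io import load_annotation, parse_opm_membrane, parse_structure


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--structures", type=Path, required=True)
    parser.add_argument("--annotations", type=Path, required=True)
    parser.add_argument("--labels", type=Path, required=True)
    parser.add_argument("--tolerance", type=float, default=3.0,
                        help="acceptable |class mean - signature| (deg)")
    args = parser.parse_args()

    labels = {}
    with open(args.labels) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sid, label = line.split("\t")[:2]
                labels[sid.strip()] = label.strip()

    per_class = defaultdict(lambda: defaultdict(list))
    for pdb in sorted(args.structures.glob("*.pdb")):
        sid = pdb.stem
        if sid not in labels:
            print(f"skip {sid}: no class label")
            continue
        ann_path = args.annotations / f"{sid}.tsv"
        if not ann_path.exists():
            print(f"skip {sid}: no annotation file {ann_path}")
            continue
        structure = parse_structure(pdb)
        annotation = load_annotation(ann_path)
        membrane = parse_opm_membrane(structure)
        for metric, (a, b) in (
            ("THX", ("THX1", "THX2")),
            ("ICV", ("ICV1", "ICV2")),
            ("THV", ("THV1", "THV2")),
        ):
            angle = conftor_angle_metric(structure, annotation, a, b, membrane=membrane)
            per_class[labels[sid]][metric].append(angle)
        print(f"{sid}: ok ({labels[sid]})")

    print(f"\n{'class':32s} {'metric':6s} {'mean':>8s} {'signature':>10s} {'|diff|':>7s}")
    failures = 0
    for label, proto in CLASS_PROTOTYPES.items():
        expected = dict(proto)
        if label == "occluded":
            expected["THV"] = THV_OCCLUDED_MEAN
        for metric, sig in expected.items():
            values = per_class.get(label, {}).get(metric)
            if not values:
                print(f"{label:32s} {metric:6s} {'--':>8s} {sig:10.1f}      no data")
                continue
            mean = sum(values) / len(values)
            diff = abs(mean - sig)
            mark = "" if diff <= args.tolerance else "  <-- outside tolerance"
            failures += diff > args.tolerance
            print(f"{label:32s} {metric:6s} {mean:8.1f} {sig:10.1f} {diff:7.1f}{mark}")
    raise SystemExit(1 if failures else 0)


if __name__ == "__main__":
    main()
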