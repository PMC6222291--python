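import numpy as np
import pytest

from conftors._errors import AnchorError, AnnotationError
from conftors.conftor import (
    AnchorSpec,
    AnchorTarget,
    ConftorSpec,
    builtin_conftor_registry,
    classify_conformation,
    compute_conftor,
    conftor_angle_metric,
    conftor_length_metric,
    registry_by_name,
    trajectory_metrics,
)
from conftors.structure_io import (
    AtomRecord,
    Model,
    RegionAnnotation,
    RegionEntry,
    Structure,
    parse_opm_membrane,
)
from conftors.synthetic import (
    ToyTransporterParams,
    make_closing_trajectory,
    make_toy_transporter,
)

from conftest import random_rigid, transform_structure


class TestRegistry:
    def test_thx1_anchors_are_crossover_pair_end_cogs(self):
        thx1 = registry_by_name()["THX1"]
        assert thx1.origin.kind == "cog_of_helix_ends"
        assert sorted(thx1.origin.region_names()) == ["TH4", "TH5"]
        assert all(t.which_end == "intracellular" for t in thx1.origin.targets)
        assert all(t.which_end == "extracellular" for t in thx1.tip.targets)

    def test_nbdx1_tip_is_first_residue_of_s9(self):
        nbdx1 = registry_by_name()["NBDX1"]
        assert nbdx1.tip.kind == "single_ca"
        target = nbdx1.tip.targets[0]
        assert target.region_name == "S9_1" and target.which_end == "first"

    def test_every_spec_resolves_with_distinct_anchors(self, toy):
        structure, annotation, membrane, _ = toy
        for spec in builtin_conftor_registry():
            c = compute_conftor(structure, annotation, spec, membrane)
            assert c.length > 0.5, spec.name


class TestComputeConftor:
    def test_nbdx_vector_is_s9_minus_coupling_cog(self, toy):
        structure, annotation, membrane, gt = toy
        specs = registry_by_name()
        c1 = compute_conftor(structure, annotation, specs["NBDX1"], membrane)
        c2 = compute_conftor(structure, annotation, specs["NBDX2"], membrane)
        ext = np.linalg.norm(c1.origin_point - c2.origin_point)
        internal = np.linalg.norm(c1.tip_point - c2.tip_point)
        assert ext == pytest.approx(gt["length:NBDX:ext"], abs=1e-6)
        assert internal == pytest.approx(gt["length:NBDX:int"], abs=1e-6)

    def test_tm_vector_points_along_membrane_normal(self, toy):
        structure, annotation, membrane, _ = toy
        for name in ("THV1", "THV2", "THX1", "THX2"):
            c = compute_conftor(structure, annotation, registry_by_name()[name], membrane)
            assert float(np.dot(c.vector, membrane.normal)) > 0

    def test_antialigned_tm_vector_is_flipped_with_warning(self, toy):
        structure, annotation, membrane, _ = toy
        # sequence-order anchors on TH4 run intracellular->extracellular, so a
        # spec written tip-to-origin points against the normal and must flip
        backwards = ConftorSpec(
            "THV1_rev",
            AnchorSpec("single_ca", (AnchorTarget("TH4", "last"),)),
            AnchorSpec("single_ca", (AnchorTarget("TH4", "first"),)),
            orient="along_normal",
        )
        with pytest.warns(UserWarning, match="flipping"):
            c = compute_conftor(structure, annotation, backwards, membrane)
        assert float(np.dot(c.vector, membrane.normal)) > 0

    def test_missing_region_is_error(self, toy):
        structure, annotation, membrane, _ = toy
        bad = ConftorSpec(
            "X",
            AnchorSpec("cog_of_residues", (AnchorTarget("TH99", "whole"),)),
            AnchorSpec("cog_of_residues", (AnchorTarget("TH1", "whole"),)),
        )
        with pytest.raises(AnnotationError, match="TH99"):
            compute_conftor(structure, annotation, bad, membrane)

    def test_coincident_anchors_are_error(self):
        atoms = [
            AtomRecord("A", 1, "", "ALA", "CA", np.array([0.0, 0.0, 0.0])),
            AtomRecord("A", 11, "", "ALA", "CA", np.array([0.1, 0.0, 0.0])),
        ]
        s = Structure("tiny", [Model(atoms, [])])
        ann = RegionAnnotation(entries=[RegionEntry("R1", "A", 1, 1), RegionEntry("R2", "A", 11, 11)])
        spec = ConftorSpec(
            "D",
            AnchorSpec("single_ca", (AnchorTarget("R1", "first"),)),
            AnchorSpec("single_ca", (AnchorTarget("R2", "first"),)),
        )
        with pytest.raises(AnchorError, match="coincide"):
            compute_conftor(s, ann, spec)


class TestMetrics:
    def test_toy_angles_match_generator_exactly(self, toy):
        structure, annotation, membrane, gt = toy
        for a, b, key in (
            ("THX1", "THX2", "angle:THX1,THX2"),
            ("THV1", "THV2", "angle:THV1,THV2"),
            ("ICV1", "ICV2", "angle:ICV1,ICV2"),
            ("ICX1", "ICX2", "angle:ICX1,ICX2"),
        ):
            got = conftor_angle_metric(structure, annotation, a, b, membrane=membrane)
            assert got == pytest.approx(gt[key], abs=1e-6)

    def test_pythagorean_span(self):
        atoms = [
            AtomRecord("A", 1, "", "ALA", "CA", np.array([0.0, 0.0, 0.0])),
            AtomRecord("A", 11, "", "ALA", "CA", np.array([3.0, 4.0, 0.0])),
        ]
        s = Structure("span", [Model(atoms, [])])
        ann = RegionAnnotation(entries=[RegionEntry("R1", "A", 1, 1), RegionEntry("R2", "A", 11, 11)])
        spec = ConftorSpec(
            "D",
            AnchorSpec("single_ca", (AnchorTarget("R1", "first"),)),
            AnchorSpec("single_ca", (AnchorTarget("R2", "first"),)),
        )
        assert conftor_length_metric(s, ann, "D", "span", registry=[spec]) == pytest.approx(5.0)

    def test_lengths_match_generator(self, toy):
        structure, annotation, membrane, gt = toy
        for name, pair, key in (
            ("NBDX", "ext", "length:NBDX:ext"),
            ("NBDX", "int", "length:NBDX:int"),
            ("WAH", "span", "length:WAH:span"),
            ("S6", "span", "length:S6:span"),
            ("WAH1_SIG2", "span", "length:WAH1_SIG2:span"),
        ):
            got = conftor_length_metric(structure, annotation, name, pair, membrane=membrane)
            assert got == pytest.approx(gt[key], abs=1e-6)

    def test_rigid_invariance_of_all_metrics(self, toy, rng):
        structure, annotation, membrane, _ = toy
        requests = [
            ("angle", ("THX1", "THX2")),
            ("angle", ("ICV1", "ICV2")),
            ("length", ("NBDX", "ext")),
            ("length", ("NBDX", "int")),
            ("length", ("WAH", "span")),
        ]
        def evaluate(s, mem):
            out = []
            for kind, args in requests:
                if kind == "angle":
                    out.append(conftor_angle_metric(s, annotation, *args, membrane=mem))
                else:
                    out.append(conftor_length_metric(s, annotation, *args, membrane=mem))
            return np.array(out)

        base = evaluate(structure, membrane)
        for _ in range(10):
            rot, trans = random_rigid(rng)
            moved = transform_structure(structure, rot, trans)
            moved_membrane = parse_opm_membrane(moved)
            np.testing.assert_allclose(evaluate(moved, moved_membrane), base, atol=1e-9)

    def test_swapping_symmetric_halves_preserves_symmetric_metrics(self, toy):
        structure, annotation, membrane, _ = toy
        swap = {
            "TH4": "TH10", "TH5": "TH11", "TH10": "TH4", "TH11": "TH5",
            "ICD1": "ICD3", "ICD2": "ICD4", "ICD3": "ICD1", "ICD4": "ICD2",
            "CH1": "CH2", "CH4": "CH3", "CH2": "CH1", "CH3": "CH4",
            "S9_1": "S9_2", "S9_2": "S9_1", "WAH1": "WAH2", "WAH2": "WAH1",
            "SIG1": "SIG2", "SIG2": "SIG1", "S6_1": "S6_2", "S6_2": "S6_1",
        }
        swapped = RegionAnnotation(
            entries=[
                RegionEntry(swap.get(e.region_name, e.region_name), e.chain_id,
                            e.start_residue, e.end_residue)
                for e in annotation.entries
            ]
        )
        for kind, args in (
            ("angle", ("THX1", "THX2")), ("angle", ("ICV1", "ICV2")),
            ("length", ("NBDX", "ext")), ("length", ("NBDX", "int")),
            ("length", ("WAH", "span")), ("length", ("S6", "span")),
        ):
            fn = conftor_angle_metric if kind == "angle" else conftor_length_metric
            a = fn(structure, annotation, *args, membrane=membrane)
            b = fn(structure, swapped, *args, membrane=membrane)
            assert a == pytest.approx(b, abs=1e-9), args


class TestClassification:
    @pytest.mark.parametrize(
        "thx,icv,expected",
        [
            (46.0, 43.0, "bottom_open_inward_facing"),
            (39.0, 38.0, "bottom_closed_inward_facing"),
            (35.0, 60.0, "bottom_closed_outward_facing"),
            (26.0, 53.0, "occluded"),
        ],
    )
    def test_prototype_points_classify_to_their_class(self, thx, icv, expected):
        result = classify_conformation({"THX": thx, "ICV": icv})
        assert result.label == expected
        assert not result.ambiguity_flag
        assert result.distances[expected] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_is_ambiguous(self):
        # equidistant between the two inward-facing prototypes
        result = classify_conformation({"THX": 42.5, "ICV": 40.5})
        assert result.ambiguity_flag

    def test_nbd_ext_breaks_inward_tie(self):
        open_result = classify_conformation({"THX": 42.5, "ICV": 40.5, "NBDX_ext": 55.0})
        assert open_result.label == "bottom_open_inward_facing"
        assert not open_result.ambiguity_flag
        closed_result = classify_conformation({"THX": 42.5, "ICV": 40.5, "NBDX_ext": 32.0})
        assert closed_result.label == "bottom_closed_inward_facing"

    def test_missing_metric_is_error(self):
        with pytest.raises(AnnotationError, match="ICV"):
            classify_conformation({"THX": 40.0})


class TestTrajectories:
    def test_identical_frames_give_constant_series(self):
        params = ToyTransporterParams(seed=3)
        frames, annotation, membrane, _ = make_closing_trajectory(params, params, 5)
        (series,) = trajectory_metrics(
            frames, annotation, ["length:NBDX:int"], membrane=membrane
        )
        assert series.frame_indices == [0, 1, 2, 3, 4]
        assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-9)

    def test_closing_schedule_recovered(self):
        start = ToyTransporterParams(nbd_int_distance=80.0, seed=3)
        end = ToyTransporterParams(nbd_int_distance=50.0, seed=3)
        frames, annotation, membrane, gt = make_closing_trajectory(start, end, 20)
        (series,) = trajectory_metrics(
            frames, annotation, ["length:NBDX:int"], membrane=membrane
        )
        np.testing.assert_allclose(series.values, gt["length:NBDX:int"], atol=1e-6)
        np.testing.assert_allclose(series.values, np.linspace(80, 50, 20), atol=1e-6)
        assert all(a > b for a, b in zip(series.values, series.values[1:]))

    def test_two_requests_return_two_series(self, toy):
        params = ToyTransporterParams(seed=3)
        frames, annotation, membrane, _ = make_closing_trajectory(params, params, 3)
        series = trajectory_metrics(
            frames, annotation,
            ["length:WAH1_SIG2:span", "length:WAH2_SIG1:span"],
            membrane=membrane,
        )
        assert [s.metric_name for s in series] == [
            "length:WAH1_SIG2:span", "length:WAH2_SIG1:span"
        ]
        assert all(len(s.values) == 3 for s in series)

    def test_frame_missing_residues_is_error(self, toy):
        structure, annotation, membrane, _ = toy
        bigger = RegionAnnotation(
            entries=list(annotation.entries) + [RegionEntry("TH99", "A", 8000, 8010)]
        )
        spec_list = [
            ConftorSpec(
                "BAD",
                AnchorSpec("cog_of_residues", (AnchorTarget("TH99", "whole"),)),
                AnchorSpec("cog_of_residues", (AnchorTarget("TH1", "whole"),)),
            ),
            ConftorSpec(
                "BAD2",
                AnchorSpec("cog_of_residues", (AnchorTarget("TH1", "whole"),)),
                AnchorSpec("cog_of_residues", (AnchorTarget("TH2", "whole"),)),
            ),
        ]
        with pytest.raises(AnchorError, match="frame 0"):
            trajectory_metrics(structure, bigger, ["length:BAD:span"], registry=spec_list)
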