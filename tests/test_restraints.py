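import numpy as np
import pytest

from gpcrpocket.errors import FormatError, ResolutionError
from gpcrpocket.numbering import parse_generic_id, resolve
from gpcrpocket.restraints import (
    REFERENCE_EDGE_MEDIANS,
    EdgeRestraint,
    RestraintParams,
    RestraintSet,
    TetrahedronRestraint,
    build_restraint_set,
    format_restraint_line,
    parse_constraint_file,
    reference_median_table,
    restraint_manifest,
    restraint_score,
    sample_params,
    score_restraint_set,
    write_constraint_file,
)
from gpcrpocket.synthetic import BundleSpec, make_bundle

ADRB1_POSE_PAIRS = [(66, 98), (66, 176), (66, 308), (98, 176), (98, 308),
                    (176, 308)]
ADRB1_REFERENCES = [23.7864, 25.6431, 19.5077, 19.0209, 26.8934, 22.3116]


def _adrb1_tetra():
    params = RestraintParams(weight=3, steepness=0.7, scale=1.05, offset=-8)
    edges = tuple(
        EdgeRestraint(pose_i=i, pose_j=j, reference=c)
        for (i, j), c in zip(ADRB1_POSE_PAIRS, ADRB1_REFERENCES)
    )
    from gpcrpocket.numbering import TETRA1_IDS

    return TetrahedronRestraint(vertex_ids=TETRA1_IDS, edges=edges,
                                params=params)


class TestSampleParams:
    def test_fixed_seed_reproducible(self):
        a = sample_params(np.random.default_rng(77))
        b = sample_params(np.random.default_rng(77))
        assert a == b

    def test_1000_draws_respect_all_ranges(self):
        rng = np.random.default_rng(5)
        draws = [sample_params(rng) for _ in range(1000)]
        assert {p.weight for p in draws} <= {2, 3, 4}
        assert all(0.4 <= p.steepness <= 0.8 for p in draws)
        assert all(1.03 <= p.scale <= 1.07 for p in draws)
        assert all(-10 <= p.offset <= -1 for p in draws)
        # uniform s: empirical mean near the range midpoint 1.05
        mean_s = np.mean([p.scale for p in draws])
        assert 1.045 <= mean_s <= 1.055
        # discrete endpoints are reachable (coupon check)
        assert {p.weight for p in draws} == {2, 3, 4}
        assert {p.offset for p in draws} == set(range(-10, 0))
        # gridded steepness stays on the 0.1 grid
        assert {round(p.steepness, 1) for p in draws} <= {0.4, 0.5, 0.6, 0.7, 0.8}

    def test_out_of_range_params_rejected(self):
        with pytest.raises(FormatError):
            RestraintParams(weight=5, steepness=0.7, scale=1.05, offset=-8)
        with pytest.raises(FormatError):
            RestraintParams(weight=3, steepness=0.9, scale=1.05, offset=-8)
        with pytest.raises(FormatError):
            RestraintParams(weight=3, steepness=0.7, scale=1.10, offset=-8)
        with pytest.raises(FormatError):
            RestraintParams(weight=3, steepness=0.7, scale=1.05, offset=0)


class TestRestraintScore:
    PARAMS = RestraintParams(weight=3, steepness=0.7, scale=1.05, offset=-8)

    def test_minimum_value_is_a_times_d_at_reference(self):
        assert restraint_score(20.0, self.PARAMS, 20.0) == pytest.approx(-24.0)

    def test_unit_deviation(self):
        # at d = C + B the harmonic term is 1: score = A*(1 + D)
        assert restraint_score(20.7, self.PARAMS, 20.0) == pytest.approx(
            3 * (1 - 8))

    def test_even_function_around_reference(self, rng):
        for delta in rng.uniform(0, 5, size=20):
            lo = restraint_score(20.0 - delta, self.PARAMS, 20.0)
            hi = restraint_score(20.0 + delta, self.PARAMS, 20.0)
            assert lo == pytest.approx(hi, rel=1e-12)

    def test_strictly_convex_with_unique_minimum(self):
        grid = np.linspace(10, 30, 201)
        scores = [restraint_score(d, self.PARAMS, 20.0) for d in grid]
        assert np.argmin(scores) == 100  # at d == C
        diffs = np.diff(scores)
        assert (diffs[:100] < 0).all() and (diffs[100:] > 0).all()


class TestBuildRestraintSet:
    def test_knowledge_base_mode_uses_reference_medians(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(
            rmap, model, pocket, np.random.default_rng(0),
            stats=reference_median_table(), scale_override=1.0)
        t2 = rset.tetra2
        a = parse_generic_id("4.57x57")
        b = parse_generic_id("5.46x461")
        idx = [frozenset((t2.vertex_ids[i], t2.vertex_ids[j]))
               for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
        edge = t2.edges[idx.index(frozenset((a, b)))]
        assert edge.reference == pytest.approx(10.76)
        refs = sorted(e.reference for e in rset.tetra1.edges)
        assert refs == pytest.approx([17.94, 18.78, 20.30, 22.50, 24.25, 25.35])

    def test_template_mode_scales_measured_distances(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(
            rmap, model, pocket, np.random.default_rng(0),
            scale_override=1.05)
        for tetra in (rset.tetra1, rset.tetra2):
            coords = {g: xyz for g, _, xyz in
                      resolve(rmap, model, tetra.vertex_ids)}
            pose_of = {g: p for g, p, _ in
                       resolve(rmap, model, tetra.vertex_ids)}
            for edge in tetra.edges:
                gid_i = next(g for g, p in pose_of.items() if p == edge.pose_i)
                gid_j = next(g for g, p in pose_of.items() if p == edge.pose_j)
                d = np.linalg.norm(coords[gid_i] - coords[gid_j])
                assert edge.reference == pytest.approx(1.05 * d, rel=1e-12)

    def test_scale_ratio_stays_in_band_without_override(self, bundle):
        model, rmap, pocket = bundle
        for seed in range(20):
            rset = build_restraint_set(rmap, model, pocket,
                                       np.random.default_rng(seed))
            for tetra in (rset.tetra1, rset.tetra2):
                coords = {g: xyz for g, _, xyz in
                          resolve(rmap, model, tetra.vertex_ids)}
                pose_of = {p: g for g, p, _ in
                           resolve(rmap, model, tetra.vertex_ids)}
                for edge in tetra.edges:
                    d = np.linalg.norm(coords[pose_of[edge.pose_i]]
                                       - coords[pose_of[edge.pose_j]])
                    assert 1.03 - 1e-9 <= edge.reference / d <= 1.07 + 1e-9

    def test_missing_vertex_names_the_id(self, bundle):
        model, rmap, pocket = bundle
        import copy

        broken = copy.deepcopy(rmap)
        del broken.entries[parse_generic_id("3.40x40")]
        with pytest.raises(ResolutionError, match="3.40x40"):
            build_restraint_set(broken, model, pocket,
                                np.random.default_rng(0))

    def test_deterministic_under_fixed_seed(self, bundle):
        model, rmap, pocket = bundle
        a = build_restraint_set(rmap, model, pocket, np.random.default_rng(9))
        b = build_restraint_set(rmap, model, pocket, np.random.default_rng(9))
        assert write_constraint_file(a) == write_constraint_file(b)

    def test_tetrahedra_can_carry_different_params(self, bundle):
        model, rmap, pocket = bundle
        seen_different = any(
            (lambda r: r.tetra1.params != r.tetra2.params)(
                build_restraint_set(rmap, model, pocket,
                                    np.random.default_rng(seed)))
            for seed in range(10)
        )
        assert seen_different


class TestScoreRestraintSet:
    def test_model_at_references_scores_sum_of_minima(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(
            rmap, model, pocket, np.random.default_rng(4),
            scale_override=1.0)  # references equal measured distances
        total, breakdown = score_restraint_set(model, rset)
        a1, d1 = rset.tetra1.params.weight, rset.tetra1.params.offset
        a2, d2 = rset.tetra2.params.weight, rset.tetra2.params.offset
        assert total == pytest.approx(6 * a1 * d1 + 6 * a2 * d2, abs=1e-9)
        assert len(breakdown) == 12

    def test_matches_per_edge_loop_oracle(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(rmap, model, pocket,
                                   np.random.default_rng(13))
        total, breakdown = score_restraint_set(model, rset)
        expected = 0.0
        for edge, params in rset.all_edges:
            d = np.linalg.norm(model.residue_by_pose(edge.pose_i).ca_xyz
                               - model.residue_by_pose(edge.pose_j).ca_xyz)
            z = (d - edge.reference) / params.steepness
            expected += params.weight * (z * z + params.offset)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_missing_pose_number_rejected(self, bundle):
        model, rmap, pocket = bundle
        tetra = _adrb1_tetra()  # poses 66..308 exist, but fake one edge
        bad = TetrahedronRestraint(
            vertex_ids=tetra.vertex_ids,
            edges=tuple(
                EdgeRestraint(pose_i=9999, pose_j=e.pose_j,
                              reference=e.reference)
                if k == 0 else e
                for k, e in enumerate(tetra.edges)),
            params=tetra.params)
        rset = RestraintSet(tetra1=bad, tetra2=tetra, seed=0)
        with pytest.raises(ResolutionError):
            score_restraint_set(model, rset)


class TestConstraintFileDialect:
    def test_line_format_token_for_token(self):
        edge = EdgeRestraint(pose_i=66, pose_j=98, reference=23.7864)
        params = RestraintParams(weight=3, steepness=0.7, scale=1.05,
                                 offset=-8)
        assert format_restraint_line(edge, params) == (
            "AtomPair CA 66 CA 98 SCALARWEIGHTEDFUNC 3 SUMFUNC 2 "
            "HARMONIC 23.7864 0.7 CONSTANTFUNC -8"
        )

    def test_two_tetra_set_emits_12_lines_tetra1_first(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(rmap, model, pocket,
                                   np.random.default_rng(3))
        lines = write_constraint_file(rset).splitlines()
        assert len(lines) == 12
        first_weight = rset.tetra1.params.weight
        assert all(f"SCALARWEIGHTEDFUNC {first_weight} " in ln
                   for ln in lines[:6])

    def test_write_parse_write_fixed_point(self, bundle):
        model, rmap, pocket = bundle
        rset = build_restraint_set(rmap, model, pocket,
                                   np.random.default_rng(8))
        text = write_constraint_file(rset)
        parsed = parse_constraint_file(text)
        rebuilt = "\n".join(
            f"AtomPair CA {p.pose_i} CA {p.pose_j} "
            f"SCALARWEIGHTEDFUNC {p.weight:.0f} SUMFUNC 2 "
            f"HARMONIC {p.reference:.4f} {p.steepness:.1f} "
            f"CONSTANTFUNC {p.offset:.0f}"
            for p in parsed) + "\n"
        assert rebuilt == text

    def test_parses_typeset_damaged_spacing(self):
        damaged = (
            "AtomPair CA66 CA 98 SCALARWEIGHTEDFUNC 3 "
            "SUMFUNC2HARMONIC 23.7864 0.7 CONSTANTFUNC-8\n"
        )
        (line,) = parse_constraint_file(damaged)
        assert (line.pose_i, line.pose_j) == (66, 98)
        assert (line.weight, line.reference, line.steepness, line.offset) == (
            3.0, 23.7864, 0.7, -8.0)

    def test_six_line_worked_example_parses(self):
        text = "".join(
            f"AtomPair CA {i} CA {j} SCALARWEIGHTEDFUNC 3 SUMFUNC 2 "
            f"HARMONIC {c} 0.7 CONSTANTFUNC -8\n"
            for (i, j), c in zip(ADRB1_POSE_PAIRS, ADRB1_REFERENCES))
        parsed = parse_constraint_file(text)
        assert len(parsed) == 6
        assert all(p.weight == 3 and p.steepness == 0.7 and p.offset == -8
                   for p in parsed)
        assert [p.reference for p in parsed] == ADRB1_REFERENCES

    def test_empty_text_and_corrupt_token(self):
        assert parse_constraint_file("") == []
        bad = ("AtomPair CA 1 CA 2 SCALARWEIGHTEDFUNC 3 SUMFUNC 2 "
               "HARMONIQUE 20.0 0.7 CONSTANTFUNC -8\n")
        with pytest.raises(FormatError, match="line 1"):
            parse_constraint_file(bad)

    def test_manifest_is_valid_json_with_all_fields(self, bundle):
        import json

        model, rmap, pocket = bundle
        rset = build_restraint_set(rmap, model, pocket,
                                   np.random.default_rng(6), seed=6)
        doc = json.loads(restraint_manifest(rset))
        assert doc["seed"] == 6
        for key in ("tetra1", "tetra2"):
            assert len(doc[key]["vertices"]) == 4
            assert len(doc[key]["edges"]) == 6
            assert set(doc[key]["params"]) == {
                "weight", "steepness", "scale", "offset"}


def test_reference_median_table_covers_all_12_edges():
    table = reference_median_table()
    assert len(REFERENCE_EDGE_MEDIANS) == 12
    for (a_txt, b_txt), med in REFERENCE_EDGE_MEDIANS.items():
        a, b = parse_generic_id(a_txt), parse_generic_id(b_txt)
        assert table.median(a, b) == pytest.approx(med)
        assert med > 0
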