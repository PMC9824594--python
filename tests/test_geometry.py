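import numpy as np
import pytest

from microscaff import (
    ScaffoldSpec,
    build_toolpath,
    generate_rectilinear_layer,
    generate_triangular_layer,
    stack_layers,
)
from microscaff.geometry import EXTRUDE, TRAVEL


def enumerate_strands(L, spacing):
    """Independent oracle: strand positions 0, spacing, ..., L."""
    positions = []
    k = 0
    while k * spacing <= L + 1e-9:
        positions.append(k * spacing)
        k += 1
    return positions


def extruding_vertices(lp):
    mask = np.zeros(len(lp.vertices), dtype=bool)
    for i, k in enumerate(lp.segment_kinds):
        if k == EXTRUDE:
            mask[i] = mask[i + 1] = True
    return lp.vertices[mask]


class TestRectilinear:
    @pytest.mark.parametrize(
        "layer_index,spacing_attr",
        [(1, "d1"), (2, "d2"), (3, "d1"), (4, "d2")],
    )
    def test_strand_count_matches_enumeration_oracle(self, ref_spec, layer_index, spacing_attr):
        lp = generate_rectilinear_layer(ref_spec, layer_index)
        expected = len(enumerate_strands(ref_spec.L, getattr(ref_spec, spacing_attr)))
        strand_kinds = [k for i, k in enumerate(lp.segment_kinds) if i % 2 == 0]
        assert len(strand_kinds) == expected
        # L=20: 21 strands at d1=1.0, 9 at d2=2.5
        assert expected == (21 if spacing_attr == "d1" else 9)

    def test_layer_z_is_index_times_height(self, ref_spec):
        lp = generate_rectilinear_layer(ref_spec, 1)
        assert lp.z == pytest.approx(0.2)
        assert generate_rectilinear_layer(ref_spec, 3).z == pytest.approx(0.6)

    def test_bounding_box_is_exactly_L_by_L(self, ref_spec):
        for idx in (1, 2):
            v = extruding_vertices(generate_rectilinear_layer(ref_spec, idx))
            assert v.min(axis=0) == pytest.approx([0.0, 0.0])
            assert v.max(axis=0) == pytest.approx([ref_spec.L, ref_spec.L])

    def test_total_extrude_length_closed_form(self, ref_spec):
        # n strands of length L plus (n-1) links of length = spacing
        lp = generate_rectilinear_layer(ref_spec, 1)
        seg = np.diff(lp.vertices, axis=0)
        total = np.linalg.norm(seg, axis=1).sum()
        n = 21
        assert total == pytest.approx(n * 20.0 + (n - 1) * 1.0)

    def test_travel_links_option(self):
        spec = ScaffoldSpec(links="travel")
        lp = generate_rectilinear_layer(spec, 1)
        assert all(k == TRAVEL for i, k in enumerate(lp.segment_kinds) if i % 2 == 1)

    def test_origin_offsets_all_vertices(self):
        lp = generate_rectilinear_layer(ScaffoldSpec(origin=(5.0, 7.0)), 1)
        assert lp.vertices[:, 0].min() == pytest.approx(5.0)
        assert lp.vertices[:, 1].min() == pytest.approx(7.0)

    def test_layer_index_out_of_range(self, ref_spec):
        with pytest.raises(IndexError):
            generate_rectilinear_layer(ref_spec, 5)
        with pytest.raises(IndexError):
            generate_rectilinear_layer(ref_spec, 0)

    def test_deterministic_bit_for_bit(self, ref_spec):
        a = generate_rectilinear_layer(ref_spec, 1)
        b = generate_rectilinear_layer(ref_spec, 1)
        assert np.array_equal(a.vertices, b.vertices)


class TestTriangular:
    def test_flank_slope_equals_amplitude_over_half_period(self):
        spec = ScaffoldSpec(pattern="triangular", d1=2.0, d2=2.0)
        lp = generate_triangular_layer(spec, 1)
        seg = np.diff(lp.vertices, axis=0)
        slopes = [
            abs(s[1] / s[0])
            for s, k in zip(seg, lp.segment_kinds)
            if k == EXTRUDE
        ]
        assert np.allclose(slopes, 2.0)  # d2 / (d1/2)

    def test_degenerate_single_period(self):
        spec = ScaffoldSpec(pattern="triangular", d1=20.0, d2=20.0, n_layers=1)
        lp = generate_triangular_layer(spec, 1)
        assert np.allclose(lp.vertices, [[0, 0], [10, 20], [20, 0]])

    def test_bounding_box_is_L_by_L(self):
        spec = ScaffoldSpec(pattern="triangular", d1=2.0, d2=2.5)
        v = extruding_vertices(generate_triangular_layer(spec, 1))
        assert v.min(axis=0) == pytest.approx([0.0, 0.0])
        assert v.max(axis=0) == pytest.approx([20.0, 20.0])


class TestStacking:
    def test_distinct_z_progression(self, ref_spec):
        tp = build_toolpath(ref_spec)
        assert tp.distinct_z() == pytest.approx([0.2, 0.4, 0.6, 0.8])

    def test_single_layer_max_z_is_h(self):
        tp = build_toolpath(ScaffoldSpec(n_layers=1))
        assert tp.points[:, 2].max() == pytest.approx(0.2)

    def test_reference_model_extent_on_every_layer(self, ref_spec):
        tp = build_toolpath(ref_spec)
        for z in tp.distinct_z():
            on_layer = tp.points[np.isclose(tp.points[:, 2], z)]
            assert on_layer[:, 0].max() - on_layer[:, 0].min() == pytest.approx(20.0)
            assert on_layer[:, 1].max() - on_layer[:, 1].min() == pytest.approx(20.0)

    def test_layer_hops_are_travel(self, ref_spec):
        tp = build_toolpath(ref_spec)
        hops = np.nonzero(np.diff(tp.layers))[0] + 1
        assert all(tp.kinds[h] == TRAVEL for h in hops)

    def test_empty_layer_list_rejected(self, ref_spec):
        with pytest.raises(ValueError):
            stack_layers(ref_spec, [])

    def test_e_not_assigned_by_stacking(self, ref_spec):
        assert build_toolpath(ref_spec).e is None


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(L=0), dict(d1=-1), dict(layer_height=0),
            dict(n_layers=0), dict(d1=25.0), dict(pattern="hexagonal"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises((ValueError, TypeError)):
            ScaffoldSpec(**kwargs)

    def test_duplicate_vertices_rejected(self):
        from microscaff import LayerPath

        with pytest.raises(ValueError):
            LayerPath(z=0.2, vertices=[[0, 0], [0, 0]], segment_kinds=[EXTRUDE])
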