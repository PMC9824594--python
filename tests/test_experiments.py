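import numpy as np
import pandas as pd
import pytest

from microscaff import ExtrusionParams, ScaffoldSpec, assign_extrusion, build_toolpath
from microscaff import experiments as exp
from microscaff.geometry import EXTRUDE


class TestMatrices:
    def test_f_matrix_multipliers(self):
        rows = exp.load_matrix("F")
        assert [r.f for r in rows] == [1.00, 0.60, 0.45, 0.30]
        assert all(r.speed == 600 and r.fan_pwm == 0 for r in rows)

    def test_t9b_conditions(self):
        t9 = {r.id: r for r in exp.load_matrix("T")}["T9B"]
        assert (t9.f, t9.speed, t9.fan_pwm) == (0.45, 4200, 255)

    def test_p3b_conditions(self):
        p3 = {r.id: r for r in exp.load_matrix("P")}["P3B"]
        assert (p3.f, p3.speed) == (0.20, 4200)
        assert p3.pass_spec.n_base_layers == 3
        assert p3.pass_spec.pass_pattern == "parallel"

    def test_failed_adhesion_rows_flagged(self):
        flagged = {r.id for r in exp.load_all_rows() if r.failed}
        assert flagged == {"V8B", "T12B", "T13B"}

    def test_row_counts_per_matrix(self):
        counts = {m: len(exp.load_matrix(m)) for m in exp.MATRICES}
        assert counts == {"F": 4, "V": 8, "T": 13, "P": 9, "D": 1}

    def test_inconsistent_pwm_annotations_kept_as_notes(self):
        t = {r.id: r for r in exp.load_matrix("T")}
        assert t["T10B"].pwm_note == "255 (19.6%)"
        assert t["T11B"].pwm_note == "50 (100 %)"
        assert t["T10B"].fan_pwm == 255 and t["T11B"].fan_pwm == 50

    def test_unknown_matrix_rejected(self):
        with pytest.raises(KeyError):
            exp.load_matrix("X")

    def test_table_round_trips_through_export(self, tmp_path):
        df = exp.matrix_table()
        out = tmp_path / "export.csv"
        df.to_csv(out, index=False)
        again = pd.read_csv(out, dtype=str, keep_default_na=False)
        pd.testing.assert_frame_equal(df.astype(str), again)


class TestSurfacePasses:
    @pytest.fixture
    def base(self, ref_params):
        spec = ScaffoldSpec(n_layers=3)
        tp = assign_extrusion(build_toolpath(spec), ref_params)
        return spec, tp

    def test_max_z_unchanged_by_passes(self, base, ref_params):
        spec, tp = base
        for pattern in ("parallel", "diagonal"):
            out = exp.add_surface_passes(
                tp, spec, exp.SurfacePassSpec(pass_pattern=pattern), ref_params
            )
            assert out.points[:, 2].max() == tp.points[:, 2].max()

    def test_zero_pass_multiplier_leaves_e_unchanged(self, base, ref_params):
        spec, tp = base
        out = exp.add_surface_passes(
            tp, spec, exp.SurfacePassSpec(pass_f=0.0), ref_params
        )
        assert out.total_e == tp.total_e

    def test_pass_moves_carry_pass_speed(self, base, ref_params):
        spec, tp = base
        out = exp.add_surface_passes(
            tp, spec, exp.SurfacePassSpec(pass_speed=5000.0), ref_params
        )
        new = out.feed[tp.n_segments:]
        assert np.all(new == 5000.0)

    def test_diagonal_passes_run_at_45_degrees(self, base, ref_params):
        spec, tp = base
        out = exp.add_surface_passes(
            tp, spec, exp.SurfacePassSpec(pass_pattern="diagonal"), ref_params
        )
        seg = np.diff(out.points[tp.n_points - 1:], axis=0)[1:]
        kinds = out.kinds[tp.n_segments + 1:]
        for s, k in zip(seg, kinds):
            if k == EXTRUDE:
                assert abs(abs(s[1] / s[0]) - 1.0) < 1e-9

    def test_pass_e_scales_with_pass_f(self, base, ref_params):
        spec, tp = base
        e_of = {}
        for pf in (0.10, 0.20):
            out = exp.add_surface_passes(
                tp, spec, exp.SurfacePassSpec(pass_f=pf), ref_params
            )
            e_of[pf] = out.total_e - tp.total_e
        assert e_of[0.20] == pytest.approx(2.0 * e_of[0.10], rel=1e-12)

    def test_pass_over_empty_toolpath_rejected(self, ref_params):
        from microscaff.geometry import Toolpath

        with pytest.raises(ValueError):
            exp.add_surface_passes(
                Toolpath.empty(), ScaffoldSpec(), exp.SurfacePassSpec(), ref_params
            )

    def test_d1b_structure(self):
        d1b = exp.load_matrix("D")[0]
        tp, settings = exp.build_experiment(d1b)
        assert int(tp.layers.max()) == 3
        assert tp.distinct_z() == pytest.approx([0.2, 0.4, 0.6])
        assert settings.fan_pwm == 255 and settings.speed == 600
        # passes at unchanged Z, at pass speed, under-extruded at f=0.20
        pass_feed = tp.feed[np.isfinite(tp.feed)]
        assert np.all(pass_feed == 5000.0)


class TestSweep:
    def test_full_sweep_writes_32_files(self, tmp_path):
        manifest = exp.run_sweep(exp.load_all_rows(), outdir=tmp_path)
        files = sorted(p.name for p in tmp_path.glob("*.gcode"))
        assert len(manifest) == 32
        assert len(files) == 32
        assert "V8B.gcode" not in files and "T13B.gcode" not in files

    def test_rerun_is_byte_identical(self, tmp_path):
        rows = exp.load_matrix("F")
        exp.run_sweep(rows, outdir=tmp_path / "a")
        exp.run_sweep(rows, outdir=tmp_path / "b")
        for p in (tmp_path / "a").glob("*.gcode"):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_empty_matrix_yields_empty_manifest(self, tmp_path):
        manifest = exp.run_sweep([], outdir=tmp_path)
        assert len(manifest) == 0

    def test_total_e_ratio_equals_f_ratio_for_matched_pairs(self):
        pairs = exp.f_linearity_pairs()
        assert pairs, "packaged tables must contain f-only pairs"
        cache = {}

        def pass_aware_e(row):
            if row.id not in cache:
                tp, _ = exp.build_experiment(row)
                if row.pass_spec is None:
                    cache[row.id] = tp.total_e
                else:
                    base_rows = exp.build_experiment(
                        exp.ExperimentRow(
                            id="base", matrix=row.matrix, f=exp.PASS_BASE_F,
                            speed=exp.PASS_BASE_SPEED, fan_pwm=exp.PASS_BASE_FAN,
                            pass_spec=None,
                        ),
                        base_spec=ScaffoldSpec(n_layers=row.pass_spec.n_base_layers),
                    )[0].total_e
                    cache[row.id] = tp.total_e - base_rows
            return cache[row.id]

        for a, b in pairs:
            ratio = pass_aware_e(a) / pass_aware_e(b)
            assert ratio == pytest.approx(a.f / b.f, rel=1e-12)
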