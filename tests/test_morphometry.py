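"""Index measurements on constructed sections, aggregation, and invariances."""

import numpy as np
import pytest

from onhmorph.geometry import BScanSection, Curve2D, Point2D
from onhmorph.morphometry import (
    RimAbsentError,
    SectionIndices,
    aggregate_eye,
    bmo_reference_line,
    compute_hrw,
    compute_lcci,
    compute_mrw,
    disc_ovality,
    section_indices,
    torsion_angle,
)
from onhmorph.synthetic import build_section


def flat_section(w=1500.0, ilm_z=-200.0, alcs=None, ilm=None):
    """Hand-built section with a horizontal BMO line at z = 0."""
    if alcs is None:
        alcs = [[-0.2 * w, 250], [1.2 * w, 250.0001]]
    if ilm is None:
        ilm = [[-2000, ilm_z], [w + 2000, ilm_z + 0.0001]]
    return BScanSection(
        section_id="manual",
        location="central",
        scan_offset=0,
        ilm=Curve2D(ilm, role="ILM"),
        bm=Curve2D([[-0.5 * w, 0], [0, 0], [w, 0], [1.5 * w, 0]], role="BM"),
        alcs=Curve2D(alcs, role="ALCS"),
        bmo_temporal=Point2D(0, 0),
        bmo_nasal=Point2D(w, 0),
        quality_score=30.0,
    )


class TestBmoReferenceLine:
    def test_horizontal(self):
        line, w = bmo_reference_line(flat_section(w=1500))
        assert w == pytest.approx(1500)
        assert line.p1.z == line.p2.z == 0

    def test_tilted_width_is_euclidean(self):
        s = flat_section()
        s.bmo_nasal = Point2D(1500, 200)
        _, w = bmo_reference_line(s)
        assert w == pytest.approx(np.hypot(1500, 200))

    @pytest.mark.parametrize("seed", range(5))
    def test_width_symmetric_under_side_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(-500, 500, 2), rng.uniform(800, 2000, 2)
        s = flat_section()
        s.bmo_temporal, s.bmo_nasal = Point2D(a[0], a[1]), Point2D(b[0], b[1])
        _, w1 = bmo_reference_line(s)
        assert w1 == pytest.approx(float(np.linalg.norm(a - b)))


class TestHrwMrw:
    def test_hrw_horizontal_crossing(self):
        ilm = [[-2000, -150], [-300, 0], [600, 400], [900, 400.1], [3500, 400.2]]
        s = flat_section(ilm=ilm)
        assert compute_hrw(s, "temporal") == pytest.approx(300)

    def test_hrw_tilted_construct_then_measure(self):
        s = build_section(
            section_id="t", location="central", scan_offset=0, w=1500,
            hrw_temporal=250, mrw_temporal=150, hrw_nasal=320, mrw_nasal=180,
            lcci=8.0, tilt_deg=10.0, shift=(40.0, -25.0),
        )
        assert compute_hrw(s, "temporal") == pytest.approx(250, abs=0.5)
        assert compute_hrw(s, "nasal") == pytest.approx(320, abs=0.5)

    def test_no_crossing_flags_rim_absent(self):
        s = flat_section(ilm_z=-50.0)  # ILM parallel above the line: no crossing
        with pytest.raises(RimAbsentError):
            compute_hrw(s, "temporal")
        idx = section_indices(s)
        assert np.isnan(idx.hrw_temporal)
        assert "rim_absent_temporal" in idx.flags

    def test_mrw_flat_ilm(self):
        s = flat_section(ilm_z=-200.0)
        assert compute_mrw(s, "temporal") == pytest.approx(200, abs=1e-4)

    def test_mrw_zero_when_ilm_touches_bmo(self):
        ilm = [[-2000, -300], [0, 0], [2000, -300.0001]]
        s = flat_section(ilm=ilm)
        assert compute_mrw(s, "temporal") == pytest.approx(0, abs=1e-9)

    def test_mrw_wavy_ilm_matches_dense_oracle(self):
        x = np.linspace(-1800, 3300, 2000)
        z = -250 + 60 * np.sin(x / 180.0)
        s = flat_section(ilm=np.column_stack([x, z]))
        pts = np.column_stack([x, z])
        seg_a, seg_b = pts[:-1], pts[1:]
        best = np.inf
        for a, b in zip(seg_a, seg_b):
            t = np.linspace(0, 1, 40)[:, None]
            best = min(best, np.linalg.norm(a + t * (b - a), axis=1).min())
        assert compute_mrw(s, "temporal") == pytest.approx(best, abs=0.5)


class TestLcci:
    def test_flat_alcs_gives_zero(self):
        s = flat_section()
        w, lccd, lcci = compute_lcci(s)
        assert lccd == pytest.approx(0, abs=1e-3)
        assert lcci == pytest.approx(0, abs=1e-3)

    def test_symmetric_parabola(self):
        w = 1500.0
        xi = np.linspace(-0.2, 1.2, 211)
        alcs = np.column_stack([xi * w, 250 + 4 * 150 * xi * (1 - xi)])
        s = flat_section(w=w, alcs=alcs)
        got_w, lccd, lcci = compute_lcci(s)
        assert got_w == pytest.approx(1500)
        assert lccd == pytest.approx(150, abs=0.1)
        assert lcci == pytest.approx(10.0, abs=0.01)

    def test_lcci_is_lccd_over_w_identity(self):
        s = build_section(
            section_id="t", location="central", scan_offset=0, w=1700,
            hrw_temporal=300, mrw_temporal=200, hrw_nasal=300, mrw_nasal=200,
            lcci=9.3,
        )
        w, lccd, lcci = compute_lcci(s)
        assert lcci == pytest.approx(100 * lccd / w, abs=1e-9)

    def test_tilted_bmo_line_matches_dense_oracle(self):
        s = build_section(
            section_id="t", location="central", scan_offset=0, w=1500,
            hrw_temporal=280, mrw_temporal=170, hrw_nasal=280, mrw_nasal=170,
            lcci=11.0, tilt_deg=7.6,  # ~200 µm z-offset between BMO points
        )
        w, lccd, lcci = compute_lcci(s)

        # oracle: march the perpendicular rays, then dense point-to-chord max
        from onhmorph.geometry import ReferenceLine, perpendicular_foot_on_curve

        line = ReferenceLine(s.bmo_temporal, s.bmo_nasal)
        f_t = perpendicular_foot_on_curve(s.bmo_temporal, line, s.alcs)
        f_n = perpendicular_foot_on_curve(s.bmo_nasal, line, s.alcs)
        a, b = f_t.as_array(), f_n.as_array()
        u = (b - a) / np.linalg.norm(b - a)
        pts = s.alcs.points
        lo, hi = sorted((a[0], b[0]))
        dense = []
        for p, q in zip(pts[:-1], pts[1:]):
            t = np.linspace(0, 1, 25)[:, None]
            dense.append(p + t * (q - p))
        dense = np.vstack(dense)
        dense = dense[(dense[:, 0] >= lo) & (dense[:, 0] <= hi)]
        rel = dense - a
        perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
        assert lccd == pytest.approx(perp.max(), abs=0.5)
        assert lcci == pytest.approx(100 * perp.max() / w, abs=0.05)


class TestAggregation:
    @staticmethod
    def _idx(v, sid="s"):
        return SectionIndices(
            section_id=sid, hrw_temporal=v, hrw_nasal=v, mrw_temporal=v / 2,
            mrw_nasal=v / 2, w=1500, lccd=v / 10, lcci=100 * (v / 10) / 1500,
        )

    def test_identical_scans_pass_through(self):
        by_loc = {loc: [self._idx(300)] * 3 for loc in ("superior_mid", "central", "inferior_mid")}
        res = aggregate_eye(by_loc, eye_id="e")
        assert res.mean_hrw == pytest.approx(300)
        assert res.mean_mrw == pytest.approx(150)
        assert res.mean_hmr == pytest.approx(2.0)
        assert res.n_usable_scans == 9

    def test_location_means_then_eye_mean(self):
        by_loc = {
            "superior_mid": [self._idx(90)],
            "central": [self._idx(100)],
            "inferior_mid": [self._idx(110)],
        }
        res = aggregate_eye(by_loc)
        assert res.mean_hrw == pytest.approx(100)

    def test_random_values_match_nested_mean_oracle(self, rng):
        locs = ("superior_mid", "central", "inferior_mid")
        by_loc = {
            loc: [self._idx(rng.uniform(50, 400)) for _ in range(3)] for loc in locs
        }
        res = aggregate_eye(by_loc)
        oracle = np.mean(
            [np.mean([s.hrw for s in by_loc[loc]]) for loc in locs]
        )
        assert res.mean_hrw == pytest.approx(oracle, abs=1e-9)

    def test_empty_location_flags_incomplete(self):
        by_loc = {"central": [self._idx(100)]}
        res = aggregate_eye(by_loc)
        assert "incomplete" in res.flags
        assert np.isnan(res.mean_hrw)


class TestDiscShape:
    def test_ovality_examples_and_boundary(self):
        assert disc_ovality(1800, 1800) == pytest.approx(1.0)
        assert disc_ovality(1950, 1500) == pytest.approx(1.3)
        assert disc_ovality(2000, 1500) > 1.3

    def test_ovality_invalid_inputs(self):
        with pytest.raises(ValueError):
            disc_ovality(1800, 0)
        with pytest.raises(ValueError):
            disc_ovality(1400, 1500)

    def test_torsion_examples(self):
        assert torsion_angle(0) == 0
        assert torsion_angle(-20) == 20
        assert torsion_angle(15) == 15  # boundary: not excluded (strict >)
        with pytest.raises(ValueError):
            torsion_angle(95)


class TestSectionInvariances:
    BASE = dict(
        section_id="t", location="central", scan_offset=0, w=1600,
        hrw_temporal=260, mrw_temporal=140, hrw_nasal=310, mrw_nasal=175,
        lcci=9.0,
    )

    @staticmethod
    def _scaled(section, k):
        return BScanSection(
            section_id=section.section_id,
            location=section.location,
            scan_offset=section.scan_offset,
            ilm=Curve2D(section.ilm.points * k, role="ILM"),
            bm=Curve2D(section.bm.points * k, role="BM"),
            alcs=Curve2D(section.alcs.points * k, role="ALCS"),
            bmo_temporal=Point2D(section.bmo_temporal.x * k, section.bmo_temporal.z * k),
            bmo_nasal=Point2D(section.bmo_nasal.x * k, section.bmo_nasal.z * k),
            quality_score=section.quality_score,
        )

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_lcci_scale_invariant(self, k):
        s = build_section(**self.BASE)
        _, _, lcci0 = compute_lcci(s)
        _, _, lcci_k = compute_lcci(self._scaled(s, k))
        assert lcci_k == pytest.approx(lcci0, abs=1e-9)

    def test_rigid_motion_changes_no_index(self):
        s0 = build_section(**self.BASE)
        s1 = build_section(**self.BASE, tilt_deg=1.1, shift=(175.0, -80.0))
        i0, i1 = section_indices(s0), section_indices(s1)
        for attr in ("hrw_temporal", "hrw_nasal", "mrw_temporal", "mrw_nasal", "w", "lcci"):
            assert getattr(i1, attr) == pytest.approx(getattr(i0, attr), abs=1e-6)

    def test_mrw_below_hrw_hence_hmr_at_least_one(self):
        s = build_section(**self.BASE)
        idx = section_indices(s)
        assert idx.mrw_temporal <= idx.hrw_temporal
        assert idx.mrw_nasal <= idx.hrw_nasal
        assert idx.hmr >= 1.0
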