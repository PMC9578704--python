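"""Sibling classification, motility, distances, angles, flatness, fate flags."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

import gutlapse as gl
from gutlapse import lineage as lin
from gutlapse import siblings as sib


def _track(cell_id, rows, parent=None):
    """rows: (frame, x, y, z[, area, gfp])"""
    recs = []
    for r in rows:
        frame, x, y, z = r[:4]
        area = r[4] if len(r) > 4 else 12.0
        gfp = r[5] if len(r) > 5 else 100.0
        recs.append((frame, x, y, z, area, gfp))
    return lin.Track(cell_id, parent, pd.DataFrame(
        recs, columns=lin.POINT_COLUMNS))


def _pair(track_a, track_b, div_frame=2, div_a=None, div_b=None):
    div = lin.DivisionEvent(0, (track_a.cell_id, track_b.cell_id), div_frame)
    return sib.SiblingPair(division=div, lineage_id=0, track_a=track_a,
                           track_b=track_b, div_frame_a=div_a, div_frame_b=div_b)


class TestClassifyPair:
    def _daughters(self, last_a, last_b):
        a = _track(1, [(f, 0.0, 0.0, 0.0) for f in range(3, last_a + 1)])
        b = _track(2, [(f, 4.0, 0.0, 0.0) for f in range(3, last_b + 1)])
        return a, b

    def test_both_dividing_is_codividing_with_interval(self):
        a, b = self._daughters(10, 12)
        p = _pair(a, b, div_a=10, div_b=12)
        assert gl.classify_pair(p, 40) == sib.LABEL_CODIVIDING
        assert p.codiv_interval_h == 2.0

    def test_one_dividing_with_long_quiescence_is_noncodividing(self):
        a, b = self._daughters(30, 36)
        p = _pair(a, b, div_a=30)
        assert gl.classify_pair(p, 40) == sib.LABEL_NONCODIVIDING

    def test_short_observation_window_unclassifiable(self):
        a, b = self._daughters(30, 33)
        p = _pair(a, b, div_a=30)
        assert gl.classify_pair(p, 40) == sib.LABEL_UNCLASSIFIABLE

    def test_neither_dividing_unclassifiable(self):
        a, b = self._daughters(40, 40)
        p = _pair(a, b)
        assert gl.classify_pair(p, 40) == sib.LABEL_UNCLASSIFIABLE

    def test_labels_partition_scene_pairs(self, small_scene):
        trees = gl.build_lineage_trees(small_scene.truth_tracks)
        pairs = gl.find_sibling_pairs(trees)
        end = int(small_scene.truth_tracks["frame"].max())
        labels = [gl.classify_pair(p, end) for p in pairs]
        allowed = {sib.LABEL_CODIVIDING, sib.LABEL_NONCODIVIDING,
                   sib.LABEL_UNCLASSIFIABLE}
        assert set(labels) <= allowed
        assert len(labels) == len(pairs)

    def test_accuracy_against_generator_fate_labels(self, small_scene):
        """Pairs with enough movie left are labeled like the generator says."""
        scene = small_scene
        trees = gl.build_lineage_trees(scene.truth_tracks)
        pairs = gl.find_sibling_pairs(trees)
        end = int(scene.truth_tracks["frame"].max())
        truth = {
            tuple(sorted((r.daughter_a, r.daughter_b))): r.label
            for r in scene.truth_pairs.itertuples()
        }
        want_map = {"symmetric-like": sib.LABEL_CODIVIDING,
                    "asymmetric-like": sib.LABEL_NONCODIVIDING}
        # sufficient window: the division happened early enough that any
        # daughter cycle (mean 8 h, sd 2.76 h) would complete before the end
        ok = [p for p in pairs if p.division.frame <= end - 20]
        assert len(ok) >= 100
        hits = 0
        for p in ok:
            got = gl.classify_pair(p, end)
            want = want_map[truth[tuple(sorted(p.division.daughter_ids))]]
            hits += (got == want)
        assert hits / len(ok) >= 0.95


class TestMotilitySeries:
    def test_three_four_five_step(self):
        t = _track(1, [(0, 0.0, 0.0, 0.0), (1, 3.0, 4.0, 0.0)])
        series = gl.motility_series(t)
        assert series.steps["step_um"].tolist() == [5.0]

    def test_z_counts_in_three_d(self):
        t = _track(1, [(0, 0.0, 0.0, 0.0), (1, 4.0, 0.0, 3.0)])
        assert gl.motility_series(t).steps["step_um"].tolist() == [5.0]

    def test_iqr_flags_jump(self):
        rows = [(f, float(f), 0.0, 0.0) for f in range(6)]
        rows.append((6, 25.0, 0.0, 0.0))  # steps 1,1,1,1,1,20
        series = gl.motility_series(_track(1, rows))
        assert series.steps["outlier"].tolist() == [False] * 5 + [True]
        assert series.clean_steps().tolist() == [1.0] * 5

    def test_single_frame_track_rejected(self):
        with pytest.raises(ValueError):
            gl.motility_series(_track(1, [(0, 0.0, 0.0, 0.0)]))

    def test_translation_invariance(self, rng):
        rows = [(f, *rng.uniform(0, 10, 3)) for f in range(8)]
        t0 = _track(1, rows)
        shifted = [(f, x + 50.0, y - 30.0, z + 7.0) for f, x, y, z in rows]
        t1 = _track(1, shifted)
        assert np.allclose(gl.motility_series(t0).steps["step_um"],
                           gl.motility_series(t1).steps["step_um"])


class TestInternuclearDistance:
    def test_coincident_daughters_start_at_zero(self):
        a = _track(1, [(3, 1.0, 1.0, 0.0)])
        b = _track(2, [(3, 1.0, 1.0, 0.0)])
        d = gl.internuclear_distance_series(_pair(a, b))
        assert d.tolist() == [0.0]

    def test_linear_separation_series(self):
        a = _track(1, [(3 + k, 2.0 + k, 0.0, 0.0) for k in range(8)])
        b = _track(2, [(3 + k, -2.0 - k, 0.0, 0.0) for k in range(8)])
        d = gl.internuclear_distance_series(_pair(a, b))
        assert d.tolist() == [4.0, 6.0, 8.0, 10.0, 12.0, 14.0]  # capped at t5

    def test_symmetry_in_daughter_order(self, rng):
        rows_a = [(3 + k, *rng.uniform(0, 10, 3)) for k in range(6)]
        rows_b = [(3 + k, *rng.uniform(0, 10, 3)) for k in range(6)]
        a, b = _track(1, rows_a), _track(2, rows_b)
        ab = gl.internuclear_distance_series(_pair(a, b))
        ba = gl.internuclear_distance_series(_pair(b, a))
        assert np.allclose(ab, ba)

    def test_scene_dichotomy_symmetric_vs_asymmetric(self):
        """Symmetric-like pairs separate; asymmetric-like ones do not."""
        params = gl.SimulationParams(n_founders=40, t_max=40.0, seed=13,
                                     field_size_um=(500.0, 500.0),
                                     p_symmetric=0.5)
        scene = gl.simulate_lineages(params)
        trees = gl.build_lineage_trees(scene.truth_tracks)
        pairs = gl.find_sibling_pairs(trees)
        truth = {tuple(sorted((r.daughter_a, r.daughter_b))): r.label
                 for r in scene.truth_pairs.itertuples()}
        deltas = {"symmetric-like": [], "asymmetric-like": []}
        for p in pairs:
            d = gl.internuclear_distance_series(p)
            if len(d) == 6:
                deltas[truth[tuple(sorted(p.division.daughter_ids))]].append(
                    d[5] - d[0])
        sym = np.asarray(deltas["symmetric-like"])
        asym = np.asarray(deltas["asymmetric-like"])
        assert len(sym) >= 50 and len(asym) >= 50
        assert sym.mean() > 3 * sym.std(ddof=1) / np.sqrt(len(sym))
        # asymmetric-like pairs: no change beyond sampling noise plus the
        # small diffusion-curvature bias, and negligible next to the
        # directed co-dividing separation
        bound = max(3 * asym.std(ddof=1) / np.sqrt(len(asym)),
                    0.05 * sym.mean())
        assert abs(asym.mean()) < bound


class TestRelativeMovement:
    def test_common_motion_cancels(self):
        a = _track(1, [(3, 0.0, 0.0, 0.0), (4, 2.0, 1.0, 0.0)])
        b = _track(2, [(3, 5.0, 0.0, 0.0), (4, 7.0, 1.0, 0.0)])
        assert gl.relative_movement_magnitudes(_pair(a, b)).tolist() == [0.0]

    def test_opposed_unit_steps(self):
        a = _track(1, [(3, 0.0, 0.0, 0.0), (4, 1.0, 0.0, 0.0)])
        b = _track(2, [(3, 5.0, 0.0, 0.0), (4, 4.0, 0.0, 0.0)])
        assert gl.relative_movement_magnitudes(_pair(a, b)).tolist() == [2.0]

    def test_z_motion_excluded(self):
        a = _track(1, [(3, 0.0, 0.0, 0.0), (4, 0.0, 0.0, 9.0)])
        b = _track(2, [(3, 5.0, 0.0, 0.0), (4, 5.0, 0.0, 0.0)])
        assert gl.relative_movement_magnitudes(_pair(a, b)).tolist() == [0.0]

    def test_symmetry_in_daughter_order(self, rng):
        rows_a = [(3 + k, *rng.uniform(0, 10, 3)) for k in range(6)]
        rows_b = [(3 + k, *rng.uniform(0, 10, 3)) for k in range(6)]
        a, b = _track(1, rows_a), _track(2, rows_b)
        assert np.allclose(gl.relative_movement_magnitudes(_pair(a, b)),
                           gl.relative_movement_magnitudes(_pair(b, a)))

    def test_greater_for_symmetric_like_pairs(self):
        params = gl.SimulationParams(n_founders=40, t_max=40.0, seed=17,
                                     field_size_um=(500.0, 500.0),
                                     p_symmetric=0.5)
        scene = gl.simulate_lineages(params)
        trees = gl.build_lineage_trees(scene.truth_tracks)
        pairs = gl.find_sibling_pairs(trees)
        truth = {tuple(sorted((r.daughter_a, r.daughter_b))): r.label
                 for r in scene.truth_pairs.itertuples()}
        mags = {"symmetric-like": [], "asymmetric-like": []}
        for p in pairs:
            m = gl.relative_movement_magnitudes(p)[:5]
            if len(m):
                mags[truth[tuple(sorted(p.division.daughter_ids))]].append(
                    float(np.mean(m)))
        res = gl.mann_whitney(mags["symmetric-like"][:50],
                              mags["asymmetric-like"][:50])
        assert res.pvalue < 0.01
        assert np.mean(mags["symmetric-like"]) > np.mean(mags["asymmetric-like"])


class TestSisterAngle:
    def test_in_plane_pair_is_zero_degrees(self):
        a = _track(1, [(3, 0.0, 0.0, 5.0)])
        b = _track(2, [(3, 4.0, 0.0, 5.0)])
        assert gl.sister_angle(_pair(a, b)).angle_deg == 0.0

    def test_equal_lateral_and_axial_is_45_degrees(self):
        a = _track(1, [(3, 0.0, 0.0, 0.0)])
        b = _track(2, [(3, 3.0, 0.0, 3.0)])
        assert gl.sister_angle(_pair(a, b)).angle_deg == pytest.approx(45.0)

    def test_one_slice_offset_near_fifteen_degrees(self):
        # lateral 11.2 µm, one 3 µm z-slice apart: just under the 15° bin edge
        a = _track(1, [(3, 0.0, 0.0, 0.0)])
        b = _track(2, [(3, 11.2, 0.0, 3.0)])
        res = gl.sister_angle(_pair(a, b))
        assert res.angle_deg == pytest.approx(
            np.degrees(np.arctan(3.0 / 11.2)), abs=1e-9)
        assert res.angle_deg == pytest.approx(15.0, abs=0.05)
        assert res.lateral_um == 11.2 and res.axial_um == 3.0

    def test_coincident_centers_rejected(self):
        a = _track(1, [(3, 1.0, 1.0, 1.0)])
        b = _track(2, [(3, 1.0, 1.0, 1.0)])
        with pytest.raises(ValueError, match="zero baseline"):
            gl.sister_angle(_pair(a, b))


class TestFlatnessCheck:
    div = lin.DivisionEvent(1, (2, 3), 5)

    def test_coplanar_neighbors_flat(self, rng):
        pts = np.column_stack([rng.uniform(0, 30, 8), rng.uniform(0, 30, 8),
                               np.full(8, 12.0)])
        res = gl.flatness_check(self.div, pts)
        assert res.flat and res.tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_thirty_degree_plane_not_flat(self, rng):
        x = rng.uniform(0, 30, 10)
        y = rng.uniform(0, 30, 10)
        z = np.tan(np.radians(30.0)) * x
        res = gl.flatness_check(self.div, np.column_stack([x, y, z]),
                                tilt_max_deg=10.0)
        assert not res.flat
        assert res.tilt_deg == pytest.approx(30.0, abs=1e-6)

    def test_noisy_flat_plane_still_flat(self, rng):
        pts = np.column_stack([
            rng.uniform(0, 30, 20), rng.uniform(0, 30, 20),
            10.0 + rng.normal(0, 0.5, 20)])
        res = gl.flatness_check(self.div, pts, tilt_max_deg=10.0)
        assert res.flat

    def test_too_few_neighbors_flagged(self):
        res = gl.flatness_check(self.div, np.zeros((3, 3)))
        assert res.flat is None
        assert res.flag == "insufficient neighbors"


class TestDifferentiationFlags:
    @staticmethod
    def _cell_track(area0, area1, gfp0, gfp1, n=49):
        rows = [
            (f, 0.0, 0.0, 0.0,
             area0 + (area1 - area0) * f / (n - 1),
             gfp0 + (gfp1 - gfp0) * f / (n - 1))
            for f in range(n)
        ]
        return _track(1, rows)

    def test_unchanged_cell_not_flagged(self):
        t = self._cell_track(12.0, 12.0, 80.0, 80.0)
        res = gl.differentiation_flags(t, 0, 48)
        assert (res.area_ratio, res.gfp_ratio) == (1.0, 1.0)
        assert not res.differentiating

    def test_growing_dimming_cell_flagged(self):
        t = self._cell_track(12.0, 24.0, 80.0, 24.0)
        res = gl.differentiation_flags(t, 0, 48, area_fold_min=1.5,
                                       gfp_fold_max=0.5)
        assert res.differentiating
        assert res.area_ratio == 2.0 and res.gfp_ratio == 0.3

    def test_zero_reference_gfp_falls_back_to_area(self):
        t = self._cell_track(12.0, 30.0, 0.0, 10.0)
        res = gl.differentiation_flags(t, 0, 48)
        assert res.differentiating
        assert "zero-reference-gfp" in res.flags
        assert np.isnan(res.gfp_ratio)

    def test_recall_on_generated_differentiating_daughters(self):
        """Quiescent daughters of asymmetric divisions are recalled >= 0.9."""
        params = gl.SimulationParams(n_founders=40, t_max=72.0, seed=19,
                                     p_symmetric=0.0,
                                     gfp_onset_range=(0.0, 4.0),
                                     field_size_um=(400.0, 400.0))
        scene = gl.simulate_lineages(params)
        tracks = scene.truth_tracks
        quiescent = tracks[tracks["fate"] == "quiescent"]
        flags = []
        for cid, grp in quiescent.groupby("cell_id"):
            frames = grp["frame"].to_numpy()
            if frames[-1] - frames[0] < 48:
                continue
            if grp.iloc[0]["gfp"] == 0:
                continue
            track = lin.Track(int(cid), None, grp[lin.POINT_COLUMNS]
                              .reset_index(drop=True))
            res = gl.differentiation_flags(
                track, int(frames[0]), int(frames[0]) + 48,
                area_fold_min=1.5, gfp_fold_max=0.5)
            flags.append(res.differentiating)
        assert len(flags) >= 50
        assert np.mean(flags) >= 0.9


class TestPairTable:
    def test_schema_and_truncation(self):
        a = _track(1, [(3 + k, 2.0 + k, 0.0, 0.0) for k in range(3)])
        b = _track(2, [(3 + k, -2.0 - k, 0.0, 0.0) for k in range(3)])
        p = _pair(a, b)
        p.label = sib.LABEL_UNCLASSIFIABLE
        df = sib.pair_table([p])
        assert df.loc[0, "dist_t0"] == 4.0
        assert np.isnan(df.loc[0, "dist_t3"])
        for col in ("division_id", "lineage_id", "label", "codiv_interval_h",
                    "angle_deg", "flat_flag"):
            assert col in df.columns
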