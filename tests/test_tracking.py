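"""Detection, linking, and velocity fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from depcyte.tracking import (DetectionParams, LinkParams, Track,
                              detect, estimate_background, link,
                              tracks_to_frame, velocities)


def _noise_frame(rng, shape=(80, 120), level=12.0, sd=3.0):
    return np.clip(rng.normal(level, sd, shape), 0, 255).astype(np.uint8)


class TestBackground:
    def test_constant_frames_reproduced(self):
        frames = np.full((25, 40, 60), 17, dtype=np.uint8)
        bg = estimate_background(frames)
        np.testing.assert_array_equal(bg, 17)

    def test_moving_cell_absent_from_median(self, rng):
        """A bright blob covering each pixel < 50% of the time leaves the
        temporal median at the background level."""
        frames = np.full((40, 50, 200), 10, dtype=np.uint8)
        for f in range(40):
            c = 5 + f * 4
            frames[f, 20:30, c:c + 10] = 200
        bg = estimate_background(frames)
        assert bg.max() <= 11

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((10, 20, 20), dtype=np.uint8))


class TestDetect:
    def test_empty_frame_no_detections(self, rng):
        bg = np.full((80, 120), 12.0)
        frame = _noise_frame(np.random.default_rng(0))
        feats = detect(frame, bg)
        assert feats == []

    def test_anomalous_merged_blob_rejected(self):
        """Two overlapping cells render as one elongated component whose
        eccentricity exceeds the anomaly cutoff (aggregate rejection)."""
        from depcyte.synthetic_imaging import (OpticsSpec, RenderNoise,
                                               render_frames)

        optics = OpticsSpec(frame_shape=(100, 140))
        truth = pd.DataFrame(
            [(0, 0, 62.0, 50.0, 7.5), (0, 1, 78.0, 50.0, 7.5)],
            columns=["frame", "particle_id", "x_px", "y_px", "diameter_um"])
        stack, _ = render_frames(truth, optics, RenderNoise(), seed=2,
                                 n_frames=1)
        empty, _ = render_frames(truth.iloc[:0], optics, RenderNoise(),
                                 seed=2, n_frames=1)
        feats = detect(stack[0], empty[0].astype(float), DetectionParams())
        assert feats == []
        relaxed = detect(stack[0], empty[0].astype(float),
                         DetectionParams(max_eccentricity=0.999,
                                         max_diameter_um=40.0))
        assert len(relaxed) == 1
        assert relaxed[0].eccentricity > 0.75

    def test_saturated_frame_warns_and_returns_empty(self):
        frame = np.full((50, 50), 255.0)
        with pytest.warns(UserWarning):
            assert detect(frame, np.zeros((50, 50))) == []

    def test_additive_illumination_offset_invariance(self):
        """Detection counts are unchanged by a global illumination offset
        (background subtraction property)."""
        rng = np.random.default_rng(1)
        bg0 = np.full((90, 130), 12.0)
        frame = bg0 + rng.normal(0, 2.0, bg0.shape)
        yy, xx = np.mgrid[:90, :130]
        rho = np.hypot(yy - 45.0, xx - 60.0)
        frame += 150 * np.exp(-0.5 * ((rho - 9) / 1.0) ** 2)
        n0 = len(detect(frame, bg0))
        n1 = len(detect(frame + 30.0, bg0 + 30.0))
        assert n0 == n1 == 1


def _detections_frame(rows):
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])


def _exhaustive_pair_assignment(prev_pts, next_pts, max_disp):
    """Minimum-total-squared-displacement matching by exhaustive search
    over the connected components of the gating graph.  Independent of the
    production linker (no assignment-solver library)."""
    gate2 = max_disp ** 2
    cand = {i: [j for j, q in enumerate(next_pts)
                if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 <= gate2]
            for i, p in enumerate(prev_pts)}
    # connected components over the bipartite gating graph
    comp_of_next: dict[int, int] = {}
    comps: list[tuple[list[int], set[int]]] = []
    for i, js in cand.items():
        hit = {comp_of_next[j] for j in js if j in comp_of_next}
        if hit:
            keep = min(hit)
            for other in sorted(hit - {keep}, reverse=True):
                comps[keep][0].extend(comps[other][0])
                comps[keep][1].update(comps[other][1])
                comps[other][0].clear()
                comps[other][1].clear()
            comps[keep][0].append(i)
            comps[keep][1].update(js)
        else:
            comps.append(([i], set(js)))
        for j in js:
            comp_of_next[j] = next(k for k, c in enumerate(comps)
                                   if j in c[1])
    match: dict[int, int] = {}
    for prevs, nexts in comps:
        nexts = sorted(nexts)
        if not prevs or not nexts:
            continue
        best, best_cost = None, math.inf
        k = min(len(prevs), len(nexts))
        for chosen_prevs in itertools.combinations(prevs, k):
            for perm in itertools.permutations(nexts, k):
                cost = 0.0
                ok = True
                for a, b in zip(chosen_prevs, perm):
                    d2 = ((prev_pts[a][0] - next_pts[b][0]) ** 2
                          + (prev_pts[a][1] - next_pts[b][1]) ** 2)
                    if d2 > gate2:
                        ok = False
                        break
                    cost += d2
                if ok and cost < best_cost:
                    best = dict(zip(chosen_prevs, perm))
                    best_cost = cost
        if best:
            match.update(best)
    return match


def _brute_force_link(dets: pd.DataFrame, max_disp: float) -> list[list[int]]:
    """Independent linking oracle: frame-to-frame optimal matching by
    exhaustive enumeration; returns particle paths as detection indices."""
    frames = sorted(dets.frame.unique())
    paths = [[i] for i in dets.index[dets.frame == frames[0]]]
    for fa, fb in zip(frames[:-1], frames[1:]):
        prev_rows = [p[-1] for p in paths if dets.loc[p[-1], "frame"] == fa]
        next_rows = list(dets.index[dets.frame == fb])
        prev_pts = [(dets.loc[i, "x_px"], dets.loc[i, "y_px"])
                    for i in prev_rows]
        next_pts = [(dets.loc[j, "x_px"], dets.loc[j, "y_px"])
                    for j in next_rows]
        match = _exhaustive_pair_assignment(prev_pts, next_pts, max_disp)
        assigned = set()
        for ia, ib in match.items():
            a, b = prev_rows[ia], next_rows[ib]
            for p in paths:
                if p[-1] == a:
                    p.append(b)
                    assigned.add(b)
                    break
        for b in next_rows:
            if b not in assigned:
                paths.append([b])
    return paths


class TestLink:
    def test_single_cell_single_track(self):
        rows = [(f, 10 + 6.0 * f, 40.0) for f in range(20)]
        tracks = link(_detections_frame(rows))
        assert len(tracks) == 1
        assert len(tracks[0].features) == 20

    def test_crossing_cells_identity_preserved(self):
        """Two cells crossing in y but well separated in x: the optimal
        assignment keeps identities where greedy nearest-neighbour (from
        the crossing point) could swap them."""
        rows = []
        for f in range(30):
            rows.append((f, 10 + 6.0 * f, 20.0 + 2.0 * f))   # rising
            rows.append((f, 100 + 6.0 * f, 80.0 - 2.0 * f))  # falling
        tracks = link(_detections_frame(rows), LinkParams(max_disp_px=12))
        assert len(tracks) == 2
        for t in tracks:
            x0 = t.features[0].x_px
            ys = t.y_px
            if x0 < 50:
                assert np.all(np.diff(ys) > 0)
            else:
                assert np.all(np.diff(ys) < 0)

    def test_memory_bridges_short_gaps(self):
        rows = [(f, 10 + 6.0 * f, 40.0) for f in range(20) if f != 9]
        tracks = link(_detections_frame(rows), LinkParams(memory=2))
        assert len(tracks) == 1
        assert tracks[0].gap_count == 1

    def test_agreement_with_brute_force_oracle(self, rng):
        """50 cells drifting with noise: >= 99% of frame-to-frame
        assignments match an independent exhaustive optimal matcher."""
        local = np.random.default_rng(99)
        rows = []
        n_frames = 12
        starts = np.column_stack([local.uniform(0, 400, 50),
                                  local.uniform(0, 600, 50)])
        for f in range(n_frames):
            for i, (y0, x0) in enumerate(starts):
                rows.append((f, x0 + 7.0 * f + local.normal(0, 0.3),
                             y0 + local.normal(0, 0.3)))
        dets = _detections_frame(rows)
        tracks = link(dets, LinkParams(max_disp_px=10, memory=0,
                                       min_track_length=2))
        paths = _brute_force_link(dets, max_disp=10)

        def edge_set(seqs):
            edges = set()
            for seq in seqs:
                for a, b in zip(seq[:-1], seq[1:]):
                    edges.add((a, b))
            return edges

        oracle_edges = edge_set([p for p in paths if len(p) > 1])
        got_paths = []
        for t in tracks:
            idx = []
            for ft in t.features:
                match = dets[(dets.frame == ft.frame)
                             & (np.abs(dets.x_px - ft.x_px) < 1e-9)
                             & (np.abs(dets.y_px - ft.y_px) < 1e-9)]
                idx.append(int(match.index[0]))
            got_paths.append(idx)
        got_edges = edge_set(got_paths)
        agreement = len(got_edges & oracle_edges) / len(oracle_edges)
        assert agreement >= 0.99


def _uniform_track(v_um_s=1000.0, n=120, fps=226.0, um_per_px=0.62,
                   noise_px=0.0, rng=None):
    t = Track(particle_id=0)
    from depcyte.tracking import CellFeature

    for f in range(n):
        x_um = 20 + v_um_s * f / fps
        x_px = x_um / um_per_px
        if noise_px and rng is not None:
            x_px += rng.normal(0, noise_px)
        t.features.append(CellFeature(frame=f, y_px=40.0, x_px=x_px,
                                      area_px2=300, diameter_um=12.0,
                                      eccentricity=0.1))
    return t


class TestVelocities:
    def test_exact_uniform_motion(self):
        track = _uniform_track()
        out = velocities(track, electrode_window_um=(250.0, 345.0))
        assert out["vi_um_s"] == pytest.approx(1000.0, rel=1e-9)
        assert out["vo_um_s"] == pytest.approx(1000.0, rel=1e-9)
        assert out["vdiff_um_s"] == pytest.approx(0.0, abs=1e-6)

    def test_frame_spacing_matches_operating_point(self):
        """1000 um/s at 226 fps: consecutive fitted displacements are
        4.42 um/frame."""
        track = _uniform_track()
        dx_um = np.diff(track.x_px) * 0.62
        np.testing.assert_allclose(dx_um, 1000.0 / 226.0, rtol=1e-9)
        assert 1000.0 / 226.0 == pytest.approx(4.42, abs=0.005)

    def test_estimator_unbiased_under_centroid_noise(self):
        """Constant 1000 um/s with 0.5 px centroid noise, 200 replicates:
        mean fitted velocity within 0.5% of truth."""
        local = np.random.default_rng(5)
        vis = []
        for _ in range(200):
            track = _uniform_track(noise_px=0.5, rng=local)
            out = velocities(track, electrode_window_um=(250.0, 345.0))
            vis.append(out["vi_um_s"])
        assert np.mean(vis) == pytest.approx(1000.0, rel=0.005)

    def test_partial_flag_when_one_side_missing(self):
        track = _uniform_track(n=40)  # ends before the window's far side
        out = velocities(track, electrode_window_um=(250.0, 345.0))
        assert "partial" in out["flags"]

    def test_all_points_inside_window_rejected(self):
        track = _uniform_track(n=10)
        with pytest.raises(ValueError):
            velocities(track, electrode_window_um=(-1000.0, 2000.0))


def test_tracks_to_frame_columns():
    tracks = link(_detections_frame(
        [(f, 10 + 6.0 * f, 40.0) for f in range(8)]))
    df = tracks_to_frame(tracks)
    assert list(df.columns) == ["particle_id", "frame", "x_px", "y_px",
                                "area_px2", "diameter_um", "eccentricity"]
    assert df.frame.is_monotonic_increasing
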