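"""Micropillar pipeline: localization, lattice fitting, tracking, forces."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mechassay import pillars, synth
from mechassay.pillars import (
    PillarTrack,
    cell_traction_summary,
    compute_forces,
    detect_pillars,
    fit_reference_lattice,
    track_pillars,
)


class TestDetection:
    def test_single_spot_subpixel(self, spec):
        img = synth.render_spots((64, 64), np.array([[32.0, 32.0]]),
                                 spec.spot_sigma_px)
        c = detect_pillars(img, spec)
        assert len(c) == 1
        assert np.abs(c[0] - 32.0).max() < 0.05

    def test_lattice_count(self, spec):
        # 4×4 square lattice
        xs = 20 + spec.pitch_px * np.arange(4)
        gx, gy = np.meshgrid(xs, xs)
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        img = synth.render_spots((128, 128), nodes, spec.spot_sigma_px)
        assert len(detect_pillars(img, spec)) == 16

    def test_snr10_localization_error(self, spec):
        """Per-coordinate localization precision < 0.1 px at peak SNR 10
        over 100 seeded repeats (the Gaussian-fit read-noise limit here is
        ≈ 0.07 px per axis)."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            c_true = 32 + rng.uniform(-0.5, 0.5, 2)
            img = synth.render_spots((64, 64), c_true[None], spec.spot_sigma_px)
            img = img + rng.normal(0, 10.0, img.shape)  # amplitude 100 → SNR 10
            c = detect_pillars(img, spec)
            assert len(c) == 1
            errs.append(c[0] - c_true)
        assert np.sqrt(np.mean(np.square(errs))) < 0.1

    def test_empty_frame_warns(self, spec):
        with pytest.warns(UserWarning, match="no spots"):
            out = detect_pillars(np.zeros((32, 32)), spec)
        assert out.shape == (0, 2)


def _lattice_nodes(spec, rotation_deg=0.0, n=6, origin=(24.0, 24.0)):
    i, j = np.meshgrid(np.arange(n), np.arange(n))
    th = np.radians(rotation_deg)
    a1 = spec.pitch_px * np.array([np.cos(th), np.sin(th)])
    a2 = spec.pitch_px * np.array([-np.sin(th), np.cos(th)])
    return np.asarray(origin) + i.ravel()[:, None] * a1 + j.ravel()[:, None] * a2


class TestReferenceLattice:
    def test_self_consistency_on_perfect_lattice(self, spec):
        nodes = _lattice_nodes(spec)
        fit = fit_reference_lattice(nodes, spec, np.zeros((160, 160), bool))
        assert fit.rms_residual_px < 0.02
        d = np.linalg.norm(
            fit.node_positions[:, None] - nodes[None], axis=2
        ).min(axis=1)
        assert d.max() < 0.02

    def test_rotation_recovery(self, spec):
        nodes = _lattice_nodes(spec, rotation_deg=5.0)
        fit = fit_reference_lattice(nodes, spec, np.zeros((200, 200), bool))
        assert fit.rotation_deg == pytest.approx(5.0, abs=0.1)

    def test_deflected_pillars_get_ideal_references(self, spec, cell_mask):
        stack, truth = synth.generate_pillar_video(
            spec, cell_mask, 1.36, n_frames=1, seed=5
        )
        cents = detect_pillars(stack[0], spec)
        fit = fit_reference_lattice(cents, spec, cell_mask, stack.shape[1:])
        nodes = truth.parameters["node_positions_px"]
        under = truth.parameters["under_cell"]
        # every true node has a fitted reference at the IDEAL position
        d = np.linalg.norm(
            fit.node_positions[:, None] - nodes[None], axis=2
        ).min(axis=0)
        assert d[under].max() < 0.05

    def test_too_few_free_pillars_rejected(self, spec):
        nodes = _lattice_nodes(spec, n=3)
        with pytest.raises(ValueError, match="reference unresolvable"):
            fit_reference_lattice(nodes, spec, np.ones((160, 160), bool))


class TestTracking:
    def test_static_deflections_constant_and_accurate(self, spec, cell_mask):
        stack, truth = synth.generate_pillar_video(
            spec, cell_mask, 1.1, n_frames=10, seed=2, anchor="max"
        )
        tracks = track_pillars(stack, spec, cell_mask)
        nodes = truth.parameters["node_positions_px"]
        defl = truth.parameters["deflections_um"]
        tol_um = 0.05 * spec.pixel_size_um
        for tr in tracks:
            i = np.argmin(
                np.linalg.norm(nodes - tr.reference_xy / spec.pixel_size_um, axis=1)
            )
            assert np.nanstd(tr.deflections, axis=0).max() < 1e-9  # constant
            assert np.abs(tr.deflections[0] - defl[i]).max() < tol_um

    def test_zero_force_null_case(self, spec, cell_mask):
        stack, _ = synth.generate_pillar_video(spec, cell_mask, 0.0,
                                               n_frames=3, seed=2)
        tracks = track_pillars(stack, spec, cell_mask)
        mags = np.concatenate([t.deflection_magnitudes for t in tracks])
        assert np.nanmax(mags) < 0.05 * spec.pixel_size_um

    def test_occluded_pillar_has_one_missing_frame(self, spec, cell_mask):
        stack, truth = synth.generate_pillar_video(spec, cell_mask, 0.0,
                                                   n_frames=12, seed=2)
        stack = np.array(stack)
        node = truth.parameters["node_positions_px"][0]
        x, y = int(round(node[0])), int(round(node[1]))
        stack[10, y - 4 : y + 5, x - 4 : x + 5] = 10.0  # erase spot in frame 10
        tracks = track_pillars(stack, spec, cell_mask)
        tr = min(
            tracks,
            key=lambda t: np.linalg.norm(t.reference_xy / spec.pixel_size_um - node),
        )
        assert tr.n_missing == 1
        assert np.isnan(tr.deflections[10, 0])

    def test_translation_equivariance(self, spec, cell_mask):
        """Integer-pixel shifts of the whole stack leave deflections unchanged."""
        stack, _ = synth.generate_pillar_video(spec, cell_mask, 1.0,
                                               n_frames=2, seed=4, anchor="max")
        t0 = track_pillars(stack, spec, cell_mask)
        shifted = np.roll(stack, (3, -2), axis=(1, 2))
        mask_s = np.roll(cell_mask, (3, -2), axis=(0, 1))
        t1 = track_pillars(shifted, spec, mask_s)
        m0 = np.sort(np.concatenate([t.deflection_magnitudes for t in t0]))
        m1 = np.sort(np.concatenate([t.deflection_magnitudes for t in t1]))
        assert np.allclose(m0, m1, atol=0.02 * spec.pixel_size_um)

    def test_matches_exhaustive_assignment_oracle(self, spec, cell_mask):
        """Nearest-node tracking agrees with a globally optimal
        centroid-to-node assignment (Hungarian) on a ≤25-pillar stack."""
        small = synth.ellipse_mask((128, 128), (64, 64), (30, 26))
        stack, _ = synth.generate_pillar_video(spec, small, 1.3, n_frames=1,
                                               seed=8, anchor="max")
        cents = detect_pillars(stack[0], spec)
        fit = fit_reference_lattice(cents, spec, small, stack.shape[1:])
        assert len(fit.node_positions) <= 25
        cost = np.linalg.norm(
            cents[:, None] - fit.node_positions[None], axis=2
        )
        ri, ci = linear_sum_assignment(cost)
        oracle = {c: cents[r] for r, c in zip(ri, ci)}
        tracks = track_pillars(stack, spec, small, lattice=fit)
        for tr in tracks:
            obs = tr.positions[0] / spec.pixel_size_um
            if np.isnan(obs[0]):
                continue
            assert np.abs(obs - oracle[tr.pillar_id]).max() < 0.05


class TestForces:
    def test_printed_spring_constant_conversion(self):
        tr = PillarTrack(0, np.zeros(2), np.array([[1.0, 0.0]]),
                        np.array([[1.0, 0.0]]))
        compute_forces([tr], 1.36)
        assert tr.forces[0] == pytest.approx(1.36)

    def test_euclidean_norm_hand_example(self):
        # |(0.3, 0.4)| = 0.5 µm → 0.68 nN at k = 1.36
        tr = PillarTrack(0, np.zeros(2), np.array([[0.3, 0.4]]),
                        np.array([[0.3, 0.4]]))
        compute_forces([tr], 1.36)
        assert tr.forces[0] == pytest.approx(0.68)

    def test_zero_and_missing(self):
        d = np.array([[0.0, 0.0], [np.nan, np.nan]])
        tr = PillarTrack(0, np.zeros(2), d, d)
        compute_forces([tr], 1.36)
        assert tr.forces[0] == 0.0 and np.isnan(tr.forces[1])

    def test_linearity_doubling(self):
        d = np.array([[0.2, 0.1], [0.4, -0.3]])
        a = PillarTrack(0, np.zeros(2), d, d)
        b = PillarTrack(0, np.zeros(2), 2 * d, 2 * d)
        compute_forces([a], 1.36)
        compute_forces([b], 1.36)
        assert np.allclose(b.forces, 2 * a.forces)

    def test_invalid_spring_constant(self):
        with pytest.raises(ValueError):
            compute_forces([], 0.0)


def _track_at(ref_um, forces):
    T = len(forces)
    d = np.column_stack([np.asarray(forces, float) / 1.36, np.zeros(T)])
    tr = PillarTrack(0, np.asarray(ref_um, float),
                    d + np.asarray(ref_um, float), d)
    compute_forces([tr], 1.36)
    return tr


class TestSummary:
    def test_constant_force(self):
        mask = np.ones((20, 20), bool)
        trs = [_track_at((1.0, 1.0), [2.0] * 60), _track_at((2.0, 2.0), [2.0] * 60)]
        s = cell_traction_summary(trs, mask, pixel_size_um=1.0)
        assert s.mean_max_traction == pytest.approx(2.0)
        assert s.n_pillars_under_cell == 2

    def test_mean_of_per_frame_maxima(self):
        mask = np.ones((20, 20), bool)
        trs = [_track_at((1.0, 1.0), [1.0, 2.0, 3.0]),
               _track_at((2.0, 2.0), [0.5, 0.5, 0.5])]
        s = cell_traction_summary(trs, mask, pixel_size_um=1.0)
        assert np.allclose(s.per_frame_max_force, [1.0, 2.0, 3.0])
        assert s.mean_max_traction == pytest.approx(2.0)

    def test_no_pillars_under_mask_rejected(self):
        mask = np.zeros((20, 20), bool)
        with pytest.raises(ValueError, match="no pillars"):
            cell_traction_summary([_track_at((1.0, 1.0), [1.0])], mask, 1.0)


class TestEndToEnd:
    def test_noiseless_recovery_within_one_percent(self, spec, cell_mask):
        stack, truth = synth.generate_pillar_video(
            spec, cell_mask, 1.1, n_frames=5, seed=1, anchor="max"
        )
        s = pillars.analyze_stack(stack, spec, cell_mask)
        assert s.mean_max_traction == pytest.approx(
            truth.parameters["max_force_nN"], rel=0.01
        )

    def test_small_cohort_recovery_within_2_sem(self, spec):
        ds, truths, _ = synth.generate_cohort("control", "pillar", seed=9, n=12)
        vals = np.array(
            [pillars.analyze_stack(s, sp, m).mean_max_traction for s, m, sp in ds]
        )
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.1) < 2 * sem
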