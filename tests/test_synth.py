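"""Generator correctness: determinism, stated truths, distributional targets."""

import numpy as np
import pytest

from mechassay import pillars, synth, tweezers
from mechassay.synth import (
    PRESETS,
    GroundTruth,
    generate_bead_trajectory,
    generate_cohort,
    generate_cumulative_counts,
    generate_indentation_curve,
    generate_invasion_stack,
    generate_pillar_video,
    lognormal_params,
)


def _mask():
    return synth.ellipse_mask((128, 128), (64, 64), (42, 36))


class TestDeterminism:
    """Identical seed + parameters must reproduce every dataset bit-exactly."""

    def test_pillar_video(self, spec, cell_mask):
        a, _ = generate_pillar_video(spec, cell_mask, 1.1, n_frames=3,
                                     noise_sd=2.0, seed=7)
        b, _ = generate_pillar_video(spec, cell_mask, 1.1, n_frames=3,
                                     noise_sd=2.0, seed=7)
        assert a.dtype == b.dtype and a.tobytes() == b.tobytes()

    def test_bead_trajectory(self):
        p = tweezers.ForceProtocol()
        a, _ = generate_bead_trajectory(p, 1.0, 0.63, seed=7)
        b, _ = generate_bead_trajectory(p, 1.0, 0.63, seed=7)
        assert a.position.tobytes() == b.position.tobytes()

    def test_indentation_curve(self):
        a, _ = generate_indentation_curve(292.0, noise_sd_nN=0.05, seed=7)
        b, _ = generate_indentation_curve(292.0, noise_sd_nN=0.05, seed=7)
        assert a.force_nN.tobytes() == b.force_nN.tobytes()

    def test_invasion_stack(self):
        la, aa, _ = generate_invasion_stack(noise_sd=3.0, seed=7)
        lb, ab, _ = generate_invasion_stack(noise_sd=3.0, seed=7)
        assert la.tobytes() == lb.tobytes() and aa.tobytes() == ab.tobytes()

    def test_counts_and_cohort(self):
        a, _ = generate_cumulative_counts(10, seed=7)
        b, _ = generate_cumulative_counts(10, seed=7)
        assert a.equals(b)
        _, ta, _ = generate_cohort("control", "afm", seed=7, n=5)
        _, tb, _ = generate_cohort("control", "afm", seed=7, n=5)
        assert ta.tobytes() == tb.tobytes()


class TestPillarVideo:
    def test_zero_force_spots_on_lattice(self, spec, cell_mask):
        stack, truth = generate_pillar_video(spec, cell_mask, 0.0, n_frames=1,
                                             seed=0)
        assert np.all(truth.parameters["deflections_um"] == 0)
        cents = pillars.detect_pillars(stack[0], spec)
        nodes = truth.parameters["node_positions_px"]
        d = np.linalg.norm(cents[:, None] - nodes[None], axis=2).min(axis=1)
        assert d.max() < 0.05

    def test_mean_deflection_matches_spring_constant(self, spec, cell_mask):
        # force_scale = k = 1.36 nN/µm  →  mean deflection exactly 1 µm
        _, truth = generate_pillar_video(spec, cell_mask, 1.36, n_frames=1,
                                         seed=3, anchor="mean")
        assert truth.parameters["mean_deflection_um"] == pytest.approx(1.0)

    def test_max_anchor_pins_peak_force(self, spec, cell_mask):
        _, truth = generate_pillar_video(spec, cell_mask, 0.9, n_frames=1,
                                         seed=3, anchor="max")
        assert truth.parameters["max_force_nN"] == pytest.approx(0.9)

    def test_unresolvable_pitch_rejected(self):
        # pillars closer than a spot diameter cannot be resolved at all
        with pytest.raises(ValueError, match="pitch"):
            pillars.PillarArraySpec(pitch_um=1.8, spot_diameter_um=2.0,
                                    pixel_size_um=0.4)


class TestBeadTrajectory:
    def test_flat_schedule_all_amplitudes_equal(self):
        p = tweezers.ForceProtocol()
        _, truth = generate_bead_trajectory(p, 2.0, 1.0, noise_sd_um=0, seed=0)
        assert np.allclose(truth.parameters["amplitudes_um"], 2.0)

    def test_endpoint_amplitude(self):
        p = tweezers.ForceProtocol()
        _, truth = generate_bead_trajectory(p, 1.0, 0.63, noise_sd_um=0, seed=0)
        amps = truth.parameters["amplitudes_um"]
        assert amps[0] == pytest.approx(1.0)
        assert amps[-1] == pytest.approx(0.63)

    def test_noiseless_brute_force_extraction_matches_truth(self):
        """Max-minus-baseline per window on the raw samples recovers the
        schedule within one frame's creep increment."""
        p = tweezers.ForceProtocol()
        fr = 10.0
        traj, truth = generate_bead_trajectory(p, 1.0, 0.63, noise_sd_um=0,
                                               frame_rate_hz=fr, seed=0)
        amps = truth.parameters["amplitudes_um"]
        x = traj.position[:, 0]
        t = traj.time
        # one-frame creep increment at the pulse end
        inc = 1.0 - ((p.pulse_on_s - 1 / fr) / p.pulse_on_s) ** 0.3
        for i in range(p.n_pulses):
            s = 1.0 + i * p.period_s
            on = (t >= s) & (t <= s + p.pulse_on_s)
            base = (t >= s - 1.0) & (t < s)
            est = x[on].max() - np.median(x[base])
            assert est == pytest.approx(amps[i], abs=amps[i] * inc + 1e-9)

    def test_rejects_bad_inputs(self):
        p = tweezers.ForceProtocol()
        with pytest.raises(ValueError):
            generate_bead_trajectory(p, 0.0, 0.63)
        with pytest.raises(ValueError):
            generate_bead_trajectory(p, 1.0, 0.63, frame_rate_hz=1.0)


class TestIndentationCurve:
    def test_matches_independent_closed_form(self):
        """Post-contact force equals an independently coded SI-unit Hertz
        formula to machine precision."""
        E, R, nu, zc = 292.0, 7.5, 0.5, 3.0
        curve, _ = generate_indentation_curve(E, R_um=R, nu=nu, contact_z_um=zc)
        delta_m = np.clip(curve.z_um - zc, 0, None) * 1e-6
        f_si = (4 / 3) * (E / (1 - nu**2)) * np.sqrt(R * 1e-6) * delta_m**1.5
        assert np.allclose(curve.force_nN, f_si * 1e9, rtol=1e-12, atol=1e-15)

    def test_contact_point_continuity(self):
        curve, _ = generate_indentation_curve(
            292.0, contact_z_um=3.0, baseline_offset_nN=0.2,
            baseline_slope_nN_per_um=0.1,
        )
        i = np.argmin(np.abs(curve.z_um - 3.0))
        assert curve.force_nN[i] == pytest.approx(0.2 + 0.1 * curve.z_um[i])

    def test_linear_in_modulus(self):
        c1, _ = generate_indentation_curve(150.0, contact_z_um=3.0)
        c2, _ = generate_indentation_curve(300.0, contact_z_um=3.0)
        post = c1.z_um > 3.0
        assert np.allclose(c2.force_nN[post], 2 * c1.force_nN[post])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_indentation_curve(292.0, z_step_um=0.0)
        with pytest.raises(ValueError):
            generate_indentation_curve(292.0, contact_z_um=10.0)


class TestInvasionStack:
    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_boundary_fractions(self, f):
        _, _, truth = generate_invasion_stack(below_fraction=f)
        p = truth.parameters
        if f == 0.0:
            assert p["cell_bottom_z_um"] == pytest.approx(p["bilayer_z_um"])
        else:
            assert p["cell_top_z_um"] == pytest.approx(p["bilayer_z_um"])

    def test_cell_outside_stack_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_invasion_stack(bilayer_z_um=5.0, below_fraction=1.0,
                                    cell_height_um=15.0)


class TestCumulativeCounts:
    def test_zero_rate(self):
        df, _ = generate_cumulative_counts(0.0, days=5, n_roi=3, seed=0)
        assert (df["new_cells"] == 0).all()

    def test_deterministic_linear_growth(self):
        df, _ = generate_cumulative_counts(10, days=5, n_roi=1,
                                           deterministic=True)
        assert np.array_equal(df["new_cells"].cumsum(), [10, 20, 30, 40, 50])

    def test_poisson_slope_recovery(self):
        import statsmodels.api as sm

        df, _ = generate_cumulative_counts(10, days=5, n_roi=50, seed=11)
        cum = df.groupby("roi_id")["new_cells"].cumsum()
        X = sm.add_constant(df["day"].to_numpy(dtype=float))
        fit = sm.OLS(cum.to_numpy(dtype=float), X).fit()
        assert abs(fit.params[1] - 10) < 2 * fit.bse[1]


class TestCohorts:
    def test_lognormal_parameterization_monte_carlo(self):
        """Sample mean/SD of 10⁴ lognormal draws hit the preset mean and
        SEM·√n within 2%."""
        stat = PRESETS["control"].traction
        mu, sigma = lognormal_params(stat.mean, stat.sd)
        draws = np.random.default_rng(5).lognormal(mu, sigma, 10_000)
        assert abs(draws.mean() - stat.mean) / stat.mean < 0.02
        assert abs(draws.std(ddof=1) - stat.sd) / stat.sd < 0.02

    def test_zero_sem_degenerate_spread(self):
        preset = synth.ConditionPreset(
            "x", stiffness=synth.CohortStat(250.0, 0.0, 10)
        )
        _, truths, _ = generate_cohort(preset, "afm", seed=0, n=4)
        assert np.all(truths == 250.0)

    def test_unknown_preset_and_missing_assay_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            generate_cohort("nope", "afm")
        with pytest.raises(ValueError, match="no data"):
            generate_cohort("siRARB", "invasion")

    def test_ground_truth_roundtrip(self):
        _, _, truth = generate_cohort("control", "afm", seed=3, n=3)
        back = GroundTruth.from_json(truth.to_json())
        assert back.assay == truth.assay and back.seed == truth.seed
        assert np.allclose(
            back.parameters["per_cell_truths"],
            truth.parameters["per_cell_truths"],
        )
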