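"""Ground-truthed synthetic data for every mechanophenotyping assay.

Each generator emulates the raw data one assay produces — micropillar videos,
bead trajectories under the pulsatile force regime, force–indentation curves,
two-channel invasion z-stacks, daily invasion counts — and returns it together
with a :class:`GroundTruth` recording the exact quantities the downstream
pipeline is supposed to recover. All randomness flows through one
``numpy.random.Generator`` seeded explicitly, so identical seeds reproduce
datasets bit-exactly.

Cohorts are parameterised by :class:`ConditionPreset` objects holding the
published cohort statistics (mean ± SEM, n) of each experimental condition;
per-cell ground truths are drawn from a lognormal with matched mean and
SD = SEM·√n, which keeps forces, moduli and amplitudes strictly positive at
the reported dispersions (a Gaussian would not).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .afm import IndentationCurve, hertz_force
from .pillars import PillarArraySpec
from .tweezers import BeadTrajectory, ForceProtocol

__all__ = [
    "GroundTruth",
    "CohortStat",
    "ConditionPreset",
    "PRESETS",
    "ellipse_mask",
    "render_spots",
    "generate_pillar_video",
    "generate_bead_trajectory",
    "generate_indentation_curve",
    "generate_invasion_stack",
    "generate_cumulative_counts",
    "generate_cohort",
    "lognormal_params",
]


@dataclass
class GroundTruth:
    """What the generator actually put into a dataset."""

    assay: str                      # pillar | tweezers | afm | invasion
    parameters: dict
    seed: int

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        s = json.dumps(asdict(self), default=_default, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(**d)


@dataclass(frozen=True)
class CohortStat:
    """Published cohort summary: mean ± SEM over n cells."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("cohort mean must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def sd(self) -> float:
        """Population-level SD implied by the SEM: sem·√n."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class ConditionPreset:
    """Cohort statistics of one experimental condition.

    ``traction`` is the mean maximum traction force (nN), ``stiffness`` the
    Hertz Young's modulus (Pa), ``relamp12`` the 12th-to-1st pulse relative
    bead displacement (dimensionless), ``invasion_day3/5`` percent invasion.
    Conditions for which the study reports no number hold ``None``.
    """

    name: str
    traction: CohortStat | None = None
    stiffness: CohortStat | None = None
    relamp12: CohortStat | None = None
    invasion_day3: CohortStat | None = None
    invasion_day5: CohortStat | None = None


#: Published cohort statistics per condition. The siRARB and agonist+siRARB
#: traction / stiffness / reinforcement means were reported only as "similar
#: to control", so they are control-matched with the condition's own n; their
#: invasion percentages were not reported at all (None).
PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset(
        "control",
        traction=CohortStat(1.1, 0.1, 70),
        stiffness=CohortStat(292, 20, 91),
        relamp12=CohortStat(0.63, 0.02, 41),
        invasion_day3=CohortStat(54, 4, 19),
        invasion_day5=CohortStat(75, 3, 21),
    ),
    "agonist": ConditionPreset(
        "agonist",
        traction=CohortStat(0.7, 0.1, 53),
        stiffness=CohortStat(202, 12, 58),
        relamp12=CohortStat(0.84, 0.06, 22),
        invasion_day3=CohortStat(44, 3, 21),
        invasion_day5=CohortStat(42, 2, 18),
    ),
    "siRARB": ConditionPreset(
        "siRARB",
        traction=CohortStat(1.1, 0.1, 97),
        stiffness=CohortStat(292, 20, 58),
        relamp12=CohortStat(0.63, 0.03, 28),
    ),
    "agonist_siRARB": ConditionPreset(
        "agonist_siRARB",
        traction=CohortStat(1.1, 0.1, 110),
        stiffness=CohortStat(292, 20, 56),
        relamp12=CohortStat(0.63, 0.03, 30),
    ),
    "agonist_OE_MLC2": ConditionPreset(
        "agonist_OE_MLC2",
        traction=CohortStat(1.0, 0.1, 87),
        stiffness=CohortStat(292, 20, 64),
        relamp12=CohortStat(0.63, 0.03, 21),
        invasion_day3=CohortStat(72, 2, 22),
        invasion_day5=CohortStat(70, 2, 22),
    ),
}


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _draw_lognormal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# micropillar videos


def ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]
) -> np.ndarray:
    """Boolean elliptical cell footprint ((cx, cy), (rx, ry), pixels)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cx, cy = center
    rx, ry = radii
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def render_spots(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amplitude: float = 100.0,
    background: float = 10.0,
) -> np.ndarray:
    """Render symmetric 2-D Gaussian spots (patch-based, 4σ support)."""
    h, w = shape
    img = np.full(shape, background, dtype=np.float64)
    r = int(np.ceil(4 * sigma_px))
    for cx, cy in centers_px:
        x0, y0 = int(round(cx)), int(round(cy))
        xs = slice(max(0, x0 - r), min(w, x0 + r + 1))
        ys = slice(max(0, y0 - r), min(h, y0 + r + 1))
        if xs.start >= xs.stop or ys.start >= ys.stop:
            continue
        gx = np.arange(xs.start, xs.stop) - cx
        gy = np.arange(ys.start, ys.stop) - cy
        img[ys, xs] += amplitude * np.outer(
            np.exp(-(gy**2) / (2 * sigma_px**2)),
            np.exp(-(gx**2) / (2 * sigma_px**2)),
        )
    return img


def generate_pillar_video(
    spec: PillarArraySpec,
    cell_mask: np.ndarray,
    force_scale_nN: float,
    n_frames: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
    anchor: str = "mean",
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a micropillar video with a cell pulling on the array.

    Pillar tops are Gaussian spots on a square lattice; pillars whose node
    lies under ``cell_mask`` are displaced toward random fixed directions
    with magnitudes scaled so that — exactly — either their *mean* equals
    ``force_scale_nN / k`` (``anchor="mean"``, so the mean deflection matches
    the nominal force) or their *maximum* does (``anchor="max"``, so the
    video's per-frame maximum force equals ``force_scale_nN``; used by the
    cohort generator whose per-cell truth is the mean-max traction).
    Deflections are constant in time (temporally smooth); the ground truth
    stores the exact per-pillar deflection vectors.
    """
    if force_scale_nN < 0:
        raise ValueError("force_scale_nN must be >= 0")
    if anchor not in ("mean", "max"):
        raise ValueError("anchor must be 'mean' or 'max'")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    shape = cell_mask.shape
    rng = np.random.default_rng(seed)
    pitch = spec.pitch_px
    sigma = spec.spot_sigma_px
    if pitch < 4 * sigma:  # = spot diameter in px: pillars unresolvable
        raise ValueError("lattice pitch smaller than spot diameter")
    margin = pitch / 2 + 4 * sigma
    xs = np.arange(margin, shape[1] - margin, pitch)
    ys = np.arange(margin, shape[0] - margin, pitch)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("lattice does not fit in frame")
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])  # px
    xi = np.round(nodes[:, 0]).astype(int)
    yi = np.round(nodes[:, 1]).astype(int)
    under = cell_mask[yi, xi]

    defl_um = np.zeros_like(nodes)
    n_under = int(under.sum())
    if n_under and force_scale_nN > 0:
        u = rng.uniform(0.3, 1.0, size=n_under)
        u = u / (u.mean() if anchor == "mean" else u.max())
        mags = (force_scale_nN / spec.spring_constant) * u
        ang = rng.uniform(0, 2 * np.pi, size=n_under)
        defl_um[under, 0] = mags * np.cos(ang)
        defl_um[under, 1] = mags * np.sin(ang)

    centers = nodes + defl_um / spec.pixel_size_um
    base = render_spots(shape, centers, sigma)
    stack = np.repeat(base[None], n_frames, axis=0)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    stack = stack.astype(np.float32)

    forces = spec.spring_constant * np.linalg.norm(defl_um, axis=1)
    truth = GroundTruth(
        assay="pillar",
        parameters={
            "force_scale_nN": force_scale_nN,
            "anchor": anchor,
            "node_positions_px": nodes,
            "under_cell": under,
            "deflections_um": defl_um,
            "forces_nN": forces,
            "max_force_nN": float(forces.max(initial=0.0)),
            "mean_deflection_um": float(
                np.linalg.norm(defl_um[under], axis=1).mean()
            ) if n_under else 0.0,
            "n_frames": n_frames,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# bead trajectories


def generate_bead_trajectory(
    protocol: ForceProtocol,
    amp1_um: float,
    relamp12: float,
    noise_sd_um: float = 0.005,
    drift_um_per_s: float = 0.0,
    frame_rate_hz: float = 10.0,
    seed: int = 0,
    t0_s: float = 1.0,
    creep_exponent: float = 0.3,
    recovery_tau_s: float = 0.5,
) -> tuple[BeadTrajectory, GroundTruth]:
    """Synthesize a bead trajectory under the pulsatile force regime.

    Displacement along the force axis is a square-wave-driven creep: during
    pulse *i* it rises as A_i·(t'/t_on)^creep_exponent and relaxes
    exponentially back during the rest period. Per-pulse amplitudes
    interpolate linearly from ``amp1_um`` (pulse 1) to ``amp1_um·relamp12``
    (pulse 12); Gaussian tracking noise and linear drift are added on top.
    """
    if amp1_um <= 0:
        raise ValueError("amp1_um must be positive")
    if relamp12 <= 0:
        raise ValueError("relamp12 must be positive")
    if frame_rate_hz < 2.0:
        raise ValueError("frame rate must resolve the pulse (>= 2 Hz)")
    rng = np.random.default_rng(seed)
    n = protocol.n_pulses
    amps = amp1_um * (1.0 + (relamp12 - 1.0) * np.arange(n) / (n - 1))
    dt = 1.0 / frame_rate_hz
    t_total = t0_s + n * protocol.period_s + 1.0
    t = np.arange(0.0, t_total, dt)
    x = np.zeros_like(t)
    for i in range(n):
        start = t0_s + i * protocol.period_s
        on = (t >= start) & (t < start + protocol.pulse_on_s)
        off = (t >= start + protocol.pulse_on_s) & (t < start + protocol.period_s)
        x[on] += amps[i] * ((t[on] - start) / protocol.pulse_on_s) ** creep_exponent
        x[off] += amps[i] * np.exp(
            -(t[off] - start - protocol.pulse_on_s) / recovery_tau_s
        )
    x = x + drift_um_per_s * t
    pos = np.outer(x, protocol.axis_unit)
    if noise_sd_um > 0:
        pos = pos + rng.normal(0.0, noise_sd_um, size=pos.shape)
    traj = BeadTrajectory(time=t, position=pos, frame_rate=frame_rate_hz)
    truth = GroundTruth(
        assay="tweezers",
        parameters={
            "amplitudes_um": amps,
            "amp1_um": amp1_um,
            "relamp12": relamp12,
            "t0_s": t0_s,
            "noise_sd_um": noise_sd_um,
            "drift_um_per_s": drift_um_per_s,
            "creep_exponent": creep_exponent,
            "recovery_tau_s": recovery_tau_s,
        },
        seed=seed,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# force-indentation curves


def generate_indentation_curve(
    E_true_pa: float,
    R_um: float = 7.5,
    nu: float = 0.5,
    contact_z_um: float = 3.0,
    z_range_um: tuple[float, float] = (0.0, 6.0),
    z_step_um: float = 0.01,
    noise_sd_nN: float = 0.0,
    baseline_slope_nN_per_um: float = 0.0,
    baseline_offset_nN: float = 0.0,
    seed: int = 0,
    cantilever_k: float = 0.03,
) -> tuple[IndentationCurve, GroundTruth]:
    """Synthesize an approach force curve with a spherical-Hertz contact.

    Pre-contact force is the linear baseline; post-contact the baseline plus
    the Hertz force at indentation δ = z − contact_z. Gaussian force noise
    is added when requested.
    """
    if E_true_pa <= 0:
        raise ValueError("E_true_pa must be positive")
    if z_step_um <= 0:
        raise ValueError("z_step_um must be positive")
    if not 0 < nu < 0.5 + 1e-12:
        raise ValueError("nu must be in (0, 0.5]")
    z0, z1 = z_range_um
    if not z0 < contact_z_um < z1:
        raise ValueError("contact_z_um must lie inside z_range_um")
    rng = np.random.default_rng(seed)
    z = np.arange(z0, z1 + z_step_um / 2, z_step_um)
    f = baseline_offset_nN + baseline_slope_nN_per_um * z
    f = f + hertz_force(z - contact_z_um, E_true_pa, R_um, nu)
    if noise_sd_nN > 0:
        f = f + rng.normal(0.0, noise_sd_nN, size=f.shape)
    curve = IndentationCurve(
        z_um=z, force_nN=f, probe_radius_um=R_um,
        cantilever_k=cantilever_k, poisson_nu=nu,
    )
    truth = GroundTruth(
        assay="afm",
        parameters={
            "E_pa": E_true_pa,
            "contact_z_um": contact_z_um,
            "R_um": R_um,
            "nu": nu,
            "noise_sd_nN": noise_sd_nN,
            "baseline_slope_nN_per_um": baseline_slope_nN_per_um,
        },
        seed=seed,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# invasion z-stacks


def generate_invasion_stack(
    bilayer_z_um: float = 15.0,
    cell_height_um: float = 15.0,
    below_fraction: float = 0.5,
    z_step_um: float = 0.5,
    depth_um: float = 30.0,
    shape_xy: tuple[int, int] = (96, 96),
    pixel_size_um: float = 0.25,
    cell_radius_um: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Synthesize a two-channel confocal z-stack of a cell astride the bilayer.

    The laminin channel is a bright plane (axially Gaussian, σ = 0.4 µm) at
    ``bilayer_z_um``; the actin channel is a solid ellipsoidal cell whose
    axial extent has exactly ``below_fraction`` of its height below the
    plane. Returns ``(laminin, actin, truth)`` with both stacks shaped
    (nz, ny, nx).
    """
    if not 0 <= below_fraction <= 1:
        raise ValueError("below_fraction must be in [0, 1]")
    if cell_height_um <= 0:
        raise ValueError("cell_height_um must be positive")
    bottom = bilayer_z_um - below_fraction * cell_height_um
    top = bottom + cell_height_um
    if bottom < 0 or top > depth_um:
        raise ValueError("cell extends outside the stack")
    rng = np.random.default_rng(seed)
    nz = int(round(depth_um / z_step_um)) + 1
    zs = np.arange(nz) * z_step_um
    ny, nx = shape_xy
    laminin = np.zeros((nz, ny, nx))
    laminin += 100.0 * np.exp(-((zs - bilayer_z_um) ** 2) / (2 * 0.4**2))[
        :, None, None
    ]
    yy, xx = np.mgrid[0:ny, 0:nx] * pixel_size_um
    cy, cx = ny * pixel_size_um / 2, nx * pixel_size_um / 2
    rr = np.hypot(yy - cy, xx - cx)
    zc = (top + bottom) / 2
    half = cell_height_um / 2
    actin = np.zeros((nz, ny, nx))
    for k, zv in enumerate(zs):
        u = (zv - zc) / half
        if abs(u) >= 1:
            continue
        r_z = cell_radius_um * np.sqrt(1 - u**2)
        # 1-pixel anti-aliased disk edge
        actin[k] = 100.0 * np.clip((r_z - rr) / pixel_size_um + 0.5, 0.0, 1.0)
    if noise_sd > 0:
        laminin = laminin + rng.normal(0, noise_sd, laminin.shape)
        actin = actin + rng.normal(0, noise_sd, actin.shape)
    truth = GroundTruth(
        assay="invasion",
        parameters={
            "below_fraction": below_fraction,
            "bilayer_z_um": bilayer_z_um,
            "cell_top_z_um": top,
            "cell_bottom_z_um": bottom,
            "cell_height_um": cell_height_um,
            "z_step_um": z_step_um,
        },
        seed=seed,
    )
    return laminin, actin, truth


# ---------------------------------------------------------------------------
# cumulative counts


def generate_cumulative_counts(
    rate_per_day: float,
    days: int = 5,
    n_roi: int = 20,
    seed: int = 0,
    condition: str = "control",
    deterministic: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-ROI daily counts of fully-invaded cells, Poisson(rate) per day.

    ``deterministic=True`` turns noise off: every ROI gains exactly
    ``rate_per_day`` cells per day.
    """
    if rate_per_day < 0:
        raise ValueError("rate_per_day must be >= 0")
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    if deterministic:
        counts = np.full((n_roi, days), rate_per_day)
    else:
        counts = rng.poisson(rate_per_day, size=(n_roi, days)).astype(float)
    df = pd.DataFrame(
        {
            "condition": condition,
            "roi_id": np.repeat(np.arange(n_roi), days),
            "day": np.tile(np.arange(1, days + 1), n_roi),
            "new_cells": counts.ravel(),
        }
    )
    truth = GroundTruth(
        assay="invasion",
        parameters={"rate_per_day": rate_per_day, "days": days, "n_roi": n_roi},
        seed=seed,
    )
    return df, truth


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    preset: ConditionPreset | str,
    assay: str,
    seed: int = 0,
    n: int | None = None,
    day: int = 3,
    **assay_kwargs,
) -> tuple[list, np.ndarray, GroundTruth]:
    """Generate a cohort of per-cell datasets for one condition and assay.

    Per-cell ground-truth values are drawn from a lognormal with the
    preset's mean and SD = SEM·√n (n from the preset, regardless of how many
    cells are requested), then the per-assay generator is called once per
    cell with an independent child seed. Returns
    ``(datasets, per_cell_truths, ground_truth)``; the dataset tuple layout
    per assay is

    * ``pillar``   — (stack, cell_mask, spec)
    * ``afm``      — IndentationCurve
    * ``tweezers`` — (BeadTrajectory, protocol, t0_s)
    * ``invasion`` — (laminin, actin, z_step_um)
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        preset = PRESETS[preset]
    stat_of = {
        "pillar": preset.traction,
        "afm": preset.stiffness,
        "tweezers": preset.relamp12,
        "invasion": preset.invasion_day3 if day == 3 else preset.invasion_day5,
    }
    if assay not in stat_of:
        raise ValueError(f"unknown assay {assay!r}")
    stat = stat_of[assay]
    if stat is None:
        raise ValueError(f"preset {preset.name!r} has no data for assay {assay!r}")
    n_cells = n if n is not None else stat.n
    assay_tag = {"pillar": 1, "tweezers": 2, "afm": 3, "invasion": 4}[assay]
    root = np.random.SeedSequence([int(seed), assay_tag])
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_cells + 1)]
    rng = np.random.default_rng(child_seeds[0])

    if assay == "invasion":
        # truths are fractions in [0, 1]; lognormal on the percent scale,
        # clipped into the physical range
        truths = np.clip(
            _draw_lognormal(rng, stat.mean, stat.sd, n_cells) / 100.0, 0.0, 1.0
        )
    else:
        truths = _draw_lognormal(rng, stat.mean, stat.sd, n_cells)

    datasets = []
    if assay == "pillar":
        spec = assay_kwargs.pop("spec", PillarArraySpec())
        shape = assay_kwargs.pop("shape", (128, 128))
        n_frames = assay_kwargs.pop("n_frames", 60)
        noise_sd = assay_kwargs.pop("noise_sd", 2.0)
        mask = ellipse_mask(
            shape, (shape[1] / 2, shape[0] / 2), (shape[1] * 0.33, shape[0] * 0.28)
        )
        for F, cs in zip(truths, child_seeds[1:]):
            stack, _ = generate_pillar_video(
                spec, mask, float(F), n_frames=n_frames, noise_sd=noise_sd,
                seed=cs, anchor="max", **assay_kwargs,
            )
            datasets.append((stack, mask, spec))
    elif assay == "afm":
        noise = assay_kwargs.pop("noise_sd_nN", 0.03)
        slope = assay_kwargs.pop("baseline_slope_nN_per_um", 0.02)
        for E, cs in zip(truths, child_seeds[1:]):
            curve, _ = generate_indentation_curve(
                float(E), noise_sd_nN=noise,
                baseline_slope_nN_per_um=slope, seed=cs, **assay_kwargs,
            )
            datasets.append(curve)
    elif assay == "tweezers":
        protocol = assay_kwargs.pop("protocol", ForceProtocol())
        amp1 = assay_kwargs.pop("amp1_um", 1.0)
        t0 = assay_kwargs.pop("t0_s", 1.0)
        for r12, cs in zip(truths, child_seeds[1:]):
            traj, _ = generate_bead_trajectory(
                protocol, amp1, float(r12), seed=cs, t0_s=t0, **assay_kwargs,
            )
            datasets.append((traj, protocol, t0))
    else:  # invasion
        z_step = assay_kwargs.pop("z_step_um", 0.5)
        for f, cs in zip(truths, child_seeds[1:]):
            lam, act, _ = generate_invasion_stack(
                below_fraction=float(f), z_step_um=z_step, seed=cs, **assay_kwargs,
            )
            datasets.append((lam, act, z_step))

    truth = GroundTruth(
        assay=assay,
        parameters={
            "preset": preset.name,
            "mean": stat.mean,
            "sd": stat.sd,
            "n": n_cells,
            "per_cell_truths": truths,
        },
        seed=seed,
    )
    return datasets, truths, truth
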