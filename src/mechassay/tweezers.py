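"""Magnetic-tweezers mechanosensing analysis.

A fibronectin-coated magnetic bead bound to surface integrins is pulled with
a pulsatile force regime (by default twelve 6 nN pulses, 3 s on / 4 s rest).
Each pulse drives a creep displacement of the bead; a cell that stiffens in
response to the applied force ("reinforcement") shows decreasing pulse
amplitudes. The readout is the per-pulse displacement amplitude normalised
to the first pulse; a paired first-vs-twelfth comparison (Wilcoxon
signed-rank) over a cohort of cells flags mechanosensing.

Amplitude convention: displacement is projected on the known force axis; the
amplitude of pulse *i* is the maximum projected displacement during the 3 s
on-window minus the median projected displacement over the final second of
the preceding rest (clipped at zero — movement against the force is noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import StatResult, paired_test

__all__ = [
    "ForceProtocol",
    "BeadTrajectory",
    "PulseWindow",
    "PulseAmplitudes",
    "segment_pulses",
    "pulse_amplitude",
    "normalize_amplitudes",
    "extract_amplitudes",
    "reinforcement_test",
]


@dataclass(frozen=True)
class ForceProtocol:
    """The pulsatile force regime applied by the tweezers."""

    pulse_force_nN: float = 6.0
    pulse_on_s: float = 3.0
    pulse_off_s: float = 4.0
    n_pulses: int = 12
    force_axis: tuple[float, float] = (1.0, 0.0)
    baseline_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_on_s <= 0 or self.pulse_off_s <= 0:
            raise ValueError("pulse_on_s and pulse_off_s must be positive")
        if self.n_pulses < 2:
            raise ValueError("need at least 2 pulses")

    @property
    def period_s(self) -> float:
        return self.pulse_on_s + self.pulse_off_s

    @property
    def total_s(self) -> float:
        return self.n_pulses * self.period_s

    @property
    def axis_unit(self) -> np.ndarray:
        v = np.asarray(self.force_axis, dtype=float)
        return v / np.linalg.norm(v)


@dataclass
class BeadTrajectory:
    """Bead position time series (s, µm)."""

    time: np.ndarray       # (T,)
    position: np.ndarray   # (T, 2)
    frame_rate: float      # Hz

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 0.01 * np.mean(dt)):
            raise ValueError("time must be strictly increasing and uniform to 1%")

    def projected(self, axis: np.ndarray) -> np.ndarray:
        return self.position @ axis


@dataclass(frozen=True)
class PulseWindow:
    """On-window and pre-pulse baseline window of one pulse (seconds)."""

    pulse: int                      # 1-based
    on: tuple[float, float]
    baseline: tuple[float, float]


@dataclass
class PulseAmplitudes:
    """Absolute and first-pulse-normalised amplitudes for one cell."""

    absolute: np.ndarray   # (n_pulses,) µm
    relative: np.ndarray   # (n_pulses,), relative[0] == 1 exactly


def segment_pulses(
    traj: BeadTrajectory, protocol: ForceProtocol, t0: float
) -> list[PulseWindow]:
    """Window boundaries for every pulse given the onset t0 of pulse 1.

    Pulse *i* is on during [t0+(i-1)·period, t0+(i-1)·period+on]; its
    baseline is the final ``baseline_window_s`` of the preceding rest (for
    pulse 1, the interval just before t0). Raises with the number of
    complete pulses found if the trajectory is too short.
    """
    t_end = float(traj.time[-1])
    need = t0 + (protocol.n_pulses - 1) * protocol.period_s + protocol.pulse_on_s
    if t_end < need - 1e-9:
        n_complete = int(
            max(0, (t_end - t0 - protocol.pulse_on_s) // protocol.period_s + 1)
        )
        raise ValueError(
            f"trajectory too short for {protocol.n_pulses} pulses: "
            f"only {n_complete} complete pulses found"
        )
    wins = []
    for i in range(protocol.n_pulses):
        start = t0 + i * protocol.period_s
        wins.append(
            PulseWindow(
                pulse=i + 1,
                on=(start, start + protocol.pulse_on_s),
                baseline=(start - protocol.baseline_window_s, start),
            )
        )
    return wins


def pulse_amplitude(
    traj: BeadTrajectory, window: PulseWindow, protocol: ForceProtocol
) -> float:
    """Amplitude of one pulse: peak-minus-baseline on the force-axis projection."""
    x = traj.projected(protocol.axis_unit)
    t = traj.time
    on = (t >= window.on[0] - 1e-9) & (t <= window.on[1] + 1e-9)
    base = (t >= window.baseline[0] - 1e-9) & (t < window.baseline[1] - 1e-9)
    if not on.any() or not base.any():
        raise ValueError(f"empty window for pulse {window.pulse}")
    amp = float(np.max(x[on]) - np.median(x[base]))
    return max(amp, 0.0)


def normalize_amplitudes(absolute: np.ndarray) -> PulseAmplitudes:
    """Normalise per-pulse amplitudes to the first pulse.

    A cell whose first pulse produced no measurable displacement cannot be
    normalised and is rejected (mirrors excluding an unanalysable cell).
    """
    absolute = np.asarray(absolute, dtype=float)
    if absolute[0] <= 0:
        raise ValueError("first-pulse amplitude is zero: cell excluded")
    rel = absolute / absolute[0]
    rel[0] = 1.0
    return PulseAmplitudes(absolute=absolute, relative=rel)


def extract_amplitudes(
    traj: BeadTrajectory, protocol: ForceProtocol, t0: float
) -> PulseAmplitudes:
    """Segment, measure and normalise all pulse amplitudes of one cell."""
    wins = segment_pulses(traj, protocol, t0)
    amps = np.array([pulse_amplitude(traj, w, protocol) for w in wins])
    return normalize_amplitudes(amps)


def reinforcement_test(
    cohort: list[PulseAmplitudes],
) -> tuple[StatResult, float, float]:
    """Cohort-level mechanosensing test.

    Paired Wilcoxon signed-rank on the per-cell (first, twelfth) absolute
    amplitudes; a significant decrease indicates cytoskeletal reinforcement.

    Returns (StatResult, mean, sem) of the relative last-pulse amplitude.
    """
    if len(cohort) < 6:
        raise ValueError("need at least 6 cells for the reinforcement test")
    a1 = np.array([c.absolute[0] for c in cohort])
    a12 = np.array([c.absolute[-1] for c in cohort])
    rel12 = np.array([c.relative[-1] for c in cohort])
    res = paired_test(a1, a12)
    mean = float(np.mean(rel12))
    sem = float(np.std(rel12, ddof=1) / np.sqrt(len(rel12)))
    return res, mean, sem
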