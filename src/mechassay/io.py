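"""Readers and writers for the assay file formats.

Image stacks are multi-page TIFF (tifffile) with spacing carried in the
ImageJ-style metadata; trajectories, curves and count tables are headed CSV;
ground truths are JSON sidecars sharing the dataset's basename.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import IndentationCurve
from .synth import GroundTruth
from .tweezers import BeadTrajectory


def write_stack(path, stack: np.ndarray, spacing_um: float | None = None) -> None:
    """Write an image stack as multi-page TIFF with axial/temporal spacing."""
    meta = {"axes": "ZYX"}
    if spacing_um is not None:
        meta["spacing"] = spacing_um
        meta["unit"] = "um"
    tifffile.imwrite(path, np.asarray(stack), imagej=True, metadata=meta)


def read_stack(path) -> tuple[np.ndarray, float | None]:
    """Read a multi-page TIFF; returns (stack, spacing_um or None)."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        spacing = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            spacing = float(tf.imagej_metadata["spacing"])
    return stack, spacing


def write_trajectory(path, traj: BeadTrajectory) -> None:
    pd.DataFrame(
        {"time_s": traj.time, "x_um": traj.position[:, 0], "y_um": traj.position[:, 1]}
    ).to_csv(path, index=False)


def read_trajectory(path, frame_rate_hz: float | None = None) -> BeadTrajectory:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if frame_rate_hz is None:
        frame_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return BeadTrajectory(
        time=t,
        position=df[["x_um", "y_um"]].to_numpy(dtype=float),
        frame_rate=frame_rate_hz,
    )


def write_curve(path, curve: IndentationCurve) -> None:
    pd.DataFrame({"z_um": curve.z_um, "force_nN": curve.force_nN}).to_csv(
        path, index=False
    )


def read_curve(
    path,
    probe_radius_um: float = 7.5,
    cantilever_k: float = 0.03,
    poisson_nu: float = 0.5,
    sensitivity_um_per_V: float | None = None,
) -> IndentationCurve:
    """Read a force curve CSV.

    Accepts either a ``force_nN`` column, a ``deflection_um`` column
    (converted with the cantilever constant: nN = µm · k[N/m]), or a
    ``deflection_V`` column plus ``sensitivity_um_per_V``.
    """
    df = pd.read_csv(path)
    z = df["z_um"].to_numpy(dtype=float)
    if "force_nN" in df.columns:
        f = df["force_nN"].to_numpy(dtype=float)
    elif "deflection_um" in df.columns:
        # F[nN] = δ[µm] · k[N/m] · 1000  (1 N/m = 1000 nN/µm)
        f = df["deflection_um"].to_numpy(dtype=float) * cantilever_k * 1e3
    elif "deflection_V" in df.columns:
        if sensitivity_um_per_V is None:
            raise ValueError("deflection_V column needs sensitivity_um_per_V")
        f = (
            df["deflection_V"].to_numpy(dtype=float)
            * sensitivity_um_per_V
            * cantilever_k
            * 1e3
        )
    else:
        raise ValueError("curve CSV needs force_nN, deflection_um or deflection_V")
    return IndentationCurve(
        z_um=z, force_nN=f, probe_radius_um=probe_radius_um,
        cantilever_k=cantilever_k, poisson_nu=poisson_nu,
    )


def write_ground_truth(path, truth: GroundTruth) -> None:
    truth.to_json(path)


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_json(path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return str(o)

    Path(path).write_text(json.dumps(obj, default=_default, indent=1))
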