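"""Quantification of the neutrophil functional assays.

Three readouts are reduced to scalar metrics:

* oxidative burst — luminol-amplified chemiluminescence kinetics sampled on
  a 30-s grid over 15 min, reduced to trapezoidal area under the curve and
  expressed as a percentage of the unstimulated negative control;
* 3D chemotaxis — manually tracked cell positions at 1-min intervals over
  60 min, reduced per cell to origin-zeroed net displacement along the
  chemoattractant axis and to velocity as total path length over time;
* NET release — extracellular-DNA (Sytox) fluorescence expressed as a fold
  index over control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default kinetic grid: a reading every 30 s for 15 min, including t = 0.
ROS_TIME_GRID_S = np.arange(0, 901, 30)

#: Default track sampling: one frame per minute for 60 min, including t = 0.
TRACK_TIMES_MIN = np.arange(0, 61)


class NormalizationError(ValueError):
    pass


@dataclass
class KineticCurve:
    """One well's chemiluminescence kinetics (RLU) on a uniform time grid."""

    timepoints: np.ndarray  # seconds
    values: np.ndarray  # RLU
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.size != self.values.size:
            raise ValueError("timepoints and values differ in length")
        dt = np.diff(self.timepoints)
        if self.timepoints.size >= 2 and not (
            np.all(dt > 0) and np.allclose(dt, dt[0])
        ):
            raise ValueError("timepoints must be strictly increasing and uniform")
        if np.nanmin(self.values) < 0:
            raise ValueError("negative luminescence value")


@dataclass
class CellTrack:
    """One cell's (x, y) positions in micrometres at uniform 1-min intervals."""

    cell_id: str
    x: np.ndarray
    y: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError(f"track {self.cell_id}: x and y differ in length")
        if self.x.size and not (
            np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))
        ):
            raise ValueError(f"track {self.cell_id}: non-finite coordinates")

    @property
    def n_samples(self) -> int:
        return int(self.x.size)


@dataclass
class AssayResult:
    metric: str
    units: str
    per_item: pd.Series  # per replicate or per cell
    summary: dict[str, float]


def ros_auc_percent(curve: KineticCurve, negative_control: KineticCurve) -> float:
    """Oxidative-burst AUC as a percentage of the negative control.

    Both curves are integrated with the trapezoid rule on their native grid;
    no baseline subtraction is applied (the ratio already normalizes
    instrument gain).
    """
    if curve.timepoints.size != negative_control.timepoints.size or not np.allclose(
        curve.timepoints, negative_control.timepoints
    ):
        raise ValueError("curve and control must share one time grid")
    auc = float(np.trapezoid(curve.values, curve.timepoints))
    auc_ctrl = float(np.trapezoid(negative_control.values, negative_control.timepoints))
    if auc_ctrl <= 0:
        raise NormalizationError(f"control AUC is {auc_ctrl:g}, cannot normalize")
    return 100.0 * auc / auc_ctrl


def track_metrics(
    tracks: Sequence[CellTrack], attractant_axis_sign: int = +1
) -> dict[str, AssayResult]:
    """Per-cell chemotaxis metrics.

    * ``net_x`` — origin-zeroed net displacement along the chemoattractant
      axis, ``sign * (x_end - x_0)`` in micrometres, summarized as mean and SD;
    * ``velocity`` — total path length (sum of stepwise Euclidean distances)
      divided by total observation time, in micrometres per minute,
      summarized as median and range.

    Tracks with fewer than two samples are skipped with a warning.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    if attractant_axis_sign not in (+1, -1):
        raise ValueError("attractant_axis_sign must be +1 or -1")
    net_x: dict[str, float] = {}
    velocity: dict[str, float] = {}
    for t in tracks:
        if t.n_samples < 2:
            warnings.warn(f"track {t.cell_id}: fewer than 2 samples, skipped")
            continue
        net_x[t.cell_id] = attractant_axis_sign * float(t.x[-1] - t.x[0])
        steps = np.hypot(np.diff(t.x), np.diff(t.y))
        total_time_min = float(t.n_samples - 1)  # 1-min sampling interval
        velocity[t.cell_id] = float(steps.sum() / total_time_min)
    if not net_x:
        raise ValueError("no track had >= 2 samples")
    nx = pd.Series(net_x, name="net_x")
    v = pd.Series(velocity, name="velocity")
    return {
        "net_x": AssayResult(
            metric="net_x",
            units="um",
            per_item=nx,
            summary={"mean": float(nx.mean()), "sd": float(nx.std(ddof=1)) if nx.size > 1 else 0.0},
        ),
        "velocity": AssayResult(
            metric="velocity",
            units="um/min",
            per_item=v,
            summary={
                "median": float(v.median()),
                "min": float(v.min()),
                "max": float(v.max()),
            },
        ),
    }


def net_release_index(
    sample_fluorescence: float, control_fluorescence: float
) -> float:
    """Extracellular-DNA fluorescence as a fold index over control."""
    if not control_fluorescence > 0:
        raise NormalizationError(
            f"control fluorescence must be positive, got {control_fluorescence!r}"
        )
    return float(sample_fluorescence) / float(control_fluorescence)


# ---------------------------------------------------------------------------
# tabular I/O


def read_kinetics_table(path) -> list[KineticCurve]:
    """Read a plate export: columns ``time_s, well, condition, value``."""
    df = pd.read_csv(path, sep="\t")
    df["well"] = df["well"].fillna("")
    df["condition"] = df["condition"].fillna("")
    curves = []
    for (well, condition), sub in df.groupby(["well", "condition"], sort=True):
        sub = sub.sort_values("time_s")
        curves.append(
            KineticCurve(
                timepoints=sub["time_s"].to_numpy(dtype=float),
                values=sub["value"].to_numpy(dtype=float),
                condition=str(condition),
                replicate=str(well),
            )
        )
    return curves


def write_kinetics_table(curves: Sequence[KineticCurve], path) -> None:
    rows = [
        (t, c.replicate, c.condition, v)
        for c in curves
        for t, v in zip(c.timepoints, c.values)
    ]
    pd.DataFrame(rows, columns=["time_s", "well", "condition", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_tracks_table(path) -> list[CellTrack]:
    """Read a manual-tracking export: ``cell_id, t_min, x_um, y_um, condition``."""
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for (cell_id, condition), sub in df.groupby(["cell_id", "condition"], sort=True):
        sub = sub.sort_values("t_min")
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                x=sub["x_um"].to_numpy(dtype=float),
                y=sub["y_um"].to_numpy(dtype=float),
                condition=str(condition),
            )
        )
    return tracks


def write_tracks_table(tracks: Sequence[CellTrack], path) -> None:
    rows = [
        (t.cell_id, i, t.x[i], t.y[i], t.condition)
        for t in tracks
        for i in range(t.n_samples)
    ]
    pd.DataFrame(rows, columns=["cell_id", "t_min", "x_um", "y_um", "condition"]).to_csv(
        path, sep="\t", index=False
    )
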