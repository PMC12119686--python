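"""Data model and I/O for per-subject peptide-array scans.

An array experiment produces, per subject, one fluorescence value per peptide
tile from the serum scan, one from the pre-serum background scan, and a set of
control-spot values from the hemagglutinin (HA) grid that frames the printed
peptides.  The pipeline starts from these per-spot intensities; image
scanning and spot quantification are upstream vendor-software steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved tile label flagging HA control-grid rows in the long-format table.
CONTROL_TILE_LABEL = -1


class CompletenessError(ValueError):
    """Raised when a subject's table is missing tiles of the library."""


@dataclass
class ArraySample:
    """One subject's scans, aligned to a tiling library by tile index."""

    subject_id: str
    group: str  # "SLE" or "HBD"
    intensities: np.ndarray  # serum scan, one value per tile
    background_scan: np.ndarray  # pre-serum scan, same tile indexing
    control_intensities: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=float)
    )

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.background_scan = np.asarray(self.background_scan, dtype=float)
        self.control_intensities = np.asarray(self.control_intensities, dtype=float)
        if self.intensities.shape != self.background_scan.shape:
            raise ValueError(
                f"{self.subject_id}: serum scan has {self.intensities.size} tiles "
                f"but background scan has {self.background_scan.size}"
            )
        for name, arr in (
            ("intensity", self.intensities),
            ("background", self.background_scan),
            ("control", self.control_intensities),
        ):
            if arr.size and np.nanmin(arr) < 0:
                raise ValueError(f"{self.subject_id}: negative {name} value")

    @property
    def n_tiles(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    control_pass: bool
    background_level: float
    notes: str = ""


def background_level(sample: ArraySample) -> float:
    """Per-array background scalar: median of the pre-serum scan.

    A per-array scalar (rather than per-spot values) is robust to isolated
    bright spots in the pre-serum scan; positivity calling compares serum
    intensities against a multiple of this scalar.
    """
    if sample.background_scan.size == 0:
        raise ValueError(f"{sample.subject_id}: empty background scan")
    return float(np.median(sample.background_scan))


def qc_control_grid(sample: ArraySample, min_fold: float = 2.0) -> QCReport:
    """Advisory QC: the HA control grid should clearly exceed background.

    Passes iff the median control-spot intensity is at least ``min_fold``
    times the array's background level.  Failing samples are flagged, not
    dropped.
    """
    bg = background_level(sample)
    if sample.control_intensities.size == 0:
        return QCReport(
            sample.subject_id,
            control_pass=False,
            background_level=bg,
            notes="no control spots present",
        )
    ctrl = float(np.median(sample.control_intensities))
    ok = ctrl >= min_fold * bg
    return QCReport(
        sample.subject_id,
        control_pass=bool(ok),
        background_level=bg,
        notes="" if ok else f"median control {ctrl:g} < {min_fold:g} x background {bg:g}",
    )


def read_array_table(path, n_tiles: int | None = None) -> list[ArraySample]:
    """Read a long-format tab-separated array table.

    Columns: ``subject_id, group, tile_index, intensity, background``.
    Rows with ``tile_index == -1`` carry HA control-spot intensities.
    Subjects are returned ordered by subject_id; tiles by tile index.
    Every subject must cover the same contiguous 0..max tile range (or the
    ``n_tiles`` of the library if given); gaps raise
    :class:`CompletenessError` naming the missing tiles.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "tile_index", "intensity", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"array table missing columns: {sorted(missing)}")
    if (df["intensity"] < 0).any() or (df["background"] < 0).any():
        raise ValueError("negative fluorescence value in array table")

    samples: list[ArraySample] = []
    tile_rows = df[df["tile_index"] != CONTROL_TILE_LABEL]
    expected = n_tiles if n_tiles is not None else int(tile_rows["tile_index"].max()) + 1
    for subject_id, sub in df.groupby("subject_id", sort=True):
        ctrl = sub[sub["tile_index"] == CONTROL_TILE_LABEL]
        spots = sub[sub["tile_index"] != CONTROL_TILE_LABEL].sort_values("tile_index")
        idx = spots["tile_index"].to_numpy()
        gaps = sorted(set(range(expected)) - set(int(i) for i in idx))
        if gaps:
            raise CompletenessError(
                f"subject {subject_id}: missing tile(s) {gaps[:10]}"
                + ("..." if len(gaps) > 10 else "")
            )
        if len(idx) != expected:
            raise CompletenessError(
                f"subject {subject_id}: duplicate tile rows present"
            )
        samples.append(
            ArraySample(
                subject_id=str(subject_id),
                group=str(sub["group"].iloc[0]),
                intensities=spots["intensity"].to_numpy(dtype=float),
                background_scan=spots["background"].to_numpy(dtype=float),
                control_intensities=ctrl["intensity"].to_numpy(dtype=float),
            )
        )
    return samples


def write_array_table(samples: list[ArraySample], path) -> None:
    """Write samples in the long format read by :func:`read_array_table`."""
    rows = []
    for s in samples:
        for i in range(s.n_tiles):
            rows.append(
                (s.subject_id, s.group, i, s.intensities[i], s.background_scan[i])
            )
        for v in s.control_intensities:
            # control rows reuse the background column for the pre-serum value
            rows.append((s.subject_id, s.group, CONTROL_TILE_LABEL, v, 0.0))
    pd.DataFrame(
        rows, columns=["subject_id", "group", "tile_index", "intensity", "background"]
    ).to_csv(path, sep="\t", index=False)
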