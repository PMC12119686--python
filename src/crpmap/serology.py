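"""Serology-derived quantities and subject records.

Anti-CRP IgG is expressed in arbitrary units (AU) as a percentage of a
high-titer positive reference serum; positivity uses the empirical 95th
percentile of a healthy-donor panel.  Antiphospholipid (aPL) positivity is
any of the four kit assays (aCL IgG/IgM, anti-beta2GPI IgG/IgM) above its
kit cutoff.  Peptide-ELISA readings are reduced to net optical density
(coated minus uncoated well), floored at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: SLEDAI-2K score at or above which disease is considered active.
ACTIVE_SLEDAI_THRESHOLD = 5

#: Default kit cutoffs (U/ml) for the four aPL assays.
DEFAULT_APL_CUTOFFS: dict[str, float] = {
    "acl_igg": 10.0,
    "acl_igm": 10.0,
    "b2gpi_igg": 10.0,
    "b2gpi_igm": 10.0,
}


class CalibrationError(ValueError):
    """Raised when a reference signal cannot normalize a measurement."""


@dataclass
class PlateReading:
    """One coated/uncoated well pair of an ELISA plate (blanked ODs)."""

    coated_od: float
    uncoated_od: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.coated_od) and math.isfinite(self.uncoated_od)):
            raise ValueError("non-finite OD reading")


@dataclass
class SubjectRecord:
    """Clinical and serology covariates for one subject.

    Derived flags (``anti_crp_positive``, ``apl_positive``, ``active``) are
    recomputed by :meth:`derive_flags`; they are kept consistent with the
    raw values they summarize.
    """

    subject_id: str
    group: str  # "SLE" or "HBD"
    anti_crp_au: float = float("nan")
    anti_crp_positive: bool = False
    acl_igg: float = float("nan")
    acl_igm: float = float("nan")
    b2gpi_igg: float = float("nan")
    b2gpi_igm: float = float("nan")
    apl_positive: bool = False
    sledai2k: int = 0
    active: bool = False
    sdi: int = 0
    complement_classical_pct: float = float("nan")
    c3d: float = float("nan")
    il6: float = float("nan")
    esr: float = float("nan")
    disease_duration: float = float("nan")

    def derive_flags(
        self,
        anti_crp_cutoff: float | None = None,
        apl_cutoffs: Mapping[str, float] = DEFAULT_APL_CUTOFFS,
    ) -> None:
        if anti_crp_cutoff is not None:
            self.anti_crp_positive = bool(self.anti_crp_au > anti_crp_cutoff)
        self.apl_positive = apl_flag(
            self.acl_igg, self.acl_igm, self.b2gpi_igg, self.b2gpi_igm, apl_cutoffs
        )
        self.active = self.sledai2k >= ACTIVE_SLEDAI_THRESHOLD


def anti_crp_au(sample_signal: float, reference_signal: float) -> float:
    """Anti-CRP arbitrary units: sample signal as % of the positive reference."""
    if not reference_signal > 0:
        raise CalibrationError(
            f"non-positive reference signal: {reference_signal!r}"
        )
    return 100.0 * sample_signal / reference_signal


def percentile_cutoff(values: Iterable[float], pct: float = 95.0) -> float:
    """Empirical percentile by the nearest-rank convention.

    Returns the ``ceil(pct/100 * n)``-th order statistic.  Positivity
    downstream is strict: value > threshold.
    """
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError(f"need >= 2 values for a percentile cutoff, got {len(vals)}")
    if not (0 < pct <= 100):
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    rank = math.ceil(pct / 100.0 * len(vals))
    return vals[rank - 1]


def net_od(reading: PlateReading) -> float:
    """Net OD: coated minus uncoated well, floored at zero."""
    return max(reading.coated_od - reading.uncoated_od, 0.0)


def apl_flag(
    acl_igg: float,
    acl_igm: float,
    b2gpi_igg: float,
    b2gpi_igm: float,
    cutoffs: Mapping[str, float] = DEFAULT_APL_CUTOFFS,
) -> bool:
    """aPL positivity: any assay strictly above its kit cutoff.

    Missing (NaN) assay values never count as positive.
    """
    values = {
        "acl_igg": acl_igg,
        "acl_igm": acl_igm,
        "b2gpi_igg": b2gpi_igg,
        "b2gpi_igm": b2gpi_igm,
    }
    return any(
        (not math.isnan(v)) and v > cutoffs[k] for k, v in values.items()
    )


def load_apl_cutoffs(path) -> dict[str, float]:
    """Kit cutoffs from a JSON config ``{"acl_igg": ..., ...}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    cutoffs = dict(DEFAULT_APL_CUTOFFS)
    unknown = set(raw) - set(cutoffs)
    if unknown:
        raise ValueError(f"unknown aPL assay names in config: {sorted(unknown)}")
    cutoffs.update({k: float(v) for k, v in raw.items()})
    return cutoffs


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """One row per subject, columns named as the record fields."""
    return pd.DataFrame([asdict(r) for r in records]).set_index("subject_id")


def write_clinical_table(records: Iterable[SubjectRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t")


def read_clinical_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    out: list[SubjectRecord] = []
    valid = {f.name for f in fields(SubjectRecord)}
    for sid, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in valid}
        for flag in ("anti_crp_positive", "apl_positive", "active"):
            if flag in kwargs:
                kwargs[flag] = bool(kwargs[flag])
        for integer in ("sledai2k", "sdi"):
            if integer in kwargs and not pd.isna(kwargs[integer]):
                kwargs[integer] = int(kwargs[integer])
        out.append(SubjectRecord(subject_id=str(sid), **kwargs))
    return out
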