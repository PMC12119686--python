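"""Positivity calling and minimal-consensus epitope inference.

A peptide tile is seropositive when its serum-scan fluorescence reaches a
multiple (default 2x) of the array's pre-serum background level.  Because the
library steps one residue at a time, an antibody recognizing a short linear
epitope lights up every tile whose peptide contains that epitope; the
minimal consensus region shared by an overlapping run of positive tiles is
the epitope call.

Calling proceeds per subject:

1. positive tiles are sorted by array index; tiles lying wholly in the
   terminal linker are discarded (they can never support an epitope);
2. positive tiles form a *run* when they are immediate neighbours on the
   array and their mature spans share at least ``min_overlap`` residues;
3. a run whose mature spans have a non-empty common intersection yields one
   call: the intersection span, clipped to the mature sequence;
4. a run whose intersection is empty necessarily covers more than one
   epitope; it is split at the cut point that maximizes the shorter of the
   two resulting intersection lengths (ties resolved toward the smaller left
   segment), recursively.

Subject-level calls are then harmonized across the cohort by single-linkage
clustering on span overlap, giving cohort epitopes with per-group positive
counts and a subject-by-epitope matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .array_model import ArraySample, background_level
from .core_sequence import PeptideTile, ProteinSequence

DEFAULT_POSITIVITY_FACTOR = 2.0
DEFAULT_MIN_OVERLAP = 3


class AlignmentError(ValueError):
    """Raised when a positivity vector does not align to the tiling library."""


class ConsistencyError(RuntimeError):
    """Raised when harmonized cohort epitopes overlap each other."""


@dataclass(frozen=True)
class EpitopeCall:
    """A minimal consensus epitope for one subject."""

    start: int
    end: int
    motif: str
    supporting_tiles: tuple[int, ...]
    mean_intensity: float = float("nan")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CohortEpitope:
    """A harmonized epitope with per-group positive subjects."""

    start: int
    end: int
    motif: str
    label: str
    positive_subjects: dict[str, list[str]] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def counts(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.positive_subjects.items()}

    @property
    def total(self) -> int:
        return sum(len(s) for s in self.positive_subjects.values())


@dataclass
class SubjectEpitopeMatrix:
    """Boolean positivity and per-cell signal, subjects x cohort epitopes."""

    positivity: pd.DataFrame  # bool
    intensity: pd.DataFrame  # float, NaN where negative
    groups: pd.Series  # subject -> group

    @property
    def per_subject_totals(self) -> pd.Series:
        return self.positivity.sum(axis=1)

    def group_counts(self, label: str) -> dict[str, int]:
        col = self.positivity[label]
        return {g: int(col[self.groups == g].sum()) for g in self.groups.unique()}


def call_positive_tiles(
    sample: ArraySample, factor: float = DEFAULT_POSITIVITY_FACTOR
) -> np.ndarray:
    """Boolean positivity per tile: intensity >= factor x background level.

    The boundary is inclusive: a tile exactly attaining the cutoff is
    positive.
    """
    bg = background_level(sample)
    return sample.intensities >= factor * bg


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _intersection(spans: Sequence[tuple[int, int]]) -> tuple[int, int] | None:
    lo = max(s[0] for s in spans)
    hi = min(s[1] for s in spans)
    return (lo, hi) if lo <= hi else None


def _segment_run(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Split a run (as index ranges into ``spans``) so every segment has a
    non-empty span intersection.  Returns [(i0, i1), ...] half-open."""
    n = len(spans)
    if _intersection(spans) is not None:
        return [(0, n)]
    # choose the cut maximizing the shorter side's intersection length
    best_cut, best_score = 1, None
    for m in range(1, n):
        left = _intersection(spans[:m])
        right = _intersection(spans[m:])
        llen = (left[1] - left[0] + 1) if left else -10**9
        rlen = (right[1] - right[0] + 1) if right else -10**9
        score = min(llen, rlen)
        if best_score is None or score > best_score:
            best_cut, best_score = m, score
    out = []
    for a, b in _segment_run(spans[:best_cut]):
        out.append((a, b))
    for a, b in _segment_run(spans[best_cut:]):
        out.append((a + best_cut, b + best_cut))
    return out


def call_subject_epitopes(
    positives: np.ndarray | Sequence[bool],
    tiles: Sequence[PeptideTile],
    seq: ProteinSequence,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    intensities: np.ndarray | None = None,
) -> list[EpitopeCall]:
    """Reduce a positivity vector to minimal consensus epitope calls.

    ``positives`` must align one-to-one with ``tiles``.  ``intensities``
    (optional, same alignment) populates each call's mean serum signal over
    its supporting tiles.  Calls are returned sorted by start coordinate.
    Calls shorter than ``min_overlap`` residues are possible when the run
    intersection itself is shorter; they are emitted with a warning.
    """
    positives = np.asarray(positives, dtype=bool)
    if positives.shape[0] != len(tiles):
        raise AlignmentError(
            f"positivity vector has {positives.shape[0]} entries for "
            f"{len(tiles)} tiles"
        )
    pos_tiles = [
        t for t, p in zip(tiles, positives) if p and t.mature_span is not None
    ]
    if not pos_tiles:
        return []

    # group into runs of immediate array neighbours with sufficient overlap
    runs: list[list[PeptideTile]] = [[pos_tiles[0]]]
    for prev, cur in zip(pos_tiles, pos_tiles[1:]):
        adjacent = cur.index == prev.index + 1
        if adjacent and _spans_overlap(prev.mature_span, cur.mature_span) >= min_overlap:
            runs[-1].append(cur)
        else:
            runs.append([cur])

    calls: list[EpitopeCall] = []
    for run in runs:
        spans = [t.mature_span for t in run]
        for i0, i1 in _segment_run(spans):
            seg = run[i0:i1]
            lo, hi = _intersection([t.mature_span for t in seg])
            idx = tuple(t.index for t in seg)
            if intensities is not None:
                mean_int = float(np.mean([intensities[i] for i in idx]))
            else:
                mean_int = float("nan")
            if hi - lo + 1 < min_overlap:
                warnings.warn(
                    f"epitope call [{lo},{hi}] shorter than {min_overlap} residues",
                    stacklevel=2,
                )
            calls.append(
                EpitopeCall(
                    start=lo,
                    end=hi,
                    motif=seq.span(lo, hi),
                    supporting_tiles=idx,
                    mean_intensity=mean_int,
                )
            )
    return sorted(calls, key=lambda c: (c.start, c.end))


def epitope_label(seq: ProteinSequence, span: tuple[int, int]) -> str:
    """Label a span in the printed style, e.g. ``PDE^168-170``."""
    start, end = span
    return f"{seq.span(start, end)}^{start}-{end}"


_LABEL_RE = re.compile(r"^([A-Z]+)\^(\d+)-(\d+)$")


def parse_epitope_label(label: str) -> tuple[str, int, int]:
    """Inverse of :func:`epitope_label`."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed epitope label {label!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def harmonize_cohort(
    calls_by_subject: Mapping[str, Sequence[EpitopeCall]],
    seq: ProteinSequence,
    groups: Mapping[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[list[CohortEpitope], SubjectEpitopeMatrix]:
    """Cluster subject-level calls into cohort epitopes.

    Single-linkage clustering links any two calls (across subjects) whose
    spans share at least ``min_overlap`` residues.  Each cluster's canonical
    span is the intersection of member spans when non-empty, otherwise the
    most frequent member span (ties toward the leftmost).  A subject is
    positive for a cohort epitope iff one of its calls belongs to the
    cluster.
    """
    flat: list[tuple[str, EpitopeCall]] = [
        (sid, c) for sid, calls in calls_by_subject.items() for c in calls
    ]
    # union-find single linkage
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if _spans_overlap(flat[i][1].span, flat[j][1].span) >= min_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    clusters: dict[int, list[int]] = {}
    for i in range(len(flat)):
        clusters.setdefault(find(i), []).append(i)

    group_labels = sorted(set(groups.values()))
    epitopes: list[CohortEpitope] = []
    members_of: list[list[int]] = []
    for members in clusters.values():
        spans = [flat[i][1].span for i in members]
        canon = _intersection(spans)
        if canon is None:
            counts: dict[tuple[int, int], int] = {}
            for s in spans:
                counts[s] = counts.get(s, 0) + 1
            canon = sorted(counts, key=lambda s: (-counts[s], s))[0]
        ep = CohortEpitope(
            start=canon[0],
            end=canon[1],
            motif=seq.span(*canon),
            label=epitope_label(seq, canon),
            positive_subjects={g: [] for g in group_labels},
        )
        for i in members:
            sid = flat[i][0]
            g = groups[sid]
            if sid not in ep.positive_subjects[g]:
                ep.positive_subjects[g].append(sid)
        epitopes.append(ep)
        members_of.append(members)

    order = sorted(range(len(epitopes)), key=lambda k: (epitopes[k].start, epitopes[k].end))
    epitopes = [epitopes[k] for k in order]
    members_of = [members_of[k] for k in order]

    for a, b in zip(epitopes, epitopes[1:]):
        if _spans_overlap(a.span, b.span) >= min_overlap:
            raise ConsistencyError(
                f"cohort epitopes {a.label} and {b.label} overlap by >= {min_overlap}"
            )

    subjects = sorted(calls_by_subject.keys())
    labels = [e.label for e in epitopes]
    pos = pd.DataFrame(False, index=subjects, columns=labels)
    inten = pd.DataFrame(np.nan, index=subjects, columns=labels)
    for ep, members in zip(epitopes, members_of):
        for i in members:
            sid, call = flat[i]
            pos.loc[sid, ep.label] = True
            cur = inten.loc[sid, ep.label]
            if np.isnan(cur) or call.mean_intensity > cur:
                inten.loc[sid, ep.label] = call.mean_intensity
    matrix = SubjectEpitopeMatrix(
        positivity=pos,
        intensity=inten,
        groups=pd.Series({s: groups[s] for s in subjects}, name="group"),
    )
    return epitopes, matrix


def write_calls_table(
    calls_by_subject: Mapping[str, Sequence[EpitopeCall]], path
) -> None:
    """Export subject-level calls as tab-separated text."""
    rows = []
    for sid in sorted(calls_by_subject):
        for c in calls_by_subject[sid]:
            rows.append(
                (sid, c.start, c.end, c.motif, len(c.supporting_tiles), c.mean_intensity)
            )
    pd.DataFrame(
        rows,
        columns=["subject_id", "start", "end", "motif", "n_supporting", "mean_intensity"],
    ).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: SubjectEpitopeMatrix, path) -> None:
    """Export the wide positivity matrix (0/1) with epitope-label columns."""
    out = matrix.positivity.astype(int).copy()
    out.insert(0, "group", matrix.groups)
    out.to_csv(path, sep="\t", index_label="subject_id")


def read_matrix(path) -> SubjectEpitopeMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    groups = df.pop("group")
    return SubjectEpitopeMatrix(
        positivity=df.astype(bool),
        intensity=pd.DataFrame(np.nan, index=df.index, columns=df.columns),
        groups=groups,
    )
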