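"""Protein sequence handling and overlapping-peptide tiling.

The array design tiles a mature protein monomer into short overlapping
peptides (by default 15-mers stepping one residue, i.e. 14-residue overlap)
after elongating both termini with a neutral glycine/serine linker so that
terminal residues are still presented in full-length peptides.  All public
coordinates are 1-based inclusive spans on the *mature* monomer, matching
the superscript convention used for epitope labels (e.g. ``PDE^168-170``);
coordinates on the flanked sequence are internal book-keeping only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default terminal linker: a 7-residue glycine/serine repeat.
DEFAULT_FLANK = "GSGSGSG"

DEFAULT_TILE_LENGTH = 15
DEFAULT_OVERLAP = 14


class SequenceFormatError(ValueError):
    """Raised when a FASTA source does not parse to a single protein record."""


class AlphabetError(ValueError):
    """Raised when a sequence contains non-amino-acid characters."""


class CoordinateError(ValueError):
    """Raised when a span lies outside the sequence or is inconsistent."""


@dataclass(frozen=True)
class ProteinSequence:
    """A mature protein monomer with 1-based residue coordinates."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"non-amino-acid characters in {self.id!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def span(self, start: int, end: int) -> str:
        """Residues of the inclusive 1-based span ``[start, end]``."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"span [{start},{end}] outside 1..{self.length} of {self.id!r}"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class EpitopeAnchor:
    """A motif pinned to printed mature coordinates, used for validation."""

    motif: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif):
            raise CoordinateError(
                f"anchor {self.motif!r}: span [{self.start},{self.end}] "
                f"does not match motif length {len(self.motif)}"
            )


#: The 11 epitopes reported for the mature CRP monomer, used as a standing
#: regression test on the packaged fixture.
CRP_EPITOPE_ANCHORS: tuple[EpitopeAnchor, ...] = (
    EpitopeAnchor("CLH", 36, 38),
    EpitopeAnchor("EILIF", 62, 66),
    EpitopeAnchor("SEIL", 80, 83),
    EpitopeAnchor("SWE", 99, 101),
    EpitopeAnchor("VRKSLKK", 117, 123),
    EpitopeAnchor("ILGQ", 134, 137),
    EpitopeAnchor("SFGGNFEGSQSL", 141, 152),
    EpitopeAnchor("DIGN", 155, 158),
    EpitopeAnchor("PDE", 168, 170),
    EpitopeAnchor("YEVQG", 192, 196),
    EpitopeAnchor("QLWP", 203, 206),
)


@dataclass(frozen=True)
class PeptideTile:
    """One printed peptide spot.

    ``flanked_span`` is the 1-based span on the linker-elongated sequence;
    ``mature_span`` is its clipped projection onto the mature monomer and is
    ``None`` for spots lying wholly inside a linker (such spots exist on the
    physical array but can never support an epitope).
    """

    index: int
    sequence: str
    flanked_span: tuple[int, int]
    mature_span: tuple[int, int] | None


def load_mature_sequence(source: str | Path) -> ProteinSequence:
    """Load a single-record amino-acid FASTA, or the builtin ``"CRP"`` fixture.

    The builtin fixture is the 206-residue mature human CRP monomer shipped
    with the package; its identity is enforced by :data:`CRP_EPITOPE_ANCHORS`
    (see :func:`validate_anchors`).
    """
    if isinstance(source, str) and source.upper() == "CRP":
        ref = importlib.resources.files("crpmap.data") / "crp_mature.fasta"
        with importlib.resources.as_file(ref) as path:
            return _read_single_fasta(path)
    return _read_single_fasta(Path(source))


def _read_single_fasta(path: Path) -> ProteinSequence:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise SequenceFormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if len(records) != 1:
        raise SequenceFormatError(
            f"expected exactly one FASTA record in {path}, got {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise SequenceFormatError(f"empty sequence in {path}")
    return ProteinSequence(id=rec.id, residues=seq)


def write_fasta(seq: ProteinSequence, path: str | Path, width: int = 60) -> None:
    """Write a single-record FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.residues[i : i + width] + "\n")


def validate_anchors(
    seq: ProteinSequence, anchors: Iterable[EpitopeAnchor]
) -> dict[str, bool]:
    """Check each anchor motif against the sequence at its printed span.

    Returns a mapping ``"MOTIF^start-end" -> passed``.  Raises
    :class:`CoordinateError` for anchors outside the sequence.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchors supplied")
    report: dict[str, bool] = {}
    for a in anchors:
        observed = seq.span(a.start, a.end)
        report[f"{a.motif}^{a.start}-{a.end}"] = observed == a.motif
    return report


def locate_motif(seq: ProteinSequence, motif: str) -> list[int]:
    """All 1-based start positions of exact matches of ``motif``, ascending."""
    if not motif:
        raise ValueError("empty motif")
    hits = []
    pos = seq.residues.find(motif)
    while pos != -1:
        hits.append(pos + 1)
        pos = seq.residues.find(motif, pos + 1)
    return hits


def tile_sequence(
    seq: ProteinSequence,
    tile_length: int = DEFAULT_TILE_LENGTH,
    overlap: int = DEFAULT_OVERLAP,
    flank: str = DEFAULT_FLANK,
) -> list[PeptideTile]:
    """Tile the flanked sequence ``flank + seq + flank`` into peptides.

    Consecutive tiles step by ``tile_length - overlap`` residues on the
    flanked sequence; with the defaults (15/14) the step is one residue and
    the tile count is ``L + 2*len(flank) - tile_length + 1``.
    """
    if not (0 <= overlap < tile_length):
        raise ValueError(f"need 0 <= overlap < tile_length, got {overlap}/{tile_length}")
    if flank and (set(flank) - AA_ALPHABET):
        raise AlphabetError(f"flank contains non-amino-acid characters: {flank!r}")
    flanked = flank + seq.residues + flank
    if tile_length > len(flanked):
        raise ValueError(
            f"tile_length {tile_length} exceeds flanked length {len(flanked)}"
        )
    step = tile_length - overlap
    nf = len(flank)
    tiles: list[PeptideTile] = []
    index = 0
    for fstart0 in range(0, len(flanked) - tile_length + 1, step):
        fstart, fend = fstart0 + 1, fstart0 + tile_length  # 1-based flanked
        # project onto mature coordinates and clip to 1..L
        mstart = max(1, fstart - nf)
        mend = min(seq.length, fend - nf)
        mature = (mstart, mend) if mstart <= mend and fend - nf >= 1 else None
        tiles.append(
            PeptideTile(
                index=index,
                sequence=flanked[fstart0 : fstart0 + tile_length],
                flanked_span=(fstart, fend),
                mature_span=mature,
            )
        )
        index += 1
    return tiles


def flank_anchor_warnings(
    seq: ProteinSequence,
    anchors: Sequence[EpitopeAnchor],
    flank: str = DEFAULT_FLANK,
) -> list[str]:
    """Warn (do not fail) if the flank creates a spurious anchor match.

    A spurious match is an anchor motif occurring in the flanked sequence at a
    position it does not occupy on the mature monomer.
    """
    flanked = flank + seq.residues + flank
    warnings: list[str] = []
    for a in anchors:
        n_mature = len(locate_motif(seq, a.motif))
        n_flanked = flanked.count(a.motif)
        if n_flanked > n_mature:
            warnings.append(
                f"flank {flank!r} creates {n_flanked - n_mature} extra "
                f"match(es) of anchor motif {a.motif!r}"
            )
    return warnings


def write_tiling_table(tiles: Sequence[PeptideTile], path: str | Path) -> None:
    """Export a tiling library as tab-separated text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tile_index\tflanked_start\tmature_start\tmature_end\tsequence\n")
        for t in tiles:
            ms, me = t.mature_span if t.mature_span else ("", "")
            fh.write(f"{t.index}\t{t.flanked_span[0]}\t{ms}\t{me}\t{t.sequence}\n")
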