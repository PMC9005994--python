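"""FASTA input/output and extraction of fixed-length candidate windows.

A candidate site is a cytosine together with ``flank`` nucleotides on each
side, giving a window of length ``2*flank + 1`` (41 nt for the default
flank of 20).  DNA input is tolerated: T is mapped to U before validation.
Cytosines whose full window would run off the end of the source sequence are
skipped — the encoders all assume fixed-length input, so no padding is ever
applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from m5cboost._util import ALPHABET

DEFAULT_FLANK = 20

_VALID = set(ALPHABET)


@dataclasses.dataclass(frozen=True)
class RnaSegment:
    """A fixed-length RNA window with the candidate cytosine at its center.

    ``center_offset`` is the 1-based position of the candidate C within the
    *source* sequence the window was cut from; for windows read directly from
    pre-cut FASTA records it is the center position within the record itself.
    """

    id: str
    sequence: str
    center_offset: int
    label: int | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n % 2 == 0:
            raise ValueError(f"segment {self.id}: even length {n}")
        if self.sequence[n // 2] != "C":
            raise ValueError(f"segment {self.id}: center nucleotide is not C")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"segment {self.id}: invalid characters {sorted(bad)}")

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2


@dataclasses.dataclass(frozen=True)
class Rejection:
    """A per-record reason why a FASTA record was not accepted as a segment."""

    id: str
    reason: str


class SegmentSet:
    """An ordered collection of :class:`RnaSegment` with unique ids."""

    def __init__(
        self,
        segments: Iterable[RnaSegment],
        species_tag: str | None = None,
        rejections: Iterable[Rejection] = (),
    ):
        self.segments: list[RnaSegment] = list(segments)
        self.species_tag = species_tag
        self.rejections: list[Rejection] = list(rejections)
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate segment ids: {dupes}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[RnaSegment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> RnaSegment:
        return self.segments[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return self.segments == other.segments

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.segments]

    @property
    def labels(self) -> list[int | None]:
        return [s.label for s in self.segments]

    def with_labels(self, labels: dict[str, int]) -> "SegmentSet":
        """Return a copy with labels attached by segment id."""
        out = [
            dataclasses.replace(s, label=labels.get(s.id, s.label))
            for s in self.segments
        ]
        return SegmentSet(out, species_tag=self.species_tag)


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA thymine to uracil."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path, flank: int = DEFAULT_FLANK) -> SegmentSet:
    """Read pre-cut candidate windows from FASTA, one segment per record.

    Records are normalized (uppercase, T->U) and validated: wrong length,
    non-C center, ambiguity codes (N, R, Y, ...) or a duplicate id lead to a
    per-record entry in ``result.rejections`` rather than an exception.
    Description fields of the form ``key=value`` are parsed; ``pos`` restores
    the source coordinate of the center and ``label`` a 0/1 class label.
    """
    want = 2 * flank + 1
    segments: list[RnaSegment] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        if rid in seen:
            rejections.append(Rejection(rid, "duplicate id"))
            continue
        seq = normalize_sequence(str(record.seq))
        bad = set(seq) - _VALID
        if bad:
            rejections.append(
                Rejection(rid, "invalid characters: " + ",".join(sorted(bad)))
            )
            continue
        if len(seq) != want:
            rejections.append(Rejection(rid, f"length != {want}"))
            continue
        if seq[flank] != "C":
            rejections.append(Rejection(rid, "center != C"))
            continue
        meta = _parse_description(record.description)
        center = int(meta.get("pos", flank + 1))
        label = int(meta["label"]) if "label" in meta else None
        seen.add(rid)
        segments.append(RnaSegment(rid, seq, center, label))
    return SegmentSet(segments, rejections=rejections)


def _parse_description(description: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def write_fasta(segments: SegmentSet, path: str | Path, width: int = 60) -> Path:
    """Write segments as FASTA; center offset and label go in the header."""
    path = Path(path)
    with open(path, "w") as fh:
        for seg in segments:
            header = f">{seg.id} pos={seg.center_offset}"
            if seg.label is not None:
                header += f" label={seg.label}"
            fh.write(header + "\n")
            for start in range(0, len(seg.sequence), width):
                fh.write(seg.sequence[start : start + width] + "\n")
    return path


def write_rejection_report(rejections: Iterable[Rejection], path: str | Path) -> Path:
    """Write rejected records as tab-separated ``id<TAB>reason`` lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for rej in rejections:
            fh.write(f"{rej.id}\t{rej.reason}\n")
    return path


def extract_candidates(
    seq: str,
    flank: int = DEFAULT_FLANK,
    seq_id: str = "seq",
    label: int | None = None,
) -> SegmentSet:
    """Extract every full-window candidate cytosine from an arbitrary sequence.

    One segment is produced per C whose +/-``flank`` window lies entirely
    inside ``seq``; near-edge cytosines are skipped.  Windows containing
    ambiguity codes are rejected per-candidate.  A sequence without any
    eligible C yields an empty set, not an error.
    """
    norm = normalize_sequence(seq)
    want = 2 * flank + 1
    if len(norm) < want:
        raise ValueError(
            f"sequence {seq_id!r} is {len(norm)} nt; need at least {want}"
        )
    segments = []
    rejections = []
    for i, nt in enumerate(norm):
        if nt != "C" or i < flank or i + flank >= len(norm):
            continue
        window = norm[i - flank : i + flank + 1]
        sid = f"{seq_id}@{i + 1}"
        bad = set(window) - _VALID
        if bad:
            rejections.append(
                Rejection(sid, "invalid characters: " + ",".join(sorted(bad)))
            )
            continue
        segments.append(RnaSegment(sid, window, i + 1, label))
    return SegmentSet(segments, rejections=rejections)


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` file (header optional)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, _, value = line.partition("\t")
            if sid == "id":
                continue
            out[sid] = int(value)
    return out
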