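"""Synthetic labeled 41-nt segment benchmarks with planted positional signal.

The generator emulates the shape of the published m5C benchmarks — balanced
sets of fixed-length windows over {A,C,G,U} with the candidate cytosine at
the center — while planting a controllable, fully known class signal: at
each *biased position* the positive class draws its nucleotide from a
mixture ``(1 - effect) * background + effect * point-mass(designated)``.
``effect = 0`` makes the classes identically distributed (a null benchmark);
``effect = 1`` fixes the designated nucleotide in every positive.

Because the signal is positional, the one-hot (BIN) indicator of the
designated nucleotide at each biased position is a known minimal relevant
feature set, which ranking and selection tests can score recovery against
(``relevant_feature_names``).  What the generator does *not* emulate:
motif/k-mer context, species-specific base composition, or dependence
between positions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from m5cboost._util import ALPHABET
from m5cboost.sequence_io import RnaSegment, SegmentSet, read_fasta, read_labels, write_fasta

#: default biased positions (1-based), spaced >= 6 nt apart so no length-5
#: composition window spans two of them, and excluding the center (21).
DEFAULT_BIASED_POSITIONS = (5, 11, 17, 27, 33, 39)


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of a planted-signal benchmark."""

    n_pos: int = 500
    n_neg: int = 500
    effect: float = 0.5
    biased_positions: tuple[int, ...] = DEFAULT_BIASED_POSITIONS
    designated: tuple[str, ...] | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    flank: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect must be in [0, 1]")
        if abs(sum(self.background) - 1) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        length = 2 * self.flank + 1
        center = self.flank + 1
        for p in self.biased_positions:
            if p == center:
                raise ValueError("the center position is fixed to C in both classes")
            if not 1 <= p <= length:
                raise ValueError(f"biased position {p} outside 1..{length}")
        if self.designated is None:
            cycle = [nt for nt in ALPHABET if nt != "C"]
            self.designated = tuple(
                cycle[i % len(cycle)] for i in range(len(self.biased_positions))
            )
        if len(self.designated) != len(self.biased_positions):
            raise ValueError("designated must match biased_positions in length")

    @property
    def length(self) -> int:
        return 2 * self.flank + 1

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
        return path


def generate(spec: SyntheticSpec) -> SegmentSet:
    """Draw a labeled segment set; same spec and seed are byte-reproducible."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.background)
    center_idx = spec.flank  # 0-based

    def draw_class(n: int, positive: bool, prefix: str) -> list[RnaSegment]:
        codes = rng.choice(4, size=(n, spec.length), p=probs)
        codes[:, center_idx] = 1  # C
        if positive and spec.effect > 0:
            for pos, nt in zip(spec.biased_positions, spec.designated):
                hit = rng.random(n) < spec.effect
                codes[hit, pos - 1] = ALPHABET.index(nt)
        width = len(str(n))
        return [
            RnaSegment(
                id=f"{prefix}{i + 1:0{width}d}",
                sequence="".join(ALPHABET[c] for c in row),
                center_offset=spec.flank + 1,
                label=1 if positive else 0,
            )
            for i, row in enumerate(codes)
        ]

    segments = draw_class(spec.n_pos, True, "pos") + draw_class(
        spec.n_neg, False, "neg"
    )
    return SegmentSet(segments, species_tag="synthetic")


def relevant_feature_names(spec: SyntheticSpec) -> list[str]:
    """The minimal planted-signal column set: the one-hot indicator of the
    designated nucleotide at each biased position."""
    return [
        f"BIN_p{pos}_{nt}"
        for pos, nt in zip(spec.biased_positions, spec.designated)
    ]


def write_fixture(segments: SegmentSet, directory: str | Path) -> dict[str, Path]:
    """Write FASTA + ``id<TAB>label`` TSV; round-trips through read_fixture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = write_fasta(segments, directory / "segments.fasta")
    labels = directory / "labels.tsv"
    with open(labels, "w") as fh:
        fh.write("id\tlabel\n")
        for seg in segments:
            fh.write(f"{seg.id}\t{seg.label if seg.label is not None else ''}\n")
    return {"fasta": fasta, "labels": labels}


def read_fixture(directory: str | Path, flank: int = 20) -> SegmentSet:
    directory = Path(directory)
    segments = read_fasta(directory / "segments.fasta", flank=flank)
    labels = read_labels(directory / "labels.tsv")
    return segments.with_labels(labels)
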