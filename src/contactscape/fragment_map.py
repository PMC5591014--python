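"""Virtual restriction digestion into an ordered first-cutter fragment map.

4C-seq libraries are built with two restriction enzymes: a frequent first
cutter (DpnII, ``GATC``) that defines the analysis fragments, and a second
cutter (Csp6I, ``GTAC``) used for recircularization.  First-cutter fragments
lacking a second-cutter site ("blind" fragments) behave anomalously during
library preparation, so the map records a blind flag per fragment.

Coordinates are 0-based half-open throughout.  The cut position convention is
blunt: a fragment boundary is placed at the first base of each first-cutter
site occurrence (real DpnII leaves a 5' overhang, but fragment identity, not
ligation chemistry, is what downstream analysis consumes).
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List

_VALID_MOTIF = re.compile(r"^[ACGT]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CutterScheme:
    """Pair of restriction motifs: first (fragmenting) and second (blind-flag) cutter.

    The default DpnII/Csp6I motifs are palindromic; non-palindromic motifs are
    scanned on both strands.
    """

    primary_site: str = "GATC"
    secondary_site: str = "GTAC"

    def __post_init__(self) -> None:
        for name, motif in (("primary_site", self.primary_site),
                            ("secondary_site", self.secondary_site)):
            if not motif or not _VALID_MOTIF.match(motif):
                raise ValueError(
                    f"{name} must be a non-empty uppercase A/C/G/T motif, got {motif!r}"
                )


@dataclass(frozen=True)
class RestrictionFragment:
    """One first-cutter fragment: [start, end) on ``chrom``, ordinal ``index``."""

    chrom: str
    start: int
    end: int
    index: int
    blind: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def _motif_positions(sequence: str, motif: str) -> List[int]:
    """Start positions of (possibly overlapping) motif occurrences.

    Scans both strands; for a palindromic motif the reverse-strand scan is a
    no-op because occurrences coincide.  Ns never match (the motif alphabet
    excludes N, so any N in the window fails the comparison).
    """
    positions = set()
    pattern = re.compile(f"(?={re.escape(motif)})")
    positions.update(m.start() for m in pattern.finditer(sequence))
    rc = reverse_complement(motif)
    if rc != motif:
        rc_pattern = re.compile(f"(?={re.escape(rc)})")
        positions.update(m.start() for m in rc_pattern.finditer(sequence))
    return sorted(positions)


def digest(sequence: str, scheme: CutterScheme, chrom: str = "chr") -> List[RestrictionFragment]:
    """Virtually digest one chromosome into ordered first-cutter fragments.

    A boundary is placed at the first base of each primary-site occurrence;
    the first fragment starts at 0 and the last ends at the sequence length.
    A cut at position 0 does not create an empty leading fragment.  Each
    fragment's ``blind`` flag is True when no secondary site occurs within it.

    A sequence without any primary site yields a single fragment spanning the
    chromosome.  An empty sequence is an error.
    """
    if not sequence:
        raise ValueError("empty chromosome")
    seq = sequence.upper()
    cuts = [p for p in _motif_positions(seq, scheme.primary_site) if p > 0]
    edges = [0] + cuts + [len(seq)]
    fragments = []
    for i, (start, end) in enumerate(zip(edges[:-1], edges[1:])):
        blind = not _motif_positions(seq[start:end], scheme.secondary_site)
        fragments.append(RestrictionFragment(chrom, start, end, i, blind))
    return fragments


@dataclass
class FragmentMap:
    """Per-chromosome ordered fragment lists with O(log n) position lookup."""

    fragments: Dict[str, List[RestrictionFragment]] = field(default_factory=dict)

    @classmethod
    def from_sequences(cls, sequences: Dict[str, str], scheme: CutterScheme) -> "FragmentMap":
        return cls({chrom: digest(seq, scheme, chrom) for chrom, seq in sequences.items()})

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {chrom: frags[-1].end for chrom, frags in self.fragments.items()}

    def chromosomes(self) -> List[str]:
        return list(self.fragments)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.fragments

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for frags in self.fragments.values():
            yield from frags

    def locate_fragment(self, chrom: str, pos: int) -> RestrictionFragment:
        """Return the unique fragment with start <= pos < end (binary search)."""
        if chrom not in self.fragments:
            raise KeyError(f"unknown chromosome {chrom!r}")
        frags = self.fragments[chrom]
        length = frags[-1].end
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} out of range for {chrom} (length {length})")
        starts = [f.start for f in frags]
        i = bisect.bisect_right(starts, pos) - 1
        return frags[i]

    def to_bed_records(self) -> Iterator[str]:
        """BED4 lines: chrom, start, end, ``frag_<index>;blind=<0|1>``."""
        for frag in self:
            yield (f"{frag.chrom}\t{frag.start}\t{frag.end}\t"
                   f"frag_{frag.index};blind={int(frag.blind)}")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.to_bed_records():
                fh.write(line + "\n")
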