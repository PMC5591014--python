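"""Per-fragment-end capture calls and windowed capture frequencies for one viewpoint.

In 4C-seq, a fragment end counts as "captured" (ligated to the viewpoint)
when at least one read maps exactly at that end, oriented toward the fragment
center: a forward read starting at the fragment's left edge, or a reverse
read ending at its right edge.  Captured ends are summarized over sliding
windows of W consecutive fragments (default W=30, so at most 2W=60 captured
sites per window); the per-window frequency f = c / (2W) feeds the
distance-decay fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .fragment_map import FragmentMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    """An aligned read span, 0-based half-open, with strand '+' or '-'."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ViewpointSpec:
    """The viewpoint fragment: the locus whose ligation partners are sequenced.

    ``position`` is the bait coordinate (typically the viewpoint fragment
    midpoint); ``exclusion_radius_fragments`` masks the viewpoint fragment and
    its neighbors, where self-ligation and undigested products dominate.
    """

    name: str
    chrom: str
    position: int
    fragment_index: int
    exclusion_radius_fragments: int = 2


@dataclass
class CaptureProfile:
    """Capture calls and window table for one viewpoint/replicate.

    ``windows`` columns: window, chrom, start, end, midpoint, n_fragments,
    c (captured ends), f (= c / (2 n_fragments)), distance (signed bp,
    midpoint - viewpoint position), excluded, truncated.
    """

    viewpoint: ViewpointSpec
    replicate: str
    window_size: int
    left_captured: np.ndarray   # per fragment on the viewpoint chromosome
    right_captured: np.ndarray
    windows: pd.DataFrame = field(repr=False)

    def to_bedgraph_records(self):
        for row in self.windows.itertuples():
            yield f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.f:.6g}"


def call_captured_ends(
    reads: List[AlignedRead], fragment_map: FragmentMap
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-fragment-end capture booleans, keyed by chromosome.

    Left end of fragment [s, e) is captured iff >=1 forward read starts at s;
    right end iff >=1 reverse read ends at e.  All other reads (wrong
    position or orientation, e.g. non-end noise) are ignored.  Reads on
    chromosomes absent from the map are skipped with a logged count.
    """
    plus_starts: Dict[str, set] = {}
    minus_ends: Dict[str, set] = {}
    skipped = 0
    for read in reads:
        if read.chrom not in fragment_map:
            skipped += 1
            continue
        if read.strand == "+":
            plus_starts.setdefault(read.chrom, set()).add(read.start)
        else:
            minus_ends.setdefault(read.chrom, set()).add(read.end)
    if skipped:
        logger.warning("%d reads on chromosomes absent from the fragment map were skipped", skipped)

    calls = {}
    for chrom, frags in fragment_map.fragments.items():
        starts = np.fromiter((f.start for f in frags), dtype=np.int64, count=len(frags))
        ends = np.fromiter((f.end for f in frags), dtype=np.int64, count=len(frags))
        ps = np.fromiter(plus_starts.get(chrom, ()), dtype=np.int64)
        me = np.fromiter(minus_ends.get(chrom, ()), dtype=np.int64)
        left = np.isin(starts, ps)
        right = np.isin(ends, me)
        calls[chrom] = (left, right)
    return calls


def windowize(
    capture_calls: Dict[str, Tuple[np.ndarray, np.ndarray]],
    fragment_map: FragmentMap,
    viewpoint: ViewpointSpec,
    replicate: str = "rep1",
    window_size: int = 30,
    step: int = 1,
) -> CaptureProfile:
    """Summarize capture calls over sliding fragment windows on the viewpoint chromosome.

    Windows span ``window_size`` consecutive fragments (step 1 by default); a
    chromosome with fewer fragments yields a single truncated, excluded
    window.  Windows containing any fragment within the viewpoint exclusion
    zone are flagged excluded and skipped by the decay fit.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    chrom = viewpoint.chrom
    if chrom not in fragment_map:
        raise KeyError(f"viewpoint chromosome {chrom!r} not in fragment map")
    frags = fragment_map.fragments[chrom]
    left, right = capture_calls[chrom]
    n = len(frags)
    ends_per_frag = left.astype(np.int64) + right.astype(np.int64)
    starts = np.fromiter((f.start for f in frags), dtype=np.int64, count=n)
    ends = np.fromiter((f.end for f in frags), dtype=np.int64, count=n)

    lo = viewpoint.fragment_index - viewpoint.exclusion_radius_fragments
    hi = viewpoint.fragment_index + viewpoint.exclusion_radius_fragments

    if n < window_size:
        c = int(ends_per_frag.sum())
        rows = [{
            "window": 0, "chrom": chrom, "start": int(starts[0]), "end": int(ends[-1]),
            "midpoint": (int(starts[0]) + int(ends[-1])) / 2.0, "n_fragments": n,
            "c": c, "f": c / (2.0 * n),
            "distance": (int(starts[0]) + int(ends[-1])) / 2.0 - viewpoint.position,
            "excluded": True, "truncated": True,
        }]
        logger.warning("chromosome %s has %d < %d fragments; single truncated window", chrom, n, window_size)
        windows = pd.DataFrame(rows)
    else:
        csum = np.concatenate([[0], np.cumsum(ends_per_frag)])
        first = np.arange(0, n - window_size + 1, step)
        last = first + window_size - 1
        c = csum[last + 1] - csum[first]
        wstart = starts[first]
        wend = ends[last]
        mid = (wstart + wend) / 2.0
        excluded = (first <= hi) & (last >= lo)
        windows = pd.DataFrame({
            "window": np.arange(len(first)),
            "chrom": chrom,
            "start": wstart, "end": wend, "midpoint": mid,
            "n_fragments": window_size,
            "c": c, "f": c / (2.0 * window_size),
            "distance": mid - viewpoint.position,
            "excluded": excluded,
            "truncated": False,
        })
    return CaptureProfile(
        viewpoint=viewpoint, replicate=replicate, window_size=window_size,
        left_captured=left, right_captured=right, windows=windows,
    )
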