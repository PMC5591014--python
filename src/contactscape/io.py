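"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA via Biopython, SAM via pysam; BED, bedGraph and the gene/expression
table are simple tab-separated files parsed here with line-number error
reporting.  Coordinates are 0-based half-open internally; SAM input is
converted from 1-based on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .capture_profile import AlignedRead
from .feature_proximity import IntervalSet, SignalTrack, validate_gene_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    """Multi-record FASTA as {name: sequence}; headers tokenized at first whitespace."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED intervals


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            yield lineno, line


def read_intervals(path, name: Optional[str] = None) -> IntervalSet:
    """BED3+ as a sorted IntervalSet; malformed lines are errors with line numbers."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED fields, got {len(fields)}")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
        intervals.append((chrom, start, end))
    return IntervalSet(intervals, name=name or Path(path).stem)


def write_bed(intervals: Iterable[Tuple[str, int, int]], path,
              names: Optional[Sequence[str]] = None,
              scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            fields = [chrom, str(start), str(end)]
            if names is not None:
                fields.append(str(names[i]))
            if scores is not None:
                if names is None:
                    fields.append(".")
                fields.append(f"{scores[i]:.4g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# alignments


def read_alignments(path, fmt: Optional[str] = None) -> List[AlignedRead]:
    """Aligned reads from SAM or BED6.

    SAM: strand from FLAG 0x10, span from POS + CIGAR (reference-consuming
    operations), converted to 0-based half-open; unmapped records (0x4) and
    mapped records without a CIGAR are skipped and counted.  BED6 is taken
    verbatim.  Format inferred from the extension when ``fmt`` is None.
    """
    if fmt is None:
        fmt = "sam" if str(path).endswith(".sam") else "bed"
    if fmt == "sam":
        return _read_sam(path)
    if fmt == "bed":
        return _read_bed6(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _read_sam(path) -> List[AlignedRead]:
    reads = []
    n_unmapped = n_nocigar = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.cigartuples is None:
                n_nocigar += 1
                continue
            reads.append(AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
            ))
    if n_unmapped:
        logger.info("%s: skipped %d unmapped records", path, n_unmapped)
    if n_nocigar:
        logger.warning("%s: skipped %d mapped records without CIGAR", path, n_nocigar)
    return reads


def _read_bed6(path) -> List[AlignedRead]:
    reads = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
        reads.append(AlignedRead(fields[0], int(fields[1]), int(fields[2]), fields[5]))
    return reads


def write_sam(reads: Sequence[AlignedRead], chrom_lengths: Dict[str, int], path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, read in enumerate(reads):
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = f"read{i}"
            seg.reference_id = tids[read.chrom]
            seg.reference_start = read.start
            seg.cigarstring = f"{read.end - read.start}M"
            seg.flag = 16 if read.strand == "-" else 0
            seg.mapping_quality = 60
            sam.write(seg)


def write_bed6_reads(reads: Sequence[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# gene table, bedGraph, manifest


GENE_COLUMNS = ["gene", "chrom", "tss", "strand", "cls"]


def read_gene_table(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    return validate_gene_table(genes)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    validate_gene_table(genes)[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bedgraph(path, name: Optional[str] = None) -> SignalTrack:
    segments = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
        segments.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return SignalTrack(segments, name=name or Path(path).stem)


def write_bedgraph(track_or_segments, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track_or_segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_manifest(entries: Dict[str, str], path) -> None:
    """Plain-text key=value manifest, keys sorted for byte-stable output."""
    with open(path, "w") as fh:
        for key in sorted(entries):
            fh.write(f"{key}={entries[key]}\n")


def read_manifest(path) -> Dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and "=" in line:
                key, _, value = line.partition("=")
                out[key] = value
    return out
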