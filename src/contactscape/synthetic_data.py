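"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of the real experiments without any
external download: a toy genome with restriction sites injected as a Poisson
process, 4C reads whose per-end capture probability follows a power-law
distance decay P(d) = A * (d/d0)^-alpha with planted multiplicative
enrichments and replicate noise, and gene/feature fixtures whose
TSS-to-feature distance distributions differ between expression classes by a
controllable effect size.

All randomness derives from a single top-level seed fanned out into named
substreams (genome, reads, genes, track), so each component regenerates
independently and bit-identically.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .capture_profile import AlignedRead, ViewpointSpec
from .fragment_map import CutterScheme, FragmentMap, RestrictionFragment, digest
from .feature_proximity import IntervalSet, SignalTrack

# named substreams off the top-level seed
_STREAM_GENOME = 1
_STREAM_READS = 2
_STREAM_GENES = 3
_STREAM_TRACK = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BREAK = {ord("A"): ord("C"), ord("C"): ord("A"), ord("G"): ord("T"), ord("T"): ord("G")}


def _cond_stream(condition: str) -> int:
    return zlib.crc32(condition.encode()) % (2 ** 16)


@dataclass(frozen=True)
class EnrichedRegion:
    """A planted contact: capture probability multiplied by ``fold`` within the span."""

    chrom: str
    start: int
    end: int
    fold: float
    conditions: Tuple[str, ...] = ("control", "mutant")

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted enrichment fold must be > 1")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated 4C experiment.

    Capture probability at distance d bp from the viewpoint is
    min(p_max, amplitude * (max(d, d0)/d0) ** -alpha), times any planted
    fold.  Captured ends emit 1 + NB(mu - 1, phi) reads; a fraction of
    noise reads land at non-end positions and must be ignored downstream.
    """

    seed: int
    genome_length: int = 500_000
    gatc_rate: float = 1 / 250
    gtac_rate: float = 1 / 250
    amplitude: float = 0.9
    alpha: float = 1.0
    d0: float = 20_000.0  # capture is near-saturated out to tens of kb in 4C
    p_max: float = 0.95
    enriched: List[EnrichedRegion] = field(default_factory=list)
    read_mu: float = 3.0
    read_phi: float = 0.5
    noise_read_fraction: float = 0.10
    read_length: int = 36

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be > 0")

    def capture_probability(self, distance_bp: np.ndarray) -> np.ndarray:
        d = np.maximum(np.abs(np.asarray(distance_bp, dtype=float)), self.d0)
        return np.minimum(self.amplitude * (d / self.d0) ** -self.alpha, self.p_max)

    def manifest(self) -> Dict[str, str]:
        out = {}
        for key, value in asdict(self).items():
            if key == "enriched":
                for i, region in enumerate(value):
                    out[f"enriched_{i}"] = (
                        f"{region['chrom']}:{region['start']}-{region['end']}"
                        f"@{region['fold']}x[{','.join(region['conditions'])}]"
                    )
            else:
                out[key] = repr(value)
        return out


# ---------------------------------------------------------------------------
# genome


def _scrub(seq: bytearray, motifs: Sequence[str], protected: Optional[set] = None) -> None:
    """Mutate bases until no unintended motif occurrence remains.

    Occurrences whose every base is protected (intended, injected sites) are
    left alone; for any other occurrence one unprotected base is flipped.
    """
    for _ in range(200):
        changed = False
        text = seq.decode()
        for motif in motifs:
            for m in re.finditer(f"(?={motif})", text):
                p = m.start()
                for off in range(len(motif) - 1, -1, -1):
                    pos = p + off
                    if protected is None or pos not in protected:
                        seq[pos] = _BREAK[seq[pos]]
                        changed = True
                        break
        if not changed:
            return
    raise RuntimeError("motif scrubbing did not converge")


def _poisson_site_positions(
    rng: np.random.Generator, length: int, rate: float, motif_len: int,
    occupied: List[int],
) -> List[int]:
    n = min(rng.poisson(rate * length), max(length - motif_len, 0))
    if n == 0:
        return []
    pos = np.sort(rng.choice(length - motif_len, size=n, replace=False))
    kept: List[int] = []
    taken = sorted(occupied)
    for p in pos:
        if kept and p - kept[-1] < motif_len:
            continue
        i = np.searchsorted(taken, p)
        if i > 0 and p - taken[i - 1] < motif_len:
            continue
        if i < len(taken) and taken[i] - p < motif_len:
            continue
        kept.append(int(p))
    return kept


def make_genome(
    seed: int,
    length: int = 500_000,
    gatc_rate: float = 1 / 250,
    gtac_rate: float = 1 / 250,
    scheme: CutterScheme = CutterScheme(),
) -> Tuple[str, Dict[str, List[int]]]:
    """Random chromosome with cutter sites injected as a Poisson process.

    The background sequence is scrubbed of accidental cutter motifs before
    injection, so the realized digest corresponds exactly to the planted
    site lists (in particular, a rate of 0 guarantees zero sites).  Returns
    (sequence, {"primary": positions, "secondary": positions}).
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    for name, rate in (("gatc_rate", gatc_rate), ("gtac_rate", gtac_rate)):
        if not 0 <= rate < 0.05:
            raise ValueError(f"{name} must lie in [0, 0.05)")
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    seq = bytearray(rng.choice(_BASES, size=length).tobytes())
    motifs = [scheme.primary_site, scheme.secondary_site]
    _scrub(seq, motifs)

    primary = _poisson_site_positions(rng, length, gatc_rate, len(scheme.primary_site), [])
    secondary = _poisson_site_positions(rng, length, gtac_rate, len(scheme.secondary_site), primary)
    protected = set()
    for p in primary:
        seq[p:p + len(scheme.primary_site)] = scheme.primary_site.encode()
        protected.update(range(p, p + len(scheme.primary_site)))
    for p in secondary:
        seq[p:p + len(scheme.secondary_site)] = scheme.secondary_site.encode()
        protected.update(range(p, p + len(scheme.secondary_site)))
    _scrub(seq, motifs, protected)
    return seq.decode(), {"primary": primary, "secondary": secondary}


def make_fragment_map(
    seed: int, n_fragments: int = 2000, mean_length: int = 250, chrom: str = "chr1",
    blind_fraction: float = 0.1,
) -> FragmentMap:
    """Fragment-map geometry without a sequence, for decay/statistics simulations."""
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    lengths = np.maximum(rng.poisson(mean_length, size=n_fragments), 20)
    edges = np.concatenate([[0], np.cumsum(lengths)])
    blind = rng.random(n_fragments) < blind_fraction
    frags = [
        RestrictionFragment(chrom, int(edges[i]), int(edges[i + 1]), i, bool(blind[i]))
        for i in range(n_fragments)
    ]
    return FragmentMap({chrom: frags})


# ---------------------------------------------------------------------------
# 4C reads


def viewpoint_at(fragment_map: FragmentMap, chrom: str, position: int,
                 name: str = "vp", exclusion_radius: int = 2) -> ViewpointSpec:
    """Viewpoint spec anchored at the fragment containing ``position``."""
    frag = fragment_map.locate_fragment(chrom, position)
    return ViewpointSpec(name=name, chrom=chrom,
                         position=(frag.start + frag.end) // 2,
                         fragment_index=frag.index,
                         exclusion_radius_fragments=exclusion_radius)


def simulate_4c(
    truth: SyntheticTruth,
    fragment_map: FragmentMap,
    viewpoint: ViewpointSpec,
    n_replicates: int = 2,
    condition: str = "control",
) -> Dict[str, List[AlignedRead]]:
    """Simulate 4C reads for each replicate of one condition.

    Every fragment end is captured with probability P(d) (times planted fold
    for this condition); each captured end emits >= 1 read exactly at the end
    position in the inward orientation.  Noise reads at non-end positions are
    added at ``truth.noise_read_fraction`` of the total and carry no capture
    signal.
    """
    chrom = viewpoint.chrom
    frags = fragment_map.fragments[chrom]
    chrom_len = frags[-1].end
    starts = np.fromiter((f.start for f in frags), dtype=np.int64, count=len(frags))
    ends = np.fromiter((f.end for f in frags), dtype=np.int64, count=len(frags))

    p_left = truth.capture_probability(starts - viewpoint.position)
    p_right = truth.capture_probability(ends - viewpoint.position)
    for region in truth.enriched:
        if region.chrom != chrom or condition not in region.conditions:
            continue
        p_left = np.where((starts >= region.start) & (starts < region.end),
                          np.minimum(p_left * region.fold, truth.p_max), p_left)
        p_right = np.where((ends >= region.start) & (ends < region.end),
                           np.minimum(p_right * region.fold, truth.p_max), p_right)

    rl = truth.read_length
    start_set = set(starts.tolist())
    end_set = set(ends.tolist())
    out: Dict[str, List[AlignedRead]] = {}
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            [truth.seed, _STREAM_READS, rep, _cond_stream(condition)])
        cap_left = rng.random(len(frags)) < p_left
        cap_right = rng.random(len(frags)) < p_right
        reads: List[AlignedRead] = []
        extra_mean = max(truth.read_mu - 1.0, 0.0)
        for pos_arr, cap, strand in ((starts, cap_left, "+"), (ends, cap_right, "-")):
            for pos in pos_arr[cap]:
                if extra_mean > 0:
                    nb_n = 1.0 / truth.read_phi
                    nb_p = nb_n / (nb_n + extra_mean)
                    n_reads = 1 + int(rng.negative_binomial(nb_n, nb_p))
                else:
                    n_reads = 1
                if strand == "+":
                    s, e = int(pos), min(int(pos) + rl, chrom_len)
                else:
                    s, e = max(int(pos) - rl, 0), int(pos)
                reads.extend(AlignedRead(chrom, s, e, strand) for _ in range(n_reads))
        if truth.noise_read_fraction > 0:
            n_noise = int(round(len(reads) * truth.noise_read_fraction
                                / (1 - truth.noise_read_fraction)))
            noise_starts = rng.integers(0, max(chrom_len - rl, 1), size=n_noise)
            noise_strands = rng.choice(np.array(["+", "-"]), size=n_noise)
            for s, st in zip(noise_starts, noise_strands):
                s = int(s)
                # keep noise off exact fragment-end capture positions
                if st == "+" and s in start_set:
                    s += 1
                if st == "-" and s + rl in end_set:
                    s += 1
                reads.append(AlignedRead(chrom, s, s + rl, st))
        out[f"rep{rep + 1}"] = reads
    return out


def irxa_like_truth(seed: int, fragment_map: FragmentMap, viewpoint: ViewpointSpec,
                    contact_fold: float = 10.0, contact_fragments: int = 10,
                    contact_offset_fragments: int = 800,
                    differential: bool = False) -> SyntheticTruth:
    """Default study conditions: one planted 10-fold contact downstream of the
    viewpoint; optionally a second, control-only region for differential tests.

    The default offset places the contact where the baseline capture
    probability is low enough that the full fold is realized below the
    ``p_max`` cap (a fold planted inside the near-viewpoint saturation zone
    would be silently truncated).
    """
    frags = fragment_map.fragments[viewpoint.chrom]
    i0 = min(viewpoint.fragment_index + contact_offset_fragments,
             len(frags) - 1 - contact_fragments)
    i1 = min(i0 + contact_fragments, len(frags) - 1)
    enriched = [EnrichedRegion(viewpoint.chrom, frags[i0].start, frags[i1].start,
                               contact_fold)]
    if differential:
        j0 = max(viewpoint.fragment_index - contact_offset_fragments - contact_fragments, 0)
        j1 = j0 + contact_fragments
        enriched.append(EnrichedRegion(viewpoint.chrom, frags[j0].start, frags[j1].start,
                                       contact_fold, conditions=("control",)))
    return SyntheticTruth(seed=seed, enriched=enriched)


# ---------------------------------------------------------------------------
# gene/feature fixtures


@dataclass
class GeneFixture:
    """Gene table, feature interval sets, signal track, and the planted parameters."""

    genes: pd.DataFrame
    enhancers: IntervalSet
    ctcf_peaks: IntervalSet
    track: SignalTrack
    params: Dict[str, float]


def _planted_feature(rng: np.random.Generator, tss: int, scale: float,
                     width: int, chrom_length: int) -> Tuple[int, int]:
    """Interval whose nearest occupied base lies at ~Exp(scale) bp from the TSS."""
    d = int(round(rng.exponential(scale)))
    if rng.random() < 0.5:
        start = tss + d
    else:
        start = tss - d - (width - 1)
    start = max(0, min(start, chrom_length - width))
    return start, start + width


def make_gene_fixture(
    seed: int,
    n_per_class: int = 200,
    enhancer_effect: float = 4.0,
    ctcf_effect_up: float = 2.0,
    ctcf_effect_down: float = 2.0,
    distance_scale: float = 20_000.0,
    n_chroms: int = 4,
    chrom_length: int = 50_000_000,
    enhancer_width: int = 500,
    peak_width: int = 200,
    bump_height: float = 5.0,
    bump_sd: float = 300.0,
    track_half_width: int = 2_500,
    track_bin: int = 25,
) -> GeneFixture:
    """Gene classes with planted TSS-to-feature distance effects plus a signal track.

    Down-class genes get enhancers at exponential distances with scale
    ``distance_scale / enhancer_effect`` (closer for effect > 1); up- and
    down-class genes get CTCF peaks closer by their own effects; all other
    classes use the base scale.  The ChIP-like track is a sum of Gaussian
    bumps at CTCF peak centers on a per-chromosome baseline, materialized
    as bedGraph-style segments around each TSS.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    rng = np.random.default_rng([seed, _STREAM_GENES])
    classes = ("up", "down", "unchanged_expressed", "not_expressed")
    margin = 200_000
    records = []
    enh, ctcf = [], []
    for cls in classes:
        enh_scale = distance_scale / enhancer_effect if cls == "down" else distance_scale
        if cls == "up":
            ctcf_scale = distance_scale / ctcf_effect_up
        elif cls == "down":
            ctcf_scale = distance_scale / ctcf_effect_down
        else:
            ctcf_scale = distance_scale
        for i in range(n_per_class):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            tss = int(rng.integers(margin, chrom_length - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append({"gene": f"{cls}_{i}", "chrom": chrom, "tss": tss,
                            "strand": strand, "cls": cls})
            enh.append((chrom, *_planted_feature(rng, tss, enh_scale,
                                                 enhancer_width, chrom_length)))
            ctcf.append((chrom, *_planted_feature(rng, tss, ctcf_scale,
                                                  peak_width, chrom_length)))
    genes = pd.DataFrame.from_records(records)
    enhancers = IntervalSet(enh, name="enhancers")
    ctcf_peaks = IntervalSet(ctcf, name="ctcf_peaks")

    track_rng = np.random.default_rng([seed, _STREAM_TRACK])
    baselines = {f"chr{i + 1}": float(track_rng.normal(1.0, 0.3)) for i in range(n_chroms)}
    segments = []
    peak_centers: Dict[str, np.ndarray] = {}
    for chrom, starts_ends in ctcf_peaks._raw.items():
        peak_centers[chrom] = (starts_ends[:, 0] + starts_ends[:, 1]) / 2.0
    regions = IntervalSet(
        ((g.chrom, max(0, g.tss - track_half_width),
          min(chrom_length, g.tss + track_half_width)) for g in genes.itertuples()),
        name="track_regions",
    ).merged()
    for chrom, start, end in regions:
        edges = np.arange(start, end, track_bin)
        centers = edges + track_bin / 2.0
        vals = np.full(len(edges), baselines.get(chrom, 1.0))
        pc = peak_centers.get(chrom)
        if pc is not None:
            near = pc[(pc >= start - 4 * bump_sd) & (pc < end + 4 * bump_sd)]
            if len(near):
                diff = centers[:, None] - near[None, :]
                vals = vals + bump_height * np.exp(-0.5 * (diff / bump_sd) ** 2).sum(axis=1)
        segments.extend(
            (chrom, int(e), int(min(e + track_bin, end)), float(v))
            for e, v in zip(edges, vals)
        )
    track = SignalTrack(segments, name="ctcf_signal")
    params = {
        "seed": seed, "n_per_class": n_per_class,
        "enhancer_effect": enhancer_effect, "ctcf_effect_up": ctcf_effect_up,
        "ctcf_effect_down": ctcf_effect_down, "distance_scale": distance_scale,
        "n_chroms": n_chroms, "chrom_length": chrom_length,
    }
    return GeneFixture(genes=genes, enhancers=enhancers, ctcf_peaks=ctcf_peaks,
                       track=track, params=params)
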