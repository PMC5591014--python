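"""End-to-end orchestration: simulate (or load) inputs, then run every stage.

``run_pipeline`` executes the stages in dependency order into a run
directory and writes a manifest (input hashes, every parameter, seed,
versions, per-stage record counts).  Identical config and inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .capture_profile import CaptureProfile, call_captured_ends, windowize
from .config import PipelineConfig
from .contact_stats import score_contacts
from .differential_contacts import group_stats, nb_test, normalize_regional
from .feature_proximity import (
    BASELINE_CLASS, EXPRESSED_CLASSES, mann_whitney, meta_profile,
    nearest_distance, permutation_null, window_frequency,
)
from .fragment_map import CutterScheme, FragmentMap
from . import io as cio
from .synthetic_data import (
    SyntheticTruth, irxa_like_truth, make_genome, make_gene_fixture,
    simulate_4c, viewpoint_at,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "mutant")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate_inputs(config: PipelineConfig, outdir: Path) -> Dict[str, object]:
    """Materialize the default synthetic preset into ``outdir`` (FASTA, SAM, manifest)."""
    seed = config.require_seed()
    scheme = CutterScheme(config.primary_site, config.secondary_site)
    sequence, sites = make_genome(seed, length=config.genome_length,
                                  scheme=scheme)
    cio.write_fasta({"chr1": sequence}, outdir / "genome.fa")
    fmap = FragmentMap.from_sequences({"chr1": sequence}, scheme)
    viewpoint = viewpoint_at(fmap, "chr1", len(sequence) // 2,
                             name="vp", exclusion_radius=config.exclusion_radius)
    truth = irxa_like_truth(seed, fmap, viewpoint, differential=True)
    read_paths: Dict[str, List[Path]] = {}
    for condition in CONDITIONS:
        reads = simulate_4c(truth, fmap, viewpoint,
                            n_replicates=config.n_replicates, condition=condition)
        read_paths[condition] = []
        for rep, rep_reads in reads.items():
            path = outdir / f"reads_{condition}_{rep}.sam"
            cio.write_sam(rep_reads, fmap.chrom_lengths, path)
            read_paths[condition].append(path)
    cio.write_manifest(truth.manifest(), outdir / "truth.txt")
    return {"fmap": fmap, "viewpoint": viewpoint, "truth": truth,
            "read_paths": read_paths, "fasta": outdir / "genome.fa",
            "n_sites": {k: len(v) for k, v in sites.items()}}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run simulate -> digest -> capture -> contacts -> differential -> proximity -> profile.

    Returns the path of the run manifest.  Any stage error aborts the run
    with the stage named in the log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.require_seed()
    counts: Dict[str, int] = {}

    for cond, paths in config.reads.items():
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input reads not found before any stage ran: {p}")
    for p in filter(None, [config.fasta, config.genes, config.signal_track]):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found before any stage ran: {p}")

    logger.info("stage simulate")
    sim = simulate_inputs(config, outdir)
    fmap: FragmentMap = sim["fmap"]
    viewpoint = sim["viewpoint"]

    logger.info("stage digest")
    fmap.write_bed(outdir / "fragments.bed")
    counts["fragments"] = sum(len(f) for f in fmap.fragments.values())

    logger.info("stage capture")
    profiles: Dict[str, List[CaptureProfile]] = {}
    for condition, paths in sim["read_paths"].items():
        profiles[condition] = []
        for path in paths:
            reads = cio.read_alignments(path)
            counts[f"reads_{path.stem}"] = len(reads)
            calls = call_captured_ends(reads, fmap)
            prof = windowize(calls, fmap, viewpoint,
                             replicate=f"{condition}_{path.stem.rsplit('_', 1)[-1]}",
                             window_size=config.window_size, step=config.window_step)
            profiles[condition].append(prof)
            _write_tsv(prof.windows, outdir / f"windows_{prof.replicate}.tsv")
            with open(outdir / f"windows_{prof.replicate}.bedgraph", "w") as fh:
                for line in prof.to_bedgraph_records():
                    fh.write(line + "\n")

    logger.info("stage contacts")
    for condition, reps in profiles.items():
        calls = score_contacts(reps, z_threshold=config.z_threshold,
                               q_threshold=config.q_threshold)
        _write_tsv(calls.table, outdir / f"contacts_{condition}.tsv")
        sig = calls.significant_windows()
        z_cols = [c for c in sig.columns if c.startswith("z_")]
        cio.write_bed(zip(sig["chrom"], sig["start"].astype(int), sig["end"].astype(int)),
                      outdir / f"contacts_{condition}_significant.bed",
                      names=[f"win{int(w)}" for w in sig["window"]],
                      scores=sig[z_cols].min(axis=1).to_numpy())
        counts[f"significant_{condition}"] = int(sig.shape[0])

    logger.info("stage differential")
    normalized = normalize_regional(profiles, center=viewpoint.position,
                                    span=config.normalization_span_bp)
    contrast = nb_test(normalized)
    _write_tsv(contrast.table, outdir / "differential.tsv")
    counts["differential_windows"] = int(contrast.table.shape[0])

    logger.info("stage proximity")
    fixture = make_gene_fixture(seed, n_per_class=config.gene_n_per_class)
    cio.write_gene_table(fixture.genes, outdir / "genes.tsv")
    cio.write_bed(iter(fixture.enhancers), outdir / "enhancers.bed")
    cio.write_bed(iter(fixture.ctcf_peaks), outdir / "ctcf_peaks.bed")
    cio.write_bedgraph(fixture.track, outdir / "ctcf_signal.bedgraph")
    genes = fixture.genes
    dist_rows = genes.copy()
    for feats in (fixture.ctcf_peaks, fixture.enhancers):
        dist_rows[f"dist_{feats.name}"] = nearest_distance(genes, feats)
    _write_tsv(dist_rows, outdir / "distances.tsv")
    summary = []
    for feats in (fixture.ctcf_peaks, fixture.enhancers):
        freq = window_frequency(genes, feats, windows=config.proximity_windows)
        freq.insert(0, "features", feats.name)
        summary.append(freq)
    _write_tsv(pd.concat(summary, ignore_index=True), outdir / "window_frequency.tsv")

    pool = genes[genes["cls"].isin(EXPRESSED_CLASSES)].reset_index(drop=True)
    down = genes[genes["cls"] == "down"].reset_index(drop=True)
    unchanged = genes[genes["cls"] == BASELINE_CLASS]
    d_enh = fixture.enhancers

    def mean_dist(df: pd.DataFrame) -> float:
        return float(np.nanmean(nearest_distance(df, d_enh)))

    perm = permutation_null(mean_dist, down, pool, n_draws=config.permutations,
                            seed=seed)
    _, mw_p = mann_whitney(nearest_distance(down, d_enh).dropna(),
                           nearest_distance(unchanged, d_enh).dropna())
    _write_tsv(pd.DataFrame([{
        "class": "down", "features": "enhancers", "statistic": "mean_nearest_distance",
        "observed": perm.observed, "null_mean": perm.null_mean, "null_sd": perm.null_sd,
        "n_draws": perm.n_draws, "p_lower": perm.p_lower, "p_upper": perm.p_upper,
        "mann_whitney_p_vs_unchanged": mw_p,
    }]), outdir / "proximity_tests.tsv")

    logger.info("stage profile")
    prof = meta_profile(genes, fixture.track, half_width=config.profile_half_width,
                        bin_width=config.profile_bin, smooth_bins=config.smooth_bins)
    curves = pd.DataFrame({"position": prof.positions})
    for cls, curve in sorted(prof.profiles.items()):
        curves[cls] = curve
    _write_tsv(curves, outdir / "meta_profile.tsv")

    logger.info("stage manifest")
    manifest = {f"param.{k}": repr(v) for k, v in config.to_dict().items()}
    manifest["version"] = __version__
    manifest["seed"] = str(seed)
    for key, val in counts.items():
        manifest[f"count.{key}"] = str(val)
    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.txt" and path.is_file():
            manifest[f"sha256.{path.name}"] = _sha256(path)
    cio.write_manifest(manifest, outdir / "manifest.txt")
    return outdir / "manifest.txt"
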