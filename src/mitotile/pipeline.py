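"""End-to-end driver: simulate -> design -> normalize -> call -> TU -> ORF.

Runs the whole analysis on a synthetic scenario with known truth and
writes every stage's outputs (FASTA, GFF3, TSV) plus a summary report
and a provenance log.  Each stage aborts with its name and cause on
error, so a failed run always says where it died.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as mio
from .config import PipelineConfig
from .expression import call_expression, select_background, transcribed_fraction
from .normalize import normalize_pipeline
from .orfs import intersect_tus_orfs, label_iorfs, six_frame_orfs
from .probes import mask_duplications, remap_probes, tile_probes
from .simulate import simulate_experiment, simulate_genome, simulate_truth
from .tu import call_tus, classify_tus, compare_tissues, region_summary

log = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - rewrapped with stage name
                raise StageFailure(name, e) from e

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute every stage in order; returns the summary report dict."""
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    genome = _simulate_stage(config)
    nr_map, probes = _design_stage(config, genome)
    truths = _truth_stage(config, genome)
    matrix = _intensity_stage(config, probes, truths)
    track = _normalize_stage(matrix)
    tracks = _calling_stage(config, track, genome, nr_map)

    report = {"parameters": asdict(config), "tissues": {}}
    tu_sets = {}
    for tissue, etrack in tracks.items():
        frac = transcribed_fraction(etrack, nr_map)
        tus = classify_tus(
            call_tus(etrack, min_run=config.min_run,
                     gap_tolerance=config.gap_tolerance),
            genome.features,
        )
        tu_sets[tissue] = tus
        hk = genome.features_of("housekeeping")
        hk_covered = (
            sum(any(t.overlap_bp_interval(f.start, f.end) for t in tus) for f in hk)
            / len(hk)
            if hk
            else 1.0
        )
        report["tissues"][tissue] = {
            "transcribed_fraction": frac,
            "n_tus": len(tus),
            "n_intergenic_tus": sum(t.tu_class == "inter_genic" for t in tus),
            "housekeeping_covered_fraction": hk_covered,
        }

    tissues = list(tracks)
    if len(tissues) >= 2:
        a, b = tissues[0], tissues[1]
        cmp = compare_tissues(tu_sets[a], tu_sets[b],
                              min_overlap=config.min_overlap,
                              mode=config.containment_mode)
        report["containment"] = {
            "reference": a, "query": b,
            "fraction_contained": cmp["fraction_contained"],
            "contained": cmp["contained"], "n_query_tus": cmp["n_b"],
        }

    orfs = _orf_stage(config, genome)
    first = tissues[0]
    inter = intersect_tus_orfs(tu_sets[first], orfs)
    report["orfs"] = {
        "n_orfs": len(orfs),
        "n_iorfs": sum(o.category == "iorf" for o in orfs),
        "n_known_gene_frames": sum(o.category == "known_gene_frame" for o in orfs),
        "intergenic_tus_with_iorf": inter["tus_with_orf"],
        "iorfs_inside_tu": inter["iorfs_in_tu"],
    }

    if write_outputs:
        _write_stage(config, out, genome, truths, matrix, tu_sets, orfs, report)
    return report


@_stage("simulate_genome")
def _simulate_stage(config):
    return simulate_genome(
        length=config.genome_length,
        n_housekeeping=config.n_housekeeping,
        n_iorf=config.n_iorf,
        n_te=config.n_te,
        duplication_lengths=tuple(config.duplication_lengths),
        background_regions=config.background_regions,
        seed=config.seed,
    )


@_stage("probe_design")
def _design_stage(config, genome):
    nr_map = mask_duplications(genome, min_len=config.min_dup_length)
    probes = tile_probes(
        nr_map, genome, probe_length=config.probe_length, step=config.step,
        circular=config.circular,
    )
    return nr_map, remap_probes(probes)


@_stage("simulate_truth")
def _truth_stage(config, genome):
    return simulate_truth(
        genome,
        [(t, float(f), float(e)) for t, f, e in config.tissue_profiles],
        nested=config.nested,
        seed=config.seed,
        baseline_signal=config.baseline_signal,
        noise_sd=config.noise_sd,
        typical_interval_bp=config.typical_interval_bp,
    )


@_stage("simulate_intensities")
def _intensity_stage(config, probes, truths):
    return simulate_experiment(probes, truths, seed=config.seed)


@_stage("normalization")
def _normalize_stage(matrix):
    return normalize_pipeline(matrix)


@_stage("expression_calling")
def _calling_stage(config, track, genome, nr_map):
    pool = select_background(track, genome.features, nr_map)
    return call_expression(
        track, pool, window_size=config.window_size, alpha=config.alpha,
        convention=config.assignment,
    )


@_stage("orf_prediction")
def _orf_stage(config, genome):
    orfs = six_frame_orfs(genome, min_aa=config.min_aa, mode=config.orf_mode)
    return label_iorfs(orfs, genome.features)


@_stage("write_outputs")
def _write_stage(config, out, genome, truths, matrix, tu_sets, orfs, report):
    mio.write_fasta(genome, out / "genome.fa")
    mio.write_gff3(genome.features, out / "features.gff3", genome.id, len(genome))
    for truth in truths:
        feats = [
            _truth_feature(truth.tissue, i, s, e)
            for i, (s, e, _) in enumerate(truth.intervals, 1)
        ]
        mio.write_gff3(feats, out / f"truth_{truth.tissue}.gff3", genome.id,
                       len(genome), ftype="transcribed_region")
    matrix.write_tsv(out / "intensities.tsv")
    for tissue, tus in tu_sets.items():
        mio.write_gff3(tus, out / f"tus_{tissue}.gff3", genome.id, len(genome),
                       ftype="transcriptional_unit")
    mio.write_gff3(orfs, out / "orfs.gff3", genome.id, len(genome), ftype="ORF")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    mio.write_provenance(out / "report.json", "pipeline", **asdict(config))


def _truth_feature(tissue, i, s, e):
    from .genome import Feature

    return Feature(id=f"{tissue}_truth_{i}", start=s, end=e, strand=".",
                   category="iorf", attributes={"tissue": tissue})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


__all__ = ["run_pipeline", "StageFailure", "PipelineConfig"]
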