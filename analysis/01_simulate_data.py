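#!/usr/bin/env python
"""Simulate the two-tissue tiling-array scenario.

Generates a 100-kb circular genome (housekeeping genes, iORF regions,
TE fragments, two untranscribed background controls), a nested
transcription truth (48.5% of the genome transcribed in calli, 32.0%
in seedlings, every seedling interval inside a calli interval, effect
size 3 noise-sd), tiles 60-mer probes at 2-bp steps on both strands,
and draws noisy intensities.  Everything downstream reads these files.
"""

from pathlib import Path

from mitotile import io as mio
from mitotile.config import PipelineConfig
from mitotile.pipeline import _truth_feature
from mitotile.probes import identity_map, mask_duplications, tile_probes
from mitotile.simulate import simulate_experiment, simulate_genome, simulate_truth

OUT = Path("results/sim")
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=SEED)
    cfg.to_yaml(OUT / "config.yaml")

    genome = simulate_genome(
        length=cfg.genome_length, n_housekeeping=cfg.n_housekeeping,
        n_iorf=cfg.n_iorf, n_te=cfg.n_te, duplication_lengths=(),
        background_regions=cfg.background_regions, seed=cfg.seed,
    )
    truths = simulate_truth(
        genome, [(t, f, e) for t, f, e in cfg.tissue_profiles],
        nested=True, seed=cfg.seed, typical_interval_bp=cfg.typical_interval_bp,
    )
    probes = tile_probes(identity_map(genome), genome, circular=True)
    matrix = simulate_experiment(probes, truths, seed=cfg.seed)

    mio.write_fasta(genome, OUT / "genome.fa")
    mio.write_gff3(genome.features, OUT / "features.gff3", genome.id, len(genome))
    for truth in truths:
        feats = [_truth_feature(truth.tissue, i, s, e)
                 for i, (s, e, _) in enumerate(truth.intervals, 1)]
        mio.write_gff3(feats, OUT / f"truth_{truth.tissue}.gff3", genome.id,
                       len(genome), ftype="transcribed_region")
    matrix.write_tsv(OUT / "intensities.tsv")
    mio.write_provenance(OUT / "intensities.tsv", "simulate", seed=cfg.seed)

    assert mask_duplications(genome).nr_length == len(genome)
    for truth in truths:
        frac = truth.transcribed_bases / len(genome)
        print(f"{truth.tissue}: {len(truth.intervals)} transcribed intervals, "
              f"{frac:.1%} of the genome")
    print(f"{len(probes)} probes ({len(probes) // 2} per strand) -> {OUT}")


if __name__ == "__main__":
    main()
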