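#!/usr/bin/env python
"""Six-frame ORF prediction and TU-ORF intersection.

Predicts all >= 70-aa stop-to-stop ORFs on the circular genome, labels
inter-genic ORFs (iORF_<n>, numbering skips frames that overlap known
genes on the same strand), and counts how many inter-genic calli TUs
carry at least one fully contained iORF.
"""

import json
from pathlib import Path

from mitotile.io import read_fasta, read_gff3, write_gff3
from mitotile.orfs import intersect_tus_orfs, label_iorfs, six_frame_orfs
from mitotile.tu import TranscriptionalUnit

SIM = Path("results/sim")


def load_tus(tissue):
    tus = []
    for f in read_gff3(SIM / f"tus_{tissue}.gff3"):
        tus.append(TranscriptionalUnit(
            f.id, tissue, f.start, f.end,
            int(f.attributes.get("probe_count", 0)),
            float(f.attributes.get("min_p", "nan")), float("nan"),
            tu_class=f.attributes.get("feature_class", "unclassified"),
        ))
    return tus


def main():
    genome = read_fasta(SIM / "genome.fa")
    genome.circular = True
    features = read_gff3(SIM / "features.gff3")
    orfs = label_iorfs(six_frame_orfs(genome, min_aa=70), features)
    write_gff3(orfs, SIM / "orfs.gff3", genome.id, len(genome), ftype="ORF")
    with open(SIM / "orfs.faa", "w") as fh:
        for o in orfs:
            fh.write(f">{o.orf_id} frame={o.frame} {o.start}-{o.end}\n{o.protein}\n")

    n_iorf = sum(o.category == "iorf" for o in orfs)
    print(f"{len(orfs)} ORFs >= 70 aa in six frames; {n_iorf} iORFs, "
          f"{len(orfs) - n_iorf} known-gene frames (their numbers are skipped)")

    tus = load_tus("calli")
    rep = intersect_tus_orfs(tus, orfs, containment="full")
    print(f"{rep['tus_with_orf']} of {rep['n_intergenic_tus']} inter-genic "
          f"calli TUs carry >= 1 fully contained iORF; "
          f"{rep['iorfs_in_tu']} of {rep['n_iorfs']} iORFs sit inside a TU")
    (SIM / "tu_orf_intersection.json").write_text(
        json.dumps({k: v for k, v in rep.items() if k != "members"}, indent=2)
        + "\n"
    )


if __name__ == "__main__":
    main()
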