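#!/usr/bin/env python
"""Detect transcriptional units and compare the two tissues.

TUs are maximal runs of >= 20 consecutive significant probes; each is
classified gene-associated (>= 1 bp overlap with a housekeeping gene)
or inter-genic, and every seedling TU is checked for containment in a
calli TU — the nested-truth simulation predicts 100% containment.
"""

import json
from pathlib import Path

import numpy as np

from mitotile.expression import ExpressionTrack
from mitotile.io import read_gff3, write_gff3
from mitotile.tu import call_tus, classify_tus, compare_tissues

SIM = Path("results/sim")


def load_track(tissue):
    rows = np.loadtxt(SIM / f"expression_{tissue}.bedgraph.tsv", comments="#")
    return ExpressionTrack(
        tissue=tissue,
        positions=rows[:, 0].astype(int),
        p_values=10 ** (-rows[:, 2]),
        significant=rows[:, 3].astype(bool),
    )


def main():
    features = read_gff3(SIM / "features.gff3")
    tu_sets = {}
    for tissue in ("calli", "seedling"):
        tus = classify_tus(call_tus(load_track(tissue)), features)
        tu_sets[tissue] = tus
        write_gff3(tus, SIM / f"tus_{tissue}.gff3", "sim_mt", 100_000,
                   ftype="transcriptional_unit")
        n_inter = sum(t.tu_class == "inter_genic" for t in tus)
        print(f"{tissue}: {len(tus)} TUs ({n_inter} inter-genic, "
              f"{len(tus) - n_inter} gene-associated)")

    rep = compare_tissues(tu_sets["calli"], tu_sets["seedling"])
    print(f"seedling TUs contained in calli TUs: {rep['contained']}/{rep['n_b']} "
          f"({rep['fraction_contained']:.0%})")
    (SIM / "tu_comparison.json").write_text(
        json.dumps({k: v for k, v in rep.items() if k != "details"}, indent=2)
        + "\n"
    )


if __name__ == "__main__":
    main()
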