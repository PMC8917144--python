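#!/usr/bin/env python
"""Topology weighting over non-overlapping 4-gene supergene windows.

Counts, per dataset, how many windows are won by the introgression-like
group topology ((donorSB, Sb), (recipSB, outgroup)) versus the
trans-species-like ((donorSB, recipSB), (Sb, outgroup)).
"""

import argparse
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from _common import RESULTS, load_dataset, write_json

from sbkit import filtering as flt
from sbkit import genetrees as gt
from sbkit import topoweights as tw
from sbkit.seqs import encode

SCENARIOS = ["trans_species", "independent_origins", "introgression"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--window", type=int, default=4)
    args = ap.parse_args()

    out = {}
    for name in SCENARIOS:
        table, metadata, truth, layouts, ref, depth = load_dataset(args.seed, name)
        regions = [(l.chrom, l.start, l.end) for l in layouts]
        ftable = flt.apply_filter_cascade(table, depth, regions).table
        labels = {r["sample"]: (r["species"], r["variant"])
                  for _, r in metadata.iterrows()}
        sg_layouts = [l for l in layouts if l.in_supergene]
        by_gene = {}
        for lay in sg_layouts:
            gm = gt.GeneModel(lay.gene_id, lay.chrom, lay.start, lay.end,
                              in_supergene=True)
            by_gene[lay.gene_id] = gt.consensus_sequences(
                encode(ref[lay.chrom][lay.start:lay.end]), ftable, gm
            )
        windows = tw.make_windows(sg_layouts, args.window)
        group_map = {
            "donorSB": [s for s in ftable.samples
                        if labels[s][0] in ("inv", "mac") and labels[s][1] == "SB"],
            "recipSB": [s for s in ftable.samples
                        if labels[s][0] == "rich" and labels[s][1] == "SB"],
            "sb": [s for s in ftable.samples if labels[s][1] == "Sb"],
            "outgroup": [s for s in ftable.samples if labels[s][0] == "gem"],
        }
        rows = tw.weigh_windows(by_gene, windows, group_map, seed=args.seed)
        summary = tw.summarize_windows(rows)
        intro = "((donorSB,sb),(outgroup,recipSB))"
        trans = "((donorSB,recipSB),(outgroup,sb))"
        out[name] = {
            "counts": summary["counts"],
            "ties": summary["ties"],
            "n_windows": summary["n_windows"],
            "introgression_vs_trans_ratio": summary["ratios"].get(
                f"{intro} / {trans}"
            ),
        }
        print(
            f"{name}: {summary['counts']} over {summary['n_windows']} windows "
            f"(intro/trans ratio {out[name]['introgression_vs_trans_ratio']})"
        )
    write_json(RESULTS / "05_topology_weights.json", out)


if __name__ == "__main__":
    main()
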