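"""Shared plumbing for the numbered analysis drivers."""

import json
import pathlib

ROOT = pathlib.Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def dataset_dir(seed: int, scenario: str) -> pathlib.Path:
    return SCRATCH / "datasets" / f"{scenario}_seed{seed}"


def load_dataset(seed: int, scenario: str):
    """Parse a dataset written by 01_simulate_datasets.py back from disk."""
    import numpy as np
    import pandas as pd

    from sbkit.genotypes import read_vcf
    from sbkit.simdata import GeneLayout

    d = dataset_dir(seed, scenario)
    if not d.exists():
        raise SystemExit(
            f"{d} missing -- run analysis/01_simulate_datasets.py first"
        )
    table = read_vcf(d / "genotypes.vcf")
    metadata = pd.read_csv(d / "metadata.tsv", sep="\t")
    truth = json.loads((d / "truth.json").read_text())
    layouts = []
    for line in (d / "genes.gff3").read_text().splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
        layouts.append(
            GeneLayout(attrs["ID"], f[0], int(f[3]) - 1, int(f[4]),
                       attrs.get("in_supergene") == "1")
        )
    ref = {}
    chrom, buf = None, []
    for line in (d / "reference.fasta").read_text().splitlines():
        if line.startswith(">"):
            if chrom:
                ref[chrom] = "".join(buf)
            chrom, buf = line[1:].split()[0], []
        else:
            buf.append(line)
    if chrom:
        ref[chrom] = "".join(buf)
    depth = {}
    dp = pd.read_csv(d / "depth.tsv", sep="\t")
    for c, grp in dp.groupby("chrom"):
        arr = np.zeros(int(grp["pos"].max()))
        arr[grp["pos"].values - 1] = grp["mean_depth"].values
        depth[c] = arr
    return table, metadata, truth, layouts, ref, depth


def write_json(path: pathlib.Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
    print(f"wrote {path.relative_to(ROOT)}")
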