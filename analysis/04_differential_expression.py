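#!/usr/bin/env python
"""Differential expression across the four low-vs-normal nitrogen contrasts.

Median-of-ratios normalization, FPKM, and the moment-based NB Wald test
for NT/NS material x leaf/root contrasts.  DEGs are called at
|log2FC| >= 1 with FDR < 0.05 (the raw-p variant is also written), and
the four up/down sets are intersected in a Venn decomposition.  Reports
recovery of the planted DE genes and the sensitive/tolerant asymmetry.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import nitroscreen as ns
from nitroscreen.diffexpr import fpkm

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "deg"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = ROOT / "data"
    counts = pd.read_csv(data / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(data / "gene_lengths.tsv", sep="\t", index_col=0)["length_bp"]
    meta = pd.read_csv(data / "samples.csv", dtype={"nitrogen": str})

    sf = ns.size_factors(counts)
    sf.to_csv(OUT / "size_factors.tsv", sep="\t")
    expr = fpkm(counts, lengths)
    expr.to_csv(OUT / "fpkm.tsv", sep="\t")

    cfg = ns.SimulationConfig.from_yaml(str(data / "config.yaml"))
    truth = ns.SyntheticTruth()
    ns.simulate_counts(cfg, truth)  # regenerate planted DE labels

    sets, totals = {}, {"NT": 0, "NS": 0}
    for spec in ns.default_contrasts(meta):
        res = ns.nb_test(counts, spec)
        res.to_csv(OUT / f"de_{spec.name}.tsv", sep="\t")
        degs = ns.call_degs(res, lfc_min=1.0, alpha=0.05, use_fdr=True)
        degs_rawp = ns.call_degs(res, lfc_min=1.0, alpha=0.05, use_fdr=False)
        sets[spec.name] = degs["up"] | degs["down"]
        totals[spec.name[:2]] += len(sets[spec.name])
        for d in ("up", "down"):
            pd.Series(sorted(degs[d])).to_csv(OUT / f"{d}_{spec.name}.txt", index=False, header=False)
        planted = {g for g, _ in truth.de_genes.get(spec.name, [])}
        called = sets[spec.name]
        recall = len(called & planted) / len(planted) if planted else float("nan")
        print(f"{spec.name}: {len(degs['up'])} up / {len(degs['down'])} down (FDR) | "
              f"{len(degs_rawp['up'])} up / {len(degs_rawp['down'])} down (raw p) | "
              f"planted recall {100 * recall:.0f}%")

    if totals["NT"]:
        print(f"sensitive/tolerant total DEG ratio: {totals['NS'] / totals['NT']:.1f} "
              f"({totals['NS']} vs {totals['NT']})")

    v = ns.venn(sets)
    with open(OUT / "venn.json", "w") as fh:
        json.dump(
            {"regions": {"+".join(k): n for k, n in sorted(v["counts"].items())},
             "core": sorted(v["core"])},
            fh, indent=1,
        )
    print(f"four-way core intersection: {len(v['core'])} genes")


if __name__ == "__main__":
    main()
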