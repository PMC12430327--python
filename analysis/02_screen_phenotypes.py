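#!/usr/bin/env python
"""Screen the panel for low-nitrogen tolerance.

Computes the CV-weighted fuzzy-membership tolerance index from the
replicate phenotypes, clusters lines into tolerant / intermediate /
sensitive classes (Ward on the per-trait membership vectors), and writes
trait summaries, correlations and the two-way ANOVA table.  Reports how
well the classes recover the planted archetypes.
"""

from pathlib import Path

import pandas as pd

import nitroscreen as ns
from nitroscreen.phenotype import class_proportions, linkage_to_newick, read_phenotypes_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = read_phenotypes_csv(ROOT / "data" / "phenotypes.csv")
    m = ns.compute_membership(pheno)
    cls = ns.classify_tolerance(m, k=3)
    summary = ns.summarize_traits(pheno)

    table = m.P.copy()
    table["index"] = m.index
    table["class"] = cls.class_of
    table.to_csv(OUT / "membership.csv", index_label="line_id")
    pd.DataFrame({"CV_pct": m.CV, "weight": m.W}).to_csv(OUT / "trait_weights.csv", index_label="trait")
    (OUT / "dendrogram.nwk").write_text(linkage_to_newick(cls.linkage_tree, sorted(m.index.index)))
    summary.stats.to_csv(OUT / "trait_stats.tsv", sep="\t", index=False)
    summary.anova.to_csv(OUT / "anova.tsv", sep="\t", index=False)
    summary.correlations.to_csv(OUT / "correlations.tsv", sep="\t", index=False)

    sizes = cls.class_of.value_counts().to_dict()
    pct = class_proportions(sizes)
    print("tolerance classes:", sizes)
    print("percentages:", {k: round(v, 2) for k, v in pct.items()})
    print("class mean index:", cls.class_means.round(3).to_dict())

    cfg = ns.SimulationConfig.from_yaml(str(ROOT / "data" / "config.yaml"))
    _, _, truth = ns.simulate_genotypes(cfg)
    true = pd.Series(truth.tolerance_class).loc[cls.class_of.index]
    acc = (cls.class_of == true).mean()
    print(f"archetype recovery: {100 * acc:.1f}% of lines")
    ratios = summary.stats.drop_duplicates("trait").set_index("trait")["ratio_n1_over_n2"]
    print("low-N/normal-N trait ratios:", ratios.round(3).to_dict())


if __name__ == "__main__":
    main()
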