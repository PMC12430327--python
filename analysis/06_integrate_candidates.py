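#!/usr/bin/env python
"""Cross-omics candidate screen and qPCR validation.

Joins the three evidence routes — GWAS candidate windows, DEG calls (with
tolerant-specific upregulation tracked separately) and co-expression hubs
— into one evidence table, calls candidates under the default disjunctive
rule, checks hypergeometric enrichment of the candidate set for
module-derived annotation terms, and validates fold changes by 2^-ddCt
against the RNA-seq contrast.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import nitroscreen as ns
from nitroscreen.integration import DEFAULT_RULE

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "integration"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gwas_cand = pd.read_csv(ROOT / "gwas" / "candidates.tsv", sep="\t")
    hubs = pd.read_csv(ROOT / "network" / "hub_genes.tsv", sep="\t")

    deg_sets: dict[str, dict[str, set]] = {}
    for path in sorted((ROOT / "deg").glob("up_*.txt")):
        name = path.stem[3:]
        ser = pd.read_csv(path, header=None)[0] if path.stat().st_size else pd.Series(dtype=str)
        deg_sets.setdefault(name, {})["up"] = set(ser)
    for path in sorted((ROOT / "deg").glob("down_*.txt")):
        name = path.stem[5:]
        ser = pd.read_csv(path, header=None)[0] if path.stat().st_size else pd.Series(dtype=str)
        deg_sets.setdefault(name, {})["down"] = set(ser)

    evidence = ns.integrate(gwas_cand, deg_sets, hubs, rule=DEFAULT_RULE)
    evidence.to_csv(OUT / "evidence.tsv", sep="\t", index=False)
    candidates = evidence.loc[evidence["candidate"], "gene_id"].tolist()
    print(f"evidence table: {len(evidence)} genes with any support")
    print(f"candidates under rule '{DEFAULT_RULE}': {len(candidates)}")
    route_counts = evidence.loc[evidence["candidate"], ["gwas_candidate", "deg_any", "deg_up_in_tolerant", "wgcna_hub"]].sum()
    print("evidence routes among candidates:", route_counts.to_dict())

    # enrichment of candidates for module membership, used as a stand-in
    # annotation vocabulary (gene -> its module label)
    modules = pd.read_csv(ROOT / "network" / "modules.csv").set_index("gene")["module"]
    background = set(modules.index)
    gene2term = {g: {f"module:{m}"} for g, m in modules.items() if m != "grey"}
    geneset = set(candidates) & background
    if geneset:
        enr = ns.enrich(geneset, background, gene2term)
        enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
        top = enr.sort_values("p").iloc[0]
        print(f"top enriched term: {top['term']} (overlap {top['overlap']}/{top['term_size']}, "
              f"p = {top['p']:.2e}, FDR = {top['fdr']:.2e})")

    # qPCR validation against the tolerant-material root contrast
    data = ROOT / "data"
    cfg = ns.SimulationConfig.from_yaml(str(data / "config.yaml"))
    truth = ns.SyntheticTruth()
    ns.simulate_counts(cfg, truth)
    contrast = "NT-0.05R_vs_NT-4R"
    assay_genes = sorted(g for g, _ in truth.de_genes[contrast])[:8]
    qpcr = pd.read_csv(data / "qpcr_ct.csv")
    have = set(qpcr["gene"])
    assay_genes = [g for g in assay_genes if g in have]
    dres = ns.ddct(qpcr, control_condition="NN", reference_gene="Actin")
    dres.table.to_csv(OUT / "ddct.csv", index=False)
    de_res = pd.read_csv(ROOT / "deg" / f"de_{contrast}.tsv", sep="\t", index_col=0)
    rep = ns.concordance(dres, de_res, assay_genes, "LN")
    summary = {
        "n_candidates": len(candidates),
        "n_assayed": rep["n_shared"],
        "fraction_concordant": rep.get("fraction_concordant"),
        "pearson_r": rep.get("pearson_r"),
    }
    rep["per_gene"].to_csv(OUT / "qpcr_concordance.csv", index=False)
    with open(OUT / "concordance.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"qPCR vs RNA-seq over {rep['n_shared']} assayed genes: "
          f"{100 * rep.get('fraction_concordant', 0):.0f}% sign-concordant, "
          f"r = {rep.get('pearson_r', float('nan')):.2f}")


if __name__ == "__main__":
    main()
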