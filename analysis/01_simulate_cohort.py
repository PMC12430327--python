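#!/usr/bin/env python
"""Generate the synthetic study cohort every later stage analyses.

201 inbred lines in 3 subpopulations genotyped at 5,000 SNPs; six seedling
traits at two nitrogen levels x 3 replicates with planted
tolerant/intermediate/sensitive archetypes; RNA-seq counts for 24 samples
(2 materials x 2 tissues x 2 nitrogen levels x 3 replicates) with planted
co-expression modules and DEGs; qPCR Ct tables; and a gene annotation
sharing the RNA-seq identifier namespace.  Everything is a pure function
of the seed, so downstream scripts can regenerate ground truth.
"""

from pathlib import Path

import pandas as pd

import nitroscreen as ns
from nitroscreen import gwas as gw
from nitroscreen.synthetic import write_gff3

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ns.SimulationConfig(
        seed=SEED,
        n_lines=201,
        n_subpops=3,
        n_snps=5000,
        n_genes=2000,
        n_modules=5,
        n_de_genes=400,
        archetype_separation=0.10,
        heritability=0.9,
    )
    geno, Q, truth = ns.simulate_genotypes(cfg)
    pheno = ns.simulate_phenotypes(geno, truth, cfg)
    counts, lengths, meta = ns.simulate_counts(cfg, truth)
    annotation = ns.simulate_annotation(cfg, geno)
    # assay the first eight DE genes planted in the tolerant-root contrast,
    # the contrast the validation step compares against
    assay = sorted(g for g, _ in truth.de_genes["NT-0.05R_vs_NT-4R"])[:8]
    qpcr = ns.simulate_qpcr(truth, cfg, genes=assay)

    gw.write_vcf(geno, OUT / "genotypes.vcf")
    gw.write_dosage_tsv(geno, OUT / "dosages.tsv", OUT / "snp_map.tsv")
    pd.DataFrame(Q, index=geno.line_ids, columns=[f"P{k+1}" for k in range(cfg.n_subpops)]).to_csv(
        OUT / "structure.tsv", sep="\t", index_label="line_id"
    )
    pheno.to_csv(OUT / "phenotypes.csv", index=False)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    lengths.to_csv(OUT / "gene_lengths.tsv", sep="\t")
    meta.to_csv(OUT / "samples.csv", index=False)
    qpcr.to_csv(OUT / "qpcr_ct.csv", index=False)
    write_gff3(annotation, OUT / "annotation.gff3")
    truth.to_json(OUT / "truth.json")
    cfg.to_yaml(OUT / "config.yaml")

    classes = pd.Series(truth.tolerance_class).value_counts()
    print(f"cohort written to {OUT}")
    print(f"  {cfg.n_lines} lines x {geno.n_snps} SNPs, {cfg.n_genes} genes x {len(meta)} samples")
    print("  planted archetypes:", classes.to_dict())
    print(f"  planted DE genes per contrast:", {k: len(v) for k, v in truth.de_genes.items()})


if __name__ == "__main__":
    main()
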