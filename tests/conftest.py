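import warnings

import numpy as np
import pandas as pd
import pytest

import nitroscreen as ns

warnings.filterwarnings("ignore", message="dropping .* collinear structure")


@pytest.fixture(scope="session")
def small_cfg() -> ns.SimulationConfig:
    return ns.SimulationConfig(seed=11, n_lines=60, n_snps=400, n_genes=300, n_de_genes=40)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """A small simulated panel: genotypes, structure, truth, phenotypes."""
    geno, Q, truth = ns.simulate_genotypes(small_cfg)
    pheno = ns.simulate_phenotypes(geno, truth, small_cfg)
    return geno, Q, truth, pheno


@pytest.fixture(scope="session")
def count_cohort(small_cfg):
    truth = ns.SyntheticTruth()
    counts, lengths, meta = ns.simulate_counts(small_cfg, truth)
    return counts, lengths, meta, truth


@pytest.fixture()
def toy_pheno() -> pd.DataFrame:
    """3 lines x 2 traits built so the relative-value columns are
    (1.0, 0.6, 0.8) and (0.8, 0.4, 0.6)."""
    x = {"t1": [1.0, 0.6, 0.8], "t2": [0.8, 0.4, 0.6]}
    rows = []
    for i, line in enumerate(["A", "B", "C"]):
        for trait in ("t1", "t2"):
            for rep in (1, 2):
                rows.append((line, trait, "N2", rep, 10.0))
                rows.append((line, trait, "N1", rep, 10.0 * x[trait][i]))
    return pd.DataFrame(rows, columns=["line_id", "trait", "nitrogen_level", "replicate", "value"])


def make_geno(dosages, chroms=None, positions=None) -> ns.GenotypeMatrix:
    """Small helper to build a GenotypeMatrix from a dosage array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if chroms is None:
        chroms = ["chr1"] * m
    if positions is None:
        positions = []
        seen = {}
        for c in chroms:
            seen[c] = seen.get(c, 0) + 1000
            positions.append(seen[c])
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return ns.GenotypeMatrix(d, [f"L{i}" for i in range(n)], snp_map)
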