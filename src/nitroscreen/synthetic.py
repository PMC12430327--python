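"""Synthetic cohort generator for the low-nitrogen screening pipeline.

Emulates the study design every downstream stage assumes: 201 maize inbred
lines from three subpopulations genotyped at biallelic SNPs; six seedling
traits (lengths, fresh and dry weights) measured under low (N1, 0.05
mmol/L) and normal (N2, 4 mmol/L) nitrogen with three replicates and a
genotype-by-nitrogen interaction driven by tolerant/intermediate/sensitive
archetypes; negative-binomial RNA-seq counts for 8 genotype groups x 2
tissues x 2 nitrogen levels x 3 replicates with planted co-expression
modules and differential genes; and qPCR Ct tables with an Actin
reference.  Every generator is a pure function of its seed and emits
ground-truth labels for recovery tests.

Population model: Balding-Nichols drift of subpopulation allele
frequencies around an ancestral frequency, with near-pure ancestry rows
(a small admixture fraction keeps the structure matrix non-degenerate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gwas import GenotypeMatrix

TRAITS = (
    "seedling_length",
    "root_length",
    "shoot_fresh_weight",
    "root_fresh_weight",
    "shoot_dry_weight",
    "root_dry_weight",
)

# trait population means in cm / g at the four-leaf seedling stage
_BASE_MEANS = {
    "seedling_length": 30.0,
    "root_length": 25.0,
    "shoot_fresh_weight": 2.0,
    "root_fresh_weight": 1.5,
    "shoot_dry_weight": 0.30,
    "root_dry_weight": 0.20,
}

# low-N trait means as fractions of normal-N means (seedling length, root
# length, shoot/root fresh weight, shoot/root dry weight)
_DEFAULT_NITROGEN_EFFECT = (0.90, 0.93, 0.84, 0.89, 0.85, 0.93)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    # genotypes
    n_lines: int = 201
    n_subpops: int = 3
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.1
    admixture: float = 0.1
    n_chroms: int = 10
    # phenotypes
    n_causal_per_trait: int = 5
    heritability: float = 0.8
    nitrogen_effect: tuple[float, ...] = _DEFAULT_NITROGEN_EFFECT
    gxn_sd: float = 0.02
    archetype_fracs: tuple[float, float, float] = (0.10, 0.75, 0.15)
    archetype_separation: float = 0.08
    n_replicates: int = 3
    # RNA-seq counts
    n_genes: int = 2000
    n_modules: int = 5
    module_size_range: tuple[int, int] = (30, 60)
    nb_dispersion: float = 0.1
    n_de_genes: int = 100
    n_shared_de_genes: int = 4
    de_log2fc: float = 2.0
    sample_log2_sd: float = 0.25
    lib_size_sd: float = 0.1
    # qPCR
    ct_sd: float = 0.2
    ct_baseline: float = 20.0

    def __post_init__(self) -> None:
        counts = dict(
            n_lines=self.n_lines,
            n_subpops=self.n_subpops,
            n_snps=self.n_snps,
            n_causal_per_trait=self.n_causal_per_trait,
            n_genes=self.n_genes,
            n_modules=self.n_modules,
            n_de_genes=self.n_de_genes,
            n_replicates=self.n_replicates,
            n_chroms=self.n_chroms,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < min < max <= 0.5, got {self.maf_range}")
        if not 0 <= self.heritability <= 1:
            raise ConfigurationError(f"heritability must be in [0, 1], got {self.heritability}")
        if not 0 < self.fst < 1:
            raise ConfigurationError("fst must be in (0, 1)")
        if len(self.nitrogen_effect) != len(TRAITS):
            raise ConfigurationError("nitrogen_effect needs one entry per trait")
        if self.nb_dispersion < 0 or self.ct_sd < 0:
            raise ConfigurationError("dispersion and ct_sd must be nonnegative")
        lo, hi = self.module_size_range
        if not 2 <= lo <= hi:
            raise ConfigurationError("module_size_range must be an increasing pair of counts >= 2")

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maf_range", "nitrogen_effect", "archetype_fracs", "module_size_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    causal_snps: list[tuple[str, str, float]] = field(default_factory=list)  # (snp_id, trait, effect)
    tolerance_class: dict[str, str] = field(default_factory=dict)  # line -> class
    tolerance_multiplier: dict[str, float] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)  # gene -> module (0 = unassigned)
    de_genes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)  # contrast -> [(gene, dir)]
    true_fold_change: dict[str, float] = field(default_factory=dict)  # gene -> fold change (low/normal N)
    sample_factors: pd.DataFrame | None = None  # latent per-sample module factors

    def to_json(self, path: str) -> None:
        payload = {
            "causal_snps": self.causal_snps,
            "tolerance_class": self.tolerance_class,
            "tolerance_multiplier": self.tolerance_multiplier,
            "module_labels": self.module_labels,
            "de_genes": self.de_genes,
            "true_fold_change": self.true_fold_change,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=lambda o: o.item())


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray, SyntheticTruth]:
    """Structured biallelic genotypes plus ancestry matrix and truth labels.

    Subpopulation allele frequencies drift around an ancestral frequency
    (Beta with Balding-Nichols parameterization, drift = cfg.fst); lines
    split into equal-sized subpopulations with ancestry rows summing to 1.
    SNPs whose realized minor-allele frequency falls outside maf_range are
    redrawn so the emitted panel respects the configured spectrum.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_lines, cfg.n_snps, cfg.n_subpops
    lo, hi = cfg.maf_range

    # ancestry: equal blocks, optionally blended with a uniform Dirichlet
    own = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    Q = np.zeros((n, k))
    Q[np.arange(n), own] = 1.0
    if cfg.admixture > 0 and k > 1:
        Q = (1 - cfg.admixture) * Q + cfg.admixture * rng.dirichlet(np.ones(k), size=n)
    Q /= Q.sum(axis=1, keepdims=True)

    f = cfg.fst
    a_scale = (1 - f) / f

    def draw(n_snps: int) -> tuple[np.ndarray, np.ndarray]:
        p_anc = rng.uniform(lo, hi, size=n_snps)
        sub = rng.beta(p_anc * a_scale, (1 - p_anc) * a_scale, size=(k, n_snps))
        sub = np.clip(sub, 1e-4, 1 - 1e-4)
        line_freq = Q @ sub
        return rng.binomial(2, line_freq).astype(float), sub

    dosages, _ = draw(m)
    for _ in range(50):
        freq = dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        bad = (maf < lo) | (maf > hi)
        if not bad.any():
            break
        redraw, _ = draw(int(bad.sum()))
        dosages[:, bad] = redraw

    chrom_of = np.sort(rng.integers(0, cfg.n_chroms, size=m))
    pos = np.empty(m, dtype=int)
    for c in range(cfg.n_chroms):
        sel = chrom_of == c
        gaps = rng.integers(500, 50_000, size=sel.sum())
        pos[sel] = np.cumsum(gaps)
    alleles = rng.choice(["A", "C", "G", "T"], size=(m, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": pos,
            "ref": alleles[:, 0],
            "alt": alleles[:, 1],
        }
    )
    line_ids = [f"line{i:03d}" for i in range(n)]
    geno = GenotypeMatrix(dosages, line_ids, snp_map)

    truth = SyntheticTruth()
    # tolerance archetypes at fixed fractions (tolerant / intermediate / sensitive)
    fr = np.asarray(cfg.archetype_fracs, dtype=float)
    fr = fr / fr.sum()
    n_tol = int(round(fr[0] * n))
    n_sen = int(round(fr[2] * n))
    order = rng.permutation(n)
    classes = np.full(n, "intermediate", dtype=object)
    classes[order[:n_tol]] = "tolerant"
    classes[order[n_tol : n_tol + n_sen]] = "sensitive"
    truth.tolerance_class = dict(zip(line_ids, classes))

    # causal SNPs per trait, in trait units per alt-allele copy
    for t_idx, trait in enumerate(TRAITS):
        ids = rng.choice(m, size=min(cfg.n_causal_per_trait, m), replace=False)
        scale = 0.06 * _BASE_MEANS[trait]
        for j in ids:
            effect = float(rng.normal(0.0, scale))
            truth.causal_snps.append((snp_map["snp_id"].iloc[j], trait, effect))
    return geno, Q, truth


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    geno: GenotypeMatrix, truth: SyntheticTruth, cfg: SimulationConfig
) -> pd.DataFrame:
    """Long-format seedling phenotypes (line, trait, nitrogen_level, replicate, value).

    Normal-N replicate values are trait mean + causal-SNP effects +
    polygenic line effect + replicate noise scaled so the causal+polygenic
    share of line-mean variance equals cfg.heritability.  Low-N values are
    the same genetic value times the per-trait nitrogen effect times a
    line-specific tolerance multiplier (archetype offset +/-
    archetype_separation, jittered by gxn_sd).
    """
    if not 0 <= cfg.heritability <= 1:
        raise ConfigurationError("heritability must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1)
    n = geno.n_lines
    snp_index = {s: j for j, s in enumerate(geno.snp_map["snp_id"])}
    for snp_id, _, _ in truth.causal_snps:
        if snp_id not in snp_index:
            raise ValueError(f"causal SNP {snp_id} not present in genotype matrix")

    mult = np.ones(n)
    for i, line in enumerate(geno.line_ids):
        cls = truth.tolerance_class.get(line, "intermediate")
        if cls == "tolerant":
            mult[i] = 1.0 + cfg.archetype_separation
        elif cls == "sensitive":
            mult[i] = 1.0 - cfg.archetype_separation
    mult = mult + rng.normal(0.0, cfg.gxn_sd, size=n)
    truth.tolerance_multiplier = dict(zip(geno.line_ids, mult.astype(float)))

    rows = []
    for t_idx, trait in enumerate(TRAITS):
        mu = _BASE_MEANS[trait]
        g = np.zeros(n)
        for snp_id, tr, effect in truth.causal_snps:
            if tr == trait:
                g += effect * geno.dosages[:, snp_index[snp_id]]
        g -= g.mean()
        poly = rng.normal(0.0, 0.05 * mu, size=n)
        genetic = g + poly
        var_g = genetic.var()
        h2 = cfg.heritability
        if h2 >= 1.0:
            noise_sd = 0.0
        elif h2 <= 0.0:
            noise_sd = 10.0 * np.sqrt(var_g) if var_g > 0 else 0.1 * mu
        else:
            noise_sd = np.sqrt(var_g * (1 - h2) / h2)
        ne = cfg.nitrogen_effect[t_idx]
        base = np.clip(mu + genetic, 0.05 * mu, None)
        ratio = np.clip(ne * mult, 0.05, None)
        for rep in range(1, cfg.n_replicates + 1):
            eps2 = rng.normal(0.0, noise_sd, size=n)
            eps1 = rng.normal(0.0, noise_sd, size=n)
            v2 = np.clip(base + eps2, 0.0, None)
            v1 = np.clip(base * ratio + eps1, 0.0, None)
            for i, line in enumerate(geno.line_ids):
                rows.append((line, trait, "N2", rep, v2[i]))
                rows.append((line, trait, "N1", rep, v1[i]))
    return pd.DataFrame(rows, columns=["line_id", "trait", "nitrogen_level", "replicate", "value"])


# ---------------------------------------------------------------------------
# RNA-seq counts


def _sample_sheet(n_reps: int = 3) -> pd.DataFrame:
    rows = []
    for material in ("NT", "NS"):
        for nitrogen in ("0.05", "4"):
            for tissue in ("L", "R"):
                for rep in range(1, n_reps + 1):
                    rows.append(
                        {
                            "sample": f"{material}-{nitrogen}{tissue}-{rep}",
                            "material": material,
                            "tissue": tissue,
                            "nitrogen": nitrogen,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


DEFAULT_CONTRASTS = (
    ("NT-0.05L_vs_NT-4L", "NT", "L"),
    ("NS-0.05L_vs_NS-4L", "NS", "L"),
    ("NT-0.05R_vs_NT-4R", "NT", "R"),
    ("NS-0.05R_vs_NS-4R", "NS", "R"),
)


def simulate_counts(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial counts for 24 samples with planted modules and DEGs.

    Returns (counts genes x samples, gene lengths in bp, sample sheet).
    Genes in a module share a latent per-sample factor, inducing
    within-module correlation; DE genes shift their log2 mean by
    +/- cfg.de_log2fc between nitrogen levels within one material x tissue
    contrast.  Mirroring the study's asymmetry, sensitive-material (NS)
    contrasts carry three times as many planted DEGs as tolerant (NT)
    ones, and cfg.n_shared_de_genes core genes respond to low nitrogen in
    every contrast.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    meta = _sample_sheet(3)
    n_samples = len(meta)
    genes = [f"gene{g:05d}" for g in range(cfg.n_genes)]

    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    labels = np.zeros(cfg.n_genes, dtype=int)
    cursor = 0
    for mod, size in enumerate(sizes, start=1):
        size = min(size, cfg.n_genes - cursor)
        labels[cursor : cursor + size] = mod
        cursor += size
    truth.module_labels = {g: int(l) for g, l in zip(genes, labels)}

    base_log2 = rng.normal(5.0, 1.5, size=cfg.n_genes)
    # latent module factors, orthogonalized across samples so distinct
    # planted modules stay distinguishable at 24 samples
    factors = rng.normal(0.0, 1.0, size=(cfg.n_modules, n_samples))
    if cfg.n_modules <= n_samples:
        qmat, rmat = np.linalg.qr(factors.T)
        factors = (qmat * np.sign(np.diag(rmat))).T * np.sqrt(n_samples)
    truth.sample_factors = pd.DataFrame(
        factors.T, index=meta["sample"], columns=[f"module{m}" for m in range(1, cfg.n_modules + 1)]
    )
    loading = rng.uniform(0.7, 1.0, size=cfg.n_genes) * rng.choice([-1.0, 1.0], size=cfg.n_genes)

    log2_mu = np.tile(base_log2[:, None], (1, n_samples))
    for g in range(cfg.n_genes):
        if labels[g] > 0:
            log2_mu[g] += loading[g] * factors[labels[g] - 1]
    # mild residual sample wobble outside modules keeps profiles non-constant
    if cfg.sample_log2_sd > 0:
        log2_mu += rng.normal(0.0, cfg.sample_log2_sd, size=log2_mu.shape)

    # plant DE genes: unassigned genes only, split across the 4 contrasts
    # with the NS:NT asymmetry
    free = np.where(labels == 0)[0]
    weights = {"NT": 1, "NS": 3}
    total_w = sum(weights[m] for _, m, _ in DEFAULT_CONTRASTS)
    rng.shuffle(free)
    cursor = 0
    truth.de_genes = {}
    low_mask = (meta["nitrogen"] == "0.05").to_numpy()
    for name, material, tissue in DEFAULT_CONTRASTS:
        n_de = int(round(cfg.n_de_genes * weights[material] / total_w))
        chosen = free[cursor : cursor + n_de]
        cursor += n_de
        cols = ((meta["material"] == material) & (meta["tissue"] == tissue)).to_numpy()
        planted = []
        for g in chosen:
            direction = "up" if rng.random() < 0.5 else "down"
            shift = cfg.de_log2fc if direction == "up" else -cfg.de_log2fc
            log2_mu[g, cols & low_mask] += shift
            planted.append((genes[g], direction))
            truth.true_fold_change[genes[g]] = float(2.0**shift)
        truth.de_genes[name] = planted
    # core genes responding to low nitrogen in every material and tissue
    shared = free[cursor : cursor + cfg.n_shared_de_genes]
    for g in shared:
        direction = "up" if rng.random() < 0.5 else "down"
        shift = cfg.de_log2fc if direction == "up" else -cfg.de_log2fc
        log2_mu[g, low_mask] += shift
        truth.true_fold_change[genes[g]] = float(2.0**shift)
        for name, _, _ in DEFAULT_CONTRASTS:
            truth.de_genes[name].append((genes[g], direction))
    for g in genes:
        truth.true_fold_change.setdefault(g, 1.0)

    lib_factor = np.exp(rng.normal(0.0, cfg.lib_size_sd, size=n_samples)) if cfg.lib_size_sd > 0 else np.ones(n_samples)
    mu = (2.0**log2_mu) * lib_factor
    if cfg.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu * cfg.nb_dispersion)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample"].tolist())
    lengths = pd.Series(rng.integers(500, 5000, size=cfg.n_genes), index=genes, name="length_bp")
    return counts_df, lengths, meta


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    genes: list[str] | None = None,
    reference_gene: str = "Actin",
    n_bio: int = 3,
    n_tech: int = 3,
) -> pd.DataFrame:
    """Ct tables for assayed genes plus the reference, two conditions.

    Ct = baseline - log2(expression) + N(0, ct_sd) per well; the reference
    gene has fold change 1 by construction.  Conditions are "LN"
    (treatment, expression = true fold change) and "NN" (control,
    expression = 1).  Three biological x three technical replicates.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    if genes is None:
        genes = sorted(g for g, fc in truth.true_fold_change.items() if fc != 1.0)[:8]
    for g in genes:
        if g not in truth.true_fold_change:
            raise ValueError(f"no true fold change recorded for {g}")
    rows = []
    for gene in list(genes) + [reference_gene]:
        fc = truth.true_fold_change.get(gene, 1.0) if gene != reference_gene else 1.0
        for condition, expr in (("LN", fc), ("NN", 1.0)):
            ct_true = cfg.ct_baseline - np.log2(expr)
            for bio in range(1, n_bio + 1):
                for tech in range(1, n_tech + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": float(ct_true + rng.normal(0.0, cfg.ct_sd)),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene annotation


def simulate_annotation(cfg: SimulationConfig, geno: GenotypeMatrix) -> pd.DataFrame:
    """Gene models tiled over the simulated chromosomes.

    Gene identifiers match the RNA-seq count matrix so GWAS windows, DEG
    sets and network modules share one namespace.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    chroms = geno.snp_map.groupby("chrom", sort=False)["pos"].max()
    genes = [f"gene{g:05d}" for g in range(cfg.n_genes)]
    chrom_names = list(chroms.index)
    rows = []
    per_chrom = int(np.ceil(cfg.n_genes / len(chrom_names)))
    gi = 0
    for chrom in chrom_names:
        span = int(chroms[chrom])
        n_here = min(per_chrom, cfg.n_genes - gi)
        if n_here <= 0:
            break
        starts = np.sort(rng.integers(1, max(span, 10_000), size=n_here))
        for s in starts:
            length = int(rng.integers(1000, 8000))
            rows.append({"gene_id": genes[gi], "chrom": chrom, "start": int(s), "end": int(s) + length})
            gi += 1
    return pd.DataFrame(rows)


def write_gff3(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\tsynthetic\tgene\t{g['start']}\t{g['end']}\t.\t+\t.\tID={g['gene_id']}\n"
            )
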