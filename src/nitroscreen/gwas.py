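"""Association mapping for the inbred-line panel.

The scan follows the standard Q+K mixed linear model

    y = mu + Q alpha + x beta + u + e,   u ~ N(0, sg2 * K),  e ~ N(0, se2 * I)

with population-structure covariates Q as fixed effects and a polygenic
random effect whose covariance is proportional to a realized-relationship
kinship matrix K.  Variance components are estimated once by REML on the
null (no-SNP) model and held fixed across the scan (the P3D/EMMAX
approximation); each SNP is then tested by a generalized-least-squares
F test in the eigenspace of K.

Also provided: genotype QC, VanRaden kinship, pairwise LD (dosage r^2 and
EM-based D'), LD-decay curves, significance calling with Manhattan/QQ
plots, and candidate-gene window extraction against a gene annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as _qr
from scipy.optimize import minimize_scalar


class EmptyPanelError(ValueError):
    """All SNPs were removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix for a panel of inbred lines.

    dosages holds alt-allele counts in {0, 1, 2} as floats, with np.nan for
    missing calls (mean-imputed values appear after QC).  snp_map has one
    row per SNP: snp_id, chrom, pos (1-based bp), ref, alt; positions must
    be strictly increasing within each chromosome.
    """

    dosages: np.ndarray
    line_ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.snp_map)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snp_map)} SNPs"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        # imputed dosages are fractional; only check the raw range
        if not (np.nanmin(self.dosages, initial=0) >= 0 and np.nanmax(self.dosages, initial=0) <= 2):
            raise ValueError("dosages must lie in [0, 2]")
        del valid
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask],
            list(self.line_ids),
            self.snp_map.loc[mask].reset_index(drop=True),
        )


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_kept: int


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.20
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with MAF <= maf_min or missing fraction >= miss_max.

    Surviving missing dosages are imputed to the SNP mean, so downstream
    kinship and the scan operate on a complete matrix.  Idempotent.
    """
    maf = geno.maf()
    miss = geno.missing_rate()
    bad_maf = np.isnan(maf) | (maf <= maf_min)
    bad_miss = miss >= miss_max
    keep = ~(bad_maf | bad_miss)
    if not keep.any():
        raise EmptyPanelError("no SNPs survive QC")
    out = geno.subset_snps(keep)
    col_mean = np.nanmean(out.dosages, axis=0)
    idx = np.where(np.isnan(out.dosages))
    out.dosages[idx] = col_mean[idx[1]]
    report = QCReport(
        n_input=geno.n_snps,
        n_removed_maf=int(bad_maf.sum()),
        n_removed_missing=int((bad_miss & ~bad_maf).sum()),
        n_kept=out.n_snps,
    )
    return out, report


# ---------------------------------------------------------------------------
# kinship


def kinship(geno: GenotypeMatrix) -> np.ndarray:
    """Centered realized-relationship (VanRaden) kinship K = Z Z' / c.

    Z is the column-centered dosage matrix and c = sum_j 2 p_j (1 - p_j).
    Eigenvalues are clipped at zero so K is positive semidefinite.
    Requires complete (QC'd, imputed) genotypes.
    """
    d = geno.dosages
    if np.isnan(d).any():
        raise ValueError("kinship requires imputed genotypes (run qc_filter first)")
    p = d.mean(axis=0) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    z = d - 2.0 * p
    k = z @ z.T / c
    w, v = np.linalg.eigh((k + k.T) / 2.0)
    k = (v * np.clip(w, 0.0, None)) @ v.T
    return (k + k.T) / 2.0


# ---------------------------------------------------------------------------
# linkage disequilibrium


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies from unphased dosages.

    Returns (p11, p10, p01, p00) where the first index is the alt allele at
    locus 1.  Only double heterozygotes have ambiguous phase.
    """
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1 = g1[ok].astype(int)
    g2 = g2[ok].astype(int)
    n = len(g1)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    table = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        table[a, b] += 1
    p1 = g1.mean() / 2.0
    p2 = g2.mean() / 2.0
    # init at linkage equilibrium
    p = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    n_dh = table[1, 1]
    for _ in range(max_iter):
        # unambiguous haplotype counts
        c11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
        c10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
        c01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
        c00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
        if n_dh > 0:
            cis = p[0] * p[3]
            trans = p[1] * p[2]
            w = cis / (cis + trans) if cis + trans > 0 else 0.5
            c11 += n_dh * w
            c00 += n_dh * w
            c10 += n_dh * (1 - w)
            c01 += n_dh * (1 - w)
        new = np.array([c11, c10, c01, c00]) / (2.0 * n)
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p


def _dprime(hap: np.ndarray) -> float:
    p11, p10, p01, p00 = hap
    pa = p11 + p10
    pb = p11 + p01
    d = p11 - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0
    return float(min(abs(d) / dmax, 1.0))


@dataclass
class LDResult:
    pairs: pd.DataFrame  # snp1, snp2, dist_bp, r2, dprime
    decay: pd.DataFrame  # bin_lo, bin_hi, mean_r2, n_pairs
    decay_distance: float | None  # midpoint of first bin with mean r2 < threshold


def ld_stats(
    geno: GenotypeMatrix,
    max_dist_bp: int = 500_000,
    bins: int = 10,
    r2_threshold: float = 0.1,
) -> LDResult:
    """Pairwise LD within max_dist_bp on each chromosome.

    r^2 is the squared dosage correlation (composite genotypic LD, the
    standard for unphased chip data); D' comes from EM haplotype-frequency
    estimation.  The decay curve bins pair distances and reports the mean
    r^2 per bin; the decay distance is the midpoint of the first bin whose
    mean r^2 drops below r2_threshold.
    """
    rows = []
    for chrom, grp in geno.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than two SNPs, no LD pairs")
            continue
        pos = grp["pos"].to_numpy()
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                dist = pos[jj] - pos[ii]
                if dist > max_dist_bp:
                    break
                g1 = geno.dosages[:, idx[ii]]
                g2 = geno.dosages[:, idx[jj]]
                ok = ~(np.isnan(g1) | np.isnan(g2))
                if ok.sum() < 3 or np.std(g1[ok]) == 0 or np.std(g2[ok]) == 0:
                    continue
                r = np.corrcoef(g1[ok], g2[ok])[0, 1]
                hap = em_haplotype_freqs(g1, g2)
                rows.append(
                    {
                        "snp1": grp["snp_id"].iloc[ii],
                        "snp2": grp["snp_id"].iloc[jj],
                        "dist_bp": int(dist),
                        "r2": float(r * r),
                        "dprime": _dprime(hap),
                    }
                )
    pairs = pd.DataFrame(rows, columns=["snp1", "snp2", "dist_bp", "r2", "dprime"])
    if pairs.empty:
        return LDResult(pairs, pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"]), None)
    edges = np.linspace(0, max_dist_bp, bins + 1)
    which = np.clip(np.digitize(pairs["dist_bp"], edges) - 1, 0, bins - 1)
    decay_rows = []
    decay_distance = None
    for b in range(bins):
        sel = which == b
        if not sel.any():
            continue
        mean_r2 = float(pairs.loc[sel, "r2"].mean())
        decay_rows.append(
            {"bin_lo": edges[b], "bin_hi": edges[b + 1], "mean_r2": mean_r2, "n_pairs": int(sel.sum())}
        )
        if decay_distance is None and mean_r2 < r2_threshold:
            decay_distance = float((edges[b] + edges[b + 1]) / 2.0)
    return LDResult(pairs, pd.DataFrame(decay_rows), decay_distance)


# ---------------------------------------------------------------------------
# mixed linear model scan


@dataclass
class MixedModelFit:
    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, stat, p
    sigma_g2: float
    sigma_e2: float

    @property
    def lambda_ratio(self) -> float:
        """lambda = se2 / sg2, the residual-to-polygenic variance ratio."""
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf


def _design_with_structure(n: int, Q: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if Q is not None:
        Q = np.asarray(Q, dtype=float)
        X = np.hstack([X, Q])
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            # ancestry proportions sum to 1 and are collinear with the
            # intercept; drop trailing columns until full rank
            _, _, piv = _qr(X, mode="economic", pivoting=True)
            keep = np.sort(piv[:r])
            warnings.warn(
                f"dropping {X.shape[1] - r} collinear structure column(s) from the design"
            )
            X = X[:, keep]
    return X


def _reml_neg_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = s + delta
    w = 1.0 / d
    n, p = Xr.shape
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss = float(np.sum(r * r * w))
    if rss <= 0:
        return np.inf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.sum(np.log(d))
        + logdet_xwx
    )
    return -ll


def mlm_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    Q: np.ndarray | None = None,
    K: np.ndarray | None = None,
) -> MixedModelFit:
    """Q+K mixed-model association scan with null-model variance components.

    REML estimates sg2 and se2 once on the no-SNP model via the spectral
    decomposition of K, then every SNP is tested by a GLS F test in the
    rotated (whitened) space with those components held fixed.  With
    K = I and no Q this reduces exactly to per-SNP ordinary least squares.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = geno.n_lines
    if len(y) != n:
        raise ValueError("phenotype length does not match line count")
    if np.isnan(geno.dosages).any():
        raise ValueError("scan requires imputed genotypes (run qc_filter first)")
    if K is None:
        K = np.eye(n)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("K has wrong shape")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    X0 = _design_with_structure(n, Q)

    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6:
        raise ValueError("K is not positive semidefinite")
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    X0r = U.T @ X0

    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(g, s, yr, X0r) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(_reml_neg_loglik, bounds=(lo, hi), args=(s, yr, X0r), method="bounded")
    delta = float(np.exp(res.x))

    d = s + delta
    w = 1.0 / d
    p_cov = X0r.shape[1]
    XtWX = X0r.T @ (X0r * w[:, None])
    beta0 = np.linalg.solve(XtWX, X0r.T @ (yr * w))
    r0 = yr - X0r @ beta0
    sg2 = float(np.sum(r0 * r0 * w) / (n - p_cov))
    se2 = delta * sg2

    # whiten and residualize against covariates
    sw = np.sqrt(w)
    Aw = X0r * sw[:, None]
    yw = yr * sw
    Qa, _ = np.linalg.qr(Aw)
    y_t = yw - Qa @ (Qa.T @ yw)
    Gw = (U.T @ geno.dosages) * sw[:, None]
    G_t = Gw - Qa @ (Qa.T @ Gw)

    sxx = np.einsum("ij,ij->j", G_t, G_t)
    sxy = G_t.T @ y_t
    syy = float(y_t @ y_t)
    df = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 1e-12, sxy / sxx, 0.0)
        rss = syy - np.where(sxx > 1e-12, sxy**2 / sxx, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.where(sxx > 1e-12, sigma2 / sxx, np.inf))
        fstat = np.where(sxx > 1e-12, (beta / se) ** 2, 0.0)
    pvals = stats.f.sf(fstat, 1, df)
    pvals = np.where(sxx > 1e-12, pvals, 1.0)
    table = pd.DataFrame(
        {
            "snp_id": geno.snp_map["snp_id"].to_numpy(),
            "chrom": geno.snp_map["chrom"].to_numpy(),
            "pos": geno.snp_map["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "stat": fstat,
            "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
        }
    )
    return MixedModelFit(table=table, sigma_g2=sg2, sigma_e2=se2)


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2(1) ratio."""
    chi2 = stats.chi2.isf(np.asarray(pvalues, dtype=float), 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# significance calling and candidate windows


def call_hits(
    fit: MixedModelFit,
    p_max: float = 1e-5,
    trait: str | None = None,
    nitrogen_level: str | None = None,
    plot_prefix: str | None = None,
) -> pd.DataFrame:
    """SNPs at p <= p_max (boundary inclusive), annotated with trait/level.

    When plot_prefix is given, Manhattan and QQ plots are written to
    <prefix>_manhattan.png and <prefix>_qq.png.
    """
    hits = fit.table[fit.table["p"] <= p_max].copy()
    hits["trait"] = trait
    hits["nitrogen_level"] = nitrogen_level
    if plot_prefix is not None:
        manhattan_plot(fit, f"{plot_prefix}_manhattan.png", p_max=p_max)
        qq_plot(fit, f"{plot_prefix}_qq.png")
    return hits.reset_index(drop=True)


def manhattan_plot(fit: MixedModelFit, path: str, p_max: float = 1e-5) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = fit.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(tab.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p"]), s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    ax.axhline(-np.log10(p_max), color="red", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(fit: MixedModelFit, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(fit.table["p"].to_numpy())
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene features (gene_id, chrom, start, end) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        rows.append({"gene_id": gid, "chrom": gene.seqid, "start": gene.start, "end": gene.end})
    return pd.DataFrame(rows)


def candidate_genes(
    hits: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 500_000
) -> pd.DataFrame:
    """Genes intersecting the closed window [pos - w, pos + w] of each hit.

    Coordinates are 1-based closed (GFF3 convention); the window is
    truncated at position 1.  Each candidate carries its anchor SNP and the
    distance to it (0 when the gene interval contains the SNP).  Output
    order is independent of the annotation's record order.
    """
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    out = []
    gene_chroms = set(genes["chrom"].astype(str))
    for _, hit in hits.iterrows():
        chrom = str(hit["chrom"])
        if chrom not in gene_chroms:
            warnings.warn(f"hit {hit['snp_id']}: chromosome {chrom} absent from annotation; skipped")
            continue
        pos = int(hit["pos"])
        lo = max(1, pos - window_bp)
        hi = pos + window_bp
        sel = genes[(genes["chrom"].astype(str) == chrom) & (genes["end"] >= lo) & (genes["start"] <= hi)]
        for _, g in sel.iterrows():
            if g["start"] <= pos <= g["end"]:
                dist = 0
            else:
                dist = int(min(abs(g["start"] - pos), abs(g["end"] - pos)))
            out.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": chrom,
                    "start": int(g["start"]),
                    "end": int(g["end"]),
                    "distance_bp": dist,
                    "anchor_snp": hit["snp_id"],
                    "trait": hit.get("trait"),
                    "nitrogen_level": hit.get("nitrogen_level"),
                }
            )
    cols = ["gene_id", "chrom", "start", "end", "distance_bp", "anchor_snp", "trait", "nitrogen_level"]
    df = pd.DataFrame(out, columns=cols)
    return df.sort_values(["chrom", "start", "gene_id", "anchor_snp"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype I/O


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write unphased GT-only VCF (dosage 1 -> 0/1, missing -> ./.)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, grp in geno.snp_map.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.line_ids) + "\n")
        for j, row in geno.snp_map.iterrows():
            gts = [
                gt_map.get(geno.dosages[i, j], "./.") if not np.isnan(geno.dosages[i, j]) else "./."
                for i in range(geno.n_lines)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load a GT-only VCF into a dosage matrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        gt = var.gt_types.astype(float)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        dosage_cols.append(col)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else "N",
            }
        )
    return GenotypeMatrix(np.column_stack(dosage_cols), line_ids, pd.DataFrame(rows))


def write_dosage_tsv(geno: GenotypeMatrix, path: str, map_path: str | None = None) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.line_ids, columns=geno.snp_map["snp_id"])
    df.to_csv(path, sep="\t", index_label="line_id")
    if map_path is not None:
        geno.snp_map.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(path: str, map_path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line_id")
    snp_map = pd.read_csv(map_path, sep="\t")
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)), snp_map)
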