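"""Negative-binomial differential expression for small replicated designs.

Counts are normalized by median-of-ratios size factors, per-gene
dispersions are estimated by method-of-moments and shrunk 50/50 toward a
lowess mean-dispersion trend, and each gene is tested by a Wald statistic
on the log2 fold change with a delta-method standard error under the NB
variance function Var = mu + alpha * mu^2.  The statistic is referred to
the standard normal (the shrunken dispersion already stabilizes the
variance estimate at three replicates per group); p-values are
BH-adjusted across genes.  This is deliberately a transparent
moment-based construction, not a clone of the empirical-Bayes machinery
of the established DE packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Falls back to total-count scaling when no gene is nonzero in every
    sample.  Raises on an all-zero sample.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        logref = np.log(arr[allpos]).mean(axis=1)
        sf = np.exp(np.median(np.log(arr[allpos]) - logref[:, None], axis=0))
    else:
        tot = arr.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * library_size)."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("zero library size")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


@dataclass
class ContrastSpec:
    """Two disjoint sample groups; log2FC is group_a over group_b."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name}: groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.name}: each group needs >= 2 samples")


def default_contrasts(sample_meta: pd.DataFrame) -> list[ContrastSpec]:
    """The four low-vs-normal nitrogen contrasts per material x tissue."""
    specs = []
    for material in ("NT", "NS"):
        for tissue in ("L", "R"):
            sel = (sample_meta["material"] == material) & (sample_meta["tissue"] == tissue)
            a = sample_meta.loc[sel & (sample_meta["nitrogen"] == "0.05"), "sample"].tolist()
            b = sample_meta.loc[sel & (sample_meta["nitrogen"] == "4"), "sample"].tolist()
            specs.append(ContrastSpec(f"{material}-0.05{tissue}_vs_{material}-4{tissue}", a, b))
    return specs


def _moment_dispersion(y: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene pooled within-group moment estimate of NB dispersion.

    Returns (mean, raw alpha >= 0) using Var = mu + alpha mu^2 with the
    within-group sample variance pooled across both groups.
    """
    mus, var_num, var_den = [], 0.0, 0
    for idx in groups:
        sub = y[:, idx]
        mus.append(sub.mean(axis=1))
        var_num = var_num + sub.var(axis=1, ddof=1) * (len(idx) - 1)
        var_den += len(idx) - 1
    pooled_var = var_num / var_den
    mu = np.mean(mus, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / mu**2
    return mu, np.clip(np.nan_to_num(alpha), 0.0, None)


def _trend_dispersion(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Lowess trend of dispersion on mean expression (log-log)."""
    ok = mu > 0
    if ok.sum() < 10:
        return np.full_like(alpha, max(np.median(alpha[ok]) if ok.any() else 0.0, 1e-8))
    x = np.log(mu[ok])
    z = np.log(alpha[ok] + 1e-8)
    fit = lowess(z, x, frac=0.5, return_sorted=True)
    trend = np.interp(np.log(np.clip(mu, 1e-8, None)), fit[:, 0], fit[:, 1])
    return np.exp(trend) - 1e-8


def nb_test(
    counts: pd.DataFrame,
    contrast: ContrastSpec,
    sf: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of contrast.group_a vs contrast.group_b.

    Returns a DataFrame indexed by gene with base_mean, log2fc, se, stat,
    p and BH-adjusted fdr.  Genes with zero counts in every sample of the
    contrast are excluded before testing.
    """
    cols = contrast.group_a + contrast.group_b
    missing = [c for c in cols if c not in counts.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")
    sub = counts[cols]
    sub = sub.loc[sub.sum(axis=1) > 0]
    if sf is None:
        sf = size_factors(sub)
    else:
        sf = sf.reindex(cols)
    y = sub.to_numpy(dtype=float) / sf.to_numpy()
    ia = np.arange(len(contrast.group_a))
    ib = np.arange(len(contrast.group_a), len(cols))
    na, nb = len(ia), len(ib)

    mu, alpha_raw = _moment_dispersion(y, [ia, ib])
    alpha_trend = _trend_dispersion(mu, alpha_raw)
    alpha = 0.5 * alpha_raw + 0.5 * np.clip(alpha_trend, 0.0, None)

    ma = y[:, ia].mean(axis=1)
    mb = y[:, ib].mean(axis=1)
    # moderate means with a small prior count so zero groups stay finite
    ma_m = ma + prior_count
    mb_m = mb + prior_count
    log2fc = np.log2(ma_m / mb_m)

    inv_s = 1.0 / sf.to_numpy()
    sum_inv_a = inv_s[ia].sum()
    sum_inv_b = inv_s[ib].sum()
    var_ma = (ma_m * sum_inv_a + alpha * ma_m**2 * na) / na**2
    var_mb = (mb_m * sum_inv_b + alpha * mb_m**2 * nb) / nb**2
    se = np.sqrt(var_ma / ma_m**2 + var_mb / mb_m**2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "base_mean": (ma + mb) / 2.0,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "fdr": fdr,
        },
        index=sub.index,
    )


def call_degs(
    res: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05, use_fdr: bool = True
) -> dict[str, set[str]]:
    """Up/down DEG sets at |log2FC| >= lfc_min and p (or FDR) < alpha.

    The fold-change boundary is inclusive; the significance column is FDR
    by default with raw p available (the two published threshold variants).
    """
    sig = res["fdr"] < alpha if use_fdr else res["p"] < alpha
    up = set(res.index[(res["log2fc"] >= lfc_min) & sig])
    down = set(res.index[(res["log2fc"] <= -lfc_min) & sig])
    return {"up": up, "down": down}


def venn(sets: dict[str, set]) -> dict:
    """Exclusive region counts and the core intersection of named sets.

    Regions are keyed by the sorted tuple of member set names; only the
    2^n - 1 nonempty membership patterns are reported (15 for four sets).
    """
    names = list(sets)
    universe = set().union(*sets.values()) if sets else set()
    counts: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], set] = {}
    for item in universe:
        pattern = tuple(sorted(n for n in names if item in sets[n]))
        counts[pattern] = counts.get(pattern, 0) + 1
        members.setdefault(pattern, set()).add(item)
    core = set.intersection(*sets.values()) if sets else set()
    return {"counts": counts, "members": members, "core": core}
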