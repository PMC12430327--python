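"""Weighted gene co-expression network construction and module detection.

The network is built from scratch: adjacency a_ij = |cor(x_i, x_j)|^beta
(unsigned default; the signed variant uses ((1 + cor)/2)^beta), the
topological overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{j != i} a_ij and TOM_ii = 1, average-linkage
hierarchical clustering of 1 - TOM, and a static-height tree cut (the
"tree" variant of dynamic cutting: cut at a fixed height, 0.99 by
default, and discard clusters below the minimum module size to grey).
Eigengenes are the first principal component of the standardized module
submatrix, sign-fixed against the module mean profile; modules whose
eigengene dissimilarity falls below the merge height are merged
iteratively.  Soft-threshold selection follows the scale-free fit
criterion (signed R^2 of the log-log binned degree distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class NetworkConfig:
    soft_power: int = 12
    signed: bool = False
    min_module_size: int = 30
    merge_height: float = 0.6
    fpkm_min: float = 1.0
    scale_free_r2_target: float = 0.8
    cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.merge_height < 1:
            raise ValueError("merge_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def filter_expressed(expr: pd.DataFrame, floor: float = 1.0, mode: str = "any") -> pd.DataFrame:
    """Drop low-expression genes from a genes x samples FPKM matrix.

    mode="any" (default) removes a gene only when it is below the floor in
    every sample; mode="all" keeps only genes at or above the floor in
    every sample (the strict reading).
    """
    if mode == "any":
        keep = (expr >= floor).any(axis=1)
    elif mode == "all":
        keep = (expr >= floor).all(axis=1)
    else:
        raise ValueError("mode must be 'any' or 'all'")
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("no genes survive the expression filter")
    return out


def _correlation(expr: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant-expression gene(s)")
        arr = arr[~constant]
    genes = expr.index[~constant]
    if len(genes) < 2:
        raise ValueError("need at least two non-constant genes")
    cor = np.corrcoef(arr)
    return np.clip(cor, -1.0, 1.0), genes


def adjacency(expr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency with zero diagonal."""
    cor, genes = _correlation(expr)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def tom(expr: pd.DataFrame, cfg: NetworkConfig) -> pd.DataFrame:
    """Topological overlap matrix (diagonal defined as 1)."""
    adj = adjacency(expr, cfg.soft_power, cfg.signed)
    return tom_from_adjacency(adj)


def tom_from_adjacency(adj: pd.DataFrame) -> pd.DataFrame:
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=0)
    shared = a @ a  # a_ii = 0, so u = i, j terms vanish
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (shared + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates: range = range(1, 21),
    target_r2: float = 0.8,
    signed: bool = False,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Scale-free fit index and mean connectivity for candidate powers.

    The fit index is the signed R^2 (negative when the log-log slope is
    positive) of the regression of log10 p(k) on log10 k over occupied
    connectivity bins.  The chosen power is the smallest whose fit meets
    target_r2, falling back to the argmax of the fit column.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to pick a soft threshold")
    cor, _ = _correlation(expr)
    base = ((1.0 + cor) / 2.0) if signed else np.abs(cor)
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidates:
        a = base**beta
        k = a.sum(axis=0)
        rows.append({"power": beta, "fit_r2": _scale_free_fit(k, n_bins), "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table["fit_r2"].notna() & (table["fit_r2"] >= target_r2)
    if ok.any():
        beta = int(table.loc[ok, "power"].iloc[0])
    elif table["fit_r2"].notna().any():
        beta = int(table.loc[table["fit_r2"].idxmax(), "power"])
    else:
        beta = int(table["power"].iloc[-1])
        warnings.warn("scale-free fit undefined for all powers; using the largest candidate")
    return beta, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    if np.allclose(k, k[0]):
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 2:
        return np.nan
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


@dataclass
class ModuleSet:
    color_of: pd.Series  # gene -> module color or "grey"
    eigengenes: pd.DataFrame  # samples x modules, unit variance
    linkage_tree: np.ndarray
    cut_height: float

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def module_genes(self, module: str) -> list[str]:
        return sorted(self.color_of.index[self.color_of == module])


def _eigengene(expr_block: pd.DataFrame) -> pd.Series:
    """First PC sample scores of the standardized block, sign-fixed."""
    z = expr_block.to_numpy(dtype=float)
    z = (z - z.mean(axis=1, keepdims=True)) / np.where(z.std(axis=1, keepdims=True) == 0, 1, z.std(axis=1, keepdims=True))
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_profile = z.mean(axis=0)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    return pd.Series(pc, index=expr_block.columns)


def detect_modules(tom_df: pd.DataFrame, expr: pd.DataFrame, cfg: NetworkConfig) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static-height cut.

    Clusters smaller than min_module_size become grey; eigengenes are
    computed per module and modules with eigengene dissimilarity
    (1 - cor) below merge_height are merged until stable.
    """
    genes = tom_df.index
    expr = expr.loc[genes]
    dist = 1.0 - tom_df.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = float(cfg.cut_height)
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= cfg.min_module_size]
    # name modules by descending size with the conventional color sequence
    keep.sort(key=lambda c: (-sizes[c], c))
    color_map = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(keep)}
    colors = pd.Series(
        [color_map.get(c, "grey") for c in raw], index=genes, name="module", dtype=object
    )

    colors = _merge_close_modules(colors, expr, cfg.merge_height)
    eig = _eigengene_frame(colors, expr)
    return ModuleSet(color_of=colors, eigengenes=eig, linkage_tree=Z, cut_height=cut)


def _eigengene_frame(colors: pd.Series, expr: pd.DataFrame) -> pd.DataFrame:
    mods = [m for m in colors.unique() if m != "grey"]
    mods.sort(key=lambda m: (-int((colors == m).sum()), m))
    data = {m: _eigengene(expr.loc[colors.index[colors == m]]) for m in mods}
    return pd.DataFrame(data, index=expr.columns)


def _merge_close_modules(colors: pd.Series, expr: pd.DataFrame, merge_height: float) -> pd.Series:
    while True:
        eig = _eigengene_frame(colors, expr)
        mods = list(eig.columns)
        if len(mods) < 2:
            return colors
        cor = np.corrcoef(eig.to_numpy().T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            return colors
        big, small = mods[i], mods[j]
        if (colors == small).sum() > (colors == big).sum():
            big, small = small, big
        colors = colors.replace({small: big})


def module_membership(modset: ModuleSet, expr: pd.DataFrame) -> pd.DataFrame:
    """MM: correlation of each gene's profile with every module eigengene."""
    genes = modset.color_of.index
    z = expr.loc[genes].to_numpy(dtype=float)
    out = {}
    for m in modset.modules:
        e = modset.eigengenes[m].to_numpy()
        out[m] = [np.corrcoef(row, e)[0, 1] if row.std() > 0 else np.nan for row in z]
    return pd.DataFrame(out, index=genes)


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """GS: absolute correlation of each gene with a sample trait."""
    t = trait.reindex(expr.columns).to_numpy(dtype=float)
    vals = []
    for _, row in expr.iterrows():
        r = row.to_numpy(dtype=float)
        vals.append(abs(np.corrcoef(r, t)[0, 1]) if r.std() > 0 and t.std() > 0 else np.nan)
    return pd.Series(vals, index=expr.index, name="GS")


@dataclass
class ModuleTraitCorr:
    r: pd.DataFrame  # module x trait Pearson r
    p: pd.DataFrame  # module x trait two-sided p


def module_trait(modset: ModuleSet, traits: pd.DataFrame) -> ModuleTraitCorr:
    """Pearson correlation of each module eigengene with each sample trait.

    Constant traits yield NaN entries (reported as missing).
    """
    traits = traits.reindex(modset.eigengenes.index)
    if traits.isna().any().any():
        raise ValueError("sample trait table does not align with expression samples")
    r = pd.DataFrame(index=modset.modules, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=modset.modules, columns=traits.columns, dtype=float)
    for m in modset.modules:
        e = modset.eigengenes[m].to_numpy()
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(e) == 0:
                continue
            rr, pp = stats.pearsonr(e, tv)
            r.loc[m, t] = rr
            p.loc[m, t] = pp
    return ModuleTraitCorr(r=r, p=p)


def hub_genes(
    modset: ModuleSet,
    tom_df: pd.DataFrame,
    module: str,
    weight_min: float = 0.2,
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intramodular hubs by connectivity over TOM edges above weight_min.

    Returns (ranked hub table, retained edge list).  Ties in connectivity
    break by gene id.
    """
    if module not in modset.modules:
        raise ValueError(f"unknown module: {module}")
    genes = modset.module_genes(module)
    sub = tom_df.loc[genes, genes].to_numpy()
    edges = []
    conn = dict.fromkeys(genes, 0.0)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = sub[i, j]
            if w > weight_min:
                edges.append({"gene1": genes[i], "gene2": genes[j], "weight": float(w)})
                conn[genes[i]] += w
                conn[genes[j]] += w
    edge_df = pd.DataFrame(edges, columns=["gene1", "gene2", "weight"])
    if edge_df.empty:
        warnings.warn(f"module {module}: no edges above weight {weight_min}")
    hub_df = (
        pd.DataFrame({"gene": genes, "connectivity": [conn[g] for g in genes]})
        .sort_values(["connectivity", "gene"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    return hub_df, edge_df


def write_graphml(edges: pd.DataFrame, path: str) -> None:
    """Edge list as GraphML for network viewers."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["gene1"], e["gene2"], weight=float(e["weight"]))
    nx.write_graphml(g, path)
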