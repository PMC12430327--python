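"""Fuzzy-membership tolerance screening of germplasm panels.

For each line i and trait j the low-to-normal nitrogen response ratio is

    X_ij = mean(N1 value) / mean(N2 value)

standardized per trait by min-max to P_ij in [0, 1], weighted by the
trait's discriminating power W_j = CV_j / sum(CV) (CV computed on the X_ij
column, sample SD), and combined into the composite tolerance index

    P_i = sum_j P_ij * W_j in [0, 1];

higher P_i means stronger low-nitrogen tolerance.  Lines are then split
into tolerant / intermediate / sensitive classes by hierarchical
clustering (Ward linkage, Euclidean distance) of the per-trait membership
vectors, with classes labelled by descending class-mean index.  Trait
summaries (means, CV%, nitrogen ratio, two-way ANOVA, correlations) round
out the screening report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

REQUIRED_COLUMNS = ("line_id", "trait", "nitrogen_level", "replicate", "value")


class DegenerateTraitError(ValueError):
    pass


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if (pheno["value"] < 0).any():
        raise ValueError("phenotype values must be nonnegative")
    return pheno


def read_phenotypes_csv(path: str) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


@dataclass
class MembershipResult:
    X: pd.DataFrame  # lines x traits relative values X_ij
    P: pd.DataFrame  # lines x traits standardized values P_ij
    X_min: pd.Series
    X_max: pd.Series
    CV: pd.Series  # per-trait CV of the X column, percent
    W: pd.Series  # weights, sum to 1
    index: pd.Series  # composite tolerance index P_i per line


def compute_membership(
    pheno: pd.DataFrame,
    traits: list[str] | None = None,
    cv_on: str = "relative",
) -> MembershipResult:
    """Composite low-nitrogen tolerance index from a long phenotype table.

    Replicates are averaged per line x trait x nitrogen level before the
    ratio is taken.  cv_on selects whether trait weights use the CV of the
    relative values ("relative", default: weights measure discriminating
    power of the stress response) or of the raw normal-N trait ("raw").
    """
    validate_phenotypes(pheno)
    if traits is not None:
        pheno = pheno[pheno["trait"].isin(traits)]
        if pheno.empty:
            raise ValueError("no phenotype rows for requested traits")
    means = pheno.groupby(["line_id", "trait", "nitrogen_level"])["value"].mean().unstack("nitrogen_level")
    for level in ("N1", "N2"):
        if level not in means.columns:
            raise ValueError(f"nitrogen level {level} missing from phenotype table")
    zero = means["N2"] == 0
    if zero.any():
        line, trait = means.index[zero.argmax()]
        raise ZeroDivisionError(f"normal-nitrogen mean is zero for line {line}, trait {trait}")
    if means[["N1", "N2"]].isna().any().any():
        raise ValueError("every line must be measured at both nitrogen levels")
    X = (means["N1"] / means["N2"]).unstack("trait")
    x_min = X.min()
    x_max = X.max()
    degenerate = x_max - x_min <= 0
    if degenerate.any():
        raise DegenerateTraitError(
            f"constant relative-value column for trait(s): {list(X.columns[degenerate])}"
        )
    P = (X - x_min) / (x_max - x_min)
    if cv_on == "relative":
        cv = 100.0 * X.std(ddof=1) / X.mean()
    elif cv_on == "raw":
        raw = means["N2"].unstack("trait")
        cv = 100.0 * raw.std(ddof=1) / raw.mean()
    else:
        raise ValueError("cv_on must be 'relative' or 'raw'")
    W = cv / cv.sum()
    index = (P * W).sum(axis=1)
    return MembershipResult(X=X, P=P, X_min=x_min, X_max=x_max, CV=cv, W=W, index=index)


@dataclass
class ToleranceClassification:
    class_of: pd.Series  # line -> class label
    linkage_tree: np.ndarray  # scipy linkage matrix
    class_means: pd.Series  # class -> mean index
    leaf_order: list[str]


_CLASS_NAMES_3 = ("tolerant", "intermediate", "sensitive")


def classify_tolerance(
    m: MembershipResult, k: int = 3, on: str = "vector"
) -> ToleranceClassification:
    """Ward hierarchical clustering of lines cut at k classes.

    on="vector" clusters the per-trait membership rows P_i. (default);
    on="scalar" clusters the composite index P_i alone.  Classes are
    labelled tolerant / intermediate / sensitive (k = 3) by descending
    class-mean index.
    """
    lines = sorted(m.index.index)  # line order fixed by id for determinism
    if len(lines) < k:
        raise ValueError(f"need at least k={k} lines, got {len(lines)}")
    if np.isclose(m.index.std(ddof=0), 0.0):
        raise ValueError("tolerance index is constant; no meaningful partition")
    if on == "vector":
        data = m.P.loc[lines].to_numpy()
    elif on == "scalar":
        data = m.index.loc[lines].to_numpy()[:, None]
    else:
        raise ValueError("on must be 'vector' or 'scalar'")
    Z = hierarchy.linkage(data, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    idx = m.index.loc[lines]
    order = (
        pd.DataFrame({"cluster": raw, "index": idx.to_numpy()})
        .groupby("cluster")["index"]
        .mean()
        .sort_values(ascending=False)
    )
    if k == 3:
        names = dict(zip(order.index, _CLASS_NAMES_3))
    else:
        names = {c: f"class_{r + 1}" for r, c in enumerate(order.index)}
    labels = pd.Series([names[c] for c in raw], index=lines, name="class")
    class_means = labels.to_frame().join(idx.rename("index")).groupby("class")["index"].mean()
    leaves = hierarchy.leaves_list(Z)
    return ToleranceClassification(
        class_of=labels,
        linkage_tree=Z,
        class_means=class_means,
        leaf_order=[lines[i] for i in leaves],
    )


def class_proportions(class_sizes: dict[str, int]) -> pd.Series:
    """Percentage of the panel in each tolerance class."""
    total = sum(class_sizes.values())
    if total <= 0:
        raise ValueError("class sizes must sum to a positive count")
    return pd.Series({k: 100.0 * v / total for k, v in class_sizes.items()}, name="percent")


def classify_by_threshold(m: MembershipResult, tolerant_min: float, sensitive_max: float) -> pd.Series:
    """Alternative three-way split by fixed thresholds on the scalar index."""
    if not sensitive_max < tolerant_min:
        raise ValueError("sensitive_max must be below tolerant_min")
    idx = m.index
    out = pd.Series("intermediate", index=idx.index, name="class", dtype=object)
    out[idx >= tolerant_min] = "tolerant"
    out[idx <= sensitive_max] = "sensitive"
    return out


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# trait summaries


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class TraitSummary:
    stats: pd.DataFrame  # trait x level: mean, sd, cv_pct; plus ratio_n1_over_n2
    anova: pd.DataFrame  # trait: F and p for genotype, nitrogen, interaction
    correlations: pd.DataFrame  # (trait, level) pairs: r, p, stars


def summarize_traits(pheno: pd.DataFrame) -> TraitSummary:
    """Per-trait descriptive statistics, two-way fixed-effects ANOVA
    (genotype, nitrogen level, interaction) and Pearson correlations
    between line-mean trait values with two-sided t-test p and star codes.
    """
    validate_phenotypes(pheno)
    if pheno["line_id"].nunique() < 2 or pheno["nitrogen_level"].nunique() < 2:
        raise ValueError("ANOVA needs at least two genotypes and two nitrogen levels")
    rep_counts = pheno.groupby(["line_id", "trait", "nitrogen_level"])["value"].count()
    if (rep_counts < 2).any():
        raise ValueError("ANOVA needs >= 2 replicates per line x trait x level cell")

    rows = []
    for (trait, level), grp in pheno.groupby(["trait", "nitrogen_level"]):
        mean = grp["value"].mean()
        sd = grp["value"].std(ddof=1)
        rows.append(
            {"trait": trait, "nitrogen_level": level, "mean": mean, "sd": sd, "cv_pct": 100.0 * sd / mean}
        )
    stat_df = pd.DataFrame(rows)
    ratio = (
        stat_df.pivot(index="trait", columns="nitrogen_level", values="mean")
        .eval("N1 / N2")
        .rename("ratio_n1_over_n2")
    )
    stat_df = stat_df.merge(ratio, on="trait")

    anova_rows = []
    for trait, grp in pheno.groupby("trait"):
        tab = _two_way_anova(grp)
        tab["trait"] = trait
        anova_rows.append(tab)
    anova = pd.concat(anova_rows, ignore_index=True)

    means = (
        pheno.groupby(["line_id", "trait", "nitrogen_level"])["value"]
        .mean()
        .unstack(["trait", "nitrogen_level"])
    )
    cols = list(means.columns)
    corr_rows = []
    for a in range(len(cols)):
        for b in range(len(cols)):
            if a == b:
                r, p = 1.0, 0.0
            else:
                r, p = stats.pearsonr(means[cols[a]], means[cols[b]])
            corr_rows.append(
                {
                    "var1": f"{cols[a][1]}.{cols[a][0]}",
                    "var2": f"{cols[b][1]}.{cols[b][0]}",
                    "r": float(r),
                    "p": float(p),
                    "stars": significance_stars(float(p)),
                }
            )
    return TraitSummary(stats=stat_df, anova=anova, correlations=pd.DataFrame(corr_rows))


def _two_way_anova(grp: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA via statsmodels OLS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = grp.rename(columns={"line_id": "genotype", "nitrogen_level": "nitrogen"})
    model = smf.ols("value ~ C(genotype) * C(nitrogen)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = []
    mapping = {
        "C(genotype)": "genotype",
        "C(nitrogen)": "nitrogen",
        "C(genotype):C(nitrogen)": "interaction",
    }
    for key, name in mapping.items():
        out.append({"factor": name, "F": float(tab.loc[key, "F"]), "p": float(tab.loc[key, "PR(>F)"])})
    return pd.DataFrame(out)
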