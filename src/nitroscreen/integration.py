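"""Cross-omics candidate integration, qPCR relative quantification and
hypergeometric enrichment.

Candidates are called from an evidence table with one row per gene and
boolean flags for the three evidence routes — a GWAS candidate window, a
differential-expression call (with up-in-tolerant specificity tracked
separately), and co-expression hub status — combined by a configurable
boolean rule.  qPCR fold changes use the 2^-ddCt method against a
reference gene (amplification efficiency fixed at 2), and DEG/qPCR
concordance is summarized as sign agreement plus Pearson correlation of
the log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_RULE = "(gwas_candidate and deg_any) or wgcna_hub or deg_up_in_tolerant"

FLAG_COLUMNS = ("gwas_candidate", "deg_any", "deg_up_in_tolerant", "wgcna_hub")


def integrate(
    gwas_candidates: pd.DataFrame | list[str],
    deg_sets: dict[str, dict[str, set[str]]],
    hubs: pd.DataFrame | list[str],
    rule: str = DEFAULT_RULE,
    tolerant_prefix: str = "NT",
) -> pd.DataFrame:
    """Evidence table over the union of genes, with candidate calls.

    deg_sets maps contrast name -> {"up": set, "down": set}.  A gene is
    "up in tolerant" when it is upregulated in a tolerant-material
    contrast (name starting with tolerant_prefix) and not differentially
    expressed in any sensitive-material contrast.  The rule is a boolean
    expression over the flag names, evaluated per gene.
    """
    if isinstance(gwas_candidates, pd.DataFrame):
        gwas_map: dict[str, str] = {}
        for _, row in gwas_candidates.iterrows():
            gwas_map.setdefault(str(row["gene_id"]), str(row.get("anchor_snp", "")))
        gwas_genes = set(gwas_map)
    else:
        gwas_genes = set(map(str, gwas_candidates))
        gwas_map = dict.fromkeys(gwas_genes, "")
    if isinstance(hubs, pd.DataFrame):
        hub_map = {str(r["gene"]): str(r.get("module", "")) for _, r in hubs.iterrows()}
    else:
        hub_map = dict.fromkeys(map(str, hubs), "")
    hub_genes = set(hub_map)

    deg_any: dict[str, set[str]] = {}
    up_tol: set[str] = set()
    de_in_sensitive: set[str] = set()
    for name, sets_ in deg_sets.items():
        up = set(map(str, sets_.get("up", set())))
        down = set(map(str, sets_.get("down", set())))
        for g in up | down:
            deg_any.setdefault(g, set()).add(name)
        if name.startswith(tolerant_prefix):
            up_tol |= up
        else:
            de_in_sensitive |= up | down
    up_specific = up_tol - de_in_sensitive

    genes = sorted(gwas_genes | set(deg_any) | hub_genes)
    rows = []
    for g in genes:
        flags = {
            "gwas_candidate": g in gwas_genes,
            "deg_any": g in deg_any,
            "deg_up_in_tolerant": g in up_specific,
            "wgcna_hub": g in hub_genes,
        }
        try:
            candidate = bool(eval(rule, {"__builtins__": {}}, dict(flags)))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"cannot evaluate candidate rule {rule!r}: {exc}") from exc
        rows.append(
            {
                "gene_id": g,
                **flags,
                "candidate": candidate,
                "anchor_snp": gwas_map.get(g, ""),
                "contrasts": ";".join(sorted(deg_any.get(g, set()))),
                "module": hub_map.get(g, ""),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", *FLAG_COLUMNS, "candidate", "anchor_snp", "contrasts", "module"],
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification


@dataclass
class DdctResult:
    table: pd.DataFrame  # gene x condition: mean_ct, delta_ct, ddct, rq
    control_condition: str
    reference_gene: str


def ddct(q: pd.DataFrame, control_condition: str, reference_gene: str = "Actin") -> DdctResult:
    """2^-ddCt relative expression per gene and condition.

    Replicate Ct values are averaged per gene x condition before
    differencing; dCt = Ct_target - Ct_reference, ddCt relative to the
    control condition, RQ = 2^-ddCt (so the control RQ is 1 by
    construction).
    """
    required = {"gene", "condition", "ct"}
    if not required.issubset(q.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    mean_ct = q.groupby(["gene", "condition"])["ct"].mean().unstack("condition")
    if reference_gene not in mean_ct.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from qPCR table")
    if control_condition not in mean_ct.columns:
        raise ValueError(f"control condition {control_condition!r} missing")
    if mean_ct.loc[reference_gene].isna().any():
        raise ValueError("reference gene must have Ct in every condition")
    dct = mean_ct.sub(mean_ct.loc[reference_gene], axis=1)
    ddct_tab = dct.sub(dct[control_condition], axis=0)
    rq = 2.0 ** (-ddct_tab)
    rows = []
    for gene in mean_ct.index:
        for cond in mean_ct.columns:
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_ct": mean_ct.loc[gene, cond],
                    "delta_ct": dct.loc[gene, cond],
                    "ddct": ddct_tab.loc[gene, cond],
                    "rq": rq.loc[gene, cond],
                }
            )
    return DdctResult(pd.DataFrame(rows), control_condition, reference_gene)


def concordance(
    ddct_res: DdctResult,
    de_res: pd.DataFrame,
    genes: list[str],
    treat_condition: str,
) -> dict:
    """Sign agreement and correlation between qPCR and RNA-seq fold changes.

    Compares log2(RQ) in the treatment condition with the RNA-seq log2FC
    per gene; a pair is concordant when the signs agree (both zero
    counts as agreement).  Pearson r is reported when >= 2 genes are
    shared, otherwise omitted.
    """
    tab = ddct_res.table
    shared = [g for g in genes if g in set(tab["gene"]) and g in de_res.index]
    rows = []
    for g in shared:
        rq = tab.loc[(tab["gene"] == g) & (tab["condition"] == treat_condition), "rq"]
        if rq.empty:
            continue
        lfc_q = float(np.log2(rq.iloc[0]))
        lfc_r = float(de_res.loc[g, "log2fc"])
        agree = (lfc_q == 0 and lfc_r == 0) or (lfc_q * lfc_r > 0)
        rows.append({"gene": g, "qpcr_log2fc": lfc_q, "rnaseq_log2fc": lfc_r, "concordant": agree})
    per_gene = pd.DataFrame(rows)
    out = {"per_gene": per_gene, "n_shared": len(per_gene)}
    if len(per_gene) > 0:
        out["fraction_concordant"] = float(per_gene["concordant"].mean())
    if len(per_gene) >= 2:
        r, _ = stats.pearsonr(per_gene["qpcr_log2fc"], per_gene["rnaseq_log2fc"])
        out["pearson_r"] = float(r)
    return out


# ---------------------------------------------------------------------------
# enrichment


def enrich(
    geneset: set[str], background: set[str], gene2term: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric (upper-tail) enrichment per term, BH-adjusted.

    gene2term maps gene -> set of term identifiers; genes absent from the
    map simply carry no annotation.  The gene set must be a subset of the
    background.
    """
    geneset = set(geneset)
    background = set(background)
    stray = geneset - background
    if stray:
        raise ValueError(f"gene set members absent from background: {sorted(stray)[:5]}")
    term_members: dict[str, set[str]] = {}
    for g in background:
        for t in gene2term.get(g, ()):  # annotations outside background ignored
            term_members.setdefault(t, set()).add(g)
    M, n = len(background), len(geneset)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & geneset)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "expected": n * K / M,
                "p": min(max(p, 0.0), 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "expected", "p"])
    if not df.empty:
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df
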