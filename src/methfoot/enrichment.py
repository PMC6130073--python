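"""Fisher's-exact gene-set enrichment over a user-supplied term map.

One-sided over-representation p per term from the hypergeometric tail
P(X >= k) with K genes in the analysis set, m background genes carrying
the term and N background genes total; BH across terms.  A term is
significant only when it contains more than five analysis genes AND its
q-value is below 0.05 — both conditions exactly as the decision rule the
pipeline reproduces.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_GENES = 5  # strict: significant requires k > 5
Q_THRESHOLD = 0.05


def fisher_enrichment(
    gene_set: list[str] | set[str],
    background: list[str] | set[str],
    term_map: pd.DataFrame,
) -> pd.DataFrame:
    """Enrichment of `gene_set` against `background` for each term.

    term_map: DataFrame with columns gene, term and optionally term_name.
    Genes are de-duplicated per term before counting.
    """
    gene_set = set(gene_set)
    background = set(background)
    offenders = sorted(gene_set - background)
    if offenders:
        raise ValueError(f"genes absent from background: {offenders[:10]}")
    if "term_name" not in term_map.columns:
        term_map = term_map.assign(term_name=term_map["term"])
    big_n = len(background)
    big_k = len(gene_set)
    rows = []
    grouped = term_map[term_map["gene"].isin(background)].groupby("term")
    for term, sub in grouped:
        genes = set(sub["gene"])
        m = len(genes)
        k = len(genes & gene_set)
        if m == 0:
            continue
        # one-sided Fisher == hypergeometric upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, big_k))
        table = [[k, big_k - k], [m - k, big_n - big_k - (m - k)]]
        odds = stats.fisher_exact(table, alternative="greater")[0]
        rows.append(
            {
                "term": term,
                "term_name": sub["term_name"].iloc[0],
                "k": k,
                "K": big_k,
                "m": m,
                "N": big_n,
                "odds_ratio": float(odds),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not len(df):
        return df
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = (df["k"] > MIN_GENES) & (df["q"] < Q_THRESHOLD)
    return df.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
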