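"""Top-fraction outlier gene sets and Fisher's exact term enrichment.

The outlier sets are the top 5% of 1:1 ortholog genes ranked by a score
(clade length ratio or clade rate ratio).  Over-representation of a
GO/KEGG-style term in such a set relative to the full baseline universe
is tested with the one-sided Fisher's exact test (hypergeometric upper
tail); p-values are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "top_fraction",
    "fisher_enrichment",
    "adjust_pvalues",
    "read_annotation_map",
]


def top_fraction(scores: dict[str, float] | pd.Series, fraction: float = 0.05) -> list[str]:
    """The floor(fraction * n) genes with the highest scores.

    Boundary ties break to the lexicographically smaller gene id so the
    selection is deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    scores = pd.Series(scores, dtype=float)
    if scores.empty:
        raise ValueError("empty score table")
    k = math.floor(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:k]]


def read_annotation_map(source) -> pd.DataFrame:
    """TSV (gene_id, term_id[, term_name, category]) -> DataFrame."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    names = ["gene_id", "term_id", "term_name", "category"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    if "category" not in df.columns:
        df["category"] = "NA"
    return df


def fisher_enrichment(
    test: set[str],
    baseline: set[str],
    annotations: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test for every annotated term.

    For a term annotated in K of the N baseline genes with k hits in the
    n-gene test set, p = P[X >= k] with X hypergeometric(N, K, n) — the
    one-sided Fisher's exact test.  Returns one row per term with
    counts, raw p, and Benjamini-Hochberg adjusted p, sorted by adjusted
    then raw p.
    """
    if not test:
        raise ValueError("empty test set")
    if not test <= baseline:
        raise ValueError("test set must be a subset of the baseline universe")
    ann = annotations[annotations["gene_id"].isin(baseline)]
    n_total = len(baseline)
    n_test = len(test)
    rows = []
    for (term, name, cat), sub in ann.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        genes = set(sub["gene_id"])
        big_k = len(genes)
        k = len(genes & test)
        p = float(hypergeom.sf(k - 1, n_total, big_k, n_test))
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "category": cat,
                "k_test": k,
                "K_baseline": big_k,
                "n_test": n_test,
                "N_baseline": n_total,
                "p_raw": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "category",
            "k_test",
            "K_baseline",
            "n_test",
            "N_baseline",
            "p_raw",
        ],
    )
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = adjust_pvalues(out["p_raw"].tolist())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(
        ["p_adj", "p_raw", "term_id"], ignore_index=True
    )


def adjust_pvalues(pvalues: list[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg step-up adjustment (monotone, order-preserving)."""
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(pvalues, method=method)
    return [float(p) for p in adj]
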