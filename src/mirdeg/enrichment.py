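"""GO/KEGG over-representation with rich factor and BH-adjusted p-values.

For a query gene set of size n drawn from a universe of N annotated genes,
a term annotating K genes with k of them in the query is scored with the
hypergeometric upper tail p = P[X >= k], X ~ Hypergeom(N, K, n).  The rich
factor k / K measures the degree of enrichment.  The universe defaults to
all annotated genes in the map.  KEGG-style terms additionally roll up into
a top-level class distribution table (percentages over classified genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["term", "name", "namespace", "k", "K", "n", "N", "rich_factor", "p", "p_adj"]


def rich_factor(k: int, K: int) -> float:
    """Hits-in-query over genes-annotated-to-term."""
    if K == 0:
        raise ValueError("term annotates no genes")
    return k / K


def invert_annotation(annotation: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
    """gene -> terms map inverted to term -> genes."""
    out: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def hypergeom_enrich(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    term_info: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set, one row per term.

    ``annotation`` maps gene -> term ids; the universe defaults to all
    annotated genes.  Query genes outside the universe are ignored.  Terms
    with K = 0 inside the universe are skipped.  Results depend only on
    (N, K, n, k) and are sorted by p then term id.
    """
    by_term = invert_annotation(annotation)
    uni = set(universe) if universe is not None else set(annotation)
    q = set(query) & uni
    N, n = len(uni), len(q)
    rows = []
    for term in sorted(by_term):
        genes = by_term[term] & uni
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        name, ns = (term_info or {}).get(term, ("", ""))
        rows.append(
            {
                "term": term, "name": name, "namespace": ns,
                "k": k, "K": K, "n": n, "N": N,
                "rich_factor": rich_factor(k, K), "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df[RESULT_COLUMNS]


@dataclass
class ClassDistribution:
    table: pd.DataFrame
    n_classified: int
    n_unclassified: int


def kegg_class_distribution(
    genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    term_info: Mapping[str, tuple[str, str]],
    namespaces: Iterable[str] | None = None,
) -> ClassDistribution:
    """Percentage of genes per top-level class (plot-ready table).

    A gene counts once per class it maps to through its terms; percentages
    are over class assignments of classified genes and sum to 100 up to
    rounding.  Genes without any classified term are reported as a count.
    """
    keep = set(namespaces) if namespaces is not None else None
    counts: dict[str, int] = {}
    classified = unclassified = 0
    for gene in set(genes):
        classes = set()
        for term in annotation.get(gene, ()):
            info = term_info.get(term)
            if info is None:
                continue
            ns = info[1]
            if keep is None or ns in keep:
                classes.add(ns)
        if classes:
            classified += 1
            for c in classes:
                counts[c] = counts.get(c, 0) + 1
        else:
            unclassified += 1
    total = sum(counts.values())
    rows = [
        {"class": c, "genes": counts[c], "percent": 100.0 * counts[c] / total}
        for c in sorted(counts, key=lambda c: (-counts[c], c))
    ]
    return ClassDistribution(
        table=pd.DataFrame(rows, columns=["class", "genes", "percent"]),
        n_classified=classified,
        n_unclassified=unclassified,
    )
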