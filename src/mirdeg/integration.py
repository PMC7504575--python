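"""Three-layer evidence integration and antagonistic-module classification.

A regulatory pair enters the module tables only when all three sequencing
layers carry it: the miRNA has a differential-expression record (sRNA layer),
its target gene has one (transcriptome layer), and a degradome cleavage event
links the two.  A pair is *antagonistic* under a contrast when both members
are significant at raw p < alpha and their log2 fold-changes carry strictly
opposite signs — significantly up-regulated miRNA with down-regulated target
("miRNA-up/target-down") or the reverse ("miRNA-down/target-up").  Pairs with
same-signed significant changes are "concordant"; everything else is "ns".

The same classifier applies to genotype contrasts (tolerant vs sensitive per
treatment), where "up" means more abundant in the tolerant genotype.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .degradome import CleavageEvent

DEFAULT_ALPHA = 0.05

PATTERN_UP_DOWN = "miRNA-up/target-down"
PATTERN_DOWN_UP = "miRNA-down/target-up"

MODULE_COLUMNS = [
    "mirna", "gene", "transcript", "contrast", "mirna_log2fc", "mirna_p",
    "gene_log2fc", "gene_p", "category", "pattern", "pairing_type",
]

_ISOFORM_RE = re.compile(r"-\d+$")


def transcript_to_gene(transcript_id: str) -> str:
    """Strip a trailing isoform suffix ("-2", "-4", ...) from a transcript id."""
    return _ISOFORM_RE.sub("", transcript_id)


def classify_antagonistic(
    mirna_log2fc: float,
    mirna_p: float,
    gene_log2fc: float,
    gene_p: float,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Pattern label for one miRNA/target pair under one contrast.

    Requires both raw p-values < alpha and both fold-changes non-zero;
    +/-inf sentinels are valid signed fold-changes.  Returns one of
    'miRNA-up/target-down', 'miRNA-down/target-up', 'concordant', 'ns'.
    """
    for v in (mirna_log2fc, gene_log2fc):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "ns"
    if not (mirna_p < alpha and gene_p < alpha):
        return "ns"
    if mirna_log2fc == 0 or gene_log2fc == 0:
        return "ns"
    if mirna_log2fc > 0 and gene_log2fc < 0:
        return PATTERN_UP_DOWN
    if mirna_log2fc < 0 and gene_log2fc > 0:
        return PATTERN_DOWN_UP
    return "concordant"


@dataclass
class JoinAudit:
    """Per-layer dropout bookkeeping for the three-omics join."""

    n_events: int = 0
    n_pairs_evidenced: int = 0
    n_no_mirna_de: int = 0
    n_no_gene_de: int = 0
    n_quarantined: int = 0
    n_pairs_joined: int = 0


def join_evidence(
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    events: Iterable[CleavageEvent],
    alpha: float = DEFAULT_ALPHA,
    condition_matched: bool = False,
    gene_resolver=transcript_to_gene,
    known_pairs: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, JoinAudit]:
    """Join DE tables with degradome events into classified regulatory pairs.

    ``mirna_de`` / ``gene_de`` are DiffResult tables (columns feature,
    contrast, p, log2fc, ...); gene features are gene ids, so degradome
    transcript ids are resolved through ``gene_resolver``.  By default an
    event from any library qualifies a pair for every contrast; with
    ``condition_matched`` the event's library name must contain the
    contrast's stress level.  ``known_pairs`` (miRNA id, gene id) marks rows
    'conserved' vs 'newly discovered'.
    """
    audit = JoinAudit()
    best_events: dict[tuple[str, str], CleavageEvent] = {}
    libraries: dict[tuple[str, str], set[str]] = {}
    for e in events:
        audit.n_events += 1
        gene = gene_resolver(e.alignment.transcript_id)
        if gene is None:
            audit.n_quarantined += 1
            continue
        key = (e.alignment.mirna_id, gene)
        libraries.setdefault(key, set()).add(e.library_id)
        prev = best_events.get(key)
        if prev is None or e.category < prev.category or (
            e.category == prev.category and e.tpb > prev.tpb
        ):
            best_events[key] = e
    audit.n_pairs_evidenced = len(best_events)

    mirna_idx = mirna_de.set_index(["feature", "contrast"])
    gene_idx = gene_de.set_index(["feature", "contrast"])
    mirna_contrasts = mirna_de.groupby("feature")["contrast"].agg(set).to_dict()
    gene_contrasts = gene_de.groupby("feature")["contrast"].agg(set).to_dict()

    rows = []
    for (mid, gene), ev in sorted(best_events.items()):
        mcontr = mirna_contrasts.get(mid)
        gcontr = gene_contrasts.get(gene)
        if not mcontr:
            audit.n_no_mirna_de += 1
            continue
        if not gcontr:
            audit.n_no_gene_de += 1
            continue
        for contrast in sorted(mcontr & gcontr):
            if condition_matched:
                stress = str(contrast).split("_vs_")[0].split("|")[-1]
                if not any(stress in lib for lib in libraries[(mid, gene)]):
                    continue
            mrow = mirna_idx.loc[(mid, contrast)]
            grow = gene_idx.loc[(gene, contrast)]
            pattern = classify_antagonistic(
                mrow["log2fc"], mrow["p"], grow["log2fc"], grow["p"], alpha
            )
            rows.append(
                {
                    "mirna": mid,
                    "gene": gene,
                    "transcript": ev.alignment.transcript_id,
                    "contrast": contrast,
                    "mirna_log2fc": mrow["log2fc"],
                    "mirna_p": mrow["p"],
                    "gene_log2fc": grow["log2fc"],
                    "gene_p": grow["p"],
                    "category": ev.category,
                    "pattern": pattern,
                    "pairing_type": (
                        "conserved"
                        if known_pairs is not None and (mid, gene) in known_pairs
                        else "newly discovered"
                    ),
                }
            )
            audit.n_pairs_joined += 1
    return pd.DataFrame(rows, columns=MODULE_COLUMNS), audit


def antagonistic_modules(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rows with an antagonistic pattern (concordant and ns excluded)."""
    return pairs[pairs["pattern"].isin([PATTERN_UP_DOWN, PATTERN_DOWN_UP])].reset_index(drop=True)


def genotype_modules(pairs: pd.DataFrame, treatments: Iterable[str] | None = None) -> dict[str, pd.DataFrame]:
    """Antagonistic module table per treatment for genotype contrasts.

    Expects contrasts of the form ``TL_vs_SL|<treatment>`` (up = more
    abundant in the tolerant genotype).  Returns one table per treatment.
    """
    mods = antagonistic_modules(pairs)
    out: dict[str, pd.DataFrame] = {}
    contr = mods["contrast"].astype(str)
    found = sorted({c.split("|")[-1] for c in contr if "|" in c})
    for tr in treatments or found:
        out[tr] = mods[contr.str.endswith(f"|{tr}")].reset_index(drop=True)
    return out


def build_network(pairs: pd.DataFrame) -> nx.MultiDiGraph:
    """Multigraph of miRNA -> gene edges (one edge per contrast and pattern)."""
    g = nx.MultiDiGraph()
    for row in antagonistic_modules(pairs).itertuples():
        g.add_node(row.mirna, kind="miRNA")
        g.add_node(row.gene, kind="gene")
        g.add_edge(
            row.mirna, row.gene,
            pattern=row.pattern, contrast=row.contrast, category=row.category,
        )
    return g


def export_network(pairs: pd.DataFrame, sif_path=None, tsv_path=None) -> pd.DataFrame:
    """Write SIF and GraphML-compatible TSV edge lists; return the degree report.

    The degree report lists every node with its kind and (out- or in-) degree,
    exposing miRNAs targeting multiple mRNAs and mRNAs hit by several miRNAs.
    """
    g = build_network(pairs)
    edges = antagonistic_modules(pairs)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for row in edges.itertuples():
                fh.write(f"{row.mirna}\t{row.pattern}\t{row.gene}\n")
    if tsv_path is not None:
        edges[["mirna", "gene", "pattern", "contrast", "category"]].to_csv(
            tsv_path, sep="\t", index=False
        )
    rows = [
        {
            "node": n,
            "kind": g.nodes[n]["kind"],
            "degree": g.out_degree(n) if g.nodes[n]["kind"] == "miRNA" else g.in_degree(n),
        }
        for n in g.nodes
    ]
    return pd.DataFrame(rows, columns=["node", "kind", "degree"]).sort_values(
        ["kind", "degree"], ascending=[True, False]
    ).reset_index(drop=True)
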