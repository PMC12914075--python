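"""Over-representation analysis against user-supplied GMT annotations.

For a query protein set drawn from a universe (either a genome-scale
background file or the measured panel itself), each term's enrichment p is
the upper-tail hypergeometric probability of observing at least k query
hits, Benjamini-Hochberg adjusted across tested terms. Two filter modes
mirror common practice: ``adjusted`` keeps p < 0.05 and q < 0.05;
``fold`` keeps fold-enrichment > 5 with unadjusted p < 0.05.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file: term, description, tab-separated member symbols."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, *members = parts
            out[term] = (desc, {m.strip().casefold() for m in members if m.strip()})
    return out


def harmonize(symbols) -> set[str]:
    """Exact-match harmonization after case-folding."""
    return {str(s).strip().casefold() for s in symbols if str(s).strip()}


def ora(
    query,
    universe,
    annotations: dict[str, tuple[str, set[str]]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    Query symbols outside the universe are reported (warned) and dropped,
    never silently. Terms with no members in the universe are skipped.
    Returns one row per tested term with k, n, K, N, p, BH q and
    fold-enrichment = (k/n)/(K/N), sorted by q then fold-enrichment.
    """
    uni = harmonize(universe)
    q = harmonize(query)
    unmatched = q - uni
    if unmatched:
        log.warning("ora: %d query symbol(s) outside the universe dropped: %s",
                    len(unmatched), sorted(unmatched)[:10])
    q &= uni
    if not q:
        log.warning("ora: empty query after intersection with the universe")
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "p", "q", "fold_enrichment"]
        ).set_index("term")
    N, n = len(uni), len(q)
    rows = []
    for term, (desc, members) in annotations.items():
        K = len(members & uni)
        if K == 0:
            continue
        k = len(members & q)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term, "name": desc, "k": k, "n": n, "K": K, "N": N,
            "p": p, "fold_enrichment": (k / n) / (K / N),
        })
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["q", "fold_enrichment"], ascending=[True, False])


def filter_terms(rows: pd.DataFrame, mode: str = "adjusted") -> pd.DataFrame:
    """Apply one of the two significance filters to an ORA table."""
    if rows.empty:
        return rows
    if mode == "adjusted":
        return rows[(rows["p"] < 0.05) & (rows["q"] < 0.05)]
    if mode == "fold":
        return rows[(rows["fold_enrichment"] > 5) & (rows["p"] < 0.05)]
    raise ValueError(f"unknown filter mode {mode!r}")


def term_gene_edges(
    rows: pd.DataFrame,
    query,
    annotations: dict[str, tuple[str, set[str]]],
) -> pd.DataFrame:
    """Term-gene edge list for the filtered terms (network export)."""
    q = harmonize(query)
    edges = [
        {"term": term, "gene": g}
        for term in rows.index
        for g in sorted(annotations[term][1] & q)
    ]
    return pd.DataFrame(edges, columns=["term", "gene"])
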