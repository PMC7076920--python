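"""Hypergeometric over-representation analysis (GO/KEGG-style).

Terms are flat gene sets; for a query of K genes drawn from a universe of N
genes, a term annotating n universe genes and overlapping the query in k is
scored with the one-sided upper-tail hypergeometric probability P[X >= k].
Results are filtered at raw P < 0.05 by default (the conventional ORA
cutoff); the BH-adjusted P is reported alongside for users who prefer FDR
filtering.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .errors import ContractError, LoadError

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts annotated genes among K draws without replacement from a
    universe of N genes of which n are annotated.
    """
    if not (0 <= k <= K <= N):
        raise ContractError(f"require 0 <= k <= K <= N, got k={k}, K={K}, N={N}")
    if not (0 <= n <= N):
        raise ContractError(f"require 0 <= n <= N, got n={n}, N={N}")
    if k > n:
        return 0.0
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n, K))


def load_annotation(path) -> dict:
    """Read a term_id/term_name/gene_id TSV into term_id -> (name, gene set)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene_id"}
    if not required.issubset(df.columns):
        raise LoadError(
            f"{path}: expected columns term_id, term_name, gene_id; "
            f"found {list(df.columns)}"
        )
    annotation: dict[str, tuple[str, set]] = {}
    for term_id, grp in df.groupby("term_id", sort=True):
        annotation[term_id] = (grp["term_name"].iloc[0], set(grp["gene_id"]))
    return annotation


def enrich(
    query_genes,
    annotation: dict,
    universe,
    p_threshold: float = 0.05,
    strict: bool = True,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` against every annotated term.

    One row per term overlapping the query, sorted by ascending raw P and
    filtered at p_raw < p_threshold (strict); BH-adjusted P over all
    overlapping terms is reported but not used for the default filter.
    Query genes outside the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ContractError("enrichment universe is empty")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped", len(outside)
        )
        query &= universe
    K, N = len(query), len(universe)
    rows = []
    for term_id in sorted(annotation):
        name, members = annotation[term_id]
        members = set(members) & universe
        overlap = members & query
        k, n = len(overlap), len(members)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_p(k, K, n, N),
                "gene_ratio": k / K,
                "member_genes": ",".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "n", "N",
            "p_raw", "p_adj", "gene_ratio", "member_genes",
        ],
    )
    if len(result):
        result["p_adj"] = adjust_bh(result["p_raw"].to_numpy())
    if strict:
        result = result[result["p_raw"] < p_threshold]
    else:
        result = result[result["p_raw"] <= p_threshold]
    return result.sort_values(
        ["p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)


def write_enrichment(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)
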