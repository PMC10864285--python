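"""Gene-set overrepresentation and protein-interaction subnetworks.

Overrepresentation follows the standard hypergeometric upper-tail test
with Benjamini-Hochberg false-discovery control, applied after dropping
terms that share fewer than two genes with the input set. The PPI step
keeps edges at or above a combined-confidence cutoff (default 0.4,
"medium confidence") and reports the connected components induced on the
query genes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import OverrepResult, ScreenThresholds


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes when drawing ``n`` items without replacement from
    a background of ``N`` containing ``K`` successes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation(
    input_genes: Iterable[str],
    terms: Mapping[str, Set[str]],
    background: Optional[Iterable[str]] = None,
    thresholds: ScreenThresholds = ScreenThresholds(),
    term_names: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> List[OverrepResult]:
    """Test every gene-set term for overrepresentation in the input set.

    ``background`` defaults to the union of all term members. Terms with
    overlap below ``thresholds.min_term_overlap`` are dropped before
    testing, and BH correction runs across the retained terms only.
    Input genes outside the background are dropped (or an error with
    ``strict=True``); the common convention of overrepresentation tools.
    """
    term_names = term_names or {}
    term_sets = {t: set(m) for t, m in terms.items()}
    if background is None:
        bg: Set[str] = set().union(*term_sets.values()) if term_sets else set()
    else:
        bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(input_genes)
    outside = query - bg
    if outside and strict:
        raise ValueError(
            f"{len(outside)} input genes outside the background, e.g. "
            f"{sorted(outside)[:3]}")
    query &= bg
    n, N = len(query), len(bg)

    rows = []
    for term_id in sorted(term_sets):
        members = term_sets[term_id] & bg
        overlap = query & members
        if len(overlap) < thresholds.min_term_overlap:
            continue
        p = hypergeom_p(len(overlap), len(members), n, N)
        rows.append((term_id, overlap, members, p))
    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    results = [
        OverrepResult(
            term_id=term_id,
            term_name=term_names.get(term_id, term_id),
            k=len(overlap),
            K=len(members),
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
            overlap_genes=tuple(sorted(overlap)),
        )
        for (term_id, overlap, members, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_gmt(source) -> Tuple[Dict[str, Set[str]], Dict[str, str]]:
    """Read a GMT file: term_id <tab> description <tab> member genes...

    Returns (terms, term_names).
    """
    terms: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    close = False
    if isinstance(source, (str,)):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            term_id, desc, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"term {term_id!r} has no members")
            terms[term_id] = set(members)
            names[term_id] = desc
    finally:
        if close:
            fh.close()
    return terms, names


def load_edges(source) -> pd.DataFrame:
    """Read a 3-column PPI edge TSV: gene_a, gene_b, combined_score."""
    df = pd.read_csv(source, sep="\t", dtype={0: str, 1: str})
    df.columns = ["gene_a", "gene_b", "combined_score"]
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1)).any():
        raise ValueError("combined scores must lie in [0, 1]")
    return df


def ppi_subnetwork(
    edges: pd.DataFrame,
    genes: Iterable[str],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> Tuple[nx.Graph, List[Set[str]]]:
    """Induced PPI subnetwork on a gene set after score filtering.

    Edges below ``min_ppi_score`` are discarded, self-loops removed, and
    repeated pairs deduplicated keeping the maximum score. Every query
    gene appears as a node (isolated if unconnected). Returns the graph
    and its connected components sorted largest first (ties by smallest
    member for determinism).
    """
    genes = set(genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b, score in edges[["gene_a", "gene_b", "combined_score"]].itertuples(
            index=False):
        if a == b:
            continue
        if a not in genes or b not in genes:
            continue
        if score < thresholds.min_ppi_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
        else:
            g.add_edge(a, b, combined_score=float(score))
    components = sorted(
        (set(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    return g, components
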