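"""Candidate prioritization: novelty, stock availability, orthologs, and
single-cell germline bias.

Selection reduces the tissue-enriched candidates to genes worth crossing:
uncharacterized symbols (plain CG numbers), genes with an available shRNA
stock, and annotation with human/mouse orthologs and ovary single-cell
cluster expression (germ cells vs. germarium soma vs. follicle cells).
"""

from __future__ import annotations

import math
import re
import statistics
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .types import ScClusterExpression

_CG_NUMBER = re.compile(r"^CG\d+$")

#: Sentinel used in ortholog tables for "no ortholog found".
NOTFOUND = "notfound"


def is_uncharacterized(symbol: str) -> bool:
    """True when a symbol is a bare CG number (an unnamed, unstudied gene).

    Multi-gene probe-set symbols joined by ``///`` count as
    uncharacterized when any component is a bare CG number.
    """
    if not symbol or not symbol.strip():
        raise ValueError("empty gene symbol")
    return any(
        _CG_NUMBER.match(part.strip()) is not None
        for part in symbol.split("///")
    )


def filter_by_stock(
    genes: pd.DataFrame,
    stock_table: pd.DataFrame,
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """Keep genes with at least one RNAi stock; set ``has_rnai_stock``.

    ``stock_table`` needs columns ``gene_id`` and ``stock_id``.
    """
    if stock_table.empty:
        with_stock: set = set()
    else:
        with_stock = set(stock_table["gene_id"].unique())
    out = genes.copy()
    out["has_rnai_stock"] = out[gene_col].isin(with_stock)
    return out[out["has_rnai_stock"]].copy()


def annotate_orthologs(
    genes: pd.DataFrame,
    orthologs: pd.DataFrame,
    gene_col: str = "gene_id",
) -> pd.DataFrame:
    """Left-join human/mouse ortholog symbols; absent rows get 'notfound'."""
    orth = orthologs.rename(
        columns={"human": "human_ortholog", "mouse": "mouse_ortholog"})
    out = genes.merge(
        orth[["gene_id", "human_ortholog", "mouse_ortholog"]],
        how="left", left_on=gene_col, right_on="gene_id")
    for col in ("human_ortholog", "mouse_ortholog"):
        out[col] = out[col].fillna(NOTFOUND).replace("", NOTFOUND)
    return out


def cluster_median(
    stage_values: Mapping[str, float],
    stage_to_cluster: Mapping[str, str],
    gene_id: str = "",
    clusters: Sequence[str] = ("gc", "soma", "fc"),
) -> ScClusterExpression:
    """Collapse stage-level expression to per-cluster medians.

    Each stage must map to exactly one cluster; even stage counts use the
    midpoint of the two central values. A cluster with no stages gets
    NaN (flagged by downstream consumers, not an error here).
    """
    per_cluster: Dict[str, list] = {c: [] for c in clusters}
    for stage, value in stage_values.items():
        if stage not in stage_to_cluster:
            raise ValueError(f"stage {stage!r} has no cluster assignment")
        cluster = stage_to_cluster[stage]
        if cluster not in per_cluster:
            raise ValueError(f"unknown cluster {cluster!r} for stage {stage!r}")
        per_cluster[cluster].append(float(value))
    medians = {
        c: statistics.median(vals) if vals else math.nan
        for c, vals in per_cluster.items()
    }
    return ScClusterExpression(gene_id=gene_id, **medians)


def germline_bias(e: ScClusterExpression) -> bool:
    """True when germ-cell expression strictly exceeds both somatic clusters."""
    for name in ("gc", "soma", "fc"):
        if math.isnan(getattr(e, name)):
            raise ValueError(f"cluster {name!r} undefined for {e.gene_id!r}")
    return e.gc > e.soma and e.gc > e.fc


def single_cell_medians(
    sc_table: pd.DataFrame, stage_to_cluster: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene cluster medians from a long (gene_id, stage, value) table."""
    rows = []
    for gene_id, grp in sc_table.groupby("gene_id", sort=True):
        stage_values = dict(zip(grp["stage"], grp["value"]))
        e = cluster_median(stage_values, stage_to_cluster, gene_id=str(gene_id))
        bias = (
            germline_bias(e)
            if not any(math.isnan(v) for v in (e.gc, e.soma, e.fc))
            else None
        )
        rows.append({"gene_id": gene_id, "gc": e.gc, "soma": e.soma,
                     "fc": e.fc, "germline_bias": bias})
    return pd.DataFrame(rows)


def prioritize(
    candidates: pd.DataFrame,
    stock_table: pd.DataFrame,
    orthologs: Optional[pd.DataFrame] = None,
    include: Optional[Iterable[str]] = None,
    exclude: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Full prioritization: selected groups -> uncharacterized -> stocked.

    ``include``/``exclude`` are explicit gene-id lists standing in for
    the manual-review step, which has no reproducible rule; by default
    nothing is manually added or removed.
    """
    out = candidates[candidates["group"] != "not_selected"].copy()
    out["uncharacterized"] = out["gene_symbol"].map(is_uncharacterized)
    out = out[out["uncharacterized"]]
    out = filter_by_stock(out, stock_table)
    if orthologs is not None:
        out = annotate_orthologs(out, orthologs)
    if include is not None:
        inc = set(include)
        out = out[out["gene_id"].isin(inc)]
    if exclude is not None:
        out = out[~out["gene_id"].isin(set(exclude))]
    return out.reset_index(drop=True)
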