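"""Scoring of X-chromosome nondisjunction (NDJ) test crosses.

Females carrying a germline-driven shRNA are crossed to X / B^S Y males.
Normal segregation gives X/X daughters and X/B^S Y sons; X nondisjunction
in the mother gives diplo-X and nullo-X ova, whose surviving products are
X/X/B^S Y daughters and X/O sons. The reciprocal zygotes (XXX, YO) die,
so every scored exceptional fly represents two exceptional zygotes. The
NDJ frequency is therefore

    NDJ = 2(XO + XXY) / [2(XO + XXY) + XX + XY]

A line is positive when any of three phenotypes holds in either germline
driver: sterility, NDJ frequency at or above the threshold (default
1.7%), or a small brood (adjusted total at or below 100). A gene is
positive when at least one of its shRNA lines is.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .types import (
    CATEGORY_ORDER,
    CrossResult,
    GeneCall,
    LineCall,
    RawTally,
    ScreenThresholds,
    venn_region_label,
)

DRIVERS = ("MVD1", "mata")


# --------------------------------------------------------------------------
# the NDJ statistic
# --------------------------------------------------------------------------

def ndj_frequency(t: RawTally) -> float:
    """NDJ frequency from a raw progeny tally, as a fraction in [0, 1].

    The factor 2 on exceptional progeny corrects for the inviable
    reciprocal zygote classes (XXX and YO).
    """
    if t.total == 0:
        raise ValueError("cannot compute NDJ frequency with zero progeny")
    ndj2 = 2 * t.ndj_events
    return ndj2 / (ndj2 + t.xx_females + t.bs_males)


def ndj_from_summary(adjusted_total: int, ndj_events: int) -> float:
    """NDJ frequency from a summary cell (adjusted total, NDJ events).

    ``adjusted_total`` is the formula's denominator 2(XO+XXY)+XX+XY, so
    the frequency is simply 2*events/total. Identical to
    :func:`ndj_frequency` on any raw tally with matching sums.
    """
    if adjusted_total <= 0:
        raise ValueError("adjusted_total must be positive")
    if ndj_events < 0 or adjusted_total < 2 * ndj_events:
        raise ValueError(
            f"inconsistent summary: total={adjusted_total}, events={ndj_events}")
    return 2 * ndj_events / adjusted_total


def ndj_percent(
    adjusted_total: int,
    ndj_events: int,
    decimals: Optional[int] = 1,
) -> float:
    """NDJ frequency in percent, optionally rounded for threshold tests."""
    pct = 100.0 * ndj_from_summary(adjusted_total, ndj_events)
    return round(pct, decimals) if decimals is not None else pct


# --------------------------------------------------------------------------
# screen-table parsing
# --------------------------------------------------------------------------

class ScreenTableError(ValueError):
    """Malformed screen-table cell, with row context."""


_COUNTS_CELL = re.compile(r"^(\d+)\s*,\s*(\d+)\s*NDJ$")


def parse_cell(text: str) -> Tuple[str, Optional[int], Optional[int]]:
    """Parse one driver cell: STERILE / ND / empty / '<total>, <k> NDJ'.

    Returns (status, adjusted_total, ndj_events); empty cells map to ND
    (not tested).
    """
    text = (text or "").strip()
    if text == "" or text.upper() == "ND":
        return "ND", None, None
    if text.upper() == "STERILE":
        return "STERILE", None, None
    m = _COUNTS_CELL.match(text)
    if not m:
        raise ScreenTableError(f"unparseable cell {text!r}")
    total, events = int(m.group(1)), int(m.group(2))
    if total < 2 * events:
        raise ScreenTableError(
            f"cell {text!r}: adjusted total {total} < 2 x {events} NDJ events")
    return "counts", total, events


def parse_screen_table(source) -> List[CrossResult]:
    """Read a screen-results TSV into per-driver :class:`CrossResult` rows.

    Expected columns: gene_id (optional), gene_symbol, human_ortholog,
    mouse_ortholog, stock_id, mvd1, mata, and optionally no_stage14 and
    tub_gal4 (annotations only, never scored). ``source`` is a path or
    file-like object.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_symbol", "stock_id", "mvd1", "mata"}
    missing = required - set(df.columns)
    if missing:
        raise ScreenTableError(f"missing columns: {sorted(missing)}")
    results: List[CrossResult] = []
    for idx, row in df.iterrows():
        gene_id = row.get("gene_id", row["gene_symbol"])
        for col, driver in (("mvd1", "MVD1"), ("mata", "mata")):
            try:
                status, total, events = parse_cell(row[col])
            except ScreenTableError as exc:
                raise ScreenTableError(
                    f"row {idx + 2} ({row['gene_symbol']}/{row['stock_id']}, "
                    f"{driver}): {exc}") from exc
            results.append(CrossResult(
                gene_id=str(gene_id),
                gene_symbol=str(row["gene_symbol"]),
                shRNA=str(row["stock_id"]),
                driver=driver,
                status=status,
                adjusted_total=total,
                ndj_events=events,
            ))
    return results


# --------------------------------------------------------------------------
# positivity calls
# --------------------------------------------------------------------------

def call_line(
    results: Sequence[CrossResult],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> LineCall:
    """Call one gene x shRNA line from its per-driver cross results.

    Per germline driver: STERILE yields Sterile; a counts cell yields NDJ
    when the (optionally rounded) NDJ percentage reaches the threshold,
    and Small_brood when the adjusted total is at or below the brood
    cutoff. Sterile crosses are never additionally small-brood. ND cells
    carry no evidence; a line with only ND entries is untested, not
    negative. Categories are unioned across drivers.
    """
    scored = [r for r in results if r.driver in DRIVERS]
    if not scored:
        raise ValueError("no germline-driver results for this line")
    first = scored[0]
    categories = set()
    any_evidence = False
    for r in scored:
        if r.status == "ND":
            continue
        any_evidence = True
        if r.status == "STERILE":
            categories.add("Sterile")
            continue
        pct = ndj_percent(r.adjusted_total, r.ndj_events,
                          thresholds.ndj_rounding_decimals)
        if pct >= thresholds.ndj_min_pct:
            categories.add("NDJ")
        small = (
            r.adjusted_total <= thresholds.brood_max
            if thresholds.brood_inclusive
            else r.adjusted_total < thresholds.brood_max
        )
        if small:
            categories.add("Small_brood")
    return LineCall(
        gene_id=first.gene_id,
        gene_symbol=first.gene_symbol,
        shRNA=first.shRNA,
        categories=frozenset(categories),
        untested=not any_evidence,
    )


def call_gene(line_calls: Sequence[LineCall]) -> GeneCall:
    """Aggregate line calls: a gene is positive if any line is.

    Categories are the union over positive lines; untested lines are
    ignored.
    """
    if not line_calls:
        raise ValueError("no line calls for gene")
    categories = set()
    for lc in line_calls:
        if not lc.untested:
            categories |= lc.categories
    first = line_calls[0]
    return GeneCall(
        gene_id=first.gene_id,
        gene_symbol=first.gene_symbol,
        positive=len(categories) > 0,
        categories=frozenset(categories),
        per_line=tuple(line_calls),
    )


def score_screen(
    results: Sequence[CrossResult],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> List[GeneCall]:
    """Full scoring: group by gene symbol and shRNA, call lines then genes."""
    by_line: Dict[Tuple[str, str], List[CrossResult]] = {}
    for r in results:
        if r.driver in DRIVERS:
            by_line.setdefault((r.gene_symbol, r.shRNA), []).append(r)
    by_gene: Dict[str, List[LineCall]] = {}
    for (symbol, _), rs in sorted(by_line.items()):
        lc = call_line(rs, thresholds)
        by_gene.setdefault(symbol, []).append(lc)
    return [call_gene(lcs) for _, lcs in sorted(by_gene.items())]


def venn_summary(gene_calls: Sequence[GeneCall]) -> Dict[str, int]:
    """Count positive genes per exact category subset (Venn region).

    Regions with zero genes are included so the summary always carries
    the full 7-region partition; the counts sum to the number of
    positive genes.
    """
    from itertools import combinations

    regions = []
    for r in range(1, len(CATEGORY_ORDER) + 1):
        for combo in combinations(CATEGORY_ORDER, r):
            regions.append(venn_region_label(frozenset(combo)))
    counts = {label: 0 for label in regions}
    for gc in gene_calls:
        if gc.positive:
            counts[gc.venn_region] += 1
    return counts


def screen_summary(gene_calls: Sequence[GeneCall]) -> Dict[str, int]:
    """Headline counts: positives, per-category totals, exclusive regions."""
    venn = venn_summary(gene_calls)
    positives = [g for g in gene_calls if g.positive]
    out = {
        "n_genes": len(gene_calls),
        "n_positive_genes": len(positives),
        "n_positive_lines": sum(
            1 for g in gene_calls for lc in g.per_line if lc.positive),
    }
    for cat in CATEGORY_ORDER:
        out[f"n_{cat}_any"] = sum(1 for g in positives if cat in g.categories)
        out[f"n_{cat}_only"] = venn[cat]
    out["n_overlap"] = sum(
        v for k, v in venn.items() if "+" in k)
    out.update({f"venn[{k}]": v for k, v in venn.items()})
    return out


def gene_calls_frame(gene_calls: Sequence[GeneCall]) -> pd.DataFrame:
    """Flatten gene calls to a DataFrame for writing."""
    rows = []
    for g in gene_calls:
        rows.append({
            "gene_id": g.gene_id,
            "gene_symbol": g.gene_symbol,
            "positive": g.positive,
            "venn_region": g.venn_region,
            "n_lines": len(g.per_line),
        })
    return pd.DataFrame(rows)


def line_calls_frame(gene_calls: Sequence[GeneCall]) -> pd.DataFrame:
    rows = []
    for g in gene_calls:
        for lc in g.per_line:
            rows.append({
                "gene_id": lc.gene_id,
                "gene_symbol": lc.gene_symbol,
                "shRNA": lc.shRNA,
                "positive": lc.positive,
                "untested": lc.untested,
                "categories": venn_region_label(lc.categories),
            })
    return pd.DataFrame(rows)
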