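"""Core domain types shared across the screening pipeline.

The pipeline moves through three representations: probe-set expression
profiles (microarray stage), cross results (RNAi screen stage), and
gene-level phenotype calls (aggregation stage). All types are plain
dataclasses; tabular bulk data is carried as pandas DataFrames and these
types describe single records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

# Canonical ordering of phenotype categories, used for Venn region labels.
CATEGORY_ORDER = ("Sterile", "NDJ", "Small_brood")

#: The four selected tissue-expression groups plus the rejection label.
TISSUE_GROUPS = (
    "ovary_only",
    "ovary_cns",
    "ovary_testis",
    "ovary_cns_testis",
    "not_selected",
)


@dataclass(frozen=True)
class ScreenThresholds:
    """All tunable cutoffs of the screen, serialized with every run.

    Parameters
    ----------
    p_max
        Largest t-test p-value still called significant (inclusive).
    enrich_up_min
        "Up" requires enrichment strictly greater than this (default 1).
    ndj_min_pct
        Minimum nondisjunction frequency, in percent, for an NDJ call.
    brood_max
        Adjusted-total cutoff for a small-brood call.
    brood_inclusive
        If True (default) the small-brood rule is ``total <= brood_max``,
        otherwise strict ``<``.
    min_term_overlap
        Terms sharing fewer input genes than this are dropped before
        overrepresentation testing.
    min_ppi_score
        Minimum combined confidence score for a protein-interaction edge.
    ndj_rounding_decimals
        NDJ percentages are rounded to this many decimals before the
        threshold comparison; ``None`` compares the raw value.
    """

    p_max: float = 0.05
    enrich_up_min: float = 1.0
    ndj_min_pct: float = 1.7
    brood_max: int = 100
    brood_inclusive: bool = True
    min_term_overlap: int = 2
    min_ppi_score: float = 0.4
    ndj_rounding_decimals: Optional[int] = 1

    def __post_init__(self) -> None:
        if self.p_max <= 0 or self.p_max > 1:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        for name in ("enrich_up_min", "ndj_min_pct", "brood_max",
                     "min_term_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.min_ppi_score <= 1:
            raise ValueError("min_ppi_score must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProbeSetProfile:
    """Replicate intensities and detection flags for one probe set.

    ``intensities`` maps tissue name to replicate intensities (linear
    units); ``present`` carries the matching per-replicate detection
    flags. The whole-body tissue must always be reported.
    """

    probe_id: str
    gene_id: str
    gene_symbol: str
    intensities: Mapping[str, Sequence[float]]
    present: Mapping[str, Sequence[bool]]

    def __post_init__(self) -> None:
        for tissue, vals in self.intensities.items():
            if len(vals) == 0:
                raise ValueError(
                    f"{self.probe_id}: empty intensity list for {tissue!r}")
            flags = self.present.get(tissue)
            if flags is not None and len(flags) != len(vals):
                raise ValueError(
                    f"{self.probe_id}: present flags misaligned for {tissue!r}")


@dataclass(frozen=True)
class TissueCall:
    """Enrichment call for one gene in one tissue."""

    gene_id: str
    tissue: str
    enrichment: float
    p_value: Optional[float]  # None when the t-test was not computable
    direction: str  # "up" | "down" | "others"
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "others"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class RawTally:
    """Scored progeny classes of one nondisjunction test cross.

    Regular classes are X/X daughters and X/B^S Y sons; the exceptional
    (nondisjunction-derived) classes are X/O sons and X/X/B^S Y
    daughters. The reciprocal exceptional zygotes (XXX, YO) die and are
    never scored.
    """

    xx_females: int
    bs_males: int
    xo_males: int
    xxy_females: int

    def __post_init__(self) -> None:
        for f in ("xx_females", "bs_males", "xo_males", "xxy_females"):
            v = getattr(self, f)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{f} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.xx_females + self.bs_males + self.xo_males + self.xxy_females

    @property
    def ndj_events(self) -> int:
        return self.xo_males + self.xxy_females

    @property
    def adjusted_total(self) -> int:
        """Denominator of the NDJ formula: 2(XO+XXY) + XX + XY."""
        return 2 * self.ndj_events + self.xx_females + self.bs_males


@dataclass(frozen=True)
class CrossResult:
    """Outcome of one gene x shRNA line x driver cross."""

    gene_id: str
    gene_symbol: str
    shRNA: str
    driver: str  # "MVD1" | "mata" | "Tub"
    status: str  # "counts" | "STERILE" | "ND"
    adjusted_total: Optional[int] = None
    ndj_events: Optional[int] = None
    raw: Optional[RawTally] = None

    def __post_init__(self) -> None:
        if self.status not in ("counts", "STERILE", "ND"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "counts":
            if self.adjusted_total is None or self.ndj_events is None:
                raise ValueError("counts status requires totals")
            if self.adjusted_total < 2 * self.ndj_events:
                raise ValueError(
                    f"adjusted_total {self.adjusted_total} < "
                    f"2*ndj_events {2 * self.ndj_events}")
            if self.raw is not None and (
                self.raw.adjusted_total != self.adjusted_total
                or self.raw.ndj_events != self.ndj_events
            ):
                raise ValueError("raw tally inconsistent with summary")


@dataclass(frozen=True)
class LineCall:
    """Positivity call for one gene x shRNA line (union over drivers)."""

    gene_id: str
    gene_symbol: str
    shRNA: str
    categories: frozenset
    untested: bool = False

    @property
    def positive(self) -> bool:
        return len(self.categories) > 0


@dataclass(frozen=True)
class GeneCall:
    """Gene-level positivity and Venn region."""

    gene_id: str
    gene_symbol: str
    positive: bool
    categories: frozenset
    per_line: tuple = ()

    @property
    def venn_region(self) -> str:
        return venn_region_label(self.categories)


def venn_region_label(categories) -> str:
    """Canonical label of a category subset, e.g. ``Sterile+Small_brood``."""
    ordered = [c for c in CATEGORY_ORDER if c in categories]
    unknown = set(categories) - set(CATEGORY_ORDER)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    return "+".join(ordered) if ordered else "none"


@dataclass(frozen=True)
class ScClusterExpression:
    """Per-cluster median single-cell expression for one gene.

    Clusters follow the ovary atlas: germ cells (gc), germarium soma
    (soma), and follicle cells (fc). A value is NaN when the cluster had
    no contributing stages.
    """

    gene_id: str
    gc: float
    soma: float
    fc: float


@dataclass(frozen=True)
class OverrepResult:
    """Hypergeometric overrepresentation result for one gene-set term."""

    term_id: str
    term_name: str
    k: int  # overlap with the input set
    K: int  # term size within the background
    n: int  # input size within the background
    N: int  # background size
    p_value: float
    q_value: float
    overlap_genes: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("overlap outside [0, min(K, n)]")
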