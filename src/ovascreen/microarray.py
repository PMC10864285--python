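"""Candidate-gene selection funnel from replicate tissue expression.

The funnel mirrors a tissue-enrichment screen on a multi-tissue
expression atlas: per-tissue enrichment relative to whole body with a
two-sample t-test, removal of unwanted gene classes and undetected probe
sets, collapse to one representative probe per gene, and classification
into the four ovary-centred tissue groups (ovary_only, ovary+CNS,
ovary+testis, ovary+CNS+testis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ProbeSetProfile, ScreenThresholds, TissueCall


@dataclass(frozen=True)
class TissuePanel:
    """Names the special tissues of the screen; everything else is 'other'.

    ``exclude`` lists tissues dropped before analysis (e.g. cultured-cell
    columns that are not fly tissues).
    """

    whole_body: str = "whole_body"
    ovary: str = "ovary"
    testis: str = "testis"
    cns: str = "cns"
    exclude: Tuple[str, ...] = ("s2_cells",)

    @property
    def special(self) -> Tuple[str, str, str]:
        return (self.ovary, self.testis, self.cns)


# --------------------------------------------------------------------------
# per-tissue enrichment calls
# --------------------------------------------------------------------------

def _two_sample_t_p(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    """Two-tailed two-sample t-test p-value with degenerate-limit handling.

    When both samples have zero variance the t statistic is undefined;
    the limit taken is p=1 for equal means and p=0 otherwise.
    """
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def compute_tissue_call(
    profile: ProbeSetProfile,
    tissue: str,
    whole_body: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
    welch: bool = False,
) -> TissueCall:
    """Call one tissue up/down/others against whole body.

    Enrichment is mean(tissue) / mean(whole body); the p-value comes from
    a two-tailed Student's t-test (pooled variance by default, Welch when
    ``welch=True``). "up" means enrichment > 1 and p <= p_max, "down"
    means enrichment < 1 and p <= p_max, anything else is "others".

    With fewer than two replicates on either side the t-test is not
    computable: the call is forced to "others" with ``p_value=None`` and
    a flag, never an exception. A non-positive whole-body mean is an
    error because enrichment is then undefined.
    """
    x = np.asarray(profile.intensities[tissue], dtype=float)
    wb = np.asarray(profile.intensities[whole_body], dtype=float)
    wb_mean = wb.mean()
    if wb_mean <= 0:
        raise ValueError(
            f"{profile.probe_id}: whole-body mean must be positive, got {wb_mean}")
    enrichment = float(x.mean() / wb_mean)

    if len(x) < 2 or len(wb) < 2:
        return TissueCall(profile.gene_id, tissue, enrichment, None,
                          "others", flag="too_few_replicates")

    p = _two_sample_t_p(x, wb, welch)
    if enrichment > thresholds.enrich_up_min and p <= thresholds.p_max:
        direction = "up"
    elif enrichment < 1.0 and p <= thresholds.p_max:
        direction = "down"
    else:
        direction = "others"
    return TissueCall(profile.gene_id, tissue, enrichment, p, direction)


# --------------------------------------------------------------------------
# gene-symbol and present-call filters
# --------------------------------------------------------------------------

# "rna"/"rps"/"rpl" are substring rules: fly RNA-gene symbols carry the
# class as an infix (snoRNA:..., tRNA:..., mt:lrRNA) and ribosomal
# proteins as a prefix or after "m" (RpS3, RpL32, mRpS30).
_UNKNOWN = re.compile(r"^-+$")
_NONCODING = re.compile(r"^CR\d")
_RNA = re.compile(r"rna", re.IGNORECASE)
_RIBOSOMAL = re.compile(r"rp[sl]\d", re.IGNORECASE)

_REMOVAL_RULES = (
    ("unknown", _UNKNOWN),
    ("noncoding_CR", _NONCODING),
    ("rna_gene", _RNA),
    ("ribosomal", _RIBOSOMAL),
)


def _symbol_removal_reason(symbol: str) -> Optional[str]:
    symbol = symbol.strip()
    if symbol == "":
        return "unknown"
    for reason, pat in _REMOVAL_RULES:
        if pat.search(symbol):
            return reason
    return None


def _record_removal_reason(symbol: str) -> Optional[str]:
    """Removal reason for a (possibly multi-gene ///) symbol record.

    A multi-gene probe set is removed only when every component matches a
    removal pattern: as long as one component is an ordinary
    protein-coding symbol the probe still reports on it.
    """
    parts = [p.strip() for p in str(symbol).split("///")]
    reasons = [_symbol_removal_reason(p) for p in parts]
    if all(r is not None for r in reasons):
        return reasons[0]
    return None


def filter_unwanted_genes(
    symbols: pd.DataFrame, symbol_col: str = "gene_symbol"
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop unknown ("---"), non-coding (CR#), RNA, and ribosomal genes.

    Returns the kept rows and a per-reason count of dropped rows.
    """
    if symbols.empty:
        return symbols.copy(), {}
    reasons = symbols[symbol_col].map(_record_removal_reason)
    dropped = reasons.dropna()
    report = dropped.value_counts().to_dict()
    return symbols.loc[reasons.isna()].copy(), report


def filter_absent_probesets(
    profiles: Sequence[ProbeSetProfile],
    panel: TissuePanel = TissuePanel(),
    missing: str = "absent",
) -> List[ProbeSetProfile]:
    """Remove probe sets never detected in ovary, testis, or larval CNS.

    A probe set is removed only when every replicate in all three
    tissues is flagged absent. A tissue with no present flags is treated
    as all-absent by default (``missing="absent"``) or raises
    (``missing="error"``).
    """
    if missing not in ("absent", "error"):
        raise ValueError(f"missing must be 'absent' or 'error', got {missing!r}")
    kept = []
    for prof in profiles:
        any_present = False
        for tissue in panel.special:
            flags = prof.present.get(tissue)
            if flags is None:
                if missing == "error":
                    raise ValueError(
                        f"{prof.probe_id}: no present flags for {tissue!r}")
                continue
            if any(flags):
                any_present = True
                break
        if any_present:
            kept.append(prof)
    return kept


# --------------------------------------------------------------------------
# probe collapsing and group classification
# --------------------------------------------------------------------------

def select_representative_probe(
    gene_id: str,
    candidate_profiles: Sequence[ProbeSetProfile],
    calls: Mapping[str, Mapping[str, TissueCall]],
    panel: TissuePanel = TissuePanel(),
) -> str:
    """Pick one probe per gene.

    Probes are ranked by (number of present replicate flags across
    ovary/testis/CNS, number of "up" directions among those tissues),
    highest first; exact ties break to the lexicographically smallest
    probe id. ``calls`` maps probe_id -> tissue -> TissueCall.
    """
    if not candidate_profiles:
        raise ValueError(f"no candidate probes for gene {gene_id}")

    def key(prof: ProbeSetProfile):
        n_present = sum(
            sum(bool(f) for f in prof.present.get(t, ()))
            for t in panel.special
        )
        probe_calls = calls.get(prof.probe_id, {})
        n_up = sum(
            1 for t in panel.special
            if t in probe_calls and probe_calls[t].direction == "up"
        )
        return (-n_present, -n_up, prof.probe_id)

    return min(candidate_profiles, key=key).probe_id


def classify_tissue_group(
    directions: Mapping[str, str], panel: TissuePanel = TissuePanel()
) -> str:
    """Assign the four-group label from the per-tissue up/not-up pattern.

    Ovary "up" is mandatory; testis and CNS membership follows their up
    status; "up" in any other tissue rejects the gene. The whole-body
    reference never participates.
    """
    if panel.ovary not in directions:
        raise ValueError("ovary direction is required")
    if directions[panel.ovary] != "up":
        return "not_selected"
    others_up = any(
        d == "up"
        for t, d in directions.items()
        if t not in (panel.ovary, panel.testis, panel.cns, panel.whole_body)
    )
    if others_up:
        return "not_selected"
    cns_up = directions.get(panel.cns) == "up"
    testis_up = directions.get(panel.testis) == "up"
    if cns_up and testis_up:
        return "ovary_cns_testis"
    if cns_up:
        return "ovary_cns"
    if testis_up:
        return "ovary_testis"
    return "ovary_only"


# --------------------------------------------------------------------------
# the full funnel
# --------------------------------------------------------------------------

def run_selection_funnel(
    profiles: Sequence[ProbeSetProfile],
    thresholds: ScreenThresholds = ScreenThresholds(),
    panel: TissuePanel = TissuePanel(),
    welch: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole candidate-selection funnel.

    Stages: unwanted-symbol filter -> absent-probe filter -> per-tissue
    calls -> representative probe per gene -> tissue-group
    classification. Returns ``(candidates, funnel_report)`` where
    ``candidates`` has one row per gene that survived symbol/absence
    filtering (selected or not) and ``funnel_report`` the per-stage
    gene/probe counts.

    The candidate table columns: gene_id, gene_symbol, probe_id, group,
    plus ``<tissue>_direction`` / ``<tissue>_enrichment`` per tissue.
    """
    report_rows = []

    def log(stage, n_in, n_out, reason):
        report_rows.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "reason": reason})

    # stage 1: symbol filter
    sym = pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in profiles],
            "gene_id": [p.gene_id for p in profiles],
            "gene_symbol": [p.gene_symbol for p in profiles],
        }
    )
    kept_sym, drop_report = filter_unwanted_genes(sym)
    keep_ids = set(kept_sym["probe_id"]) if not sym.empty else set()
    profiles1 = [p for p in profiles if p.probe_id in keep_ids]
    log("symbol_filter", len(profiles), len(profiles1),
        ";".join(f"{k}={v}" for k, v in sorted(drop_report.items())) or "none")

    # stage 2: present-call filter
    profiles2 = filter_absent_probesets(profiles1, panel)
    log("present_filter", len(profiles1), len(profiles2),
        "no present calls in ovary/testis/CNS")

    # stage 3: per-tissue calls for every surviving probe
    calls: Dict[str, Dict[str, TissueCall]] = {}
    for prof in profiles2:
        tissue_calls = {}
        for tissue in prof.intensities:
            if tissue == panel.whole_body or tissue in panel.exclude:
                continue
            tissue_calls[tissue] = compute_tissue_call(
                prof, tissue, panel.whole_body, thresholds, welch=welch)
        calls[prof.probe_id] = tissue_calls

    # stage 4: representative probe per gene
    by_gene: Dict[str, List[ProbeSetProfile]] = {}
    for prof in profiles2:
        by_gene.setdefault(prof.gene_id, []).append(prof)
    representatives = {
        gid: select_representative_probe(gid, profs, calls, panel)
        for gid, profs in by_gene.items()
    }
    log("collapse_probes", len(profiles2), len(representatives),
        "one representative probe per gene")

    # stage 5: classification
    rows = []
    profile_by_id = {p.probe_id: p for p in profiles2}
    for gid in sorted(representatives):
        probe_id = representatives[gid]
        prof = profile_by_id[probe_id]
        tissue_calls = calls[probe_id]
        directions = {t: c.direction for t, c in tissue_calls.items()}
        group = classify_tissue_group(directions, panel)
        row = {
            "gene_id": gid,
            "gene_symbol": prof.gene_symbol,
            "probe_id": probe_id,
            "group": group,
        }
        for t, c in sorted(tissue_calls.items()):
            row[f"{t}_direction"] = c.direction
            row[f"{t}_enrichment"] = c.enrichment
        rows.append(row)
    candidates = pd.DataFrame(rows)
    n_selected = (
        int((candidates["group"] != "not_selected").sum())
        if not candidates.empty else 0
    )
    log("classify_groups", len(representatives), n_selected,
        "ovary up and no other tissue up")

    return candidates, pd.DataFrame(report_rows)


def group_counts(candidates: pd.DataFrame) -> Dict[str, int]:
    """Selected-gene counts per tissue group (not_selected excluded)."""
    if candidates.empty:
        return {}
    sel = candidates[candidates["group"] != "not_selected"]
    return sel["group"].value_counts().to_dict()
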