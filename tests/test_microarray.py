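"""Tissue-enrichment calls, probe filters, and the selection funnel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ovascreen.microarray import (
    TissuePanel,
    classify_tissue_group,
    compute_tissue_call,
    filter_absent_probesets,
    filter_unwanted_genes,
    run_selection_funnel,
    select_representative_probe,
)
from ovascreen.simulate import default_config, simulate_expression
from ovascreen.types import ProbeSetProfile, ScreenThresholds


def _profile(tissue_vals, present=None, probe="p1", gene="g1", symbol="CG1"):
    present = present or {
        t: [True] * len(v) for t, v in tissue_vals.items()}
    return ProbeSetProfile(probe, gene, symbol, tissue_vals, present)


def pooled_t_p(a, b):
    """Textbook pooled-variance two-sample t-test (independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * stats.t.sf(abs(t), n1 + n2 - 2)


class TestTissueCall:
    def test_identity_case(self):
        p = _profile({"ovary": [5.0, 5.0, 5.0], "whole_body": [5.0, 5.0, 5.0]})
        call = compute_tissue_call(p, "ovary", "whole_body")
        assert call.enrichment == 1.0
        assert call.direction == "others"

    def test_up_call_with_hand_ratio(self):
        p = _profile({"ovary": [10, 12, 9, 11], "whole_body": [2, 3, 2, 3]})
        call = compute_tissue_call(p, "ovary", "whole_body")
        assert call.enrichment == pytest.approx(4.2)
        assert call.direction == "up"
        assert call.p_value == pytest.approx(
            pooled_t_p([10, 12, 9, 11], [2, 3, 2, 3]), abs=1e-12)

    def test_down_is_the_mirror_of_up(self):
        p = _profile({"ovary": [2, 3, 2, 3], "whole_body": [10, 12, 9, 11]})
        call = compute_tissue_call(p, "ovary", "whole_body")
        assert call.enrichment < 1
        assert call.direction == "down"

    def test_single_replicate_flags_instead_of_crashing(self):
        p = _profile({"ovary": [10.0], "whole_body": [2.0, 3.0]})
        call = compute_tissue_call(p, "ovary", "whole_body")
        assert call.direction == "others"
        assert call.p_value is None
        assert call.flag == "too_few_replicates"

    def test_zero_whole_body_mean_is_an_error(self):
        p = _profile({"ovary": [1.0, 2.0], "whole_body": [0.0, 0.0]})
        with pytest.raises(ValueError):
            compute_tissue_call(p, "ovary", "whole_body")

    def test_zero_variance_degenerate_limits(self):
        same = _profile({"ovary": [4.0, 4.0], "whole_body": [4.0, 4.0]})
        assert compute_tissue_call(same, "ovary", "whole_body").direction == \
            "others"
        diff = _profile({"ovary": [8.0, 8.0], "whole_body": [4.0, 4.0]})
        call = compute_tissue_call(diff, "ovary", "whole_body")
        assert call.p_value == 0.0 and call.direction == "up"

    def test_p_matches_textbook_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(10, 2, n1)
            b = rng.normal(9, 2, n2)
            p = _profile({"t": list(a), "whole_body": list(b)})
            call = compute_tissue_call(p, "t", "whole_body")
            assert call.p_value == pytest.approx(pooled_t_p(a, b), abs=1e-9)

    @given(st.floats(min_value=1.01, max_value=50))
    @settings(max_examples=50, derandomize=True)
    def test_enrichment_monotone_in_scaling(self, c):
        base = {"ovary": [3.0, 4.0, 5.0], "whole_body": [2.0, 2.5, 3.0]}
        scaled = {"ovary": [v * c for v in base["ovary"]],
                  "whole_body": base["whole_body"]}
        e0 = compute_tissue_call(_profile(base), "ovary", "whole_body").enrichment
        e1 = compute_tissue_call(_profile(scaled), "ovary", "whole_body").enrichment
        assert e1 >= e0

    def test_direction_partition(self):
        """Exactly one of up/down/others holds for any computable call."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.lognormal(4, 0.5, 4)
            b = rng.lognormal(4, 0.5, 4)
            call = compute_tissue_call(
                _profile({"t": list(a), "whole_body": list(b)}), "t",
                "whole_body")
            assert call.direction in ("up", "down", "others")
            matches = 0
            if call.enrichment > 1 and call.p_value <= 0.05:
                matches += call.direction == "up"
            elif call.enrichment < 1 and call.p_value <= 0.05:
                matches += call.direction == "down"
            else:
                matches += call.direction == "others"
            assert matches == 1


class TestSymbolFilter:
    def test_removal_patterns(self):
        df = pd.DataFrame({"gene_symbol": [
            "CR43242", "c(3)G", "---", "snoRNA:U3:54Aa", "RpL32", "CG4951",
            "mRpS30"]})
        kept, report = filter_unwanted_genes(df)
        assert list(kept["gene_symbol"]) == ["c(3)G", "CG4951"]
        assert report["noncoding_CR"] == 1
        assert report["unknown"] == 1
        assert report["rna_gene"] == 1
        assert report["ribosomal"] == 2

    def test_multi_gene_record_kept_if_any_component_coding(self):
        df = pd.DataFrame({"gene_symbol": ["CR40001 /// CG1234",
                                           "CR40001 /// CR40002"]})
        kept, _ = filter_unwanted_genes(df)
        assert list(kept["gene_symbol"]) == ["CR40001 /// CG1234"]

    def test_empty_input(self):
        kept, report = filter_unwanted_genes(pd.DataFrame({"gene_symbol": []}))
        assert kept.empty and report == {}


class TestAbsentFilter:
    def test_removed_only_when_all_three_tissues_absent(self):
        vals = {t: [1.0, 1.0] for t in
                ("ovary", "testis", "cns", "gut", "whole_body")}
        absent = {t: [False, False] for t in ("ovary", "testis", "cns")}
        absent.update({"gut": [True, True], "whole_body": [True, True]})
        removed = _profile(vals, absent)
        one_witness = _profile(
            vals,
            {**absent, "ovary": [True, False]}, probe="p2")
        kept = filter_absent_probesets([removed, one_witness])
        assert [p.probe_id for p in kept] == ["p2"]

    def test_all_present_kept(self):
        p = _profile({t: [1.0] for t in ("ovary", "testis", "cns",
                                         "whole_body")})
        assert filter_absent_probesets([p]) == [p]

    def test_missing_flags_error_mode(self):
        p = ProbeSetProfile("p", "g", "s", {"ovary": [1.0]}, {})
        with pytest.raises(ValueError):
            filter_absent_probesets([p], missing="error")


class TestRepresentativeProbe:
    def _calls(self, probe, ups):
        from ovascreen.types import TissueCall

        return {t: TissueCall("g", t, 2.0, 0.01, "up" if t in ups else
                              "others") for t in ("ovary", "testis", "cns")}

    def test_more_present_calls_wins(self):
        a = _profile({"ovary": [1] * 4, "testis": [1] * 4, "cns": [1] * 4,
                      "whole_body": [1] * 4}, probe="A")
        b = _profile({"ovary": [1] * 4, "testis": [1] * 4, "cns": [1] * 4,
                      "whole_body": [1] * 4},
                     present={"ovary": [True] * 4, "testis": [False] * 4,
                              "cns": [True] * 4, "whole_body": [True] * 4},
                     probe="B")
        calls = {"A": self._calls("A", {"ovary"}),
                 "B": self._calls("B", {"ovary"})}
        assert select_representative_probe("g", [a, b], calls) == "A"

    def test_up_count_breaks_present_tie(self):
        a = _profile({"ovary": [1] * 4, "whole_body": [1] * 4}, probe="A")
        b = _profile({"ovary": [1] * 4, "whole_body": [1] * 4}, probe="B")
        calls = {"A": self._calls("A", set()),
                 "B": self._calls("B", {"ovary", "testis"})}
        assert select_representative_probe("g", [a, b], calls) == "B"

    def test_exact_tie_breaks_lexicographically(self):
        a = _profile({"ovary": [1] * 2, "whole_body": [1] * 2}, probe="p9")
        b = _profile({"ovary": [1] * 2, "whole_body": [1] * 2}, probe="p10")
        calls = {"p9": self._calls("p9", set()), "p10": self._calls("p10", set())}
        assert select_representative_probe("g", [a, b], calls) == "p10"

    def test_single_candidate(self):
        a = _profile({"ovary": [1], "whole_body": [1]}, probe="only")
        assert select_representative_probe("g", [a], {}) == "only"


class TestGroupClassification:
    @pytest.mark.parametrize(
        "ups, expected",
        [
            ({"ovary"}, "ovary_only"),
            ({"ovary", "cns"}, "ovary_cns"),
            ({"ovary", "testis"}, "ovary_testis"),
            ({"ovary", "testis", "cns"}, "ovary_cns_testis"),
            ({"ovary", "midgut"}, "not_selected"),
            ({"testis"}, "not_selected"),
            (set(), "not_selected"),
        ],
    )
    def test_patterns(self, ups, expected):
        tissues = ("ovary", "testis", "cns", "midgut", "head")
        directions = {t: ("up" if t in ups else "others") for t in tissues}
        assert classify_tissue_group(directions) == expected

    def test_missing_ovary_is_an_error(self):
        with pytest.raises(ValueError):
            classify_tissue_group({"testis": "up"})


class TestFunnel:
    def test_empty_input(self):
        candidates, report = run_selection_funnel([])
        assert candidates.empty
        assert (report["n_out"] == 0).all()

    def test_counts_conserve_at_every_stage(self):
        cfg = default_config(seed=5, n_genes=60, n_planted=6)
        profiles, _ = simulate_expression(cfg)
        _, report = run_selection_funnel(profiles)
        stages = report.set_index("stage")
        # each stage consumes what the previous one produced
        assert stages.loc["symbol_filter", "n_in"] == 60
        assert (stages["n_out"] <= stages["n_in"]).all()
        assert stages.loc["present_filter", "n_in"] == \
            stages.loc["symbol_filter", "n_out"]
        assert stages.loc["collapse_probes", "n_in"] == \
            stages.loc["present_filter", "n_out"]

    def test_planted_genes_recovered(self):
        # a planted gene can drop out when a noise tissue crosses the "up"
        # cutoff (~2.5% per tissue), so recovery is high but not certain
        cfg = default_config(seed=2, n_genes=100, n_planted=10)
        profiles, truth = simulate_expression(cfg)
        candidates, _ = run_selection_funnel(profiles)
        merged = candidates.merge(truth, on="gene_id")
        planted = merged[merged["true_group"] != "not_selected"]
        assert (planted["group"] == planted["true_group"]).mean() >= 0.9
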