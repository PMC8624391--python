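"""The QTL scan: LS-means, effect classification, merging, validation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_table
from ilqtl.scan import (OVERALL, QtlScan, classify_effect, ls_means,
                        merge_to_qtl, validate_against_reference)
from ilqtl.types import AnalysisConfig, GeneticInterval, IntrogressionLine


class TestLsMeans:
    def test_balanced_equals_arithmetic_mean(self):
        table = balanced_table({"A": {"control": [9, 10, 11],
                                      "75mM": [1, 2, 3]}})
        lsm = ls_means(table, "Y").set_index(["line_id", "context"])["ls_mean"]
        assert lsm[("A", "control")] == 10.0
        assert lsm[("A", "75mM")] == 2.0
        assert lsm[("A", OVERALL)] == 6.0

    def test_missing_replicate_averages_remaining(self):
        table = balanced_table({"A": {"control": [9, 10, 11]}})
        table.loc[0, "value"] = float("nan")
        lsm = ls_means(table, "Y").set_index(["line_id", "context"])["ls_mean"]
        assert lsm[("A", "control")] == 10.5


class TestClassifyEffect:
    CFG = AnalysisConfig()

    @pytest.mark.parametrize("p_trt,p_overall,expect_int,expect_main", [
        # strict significance in a single treatment -> interaction only
        ({"control": 0.5, "75mM": 0.005, "150mM": 0.5}, 0.2, True, False),
        # all three below 0.05, none below 0.01 -> main effect only
        ({"control": 0.02, "75mM": 0.03, "150mM": 0.04}, 0.001, False, True),
        # two strict + all-three/overall -> both classes
        ({"control": 0.005, "75mM": 0.005, "150mM": 0.5}, 0.01, True, True),
        # three strict treatments -> not "one or two", main effect only
        ({"control": 0.001, "75mM": 0.001, "150mM": 0.001}, 0.9, False, True),
        # nothing significant -> no association
        ({"control": 0.5, "75mM": 0.5, "150mM": 0.5}, 0.5, False, False),
    ])
    def test_rule(self, p_trt, p_overall, expect_int, expect_main):
        ps = dict(p_trt)
        ps[OVERALL] = p_overall
        is_int, is_main, partial = classify_effect(ps, self.CFG)
        assert is_int is expect_int
        assert is_main is expect_main
        assert partial is False

    def test_missing_context_flags_partial(self):
        ps = {"control": 0.005, "75mM": 0.5, OVERALL: 0.5}
        is_int, is_main, partial = classify_effect(ps, self.CFG)
        assert is_int and not is_main and partial


def _assoc(line_id, trait="SL", sign=1, chrom="2H"):
    return {"line_id": line_id, "trait": trait, "chromosome": chrom,
            "is_interaction": True, "is_main_effect": False, "partial": False,
            "effect_sign": sign, "significant_contexts": "75mM"}


def _lib(intervals: dict[str, tuple[str, float, float]]):
    return [IntrogressionLine(lid, (GeneticInterval(*iv),))
            for lid, iv in intervals.items()]


class TestMerging:
    def test_overlapping_same_sign_merge(self):
        lib = _lib({"L1": ("2H", 33.9, 62.7), "L2": ("2H", 12.5, 41.2)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1"), _assoc("L2")]), lib)
        assert len(calls) == 1
        call = calls[0]
        assert (call.merged_interval.start, call.merged_interval.end) == (12.5, 62.7)
        assert call.member_lines == ("L1", "L2")

    def test_opposite_signs_stay_separate(self):
        lib = _lib({"L1": ("2H", 33.9, 62.7), "L2": ("2H", 12.5, 41.2)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", sign=1),
                                           _assoc("L2", sign=-1)]), lib)
        assert len(calls) == 2

    def test_disjoint_intervals_get_positional_suffixes(self):
        lib = _lib({"L1": ("6H", 94.9, 108.3), "L2": ("6H", 0.3, 11.3)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", chrom="6H"),
                                           _assoc("L2", chrom="6H")]), lib,
                             library_label="BCLIB")
        names = sorted(c.qtl_name for c in calls)
        assert names == ["QSl.BCLIB.6H.a", "QSl.BCLIB.6H.b"]
        by_name = {c.qtl_name: c for c in calls}
        assert by_name["QSl.BCLIB.6H.a"].merged_interval.start == 0.3

    def test_single_call_gets_no_suffix(self):
        lib = _lib({"L1": ("4H", 1.1, 40.0)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", trait="GP",
                                                  chrom="4H")]), lib,
                             library_label="BCLIB")
        assert calls[0].qtl_name == "QGp.BCLIB.4H"

    def test_chain_overlap_merges_transitively(self):
        lib = _lib({"A": ("5H", 0, 10), "B": ("5H", 9, 20), "C": ("5H", 19, 30)})
        calls = merge_to_qtl(pd.DataFrame([_assoc(x, chrom="5H")
                                           for x in "ABC"]), lib)
        assert len(calls) == 1
        assert calls[0].merged_interval.end == 30

    def test_mixed_sign_association_never_joins(self):
        lib = _lib({"A": ("5H", 0, 10), "B": ("5H", 5, 15)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("A", sign=0),
                                           _assoc("B", sign=1)]), lib)
        assert len(calls) == 2

    def test_order_independence(self):
        lib = _lib({"A": ("2H", 0, 10), "B": ("2H", 5, 15),
                    "C": ("2H", 40, 50), "D": ("3H", 1, 2)})
        rows = [_assoc("A"), _assoc("B"), _assoc("C"),
                _assoc("D", chrom="3H")]
        ref = merge_to_qtl(pd.DataFrame(rows), lib)
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            alt = merge_to_qtl(pd.DataFrame([rows[i] for i in perm]), lib)
            assert [(c.qtl_name, c.member_lines) for c in alt] \
                == [(c.qtl_name, c.member_lines) for c in ref]

    def test_multi_chromosome_line_yields_candidate_per_chromosome(self):
        lib = [IntrogressionLine("A", (GeneticInterval("1H", 0, 10),
                                       GeneticInterval("2H", 0, 10)))]
        with pytest.warns(UserWarning, match="multiple"):
            calls = merge_to_qtl(
                pd.DataFrame([_assoc("A", chrom="1H+2H")]), lib)
        assert {c.chromosome for c in calls} == {"1H", "2H"}


class TestValidation:
    def test_marker_inside_call_matches(self):
        lib = _lib({"L1": ("5H", 138.5, 162.5)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", chrom="5H")]), lib)
        ref = pd.DataFrame([{"chromosome": "5H", "position": 156.0,
                             "label": "markerX"}])
        report = validate_against_reference(calls, ref)
        assert len(report) == 1
        assert report.iloc[0]["reference_label"] == "markerX"

    def test_other_chromosome_no_match(self):
        lib = _lib({"L1": ("5H", 138.5, 162.5)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", chrom="5H")]), lib)
        ref = pd.DataFrame([{"chromosome": "2H", "position": 156.0}])
        assert validate_against_reference(calls, ref).empty

    def test_empty_reference_empty_report(self):
        lib = _lib({"L1": ("5H", 0.0, 10.0)})
        calls = merge_to_qtl(pd.DataFrame([_assoc("L1", chrom="5H")]), lib)
        ref = pd.DataFrame(columns=["chromosome", "position"])
        assert validate_against_reference(calls, ref).empty


class TestQtlScanEnd2End:
    def test_gxt_only_effect_classified_as_interaction(self):
        """A salt-only planted shift strong in one treatment but diluted in
        the treatment-pooled comparison is an interaction, not a main
        effect."""
        rng = np.random.default_rng(0)
        lines = {f"L{i}": ("2H", 10.0 * i, 10.0 * i + 5) for i in range(10)}
        lib = _lib(lines)
        rows = []
        for lid in list(lines) + ["Scarlett"]:
            for trt in ("control", "75mM", "150mM"):
                shift = 3.5 if (lid == "L3" and trt == "150mM") else 0.0
                for rep in range(1, 4):
                    rows.append({"line_id": lid, "treatment": trt,
                                 "replicate": rep, "trait": "SL",
                                 "value": 20.0 + shift + rng.normal(0, 1)})
        res = QtlScan(pd.DataFrame(rows), lib, AnalysisConfig()).fit()
        hit = res.associations[res.associations.line_id == "L3"]
        assert len(hit) == 1
        assert bool(hit.iloc[0]["is_interaction"])
        assert not bool(hit.iloc[0]["is_main_effect"])

    def test_zero_noise_no_effects_zero_calls(self):
        lines = {f"L{i}": ("1H", 5.0 * i, 5.0 * i + 3) for i in range(5)}
        lib = _lib(lines)
        rows = [{"line_id": lid, "treatment": trt, "replicate": rep,
                 "trait": "SL", "value": 20.0}
                for lid in list(lines) + ["Scarlett"]
                for trt in ("control", "75mM", "150mM")
                for rep in range(1, 4)]
        res = QtlScan(pd.DataFrame(rows), lib, AnalysisConfig()).fit()
        assert res.n_associations == 0
        assert res.n_qtl == 0

    def test_association_count_bounds_qtl_count(self, small_experiment,
                                                default_config):
        phen = small_experiment.phenotypes
        traits = [t for t in sorted(phen["trait"].unique())
                  if t not in ("GI", "MGT")]
        res = QtlScan(phen, small_experiment.library, default_config,
                      traits=traits).fit()
        assert res.n_associations >= res.n_qtl
        # every emitted association has at least one significant context
        assert (res.associations["significant_contexts"].str.len() > 0).all()

    def test_control_line_must_exist(self, small_experiment):
        phen = small_experiment.phenotypes
        bad = phen[phen.line_id != "Scarlett"]
        with pytest.raises(ValueError, match="control line"):
            QtlScan(bad, small_experiment.library, AnalysisConfig())
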