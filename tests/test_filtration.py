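"""Differential peak filtration rules and duplicate-ion merging."""
import numpy as np
import pytest

from dacmet.filtration import (FiltrationParams, filter_candidates,
                               merge_duplicate_ions)

from conftest import make_design, make_table

DESIGN = make_design()
POST = [s for s in DESIGN.sample_ids if "h" in s]
ALL_POST = {s: 5000.0 for s in POST}


def _peak(pid, intens, mass=300.0, rt=5.0, mode="positive"):
    return (pid, mode, mass, rt, intens)


class TestFilterCandidates:
    def test_good_peak_kept(self):
        # detected post-only in 3 of 4 subjects at 2 h, max intensity 5000
        intens = {f"S{i}_2h": 5000.0 for i in (1, 2, 3)}
        table = make_table([_peak("P1", intens)], DESIGN.sample_ids)
        kept, report = filter_candidates(table, DESIGN)
        assert kept == ["P1"]
        assert report.status["P1"] == "kept"

    def test_mock_detection_excludes(self):
        intens = dict(ALL_POST, MOCK1=200.0)
        table = make_table([_peak("P1", intens)], DESIGN.sample_ids)
        kept, report = filter_candidates(table, DESIGN)
        assert kept == []
        assert report.first_failing_rule["P1"] == "detected_in_mock"

    def test_pre_dose_detection_excludes(self):
        intens = dict(ALL_POST, S2_pre=300.0)
        table = make_table([_peak("P1", intens)], DESIGN.sample_ids)
        _, report = filter_candidates(table, DESIGN)
        assert report.first_failing_rule["P1"] == "detected_pre_dose"

    def test_sporadic_detection_excludes(self):
        table = make_table([_peak("P1", {"S1_2h": 5000.0})], DESIGN.sample_ids)
        _, report = filter_candidates(table, DESIGN)
        assert report.first_failing_rule["P1"] == "min_samples_detected"

    def test_minority_excludes(self):
        # 2 of 4 subjects at every timepoint: never a strict majority
        intens = {f"S{i}_{tp:g}h": 5000.0
                  for i in (1, 2) for tp in (0.25, 0.5, 1, 2, 4, 8)}
        table = make_table([_peak("P1", intens)], DESIGN.sample_ids)
        _, report = filter_candidates(table, DESIGN)
        assert report.first_failing_rule["P1"] == "no_majority_timepoint"

    def test_ion_count_boundary(self):
        low = {f"S{i}_2h": 999.0 for i in (1, 2, 3)}
        at = {f"S{i}_2h": 1000.0 for i in (1, 2, 3)}
        table = make_table([_peak("P1", low), _peak("P2", at, mass=310.0)],
                           DESIGN.sample_ids)
        kept, report = filter_candidates(table, DESIGN)
        assert kept == ["P2"]
        assert report.first_failing_rule["P1"] == "below_min_ion_count"

    def test_report_accounting(self):
        rows = [
            _peak("P1", ALL_POST),
            _peak("P2", dict(ALL_POST, MOCK2=10.0), mass=310.0),
            _peak("P3", {"S1_4h": 2000.0}, mass=320.0),
            _peak("P4", dict(ALL_POST, S1_pre=5.0), mass=330.0),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        kept, report = filter_candidates(table, DESIGN)
        assert report.n_kept + report.n_excluded == len(table)
        assert sum(report.counts.values()) == report.n_excluded

    def test_monotone_in_min_ion_count(self):
        rows = [_peak(f"P{i}", {f"S{j}_2h": 500.0 * i for j in (1, 2, 3)},
                      mass=300.0 + i) for i in range(1, 8)]
        table = make_table(rows, DESIGN.sample_ids)
        kept_sets = []
        for threshold in (500.0, 1000.0, 2000.0, 3000.0):
            kept, _ = filter_candidates(
                table, DESIGN, FiltrationParams(min_ion_count=threshold))
            kept_sets.append(set(kept))
        for small, big in zip(kept_sets[1:], kept_sets):
            assert small <= big

    def test_deterministic_under_row_order(self):
        rows = [_peak(f"P{i}", ALL_POST, mass=300.0 + i) for i in range(5)]
        table_fwd = make_table(rows, DESIGN.sample_ids)
        table_rev = make_table(rows[::-1], DESIGN.sample_ids)
        kept_fwd, _ = filter_candidates(table_fwd, DESIGN)
        kept_rev, _ = filter_candidates(table_rev, DESIGN)
        assert kept_fwd == kept_rev

    def test_missing_mock_class_skips_rule(self, caplog):
        design = make_design(n_mock=0)
        table = make_table([_peak("P1", ALL_POST)], design.sample_ids)
        with caplog.at_level("WARNING"):
            kept, report = filter_candidates(table, design)
        assert kept == ["P1"]
        assert "detected_in_mock" in report.skipped_rules

    def test_sample_missing_from_design_rejected(self):
        table = make_table([_peak("P1", ALL_POST)],
                           DESIGN.sample_ids + ["MYSTERY"])
        with pytest.raises(ValueError, match="MYSTERY"):
            filter_candidates(table, DESIGN)


class TestMergeDuplicateIons:
    def test_opposite_modes_same_mass_merge(self):
        rows = [
            _peak("P1", ALL_POST, mass=432.10565, rt=8.30),
            _peak("N1", {s: 1000.0 for s in POST}, mass=432.10565, rt=8.35,
                  mode="negative"),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        groups = merge_duplicate_ions(table, ["P1", "N1"])
        assert groups == [["P1", "N1"]]  # representative (most intense) first

    def test_same_mode_never_mass_merged(self):
        rows = [
            _peak("P1", ALL_POST, mass=432.10565, rt=8.30),
            _peak("P2", ALL_POST, mass=432.10565, rt=8.35),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        groups = merge_duplicate_ions(table, ["P1", "P2"])
        assert len(groups) == 2

    def test_rt_gap_blocks_merge(self):
        rows = [
            _peak("P1", ALL_POST, mass=432.10565, rt=8.30),
            _peak("N1", ALL_POST, mass=432.10565, rt=8.60, mode="negative"),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        assert len(merge_duplicate_ions(table, ["P1", "N1"])) == 2

    def test_declared_relation_merges(self):
        # an in-source fragment shares RT but not mass; the user declares it
        rows = [
            _peak("P1", ALL_POST, mass=432.10565, rt=8.30),
            _peak("P2", ALL_POST, mass=256.07356, rt=8.31),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        groups = merge_duplicate_ions(table, ["P1", "P2"],
                                      relations=[("P1", "P2")])
        assert len(groups) == 1

    def test_exception_pair_never_merges(self):
        rows = [
            _peak("P1", ALL_POST, mass=165.11536, rt=4.00),
            _peak("N1", ALL_POST, mass=165.11536, rt=4.05, mode="negative"),
        ]
        table = make_table(rows, DESIGN.sample_ids)
        groups = merge_duplicate_ions(table, ["N1", "P1"],
                                      exceptions=[("P1", "N1")])
        assert len(groups) == 2

    def test_group_count_identity(self):
        # n kept peaks with k alternate ion forms -> n - k groups
        rows, kept = [], []
        for i in range(10):
            rows.append(_peak(f"P{i}", ALL_POST, mass=300.0 + 10 * i, rt=5.0))
            kept.append(f"P{i}")
        for i in range(3):  # alternates of the first three
            rows.append(_peak(f"N{i}", {s: 100.0 for s in POST},
                              mass=300.0 + 10 * i, rt=5.02, mode="negative"))
            kept.append(f"N{i}")
        table = make_table(rows, DESIGN.sample_ids)
        assert len(merge_duplicate_ions(table, kept)) == 13 - 3
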