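"""Differential peak filtration and duplicate-ion merging.

The filtration step selects administration-dependent peaks from the aligned
feature table: a candidate must be reproducibly detected, absent from the
solvent blanks (mock) and from every pre-dose sample, appear in a strict
majority of subjects at at least one post-dose timepoint, and clear a
minimum ion-count threshold.  Rules are evaluated in a fixed order and the
first failing rule is recorded per peak, giving a machine-readable audit
trail in place of a manual chromatogram review.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import FeatureTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "FiltrationParams",
    "FiltrationReport",
    "filter_candidates",
    "merge_duplicate_ions",
]

RULES = (
    "min_samples_detected",   # (i)  detected in >= N samples overall
    "detected_in_mock",       # (ii) never detected in any mock sample
    "detected_pre_dose",      # (iii) never detected pre-administration
    "no_majority_timepoint",  # (iv) strict majority of subjects at >=1 timepoint
    "below_min_ion_count",    # (v)  max post intensity >= threshold
)


@dataclass
class FiltrationParams:
    """Thresholds for differential peak filtration.

    ``post_fraction`` is the subject fraction that must be *exceeded*
    (strict majority by default) at at least one post timepoint.
    ``min_ion_count`` applies to the maximum intensity across post samples.
    """

    min_samples_detected: int = 2
    min_ion_count: float = 1000.0
    post_fraction: float = 0.5
    rt_merge_tol: float = 0.2          # minutes
    merge_ppm: float = 5.0
    merge_exceptions: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.min_samples_detected <= 0 or self.min_ion_count <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.post_fraction <= 1):
            raise ValueError("post_fraction must be in (0, 1]")
        if self.rt_merge_tol <= 0 or self.merge_ppm <= 0:
            raise ValueError("merge tolerances must be positive")
        self.merge_exceptions = frozenset(
            frozenset(pair) for pair in self.merge_exceptions)


@dataclass
class FiltrationReport:
    """Per-peak keep/exclude status with the first failing rule."""

    status: dict[str, str] = field(default_factory=dict)          # kept | excluded
    first_failing_rule: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    skipped_rules: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(1 for s in self.status.values() if s == "kept")

    @property
    def n_excluded(self) -> int:
        return sum(1 for s in self.status.values() if s == "excluded")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "peak_id": list(self.status),
            "status": list(self.status.values()),
            "first_failing_rule": [self.first_failing_rule.get(p, "")
                                   for p in self.status],
        })


def filter_candidates(table: FeatureTable, design: SampleDesign,
                      params: FiltrationParams = FiltrationParams(),
                      ) -> tuple[list[str], FiltrationReport]:
    """Select administration-dependent candidate peaks.

    A peak is kept iff, in order:

    (i)   it is detected in at least ``min_samples_detected`` samples;
    (ii)  it is never detected in any mock (solvent blank) sample;
    (iii) it is never detected in any pre-dose sample of any subject;
    (iv)  at >=1 post timepoint it is detected in strictly more than
          ``post_fraction`` of subjects;
    (v)   its maximum intensity across post samples >= ``min_ion_count``.

    A rule whose sample class is absent from the design (e.g. no mocks)
    is skipped with a warning and recorded in the report.
    """
    missing = set(design.sample_ids) - set(table.sample_ids)
    if set(table.sample_ids) - set(design.sample_ids):
        extra = sorted(set(table.sample_ids) - set(design.sample_ids))
        raise ValueError(f"sample(s) missing from design: {', '.join(extra)}")
    if missing:
        logger.warning("design sample(s) absent from table: %s",
                       ", ".join(sorted(missing)))

    detected = table.detected()
    mock_samples = [s for s in design.samples_of_class("mock")
                    if s in detected.columns]
    pre_samples = [s for s in design.samples_of_class("pre")
                   if s in detected.columns]
    post_samples = [s for s in design.samples_of_class("post")
                    if s in detected.columns]
    subjects = design.subjects

    report = FiltrationReport(counts={r: 0 for r in RULES})
    if not mock_samples:
        logger.warning("no mock samples in design; mock rule skipped")
        report.skipped_rules.append("detected_in_mock")
    if not pre_samples:
        logger.warning("no pre samples in design; pre-dose rule skipped")
        report.skipped_rules.append("detected_pre_dose")

    # subject of each post sample, grouped by timepoint
    tp_subjects: dict[float, dict[str, str]] = {}
    for s in post_samples:
        row = design.frame.loc[s]
        tp_subjects.setdefault(float(row["timepoint"]), {})[s] = str(row["subject"])

    kept: list[str] = []
    for peak_id in sorted(table.peak_ids):  # deterministic under row order
        det = detected.loc[peak_id]
        failing = None
        if det.sum() < params.min_samples_detected:
            failing = "min_samples_detected"
        elif mock_samples and det[mock_samples].any():
            failing = "detected_in_mock"
        elif pre_samples and det[pre_samples].any():
            failing = "detected_pre_dose"
        else:
            majority = False
            for tp, sample_subject in tp_subjects.items():
                hit = {subj for s, subj in sample_subject.items() if det[s]}
                if len(hit) > params.post_fraction * len(subjects):
                    majority = True
                    break
            if not majority:
                failing = "no_majority_timepoint"
            else:
                post_max = table.intensity.loc[peak_id, post_samples].max()
                if not post_max >= params.min_ion_count:
                    failing = "below_min_ion_count"
        if failing is None:
            report.status[peak_id] = "kept"
            kept.append(peak_id)
        else:
            report.status[peak_id] = "excluded"
            report.first_failing_rule[peak_id] = failing
            report.counts[failing] += 1
    return kept, report


def merge_duplicate_ions(table: FeatureTable, kept: Sequence[str],
                         rt_tol: float = 0.2, ppm: float = 5.0,
                         relations: Iterable[tuple[str, str]] = (),
                         exceptions: Iterable[frozenset] = (),
                         ) -> list[list[str]]:
    """Collapse alternate ion forms of the same metabolite into groups.

    Two kept peaks merge when they co-elute within ``rt_tol`` minutes and
    their deionized neutral masses agree within ``ppm`` across *opposite*
    ion modes, or when the pair is declared in ``relations`` (adduct or
    in-source-fragment links the user asserts).  Pairs listed in
    ``exceptions`` (e.g. ephedrine/pseudoephedrine, which co-elute at the
    same mass but are distinct compounds) never merge.

    Returns groups ordered by the most intense member, each group sorted by
    descending maximum intensity (the representative peak first).
    """
    exceptions = {frozenset(p) for p in exceptions}
    kept = sorted(kept)
    peaks = [table.peaks[pid] for pid in kept]
    max_int = table.intensity.loc[kept].max(axis=1).fillna(0.0)

    parent = {pid: pid for pid in kept}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def group_of(x: str) -> set[str]:
        root = find(x)
        return {p for p in kept if find(p) == root}

    def union_ok(a: str, b: str) -> None:
        # refuse any link that would bring an exception pair together
        merged = group_of(a) | group_of(b)
        for pair in exceptions:
            if pair <= merged:
                return
        parent[find(a)] = find(b)

    links: list[tuple[str, str]] = []
    for i, pa in enumerate(peaks):
        for pb in peaks[i + 1:]:
            if abs(pa.rt - pb.rt) > rt_tol:
                continue
            if pa.ion_mode == pb.ion_mode:
                continue
            heavier = max(pa.neutral_mass, pb.neutral_mass)
            if abs(pa.neutral_mass - pb.neutral_mass) / heavier * 1e6 <= ppm:
                links.append((pa.peak_id, pb.peak_id))
    for a, b in relations:
        if a in parent and b in parent:
            links.append((a, b))

    for a, b in sorted(links):
        if frozenset((a, b)) in exceptions:
            continue
        union_ok(a, b)

    groups: dict[str, list[str]] = {}
    for pid in kept:
        groups.setdefault(find(pid), []).append(pid)
    ordered = [sorted(members, key=lambda p: (-max_int[p], p))
               for members in groups.values()]
    ordered.sort(key=lambda g: (-max_int[g[0]], g[0]))
    return ordered
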