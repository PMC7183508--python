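"""Deterministic synthetic-experiment generator with planted ground truth.

Emits a complete multi-subject pre/post time-series experiment in the
canonical formats — feature table, sample design, MS/MS peak lists,
isotopologue patterns, annotation table — together with the planted
conjugation network, so every pipeline stage is testable end to end
without any external data.

The emulated study: four subjects dosed with a four-herb extract, plasma
sampled pre-dose and at 0.25, 0.5, 1, 2, 4 and 8 h; solvent blanks (mock),
one extract sample, and single-herb rat plasma at 1 h for origin
attribution.  Source compounds carry log-normal-shaped time profiles;
phase-II conjugates track their source's kinetics with an RT shifted by
the reaction's characteristic amount; sulfates carry a ³⁴S isotopologue
and an 80-Da neutral loss in MS/MS.  Decoy peaks violate the filtration
rules in controlled ways (background, blank contamination, sporadic,
minority, sub-threshold).

Noise model: each acquisition observes a peak's m/z with a relative error
of ``mass_noise_ppm`` (sd); the feature table reports the mean m/z over
the samples in which the peak was detected, as an aligned feature table
does, so the feature-level mass error shrinks with detection count.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (PROTON_MASS, S34_ABUNDANCE, S34_OFFSET, ElementalFormula,
                   ReactionDelta, default_reaction_table)
from .io import (AnnotationTable, FeatureTable, MsmsSpectrum, Peak,
                 SampleDesign, write_annotation_table, write_feature_table,
                 write_isotope_patterns, write_msms_mgf, write_sample_design)

__all__ = [
    "FixtureSpec",
    "PlantedMetabolite",
    "GroundTruth",
    "FixtureSet",
    "generate_fixture",
    "subnetwork_a_fixture",
    "write_fixture",
]

C13_OFFSET = 1.003355
C13_ABUNDANCE = 0.0107

#: (name, formula, herb, peak time h, profile width, in extract)
SOURCE_LIBRARY: tuple[tuple[str, str, str, float, float, bool], ...] = (
    ("liquiritigenin", "C15H12O4", "licorice", 4.0, 0.8, True),
    ("glycyrrhetinic acid", "C30H46O4", "licorice", 8.0, 0.9, False),
    ("7-hydroxycoumarin", "C9H6O3", "cinnamon", 1.0, 0.7, True),
    ("eugenol", "C10H12O2", "cinnamon", 0.5, 0.7, True),
    ("ephedrine", "C10H15NO", "ephedra", 0.5, 0.6, True),
    ("prunasin", "C14H17NO6", "apricot", 1.0, 0.8, True),
    ("cinnamic acid", "C9H8O2", "cinnamon", 0.5, 0.7, True),
    ("naringenin", "C15H12O5", "licorice", 2.0, 0.8, True),
)

DECOY_KINDS = ("background", "mock_contaminant", "sporadic",
               "minority", "sub_threshold")

CONJUGATE_NOUN = {
    "glucuronidation": "glucuronide",
    "sulfation": "sulfate",
    "glycine conjugation": "glycine conjugate",
    "glutamine conjugation": "glutamine conjugate",
    "glutathione conjugation": "glutathione conjugate",
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic experiment.

    Defaults mirror the emulated study: 4 subjects, 6 post timepoints,
    per-acquisition mass error of 2 ppm (sd), conjugate RT shifts drawn
    around each reaction's calibrated reference shift with 0.15 min jitter
    (well inside the windows).
    """

    seed: int = 1
    n_subjects: int = 4
    timepoints: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_source_compounds: int = 5
    conjugates_per_source: int = 2
    conjugate_reactions: tuple[str, ...] = ("glucuronidation", "sulfation")
    rt_shift_model: dict = field(default_factory=lambda: {
        "glucuronidation": (-1.9, 0.15),
        "sulfation": (-1.4, 0.15),
        "glycine conjugation": (1.0, 0.5),
        "glutamine conjugation": (1.0, 0.5),
        "glutathione conjugation": (1.0, 0.5),
    })
    mass_noise_ppm: float = 2.0
    rt_noise_sd: float = 0.0           # extra per-peak RT jitter, minutes
    intensity_noise_sd: float = 0.2    # log-normal multiplicative
    n_decoy_peaks: int = 30
    coincident_decoys: int = 0         # decoys placed AT a delta on purpose
    include_mock: bool = True
    include_extract: bool = True
    include_herbs: bool = True
    detection_limit: float = 100.0
    min_ion_count: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_source_compounds == 0 and self.conjugates_per_source > 0:
            raise ValueError("conjugates requested without any source compound")
        if self.n_source_compounds < 0 or self.conjugates_per_source < 0:
            raise ValueError("counts must be non-negative")
        if self.n_source_compounds > len(SOURCE_LIBRARY):
            raise ValueError(
                f"at most {len(SOURCE_LIBRARY)} source compounds available")


@dataclass
class PlantedMetabolite:
    """Ground-truth record for one planted compound."""

    name: str
    formula: ElementalFormula | None
    neutral_mass: float
    rt: float
    peak_ids: list[str]
    origin: set[str]
    in_extract: bool
    is_maoto_derived: bool
    tmax: float = 1.0
    width: float = 0.8
    amplitude: float = 1e4


@dataclass
class GroundTruth:
    """Planted metabolites, edges and flags the pipeline should recover."""

    metabolites: list[PlantedMetabolite]
    edges: list[tuple[str, str, str]]       # (source name, product name, reaction)
    merge_exception_pairs: list[tuple[str, str]] = field(default_factory=list)

    def metabolite(self, name: str) -> PlantedMetabolite:
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def maoto_peak_ids(self) -> set[str]:
        return {pid for m in self.metabolites if m.is_maoto_derived
                for pid in m.peak_ids}

    def edge_pairs(self) -> set[frozenset]:
        """Planted edges as unordered peak-id-set pairs."""
        pairs = set()
        for src, dst, _ in self.edges:
            pairs.add(frozenset((self.metabolite(src).name,
                                 self.metabolite(dst).name)))
        return pairs


@dataclass
class FixtureSet:
    """Everything :func:`generate_fixture` emits."""

    feature_table: FeatureTable
    design: SampleDesign
    msms: dict[str, MsmsSpectrum]
    isotopes: dict[str, list[tuple[float, float]]]
    annotations: AnnotationTable
    ground_truth: GroundTruth


def _profile(t: float, tmax: float, width: float) -> float:
    """Log-normal-shaped concentration-time profile, peak value 1 at tmax."""
    if t <= 0:
        return 0.0
    return float(np.exp(-(np.log(t / tmax)) ** 2 / (2 * width ** 2)))


def _build_design(spec: FixtureSpec) -> SampleDesign:
    rows = []
    for i in range(spec.n_subjects):
        subj = f"S{i + 1}"
        rows.append({"sample_id": f"{subj}_pre", "subject": subj,
                     "class": "pre", "timepoint": np.nan, "herb": ""})
        for tp in spec.timepoints:
            rows.append({"sample_id": f"{subj}_{tp:g}h", "subject": subj,
                         "class": "post", "timepoint": tp, "herb": ""})
    if spec.include_mock:
        for j in (1, 2):
            rows.append({"sample_id": f"MOCK{j}", "subject": "mock",
                         "class": "mock", "timepoint": np.nan, "herb": ""})
    if spec.include_extract:
        rows.append({"sample_id": "EXTRACT", "subject": "extract",
                     "class": "extract", "timepoint": np.nan, "herb": ""})
    if spec.include_herbs:
        for herb in ("ephedra", "apricot", "cinnamon", "licorice"):
            rows.append({"sample_id": f"HERB_{herb}", "subject": f"rat_{herb}",
                         "class": "herb_plasma", "timepoint": np.nan,
                         "herb": herb})
    return SampleDesign(pd.DataFrame(rows))


def _delta_coincident(candidate: float, existing: list[float],
                      deltas: list[float], guard_ppm: float = 25.0) -> bool:
    for mass in existing:
        heavier = max(candidate, mass)
        diff = abs(candidate - mass)
        if diff / heavier * 1e6 <= guard_ppm:   # near-duplicate mass
            return True
        for delta in deltas:
            if abs(diff - delta) / heavier * 1e6 <= guard_ppm:
                return True
    return False


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> FixtureSet:
    """Generate the full synthetic experiment for a :class:`FixtureSpec`.

    All randomness flows from ``spec.seed`` through one generator, so a
    fixed spec reproduces byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    design = _build_design(spec)
    reactions = {r.name: r for r in default_reaction_table()}

    subj_factor = {f"S{i + 1}": rng.uniform(0.6, 1.4)
                   for i in range(spec.n_subjects)}

    metabolites: list[PlantedMetabolite] = []
    edges: list[tuple[str, str, str]] = []

    for i in range(spec.n_source_compounds):
        name, formula_s, herb, tmax, width, in_extract = SOURCE_LIBRARY[i]
        formula = ElementalFormula.parse(formula_s)
        rt = rng.uniform(3.5, 12.0)
        amp = 10 ** rng.uniform(4.0, 5.5)
        metabolites.append(PlantedMetabolite(
            name=name, formula=formula, neutral_mass=formula.mass, rt=rt,
            peak_ids=[], origin={herb}, in_extract=in_extract,
            is_maoto_derived=True, tmax=tmax, width=width, amplitude=amp))
        for j in range(spec.conjugates_per_source):
            rname = spec.conjugate_reactions[j % len(spec.conjugate_reactions)]
            reaction = reactions[rname]
            mean_shift, jitter = spec.rt_shift_model.get(rname, (0.0, 0.3))
            shift = rng.normal(mean_shift, jitter)
            conj_formula = formula + reaction.gained_formula
            conj_name = f"{name} {CONJUGATE_NOUN.get(rname, rname)}"
            if spec.conjugates_per_source > len(set(spec.conjugate_reactions)):
                conj_name += f" #{j + 1}"
            metabolites.append(PlantedMetabolite(
                name=conj_name, formula=conj_formula,
                neutral_mass=conj_formula.mass,
                rt=max(0.5, rt + shift),
                peak_ids=[], origin={herb}, in_extract=False,
                is_maoto_derived=True, tmax=tmax, width=width,
                amplitude=amp * rng.uniform(0.5, 1.5)))
            edges.append((name, conj_name, rname))

    # decoys: rejection-sampled masses that coincide with no planted mass
    # and form no reaction-delta pair, unless coincident ones are requested
    delta_values = [r.delta_mass for r in reactions.values()]
    existing = [m.neutral_mass for m in metabolites]
    decoys: list[tuple[str, float, str]] = []   # (kind, mass, name)
    for d in range(spec.n_decoy_peaks):
        kind = DECOY_KINDS[d % len(DECOY_KINDS)]
        coincident = d < spec.coincident_decoys and existing
        if coincident:
            anchor = existing[int(rng.integers(len(existing)))]
            delta = delta_values[int(rng.integers(len(delta_values)))]
            mass = anchor + delta + rng.normal(0, 1e-6 * anchor)
        else:
            for _ in range(1000):
                mass = rng.uniform(150.0, 650.0)
                if not _delta_coincident(mass, existing, delta_values):
                    break
            else:  # pragma: no cover - rejection sampling exhausted
                raise RuntimeError("could not place a non-coincident decoy")
        existing.append(mass)
        decoys.append((kind, mass, f"decoy_{kind}_{d}"))

    # --- assemble the intensity matrix -----------------------------------
    samples = design.sample_ids
    post_frame = design.frame[design.frame["class"] == "post"]
    herb_samples = design.herb_samples()
    noise = spec.intensity_noise_sd

    def lognoise() -> float:
        return float(np.exp(rng.normal(0.0, noise))) if noise > 0 else 1.0

    rows: list[dict[str, float]] = []
    peak_meta: list[tuple[str, float, float]] = []   # (owner name, mass, rt)

    for m in metabolites:
        row: dict[str, float] = {}
        for s in post_frame.itertuples():
            value = (m.amplitude * subj_factor[str(s.subject)]
                     * _profile(float(s.timepoint), m.tmax, m.width) * lognoise())
            if value >= spec.detection_limit:
                row[s.sample_id] = value
        if spec.include_extract and m.in_extract:
            row["EXTRACT"] = m.amplitude * rng.uniform(0.5, 2.0)
        if spec.include_herbs:
            for herb in m.origin:
                for sid in herb_samples.get(herb, []):
                    row[sid] = max(m.amplitude * _profile(1.0, m.tmax, m.width)
                                   * lognoise(), 2 * spec.detection_limit)
        rows.append(row)
        peak_meta.append((m.name, m.neutral_mass, m.rt))

    subjects = [f"S{i + 1}" for i in range(spec.n_subjects)]
    decoy_records: list[PlantedMetabolite] = []
    for kind, mass, name in decoys:
        rt = rng.uniform(0.5, 14.0)
        amp = 10 ** rng.uniform(3.2, 5.0)
        row = {}
        if kind == "background":
            human = design.frame[design.frame["class"].isin(("pre", "post"))]
            for sid in human["sample_id"]:
                row[sid] = amp * lognoise()
        elif kind == "mock_contaminant":
            row["MOCK1"] = amp * lognoise()
            row["MOCK2"] = amp * lognoise()
            for s in post_frame.itertuples():
                if rng.random() < 0.5:
                    row[s.sample_id] = amp * lognoise()
        elif kind == "sporadic":
            s = post_frame.iloc[int(rng.integers(len(post_frame)))]
            row[s["sample_id"]] = amp * lognoise()
        elif kind == "minority":
            chosen = subjects[: max(1, spec.n_subjects // 2)]
            for s in post_frame.itertuples():
                if str(s.subject) in chosen:
                    row[s.sample_id] = amp * lognoise()
        elif kind == "sub_threshold":
            small = rng.uniform(150.0, 600.0)
            for s in post_frame.itertuples():
                value = min(small * lognoise(), spec.min_ion_count - 1.0)
                if value >= spec.detection_limit:
                    row[s.sample_id] = value
        rows.append(row)
        peak_meta.append((name, mass, rt))
        decoy_records.append(PlantedMetabolite(
            name=name, formula=None, neutral_mass=mass, rt=rt, peak_ids=[],
            origin=set(), in_extract=False, is_maoto_derived=False))

    # --- peaks: ion mode, ids, consensus m/z ------------------------------
    peaks: list[Peak] = []
    peak_rows: list[dict[str, float]] = []
    all_records = metabolites + decoy_records
    counters = {"positive": 1000, "negative": 1000}
    for record, row, (name, mass, rt) in zip(all_records, rows, peak_meta):
        mode = "positive" if rng.random() < 0.5 else "negative"
        counters[mode] += int(rng.integers(1, 9))
        peak_id = ("P" if mode == "positive" else "N") + str(counters[mode])
        sign = 1.0 if mode == "positive" else -1.0
        mz_true = mass + sign * PROTON_MASS
        n_det = max(1, len(row))
        if spec.mass_noise_ppm > 0:
            err = rng.normal(0.0, spec.mass_noise_ppm * 1e-6, size=n_det).mean()
        else:
            err = 0.0
        mz_obs = mz_true * (1.0 + err)
        rt_obs = rt + (rng.normal(0.0, spec.rt_noise_sd)
                       if spec.rt_noise_sd > 0 else 0.0)
        adduct = "[M+H]+" if mode == "positive" else "[M-H]-"
        peaks.append(Peak(peak_id, mode, mz_obs, adduct, max(0.1, rt_obs),
                          mz_obs - sign * PROTON_MASS))
        record.peak_ids.append(peak_id)
        peak_rows.append(row)

    intensity = pd.DataFrame(
        [[row.get(s, np.nan) for s in samples] for row in peak_rows],
        index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
        columns=samples)
    table = FeatureTable(peaks, intensity)

    # --- spectra and isotope patterns -------------------------------------
    msms: dict[str, MsmsSpectrum] = {}
    isotopes: dict[str, list[tuple[float, float]]] = {}
    conj_reaction = {dst: r for _, dst, r in edges}
    for m in metabolites:
        peak_id = m.peak_ids[0]
        peak = table.peaks[peak_id]
        pattern = []
        n_c = m.formula["C"] if m.formula else 0
        n_s = m.formula["S"] if m.formula else 0
        if n_c:
            pattern.append((C13_OFFSET + rng.normal(0, 5e-4),
                            n_c * C13_ABUNDANCE * (1 + rng.normal(0, 0.05))))
            pattern.append((2 * C13_OFFSET + rng.normal(0, 5e-4),
                            (n_c * C13_ABUNDANCE) ** 2 / 2))
        if n_s:
            pattern.append((S34_OFFSET + rng.normal(0, 2e-3),
                            n_s * S34_ABUNDANCE * (1 + rng.normal(0, 0.05))))
        if pattern:
            isotopes[peak_id] = sorted(pattern)
        reaction_name = conj_reaction.get(m.name)
        fragments = [(rng.uniform(60.0, peak.mz - 20.0), rng.uniform(5, 40))
                     for _ in range(2)]
        if reaction_name is not None:
            loss = reactions[reaction_name].gained_formula.mass
            fragments.append((peak.mz - loss + rng.normal(0, 0.01),
                              rng.uniform(40, 100)))
        msms[peak_id] = MsmsSpectrum(peak.mz, sorted(fragments))

    # --- annotation table: authentic standards for the sources ------------
    ann_rows = []
    for m in metabolites:
        if m.formula is not None and m.name in {e[0] for e in edges} | {
                s[0] for s in SOURCE_LIBRARY}:
            ann_rows.append({"name": m.name, "formula": m.formula.hill(),
                             "origin": ";".join(sorted(m.origin)),
                             "rt": round(m.rt, 3), "msi_level": ""})
    if not ann_rows:
        ann_rows.append({"name": "placeholder", "formula": "C6H12O6",
                         "origin": "", "rt": np.nan, "msi_level": ""})
    annotations = AnnotationTable(pd.DataFrame(ann_rows))

    truth = GroundTruth(metabolites=metabolites + decoy_records, edges=edges)
    return FixtureSet(table, design, msms, isotopes, annotations, truth)


def subnetwork_a_fixture() -> FixtureSet:
    """The licorice subnetwork-A preset: a fully specified 8-metabolite family.

    Liquiritin and isoliquiritin (418 Da glycosides) are hydrolyzed by the
    gut microbiome to their aglycones liquiritigenin (LG) and
    isoliquiritigenin (ILG, both 256 Da), which are conjugated to a sulfate
    (336 Da), two glucuronides (432 Da) and a glucuronide-sulfate (512 Da).
    RT placement encodes the observed shifts: the 336 and 432 Da conjugates
    sit 1.3 and 1.7 min before LG (2.8 and 3.2 min before ILG), so the
    window check keeps the LG pairs and the ILG sulfation pair but rejects
    the -3.2 min ILG glucuronidation pair.  The 432 Da LG conjugate is
    observed in both ion modes (P8722/N6061) to exercise duplicate-ion
    merging, and an ephedrine/pseudoephedrine pair exercises the
    co-elution merge exception.  Everything is noise-free and fixed.
    """
    lg_rt, ilg_rt = 9.0, 10.5     # ILG - LG offset = 1.5 min
    plan = [
        # name, formula, rt, tmax, amplitude, in_extract, peak ids
        ("liquiritin", "C21H22O9", 7.0, 0.5, 60000.0, True, ["N4100"]),
        ("isoliquiritin", "C21H22O9", 8.2, 0.5, 45000.0, True, ["N4200"]),
        ("liquiritigenin", "C15H12O4", lg_rt, 4.0, 50000.0, True, ["P5000"]),
        ("isoliquiritigenin", "C15H12O4", ilg_rt, 6.0, 40000.0, True, ["P5100"]),
        ("liquiritigenin sulfate", "C15H12O7S", lg_rt - 1.3, 4.0, 20000.0,
         False, ["N6443"]),
        ("liquiritigenin glucuronide", "C21H20O10", lg_rt - 1.7, 4.0, 30000.0,
         False, ["P8722", "N6061"]),
        ("isoliquiritigenin glucuronide", "C21H20O10", ilg_rt - 1.7, 6.0,
         25000.0, False, ["N6799"]),
        ("liquiritigenin glucuronide sulfate", "C21H20O13S", lg_rt - 3.0, 4.0,
         15000.0, False, ["N5429"]),
        ("ephedrine", "C10H15NO", 4.0, 0.5, 80000.0, True, ["P2001"]),
        ("pseudoephedrine", "C10H15NO", 4.1, 0.5, 70000.0, True, ["P2002"]),
    ]
    edges = [
        ("liquiritin", "liquiritigenin", "deglycosylation"),
        ("isoliquiritin", "isoliquiritigenin", "deglycosylation"),
        ("liquiritigenin", "liquiritigenin sulfate", "sulfation"),
        ("liquiritigenin", "liquiritigenin glucuronide", "glucuronidation"),
        ("isoliquiritigenin", "isoliquiritigenin glucuronide", "glucuronidation"),
        ("liquiritigenin glucuronide", "liquiritigenin glucuronide sulfate",
         "sulfation"),
        ("liquiritigenin sulfate", "liquiritigenin glucuronide sulfate",
         "glucuronidation"),
    ]
    spec = FixtureSpec(seed=0, n_source_compounds=0, conjugates_per_source=0,
                       n_decoy_peaks=0)
    design = _build_design(spec)
    subj_factor = {"S1": 1.0, "S2": 0.8, "S3": 1.2, "S4": 0.9}
    width = 0.8
    reactions = {r.name: r for r in default_reaction_table()}

    metabolites = []
    peaks: list[Peak] = []
    peak_rows: list[dict[str, float]] = []
    msms: dict[str, MsmsSpectrum] = {}
    isotopes: dict[str, list[tuple[float, float]]] = {}
    post_frame = design.frame[design.frame["class"] == "post"]

    for name, formula_s, rt, tmax, amp, in_extract, peak_ids in plan:
        formula = ElementalFormula.parse(formula_s)
        origin = {"ephedra"} if "ephedrine" in name else {"licorice"}
        metabolites.append(PlantedMetabolite(
            name=name, formula=formula, neutral_mass=formula.mass, rt=rt,
            peak_ids=list(peak_ids), origin=origin, in_extract=in_extract,
            is_maoto_derived=True, tmax=tmax, width=width, amplitude=amp))
        for k, pid in enumerate(peak_ids):
            mode = "positive" if pid.startswith("P") else "negative"
            sign = 1.0 if mode == "positive" else -1.0
            mz = formula.mass + sign * PROTON_MASS
            adduct = "[M+H]+" if mode == "positive" else "[M-H]-"
            # secondary ion forms elute nominally 0.05 min apart and weaker
            peaks.append(Peak(pid, mode, mz, adduct, rt + 0.05 * k, formula.mass))
            row: dict[str, float] = {}
            scale = 1.0 if k == 0 else 0.25
            for s in post_frame.itertuples():
                value = (amp * scale * subj_factor[str(s.subject)]
                         * _profile(float(s.timepoint), tmax, width))
                if value >= spec.detection_limit:
                    row[s.sample_id] = value
            if in_extract:
                row["EXTRACT"] = amp * scale
            for herb in origin:
                row[f"HERB_{herb}"] = max(
                    amp * scale * _profile(1.0, tmax, width),
                    2 * spec.detection_limit)
            peak_rows.append(row)
            n_s = formula["S"]
            pattern = [(C13_OFFSET, formula["C"] * C13_ABUNDANCE)]
            if n_s:
                pattern.append((S34_OFFSET, n_s * S34_ABUNDANCE))
            isotopes[pid] = sorted(pattern)
        # MS/MS on the representative ion: diagnostic neutral loss fragments
        rep = peaks[-len(peak_ids)]
        fragments = []
        if "sulfate" in name:
            fragments.append((rep.mz - reactions["sulfation"].delta_mass, 100.0))
        if "glucuronide" in name:
            fragments.append((rep.mz - reactions["glucuronidation"].delta_mass,
                              80.0))
        if fragments:
            msms[rep.peak_id] = MsmsSpectrum(rep.mz, sorted(fragments))

    samples = design.sample_ids
    intensity = pd.DataFrame(
        [[row.get(s, np.nan) for s in samples] for row in peak_rows],
        index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
        columns=samples)
    table = FeatureTable(peaks, intensity)

    ann_rows = []
    for name in ("liquiritin", "isoliquiritin", "liquiritigenin",
                 "isoliquiritigenin", "ephedrine", "pseudoephedrine"):
        m = next(x for x in metabolites if x.name == name)
        ann_rows.append({"name": name, "formula": m.formula.hill(),
                         "origin": ";".join(sorted(m.origin)),
                         "rt": m.rt, "msi_level": ""})
    annotations = AnnotationTable(pd.DataFrame(ann_rows))
    truth = GroundTruth(
        metabolites=metabolites, edges=edges,
        merge_exception_pairs=[("P2001", "P2002")])
    return FixtureSet(table, design, msms, isotopes, annotations, truth)


def write_fixture(fixture: FixtureSet, outdir) -> dict[str, Path]:
    """Write every fixture artifact to ``outdir`` in the canonical formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": outdir / "features.tsv",
        "design": outdir / "design.tsv",
        "msms": outdir / "spectra.mgf",
        "isotopes": outdir / "isotopes.tsv",
        "annotations": outdir / "standards.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_feature_table(fixture.feature_table, paths["feature_table"])
    write_sample_design(fixture.design, paths["design"])
    write_msms_mgf(fixture.msms, paths["msms"])
    write_isotope_patterns(fixture.isotopes, paths["isotopes"])
    write_annotation_table(fixture.annotations, paths["annotations"])
    gt_rows = []
    for m in fixture.ground_truth.metabolites:
        gt_rows.append({
            "name": m.name,
            "formula": m.formula.hill() if m.formula else "",
            "neutral_mass": f"{m.neutral_mass:.5f}",
            "rt": f"{m.rt:.3f}",
            "peak_ids": ";".join(m.peak_ids),
            "origin": ";".join(sorted(m.origin)),
            "in_extract": m.in_extract,
            "is_maoto_derived": m.is_maoto_derived,
        })
    pd.DataFrame(gt_rows).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
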