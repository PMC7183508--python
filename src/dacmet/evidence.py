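"""Orthogonal spectral evidence for conjugate annotation.

Three independent lines of evidence back up a mass-difference edge:

* the ³⁴S isotopologue (+1.99580 Da, ~4.25 % per sulfur atom), diagnostic
  of sulfur-containing conjugates such as sulfates;
* diagnostic neutral losses in MS/MS (80 Da for SO₃, 176 Da for the
  glucuronide moiety, 162 Da for a hexose);
* agreement of the observed RT shift with a calibrated reference shift.

The evidence feeds an explicit MSI-level rubric (Metabolomics Standards
Initiative confidence levels 1–4).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem import S34_ABUNDANCE, S34_OFFSET, monoisotopic_mass
from .io import AnnotationTable, MsmsSpectrum
from .network import ConjugationNetwork, NetworkNode

logger = logging.getLogger(__name__)

__all__ = [
    "IsotopeEvidence",
    "NeutralLossEvidence",
    "MsiAssignment",
    "DEFAULT_NEUTRAL_LOSSES",
    "detect_34S",
    "detect_neutral_loss",
    "assign_msi_level",
    "annotate_network",
]

#: Diagnostic neutral losses: (name, Da).
DEFAULT_NEUTRAL_LOSSES: tuple[tuple[str, float], ...] = (
    ("NL-80", monoisotopic_mass("SO3")),       # sulfate
    ("NL-176", monoisotopic_mass("C6H8O6")),   # glucuronide
    ("NL-162", monoisotopic_mass("C6H10O5")),  # hexose
)

#: Which neutral loss corroborates which reaction edge.
LOSS_FOR_REACTION = {
    "sulfation": "NL-80",
    "glucuronidation": "NL-176",
    "deglycosylation": "NL-162",
    "glucuronide loss": "NL-176",
}


@dataclass
class IsotopeEvidence:
    """Outcome of the ³⁴S isotopologue check for one peak."""

    has_34S: bool
    observed_offset: float | None = None
    observed_ratio: float | None = None
    estimated_sulfur_count: int = 0
    note: str = ""


@dataclass
class NeutralLossEvidence:
    """Diagnostic neutral losses matched in one MS/MS spectrum."""

    matched: list[tuple[str, float, float, float]] = field(default_factory=list)
    # entries: (name, expected Da, observed Da, fragment m/z)

    @property
    def names(self) -> set[str]:
        return {m[0] for m in self.matched}

    def __bool__(self) -> bool:
        return bool(self.matched)


@dataclass
class MsiAssignment:
    """MSI identification-confidence level with its supporting rationale."""

    level: str  # "1" | "2" | "3" | "4" | "unknown"
    rationale: list[str] = field(default_factory=list)


def detect_34S(pattern: list[tuple[float, float]] | None,
               offset_tol: float = 0.01,
               ratio_band: tuple[float, float] = (0.02, 0.08),
               max_sulfur: int = 4,
               ) -> IsotopeEvidence:
    """Detect a ³⁴S isotopologue in a peak's isotope pattern.

    ``pattern`` holds (offset Da, relative intensity vs the monoisotopic
    peak) entries.  A hit requires an isotopologue at +1.99580 ± ``offset_tol``
    Da whose per-sulfur relative intensity falls inside ``ratio_band``
    around the 4.25 % natural abundance; the tight offset tolerance keeps
    the ¹³C₂ isotopologue (+2.00671 Da) out.  The sulfur count inferred
    from the ratio is capped at ``max_sulfur`` — small-molecule conjugates
    carry few sulfur atoms, so a far larger apparent ratio is interference,
    not sulfur.  An empty pattern is *absence of evidence*, not
    counter-evidence.
    """
    if not pattern:
        return IsotopeEvidence(False, note="no pattern")
    candidates = [(off, ratio) for off, ratio in pattern
                  if abs(off - S34_OFFSET) <= offset_tol]
    if not candidates:
        return IsotopeEvidence(False, note="no isotopologue near +1.9958 Da")
    # closest-offset candidate wins
    off, ratio = min(candidates, key=lambda c: abs(c[0] - S34_OFFSET))
    n_sulfur = min(max_sulfur, max(1, round(ratio / S34_ABUNDANCE)))
    lo, hi = ratio_band
    if lo <= ratio / n_sulfur <= hi:
        return IsotopeEvidence(True, off, ratio, n_sulfur)
    return IsotopeEvidence(False, off, ratio, 0,
                           note="relative intensity outside band")


def detect_neutral_loss(spectrum: MsmsSpectrum | None,
                        losses: tuple[tuple[str, float], ...] = DEFAULT_NEUTRAL_LOSSES,
                        frag_tol: float = 0.5,
                        ) -> NeutralLossEvidence:
    """Match diagnostic neutral losses as precursor-minus-fragment differences.

    The default fragment tolerance of 0.5 Da suits ion-trap product-ion
    spectra; use ~0.01 Da for high-resolution MS/MS.
    """
    evidence = NeutralLossEvidence()
    if spectrum is None or not spectrum.fragments:
        return evidence
    for name, expected in losses:
        best = None
        for frag_mz, _ in spectrum.fragments:
            observed = spectrum.precursor_mz - frag_mz
            err = abs(observed - expected)
            if err <= frag_tol and (best is None or err < abs(best[0] - expected)):
                best = (observed, frag_mz)
        if best is not None:
            evidence.matched.append((name, expected, best[0], best[1]))
    return evidence


def assign_msi_level(node: NetworkNode,
                     annotation: AnnotationTable | None = None,
                     network: ConjugationNetwork | None = None,
                     iso: IsotopeEvidence | None = None,
                     nl: NeutralLossEvidence | None = None,
                     ppm: float = 5.0,
                     standard_rt_tol: float = 0.2,
                     shift_agreement_tol: float = 0.5,
                     ) -> MsiAssignment:
    """Assign an MSI confidence level from all available evidence.

    Rubric (first match wins):

    1. mass (≤ ``ppm``) and RT (≤ ``standard_rt_tol`` min) match to an
       authentic standard in the annotation table;
    2. the node is a conjugate — target of a preferred within-window
       network edge — with at least one orthogonal support: ³⁴S, a
       diagnostic neutral loss, or reference-shift agreement within
       ``shift_agreement_tol`` min;
    3. a database/literature annotation (mass match to a row without a
       reference RT);
    4. an elemental formula is assigned;
    otherwise ``unknown``.  Absent spectral data never downgrades a node
    below what the network supports.
    """
    rationale: list[str] = []

    def mass_match(row_mass: float) -> bool:
        heavier = max(node.neutral_mass, row_mass)
        return abs(node.neutral_mass - row_mass) / heavier * 1e6 <= ppm

    if annotation is not None:
        for row in annotation.frame.itertuples(index=False):
            if not mass_match(row.neutral_mass):
                continue
            has_rt = row.rt == row.rt  # not NaN
            if has_rt and abs(node.rt - row.rt) <= standard_rt_tol:
                rationale.append(
                    f"standard {row.name}: mass and RT match")
                return MsiAssignment("1", rationale)

    if network is not None:
        preferred = [e for e in network.edges_to(node.node_id)
                     if e.preferred and e.within_window]
        for edge in preferred:
            support = []
            if iso is not None and iso.has_34S:
                support.append("34S isotopologue")
            if nl is not None and nl.names & {LOSS_FOR_REACTION.get(edge.reaction)}:
                support.append(f"neutral loss {LOSS_FOR_REACTION[edge.reaction]}")
            if edge.shift_score is not None \
                    and edge.shift_score <= shift_agreement_tol:
                support.append(
                    f"RT shift within {shift_agreement_tol} min of reference")
            if support:
                rationale.append(
                    f"{edge.reaction} edge from {edge.source} + "
                    + ", ".join(support))
                return MsiAssignment("2", rationale)

    if annotation is not None:
        for row in annotation.frame.itertuples(index=False):
            if mass_match(row.neutral_mass):
                rationale.append(f"database/literature annotation: {row.name}")
                return MsiAssignment("3", rationale)

    if node.formula:
        rationale.append(f"elemental formula assigned: {node.formula}")
        return MsiAssignment("4", rationale)
    return MsiAssignment("unknown", rationale)


def annotate_network(network: ConjugationNetwork,
                     annotation: AnnotationTable | None = None,
                     msms: dict[str, MsmsSpectrum] | None = None,
                     isotopes: dict[str, list[tuple[float, float]]] | None = None,
                     ppm: float = 5.0,
                     standard_rt_tol: float = 0.2,
                     shift_agreement_tol: float = 0.5,
                     frag_tol: float = 0.5,
                     ) -> ConjugationNetwork:
    """Attach evidence flags and MSI levels to every node and edge.

    MS/MS spectra and isotope patterns are looked up per member peak id;
    node labels are filled in from level-1 standard matches.
    """
    msms = msms or {}
    isotopes = isotopes or {}
    node_iso: dict[str, IsotopeEvidence] = {}
    node_nl: dict[str, NeutralLossEvidence] = {}
    for node in network.nodes.values():
        iso = IsotopeEvidence(False, note="no pattern")
        for member in node.member_peaks:
            if member in isotopes:
                candidate = detect_34S(isotopes[member])
                if candidate.has_34S:
                    iso = candidate
                    break
        nl = NeutralLossEvidence()
        for member in node.member_peaks:
            if member in msms:
                found = detect_neutral_loss(msms[member], frag_tol=frag_tol)
                nl.matched.extend(found.matched)
        node_iso[node.node_id] = iso
        node_nl[node.node_id] = nl

    for edge in network.edges:
        iso = node_iso[edge.target]
        nl = node_nl[edge.target]
        if iso.has_34S:
            edge.evidence.add("iso34S")
        loss_name = LOSS_FOR_REACTION.get(edge.reaction)
        if loss_name and loss_name in nl.names:
            edge.evidence.add(loss_name)

    for node in network.nodes.values():
        assignment = assign_msi_level(
            node, annotation, network,
            node_iso[node.node_id], node_nl[node.node_id],
            ppm=ppm, standard_rt_tol=standard_rt_tol,
            shift_agreement_tol=shift_agreement_tol)
        node.msi_level = assignment.level
        if assignment.level == "1" and annotation is not None and not node.label:
            # among mass+RT matches, the standard with the closest RT wins
            # (e.g. ephedrine vs pseudoephedrine, 0.1 min apart at one mass)
            best = None
            for row in annotation.frame.itertuples(index=False):
                heavier = max(node.neutral_mass, row.neutral_mass)
                if abs(node.neutral_mass - row.neutral_mass) / heavier * 1e6 <= ppm \
                        and row.rt == row.rt \
                        and abs(node.rt - row.rt) <= standard_rt_tol:
                    if best is None or abs(node.rt - row.rt) < abs(node.rt - best.rt):
                        best = row
            if best is not None:
                node.label = best.name
                node.formula = best.formula
    for edge in network.edges:
        if network.nodes[edge.target].msi_level == "1":
            edge.evidence.add("standard_confirmed")
    return network
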