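"""Elemental mass arithmetic, biotransformation deltas and ppm matching.

Every mass handled in this package is a neutral monoisotopic mass in
daltons.  Charged-species bookkeeping (protonation, adducts) is confined to
the I/O layer, so the chemistry here is charge-agnostic.

The central object is the :class:`ReactionDelta`: a named biotransformation
(glucuronidation, sulfation, ...) whose mass shift is derived from the
elemental formula of the gained (or lost) moiety, together with the
retention-time window its conjugates are expected to fall in on a
reversed-phase column.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "MassTolerance",
    "ReactionDelta",
    "monoisotopic_mass",
    "default_reaction_table",
    "load_reaction_table",
    "match_mass_difference",
    "mass_residual_ppm",
    "PROTON_MASS",
    "S34_OFFSET",
    "S34_ABUNDANCE",
]

# Monoisotopic (most-abundant-isotope) atomic masses, Da.
# Constants embedded so a 5-ppm-level computation carries no runtime
# dependency; six decimals keeps formula sums good to ~1e-5 Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "D": 2.014102,
    "B": 11.009305,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989770,
    "Mg": 23.985042,
    "Si": 27.976927,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "K": 38.963707,
    "Ca": 39.962591,
    "Fe": 55.934936,
    "Cu": 62.929597,
    "Zn": 63.929142,
    "Se": 79.916521,
    "Br": 78.918337,
    "I": 126.904473,
}

#: Mass of a proton (H minus one electron), Da — used for (de)ionization.
PROTON_MASS = 1.007276

#: Mass offset of the 34S isotopologue relative to 32S, Da.
S34_OFFSET = 33.967867 - MONOISOTOPIC_MASS["S"]

#: Natural abundance of 34S relative to 32S.
S34_ABUNDANCE = 0.0425

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula:
    """A bag of atoms, e.g. ``C6H8O6``.

    Supports Hill-notation parsing, addition/subtraction (for building
    conjugate formulas), and monoisotopic mass.  The empty formula is valid
    and has mass zero.
    """

    __slots__ = ("element_counts",)

    def __init__(self, element_counts: Mapping[str, int] | None = None):
        counts: dict[str, int] = {}
        for symbol, n in (element_counts or {}).items():
            if symbol not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {symbol}: {n}")
            if n:
                counts[symbol] = n
        self.element_counts = counts

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``C15H12O4``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(text):
            if match.start() != pos:
                raise ValueError(f"unparseable formula: {text!r}")
            pos = match.end()
            symbol, digits = match.groups()
            if symbol not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise ValueError(f"unparseable formula: {text!r}")
        return cls(counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.element_counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValueError(
                    f"subtraction would give negative {el} count"
                )
        return ElementalFormula(counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self.element_counts == other.element_counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.element_counts.items())))

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.element_counts)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        counts = dict(self.element_counts)
        parts = []
        for el in ("C", "H"):
            if el in counts:
                n = counts.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass of a formula (object or Hill string), in Da."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return formula.mass


@dataclass(frozen=True)
class MassTolerance:
    """Mass-accuracy window in parts per million of the measured mass."""

    ppm: float = 5.0

    def __post_init__(self) -> None:
        if not self.ppm > 0:
            raise ValueError(f"ppm tolerance must be positive, got {self.ppm}")


@dataclass
class ReactionDelta:
    """A named biotransformation with a formula-derived mass shift.

    ``kind`` is ``"gain"`` when the conjugate is heavier than the source
    (e.g. glucuronidation) and ``"loss"`` when the product is lighter
    (e.g. microbial deglycosylation of a glycoside to its aglycone).
    ``rt_window`` bounds the expected retention-time shift in minutes,
    signed as ``product RT - source RT``; ``reference_shift`` is the shift
    observed for a calibrant compound (7-hydroxycoumarin conjugates by
    default) and drives source disambiguation.
    """

    name: str
    gained_formula: ElementalFormula
    rt_window: tuple[float, float]
    kind: str = "gain"
    reference_shift: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.gained_formula, str):
            self.gained_formula = ElementalFormula.parse(self.gained_formula)
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"reaction kind must be 'gain' or 'loss': {self.kind!r}")
        if not self.delta_mass > 0:
            raise ValueError(f"reaction {self.name!r} has non-positive delta mass")
        lo, hi = self.rt_window
        if lo > hi:
            raise ValueError(f"reaction {self.name!r} rt_window min > max")
        self.rt_window = (float(lo), float(hi))

    @property
    def delta_mass(self) -> float:
        """Absolute monoisotopic mass shift, Da (always positive)."""
        return self.gained_formula.mass

    def shift_in_window(self, rt_shift: float) -> bool:
        """Whether a product-minus-source RT shift lies in the closed window."""
        lo, hi = self.rt_window
        return lo <= rt_shift <= hi


#: Glutathione-conjugation moiety variants (Hill formulas).  The common
#: delta is the dehydro form (+305.06816 Da); the reduced form
#: (+307.08381 Da) can be selected instead.
GLUTATHIONE_VARIANTS = {
    "dehydro": "C10H15N3O6S",
    "reduced": "C10H17N3O6S",
}

# Reference RT shifts (minutes) calibrated on 7-hydroxycoumarin conjugates:
# sulfation shortens RT by about 1.4 min, glucuronidation by about 1.9 min.
REFERENCE_SHIFT_SULFATION = -1.4
REFERENCE_SHIFT_GLUCURONIDATION = -1.9


def default_reaction_table(glutathione: str = "dehydro") -> list[ReactionDelta]:
    """The default biotransformation table.

    Five major phase-II conjugations (glucuronic acid, sulfate, glycine,
    glutamine, glutathione) plus "other known reactions" for glycoside
    hydrolysis (hexose loss, glucuronide loss).  Glucuronidation and
    sulfation carry the reversed-phase window of -3.0 to +0.2 min (their
    conjugates elute earlier); the remaining conjugations use +/-5 min.
    """
    gsh = GLUTATHIONE_VARIANTS[glutathione]
    return [
        ReactionDelta("glucuronidation", ElementalFormula.parse("C6H8O6"),
                      (-3.0, 0.2), "gain",
                      reference_shift=REFERENCE_SHIFT_GLUCURONIDATION),
        ReactionDelta("sulfation", ElementalFormula.parse("SO3"),
                      (-3.0, 0.2), "gain",
                      reference_shift=REFERENCE_SHIFT_SULFATION),
        ReactionDelta("glycine conjugation", ElementalFormula.parse("C2H3NO"),
                      (-5.0, 5.0), "gain"),
        ReactionDelta("glutamine conjugation", ElementalFormula.parse("C5H8N2O2"),
                      (-5.0, 5.0), "gain"),
        ReactionDelta("glutathione conjugation", ElementalFormula.parse(gsh),
                      (-5.0, 5.0), "gain"),
        # "Other known reactions": hydrolysis products are lighter than the
        # glycoside they come from, so these run heavier -> lighter.
        ReactionDelta("deglycosylation", ElementalFormula.parse("C6H10O5"),
                      (-5.0, 5.0), "loss"),
        ReactionDelta("glucuronide loss", ElementalFormula.parse("C6H8O6"),
                      (-5.0, 5.0), "loss"),
    ]


def load_reaction_table(path) -> list[ReactionDelta]:
    """Load a reaction table override from a YAML file.

    Each entry: ``name``, ``formula`` (Hill string), ``window`` ([min, max]
    minutes), optional ``kind`` (gain/loss) and ``reference_shift``.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    table = []
    for entry in entries:
        table.append(ReactionDelta(
            name=entry["name"],
            gained_formula=ElementalFormula.parse(entry["formula"]),
            rt_window=tuple(entry["window"]),
            kind=entry.get("kind", "gain"),
            reference_shift=entry.get("reference_shift"),
        ))
    return table


def save_reaction_table(table: list[ReactionDelta], path) -> None:
    """Write a reaction table to YAML (inverse of :func:`load_reaction_table`)."""
    import yaml

    entries = []
    for r in table:
        entry = {"name": r.name, "formula": r.gained_formula.hill(),
                 "window": list(r.rt_window), "kind": r.kind}
        if r.reference_shift is not None:
            entry["reference_shift"] = r.reference_shift
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def mass_residual_ppm(mass_a: float, mass_b: float, delta: ReactionDelta) -> float:
    """Signed residual of a pair's mass difference against a reaction delta.

    The residual ``|heavy - light| - delta`` is normalized by the heavier
    neutral mass, in ppm.  Symmetric in argument order.
    """
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("masses must be positive")
    light, heavy = sorted((mass_a, mass_b))
    return ((heavy - light) - delta.delta_mass) / heavy * 1e6


def match_mass_difference(mass_a: float, mass_b: float, delta: ReactionDelta,
                          tol: MassTolerance = MassTolerance()) -> bool:
    """Whether two neutral masses differ by a reaction delta within tolerance.

    The ppm tolerance applies to the residual of the mass *difference*,
    normalized by the heavier member — the scale on which instrument mass
    accuracy is specified.
    """
    return abs(mass_residual_ppm(mass_a, mass_b, delta)) <= tol.ppm
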