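"""Combinatorial lipid mass database and exact-mass annotation.

Negative-ion MALDI spectra of brain tissue are dominated by glycerophospho-
and sphingolipids observed as deprotonated, chloride, formate, or (for
choline-bearing classes) demethylated anions. Peaks are assigned by comparing
measured m/z against a combinatorial database of sum-composition species
(class + total acyl carbons : total double-bond equivalents) enumerated over
configurable chain ranges and adducts.

The database is deliberately combinatorial rather than curated: it
over-enumerates chemically implausible chain combinations so that no genuine
species is missed, and relies on the ppm tolerance plus class-priority
ranking to keep assignments sane.
"""

from __future__ import annotations

import bisect as _bisect
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ElementalFormula",
    "LipidClass",
    "LipidSpecies",
    "Adduct",
    "DatabaseEntry",
    "LipidDatabase",
    "DatabaseConfig",
    "Annotation",
    "AnnotationCandidate",
    "MONOISOTOPIC_MASS",
    "ADDUCTS",
    "DEFAULT_CLASSES",
    "species_formula",
    "monoisotopic_mass",
    "apply_adduct",
    "build_database",
    "annotate_peak",
    "annotate_channels",
    "species_class",
]

# Monoisotopic isotope masses (Da).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
}

_ELEMENTS = tuple(MONOISOTOPIC_MASS)


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts over C, H, N, O, P, S, Cl."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    S: int = 0
    Cl: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count {el}={n!r} must be a non-negative integer")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS})

    def add(self, **counts: int) -> "ElementalFormula":
        """Return a copy with ``counts`` added (may be negative, result must stay >= 0)."""
        new = {el: getattr(self, el) + counts.get(el, 0) for el in _ELEMENTS}
        return ElementalFormula(**new)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (linear in the counts)."""
        return sum(getattr(self, el) * MONOISOTOPIC_MASS[el] for el in _ELEMENTS)

    def hill(self) -> str:
        """Hill-style string, e.g. ``C42H82NO8P`` (count 1 implicit, 0 omitted)."""
        parts = []
        for el in ("C", "H", "N", "O", "P", "S", "Cl"):
            n = getattr(self, el)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @classmethod
    def from_hill(cls, s: str) -> "ElementalFormula":
        counts: dict[str, int] = {}
        for el, num in re.findall(r"(Cl|C|H|N|O|P|S)(\d*)", s):
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        f = cls(**counts)
        if f.hill() != cls(**counts).hill() or not s == f.hill():
            # allow non-canonical orderings too; only check mass-relevant content
            rebuilt = sum(len(el) + len(str(n) if n > 1 else "") for el, n in counts.items() if n)
            if rebuilt != len(s):
                raise ValueError(f"cannot parse formula {s!r}")
        return f


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass (Da) of a formula; the empty formula weighs 0."""
    return f.mass


@dataclass(frozen=True)
class Adduct:
    """A negative-mode ionized form: observed m/z = (M + delta) / |charge|.

    Deltas are electron-corrected constants.
    """

    label: str
    delta: float
    charge: int = -1
    choline_only: bool = False

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


ADDUCTS: Mapping[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", -1.00727646),
    "[M+Cl]-": Adduct("[M+Cl]-", +34.96940),
    "[M+HCOO]-": Adduct("[M+HCOO]-", +44.99820),
    "[M-CH3]-": Adduct("[M-CH3]-", -15.02293, choline_only=True),
}

_STANDARD_ADDUCTS = ("[M-H]-", "[M+Cl]-", "[M+HCOO]-")
_CHOLINE_ADDUCTS = _STANDARD_ADDUCTS + ("[M-CH3]-",)


@dataclass(frozen=True)
class LipidClass:
    """A lipid class: virtual 0:0 base formula plus sum-composition increments.

    The species formula is ``base + C_t carbons + (2*C_t - 2*D_t) hydrogens``;
    the base is chosen so this reproduces reference compositions (e.g.
    PC base C8H16NO8P gives PC 34:1 = C42H82NO8P).
    """

    abbrev: str
    base: ElementalFormula
    linkage: str  # diacyl | ether | lyso | lyso-ether | sphingoid | fatty-acyl
    carbons: tuple[int, int]
    doubles: tuple[int, int]
    adducts: tuple[str, ...]
    choline: bool = False
    priority: int = 99  # lower = preferred at annotation ties
    db_offset: int = 0  # D_t allowed up to C_t//2 + db_offset

    def valid_composition(self, c_t: int, d_t: int) -> bool:
        return (
            self.carbons[0] <= c_t <= self.carbons[1]
            and self.doubles[0] <= d_t <= self.doubles[1]
            and d_t <= c_t // 2 + self.db_offset
        )


def _F(s: str) -> ElementalFormula:
    return ElementalFormula.from_hill(s)


def _mk_classes() -> dict[str, LipidClass]:
    diacyl = (20, 50)
    lyso = (12, 26)
    d_di = (0, 12)
    d_ly = (0, 6)
    spec: list[tuple] = [
        # abbrev, base, linkage, carbons, doubles, choline, priority
        ("PC", "C8H16NO8P", "diacyl", diacyl, d_di, True, 1),
        ("PE", "C5H10NO8P", "diacyl", diacyl, d_di, False, 2),
        ("PI", "C9H15O13P", "diacyl", diacyl, d_di, False, 3),
        ("PS", "C6H10NO10P", "diacyl", diacyl, d_di, False, 4),
        ("PEe", "C5H12NO7P", "ether", diacyl, d_di, False, 5),
        ("PCe", "C8H18NO7P", "ether", diacyl, d_di, True, 6),
        ("SM", "C5H13N2O6P", "sphingoid", diacyl, d_di, True, 7),
        ("PG", "C6H11O10P", "diacyl", diacyl, d_di, False, 8),
        ("PA", "C3H5O8P", "diacyl", diacyl, d_di, False, 9),
        ("SHexCer", "C6H11NO11S", "sphingoid", diacyl, d_di, False, 10),
        ("HexCer", "C6H11NO8", "sphingoid", diacyl, d_di, False, 11),
        ("Cer", "HNO3", "sphingoid", diacyl, d_di, False, 12),
        ("CerP", "H2NO6P", "sphingoid", diacyl, d_di, False, 13),
        ("Hex2Cer", "C12H21NO13", "sphingoid", diacyl, d_di, False, 14),
        ("Hex3Cer", "C18H31NO18", "sphingoid", diacyl, d_di, False, 15),
        ("SM;O3", "C5H13N2O7P", "sphingoid", diacyl, d_di, True, 16),
        ("Cer;O3", "HNO4", "sphingoid", diacyl, d_di, False, 17),
        ("HexCer;O3", "C6H11NO9", "sphingoid", diacyl, d_di, False, 18),
        ("SHexCer;O3", "C6H11NO12S", "sphingoid", diacyl, d_di, False, 19),
        ("PIP", "C9H16O16P2", "diacyl", diacyl, d_di, False, 20),
        ("PIP2", "C9H17O19P3", "diacyl", diacyl, d_di, False, 21),
        ("PGP", "C6H12O13P2", "diacyl", diacyl, d_di, False, 22),
        ("GM3", "C23H38N2O21", "sphingoid", diacyl, d_di, False, 23),
        ("GM2", "C31H51N3O26", "sphingoid", diacyl, d_di, False, 24),
        ("GM1", "C37H61N3O31", "sphingoid", diacyl, d_di, False, 25),
        ("LPC", "C8H18NO7P", "lyso", lyso, d_ly, True, 26),
        ("LPE", "C5H12NO7P", "lyso", lyso, d_ly, False, 27),
        ("LPI", "C9H17O12P", "lyso", lyso, d_ly, False, 28),
        ("LPS", "C6H12NO9P", "lyso", lyso, d_ly, False, 29),
        ("LPG", "C6H13O9P", "lyso", lyso, d_ly, False, 30),
        ("LPA", "C3H7O7P", "lyso", lyso, d_ly, False, 31),
        ("LPCe", "C8H20NO6P", "lyso-ether", lyso, d_ly, True, 32),
        ("LPEe", "C5H14NO6P", "lyso-ether", lyso, d_ly, False, 33),
        ("FA", "O2", "fatty-acyl", lyso, d_ly, False, 34),
    ]
    out: dict[str, LipidClass] = {}
    for abbrev, base, linkage, car, dbl, choline, prio in spec:
        if abbrev == "FA":
            adducts: tuple[str, ...] = ("[M-H]-",)
        elif choline:
            adducts = _CHOLINE_ADDUCTS
        else:
            adducts = _STANDARD_ADDUCTS
        out[abbrev] = LipidClass(
            abbrev, _F(base), linkage, car, dbl, adducts, choline=choline, priority=prio
        )
    return out


DEFAULT_CLASSES: Mapping[str, LipidClass] = _mk_classes()


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition species, e.g. PI 38:4."""

    lipid_class: LipidClass
    c_t: int
    d_t: int
    formula: ElementalFormula = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", species_formula(self.lipid_class, self.c_t, self.d_t))

    @property
    def name(self) -> str:
        return f"{self.lipid_class.abbrev} {self.c_t}:{self.d_t}"

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


def species_formula(lipid_class: LipidClass, c_t: int, d_t: int) -> ElementalFormula:
    """Elemental formula of the sum-composition species ``<class> C_t:D_t``.

    The class base formula is incremented by ``c_t`` carbons and
    ``2*c_t - 2*d_t`` hydrogens. Compositions outside the class's configured
    carbon/double-bond ranges (or with more double-bond equivalents than the
    chains can carry) are rejected; the virtual 0:0 composition is always
    constructible and returns the base formula itself.
    """
    if (c_t, d_t) == (0, 0):
        return lipid_class.base
    if not lipid_class.valid_composition(c_t, d_t):
        raise ValueError(
            f"composition {lipid_class.abbrev} {c_t}:{d_t} outside configured ranges "
            f"(C {lipid_class.carbons}, DB {lipid_class.doubles}, "
            f"D_t <= C_t//2 + {lipid_class.db_offset})"
        )
    return lipid_class.base.add(C=c_t, H=2 * c_t - 2 * d_t)


@dataclass(frozen=True)
class DatabaseEntry:
    species: LipidSpecies
    adduct: Adduct
    mz: float

    @property
    def name(self) -> str:
        return f"{self.species.name} {self.adduct.label}"


def apply_adduct(species: LipidSpecies, adduct: Adduct) -> DatabaseEntry:
    """Ionize a neutral species; rejects inapplicable class/adduct pairs."""
    if adduct.label not in species.lipid_class.adducts:
        raise ValueError(
            f"adduct {adduct.label} not applicable to class {species.lipid_class.abbrev}"
        )
    mz = (species.neutral_mass + adduct.delta) / abs(adduct.charge)
    return DatabaseEntry(species, adduct, mz)


@dataclass(frozen=True)
class DatabaseConfig:
    """Which classes/adducts to enumerate. Defaults reconstruct a combinatorial
    negative-mode brain lipid database of ~34,000 entries."""

    classes: tuple[LipidClass, ...] = tuple(DEFAULT_CLASSES.values())

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("class list must not be empty")


class LipidDatabase:
    """m/z-sorted list of species-adduct entries with binary-search lookup."""

    def __init__(self, entries: Sequence[DatabaseEntry]):
        self.entries: list[DatabaseEntry] = sorted(entries, key=lambda e: e.mz)
        self._mz = [e.mz for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def window(self, lo: float, hi: float) -> list[DatabaseEntry]:
        i = _bisect.bisect_left(self._mz, lo)
        j = _bisect.bisect_right(self._mz, hi)
        return self.entries[i:j]

    # -- text export / import ------------------------------------------------

    HEADER = "class\tC_t\tD_t\tformula\tadduct\tmz"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.HEADER + "\n")
            for e in self.entries:
                s = e.species
                fh.write(
                    f"{s.lipid_class.abbrev}\t{s.c_t}\t{s.d_t}\t{s.formula.hill()}\t"
                    f"{e.adduct.label}\t{e.mz:.6f}\n"
                )

    @classmethod
    def from_tsv(cls, path, classes: Mapping[str, LipidClass] = DEFAULT_CLASSES) -> "LipidDatabase":
        entries = []
        with open(path) as fh:
            header = fh.readline().strip()
            if header != cls.HEADER:
                raise ValueError(f"unexpected database header: {header!r}")
            for line in fh:
                ab, c_t, d_t, _formula, adduct, _mz = line.rstrip("\n").split("\t")
                species = LipidSpecies(classes[ab], int(c_t), int(d_t))
                entries.append(apply_adduct(species, ADDUCTS[adduct]))
        return cls(entries)


def build_database(config: DatabaseConfig | None = None) -> LipidDatabase:
    """Enumerate every valid (class, C_t, D_t, adduct) combination.

    Identical (class, C_t, D_t) compositions are generated once; the result is
    sorted ascending by m/z.
    """
    config = config or DatabaseConfig()
    entries: list[DatabaseEntry] = []
    seen: set[tuple[str, int, int]] = set()
    for lc in config.classes:
        for c_t in range(lc.carbons[0], lc.carbons[1] + 1):
            for d_t in range(lc.doubles[0], lc.doubles[1] + 1):
                if not lc.valid_composition(c_t, d_t):
                    continue
                key = (lc.abbrev, c_t, d_t)
                if key in seen:
                    continue
                seen.add(key)
                species = LipidSpecies(lc, c_t, d_t)
                for label in lc.adducts:
                    entries.append(apply_adduct(species, ADDUCTS[label]))
    return LipidDatabase(entries)


@dataclass(frozen=True)
class AnnotationCandidate:
    entry: DatabaseEntry
    ppm: float  # signed: (query - theoretical) / theoretical * 1e6


def annotate_peak(mz: float, db: LipidDatabase, tol_ppm: float = 10.0) -> list[AnnotationCandidate]:
    """Candidates within ``tol_ppm`` of ``mz``, ranked |ppm| then class priority.

    Returns an empty list when nothing matches.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = tol_ppm * 1e-6
    hits = db.window(mz * (1 - tol), mz * (1 + tol))
    cands = []
    for e in hits:
        ppm = (mz - e.mz) / e.mz * 1e6
        if abs(ppm) <= tol_ppm:
            cands.append(AnnotationCandidate(e, ppm))
    # |ppm| quantized to 0.01 ppm so exact isobars (identical anion composition,
    # ppm differing only in float rounding of the adduct constants) fall back to
    # class priority rather than noise in the last digits.
    cands.sort(
        key=lambda c: (round(abs(c.ppm), 2), c.entry.species.lipid_class.priority, c.entry.mz)
    )
    return cands


@dataclass(frozen=True)
class Annotation:
    """Annotation of one m/z channel."""

    mz: float
    candidates: tuple[AnnotationCandidate, ...]

    @property
    def matched(self) -> bool:
        return bool(self.candidates)

    @property
    def top(self) -> AnnotationCandidate | None:
        return self.candidates[0] if self.candidates else None

    @property
    def label(self) -> str | None:
        """Species label; exact isobars within 0.1 ppm of the top hit are joined
        (e.g. ``PC 34:1/PE 36:1`` for the demethylated-PC / deprotonated-PE overlap)."""
        if not self.candidates:
            return None
        top = self.candidates[0]
        names = [top.entry.species.name]
        for c in self.candidates[1:]:
            if abs(abs(c.ppm) - abs(top.ppm)) <= 0.1 and c.entry.species.name not in names:
                names.append(c.entry.species.name)
        return "/".join(names)


def annotate_channels(
    centers: Iterable[float], db: LipidDatabase, tol_ppm: float = 10.0
) -> list[Annotation]:
    """Annotate a list of channel centers; unmatched channels carry no candidates."""
    return [Annotation(mz, tuple(annotate_peak(mz, db, tol_ppm))) for mz in centers]


def species_class(label: str) -> str:
    """Class abbreviation of a species label; joined labels resolve to the
    top-ranked (first) species."""
    first = label.split("/")[0]
    return first.rsplit(" ", 1)[0]
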