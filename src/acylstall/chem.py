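"""Elemental-formula bookkeeping for nuclease digestion products of aminoacyl-tRNAs.

Complete RNase I digestion of an aminoacylated tRNA releases the 3'-terminal
adenosine still esterified to its amino acid (aminoacyl-adenosine, aa-A);
Nuclease P1 instead leaves the 5'-phosphate on that adenosine
(aminoacyl-AMP, aa-AMP).  The alpha-amino group of the amino acid may carry a
modification: an acetyl group deposited in vivo by a GNAT toxin, a formyl
group (initiator Met), or an Fmoc group introduced chemically to stabilise and
mass-tag the non-acetylated pool.  Each (amino acid, modification, digestion)
combination is a distinct LC/MS analyte whose monoisotopic mass and [M+H]+ m/z
this module computes, along with detection of isobaric analytes that a mass
analyser cannot distinguish (e.g. Leu/Ile isomers, or glutamyl-AMP vs
N-acetyl-seryl-AMP).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ElementalFormula",
    "AminoAcidSpec",
    "ModificationSpec",
    "DigestProduct",
    "IsobarGroup",
    "AMINO_ACIDS",
    "MODIFICATIONS",
    "ADENOSINE",
    "WATER",
    "HPO3",
    "PROTON_MASS",
    "formula_mass",
    "build_product",
    "find_isobars",
    "species_table",
]

#: Monoisotopic atomic masses (Da) of the elements occurring in these analytes.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Mass of the proton added on [M+H]+ ionisation (not the H atom: the electron
#: stays behind).  The 2-dp m/z values this package is compared against are
#: insensitive to the ~0.5 mDa electron mass either way.
PROTON_MASS: float = 1.0072765

_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidFormulaError(ValueError):
    """Raised when formula arithmetic would produce a negative element count."""


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative element counts over C, H, N, O, P, S.

    Supports element-wise ``+`` and ``-``; subtraction that would drive any
    count negative raises :class:`InvalidFormulaError`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for elem, n in self.counts.items():
            if elem not in _ELEMENTS:
                raise InvalidFormulaError(f"unsupported element {elem!r}")
            n = int(n)
            if n < 0:
                raise InvalidFormulaError(f"negative count for {elem}: {n}")
            if n:
                clean[elem] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C10H13N5O4"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise InvalidFormulaError(f"cannot parse formula {text!r}")
            pos = match.end()
            elem, digits = match.groups()
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise InvalidFormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, elem: str) -> int:
        return self.counts.get(elem, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            {e: self[e] + other[e] for e in _ELEMENTS if self[e] + other[e]}
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        diff = {e: self[e] - other[e] for e in _ELEMENTS}
        if any(v < 0 for v in diff.values()):
            raise InvalidFormulaError(f"subtraction yields negative counts: {diff}")
        return ElementalFormula({e: v for e, v in diff.items() if v})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in self.counts.items())

    def __str__(self) -> str:
        return "".join(
            f"{e}{self[e] if self[e] != 1 else ''}" for e in _ELEMENTS if self[e]
        )


def formula_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass (Da) of ``formula``; the empty formula weighs 0."""
    return formula.mass


ADENOSINE = ElementalFormula.parse("C10H13N5O4")
WATER = ElementalFormula.parse("H2O")
HPO3 = ElementalFormula.parse("HPO3")


@dataclass(frozen=True)
class AminoAcidSpec:
    name: str
    code: str  # one-letter
    formula: ElementalFormula  # free amino acid


def _aa(name: str, code: str, formula: str) -> AminoAcidSpec:
    return AminoAcidSpec(name, code, ElementalFormula.parse(formula))


#: The 20 canonical amino acids (free-form compositions).  Leu and Ile are
#: structural isomers and share a formula, which is why LC/MS alone cannot
#: assign their digest products.
AMINO_ACIDS: dict[str, AminoAcidSpec] = {
    aa.code: aa
    for aa in [
        _aa("Glycine", "G", "C2H5NO2"),
        _aa("Alanine", "A", "C3H7NO2"),
        _aa("Serine", "S", "C3H7NO3"),
        _aa("Proline", "P", "C5H9NO2"),
        _aa("Valine", "V", "C5H11NO2"),
        _aa("Threonine", "T", "C4H9NO3"),
        _aa("Cysteine", "C", "C3H7NO2S"),
        _aa("Leucine", "L", "C6H13NO2"),
        _aa("Isoleucine", "I", "C6H13NO2"),
        _aa("Asparagine", "N", "C4H8N2O3"),
        _aa("Aspartate", "D", "C4H7NO4"),
        _aa("Glutamine", "Q", "C5H10N2O3"),
        _aa("Lysine", "K", "C6H14N2O2"),
        _aa("Glutamate", "E", "C5H9NO4"),
        _aa("Methionine", "M", "C5H11NO2S"),
        _aa("Histidine", "H", "C6H9N3O2"),
        _aa("Phenylalanine", "F", "C9H11NO2"),
        _aa("Arginine", "R", "C6H14N4O2"),
        _aa("Tyrosine", "Y", "C9H11NO3"),
        _aa("Tryptophan", "W", "C11H12N2O2"),
    ]
}


@dataclass(frozen=True)
class ModificationSpec:
    """Net composition change on the alpha-amino group."""

    name: str
    delta: ElementalFormula


#: Acylations of the alpha-amino group.  Each replaces one amine H with an acyl
#: group; the deltas below are the net composition change.
MODIFICATIONS: dict[str, ModificationSpec] = {
    "none": ModificationSpec("none", ElementalFormula({})),
    "acetyl": ModificationSpec("acetyl", ElementalFormula.parse("C2H2O")),
    "formyl": ModificationSpec("formyl", ElementalFormula.parse("CO")),
    "fmoc": ModificationSpec("fmoc", ElementalFormula.parse("C15H10O2")),
}

DIGESTIONS = ("rnase1", "p1")


@dataclass(frozen=True)
class DigestProduct:
    """A derivatized aminoacyl-(phospho)adenosine analyte.

    ``digestion`` is ``"rnase1"`` (aminoacyl-adenosine, no phosphate) or
    ``"p1"`` (aminoacyl-adenosine-5'-monophosphate).  The composition is

        amino acid + adenosine - H2O + modification delta [+ HPO3 for P1]

    with the aminoacyl ester condensation losing one water; 2' vs 3' ester
    positional isomers are mass-identical and not distinguished.
    """

    amino_acid: AminoAcidSpec
    modification: ModificationSpec
    digestion: str
    formula: ElementalFormula

    @property
    def neutral_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return self.formula.mass

    @property
    def mz_mh(self) -> float:
        """m/z of the singly protonated ion [M+H]+."""
        return self.neutral_mass + PROTON_MASS

    @property
    def label(self) -> str:
        mod = "" if self.modification.name == "none" else f"{self.modification.name}-"
        suffix = "AMP" if self.digestion == "p1" else "Ade"
        return f"{mod}{self.amino_acid.name[:3]}-{suffix}"


def build_product(
    aa: str | AminoAcidSpec,
    modification: str | ModificationSpec = "none",
    digestion: str = "rnase1",
) -> DigestProduct:
    """Assemble the digest product of one (modified) aminoacyl-tRNA.

    Parameters
    ----------
    aa
        One-letter code or :class:`AminoAcidSpec`.
    modification
        ``"none"``, ``"acetyl"``, ``"formyl"`` or ``"fmoc"`` (applied once to
        the alpha-amino group), or a :class:`ModificationSpec`.
    digestion
        ``"rnase1"`` -> aminoacyl-adenosine; ``"p1"`` -> aminoacyl-AMP.
    """
    if isinstance(aa, str):
        try:
            aa = AMINO_ACIDS[aa]
        except KeyError:
            raise KeyError(f"unknown amino-acid code {aa!r}") from None
    if isinstance(modification, str):
        try:
            modification = MODIFICATIONS[modification.lower()]
        except KeyError:
            raise KeyError(f"unknown modification {modification!r}") from None
    if digestion not in DIGESTIONS:
        raise ValueError(f"digestion must be one of {DIGESTIONS}, got {digestion!r}")
    formula = aa.formula + ADENOSINE - WATER + modification.delta
    if digestion == "p1":
        formula = formula + HPO3
    return DigestProduct(aa, modification, digestion, formula)


@dataclass(frozen=True)
class IsobarGroup:
    """A maximal set of analytes indistinguishable at the given mass tolerance."""

    products: tuple[DigestProduct, ...]
    tolerance_ppm: float

    @property
    def mass(self) -> float:
        return sum(p.neutral_mass for p in self.products) / len(self.products)

    def __len__(self) -> int:
        return len(self.products)


def find_isobars(
    products: Iterable[DigestProduct], tolerance_ppm: float = 5.0
) -> list[IsobarGroup]:
    """Partition analytes into maximal isobar groups.

    Two products are isobaric when their neutral masses differ by at most
    ``tolerance_ppm`` (relative to their mean); groups are the transitive
    closure of that relation, so chaining of borderline pairs merges them.
    Groups are returned sorted by mass; singletons are included.
    """
    products = list(products)
    if not products:
        raise ValueError("empty product list")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    ordered = sorted(products, key=lambda p: p.neutral_mass)
    groups: list[list[DigestProduct]] = [[ordered[0]]]
    for prod in ordered[1:]:
        prev = groups[-1][-1]
        mean = 0.5 * (prev.neutral_mass + prod.neutral_mass)
        if abs(prod.neutral_mass - prev.neutral_mass) <= tolerance_ppm * 1e-6 * mean:
            groups[-1].append(prod)
        else:
            groups.append([prod])
    return [IsobarGroup(tuple(g), tolerance_ppm) for g in groups]


def species_table(
    digestion: str = "rnase1",
    modifications: Iterable[str] = ("none", "acetyl", "fmoc"),
    tolerance_ppm: float = 5.0,
) -> pd.DataFrame:
    """All analytes for one digestion as a table, with isobar group ids.

    Columns: ``name, code, modification, formula, neutral_mass, mz_mh,
    isobar_group``.
    """
    products = [
        build_product(code, mod, digestion)
        for code, mod in itertools.product(AMINO_ACIDS, modifications)
    ]
    groups = find_isobars(products, tolerance_ppm)
    gid = {id(p): i for i, grp in enumerate(groups) for p in grp.products}
    rows = [
        {
            "name": p.amino_acid.name,
            "code": p.amino_acid.code,
            "modification": p.modification.name,
            "formula": str(p.formula),
            "neutral_mass": p.neutral_mass,
            "mz_mh": p.mz_mh,
            "isobar_group": gid[id(p)],
        }
        for p in products
    ]
    return pd.DataFrame(rows).sort_values(["neutral_mass", "code"]).reset_index(drop=True)
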