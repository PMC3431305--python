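"""Elemental formulas, monoisotopic masses, ESI+ adduct m/z arithmetic and
ppm matching against an offline compound table.

In positive-mode electrospray a neutral molecule M of monoisotopic mass
``M`` appears as a cation formed by addition/loss of small species
(H+, Na+, K+, Li+, neutral water or methanol), at charge z:

    m/z = (M + sum of carrier masses) / z

Carrier masses of ionizing species are *cation* masses (atomic mass
minus one electron mass), so the electron correction is already folded
in — e.g. a proton is 1.00727646 Da, not 1.00782503. Candidate
identities are matched by signed mass error in parts per million (Dppm)
with a configurable tolerance (10 ppm by default), ranked by |Dppm|;
exact ties are all reported. Compounds carry a Lipid Maps category
(FA, GL, GP, SP, ST, PR, SL, PK, plus ON/OS/NC) which maps onto a broad
polarity class: nonpolar (NP), polar lipid (PL), or not classified (NC).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

ELECTRON_MASS = 0.000548579909

#: monoisotopic atomic masses (Da), IUPAC/CODATA
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Li": 7.01600344,
    "Cl": 34.96885268,
}

LIPID_CATEGORIES = ("FA", "GL", "GP", "SP", "ST", "PR", "SL", "PK",
                    "ON", "OS", "NC")

#: Lipid Maps category -> broad polarity class
DEFAULT_BROAD_CLASS_MAP = {
    "FA": "NP", "ST": "NP",
    "GL": "PL", "GP": "PL", "PR": "PL", "PK": "PL", "SP": "PL", "SL": "PL",
    "ON": "NC", "OS": "NC", "NC": "NC",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map, e.g. C13H28 -> {C: 13, H: 28}."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style element-count string, rejecting unknown symbols."""
    text = text.strip()
    if not text:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        if not m.group(0):
            break
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {elem!r} in formula {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(tuple(sorted(counts.items())))


def format_formula(f: ElementalFormula) -> str:
    """Hill order: C first, H second, then alphabetical."""
    d = f.as_dict()
    parts = []
    for elem in ["C", "H"] + sorted(e for e in d if e not in ("C", "H")):
        if elem in d:
            n = d[elem]
            parts.append(elem + (str(n) if n != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass in daltons."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts)


# -- adducts ---------------------------------------------------------------

# cation masses = atomic mass - electron mass; neutral species unchanged
_PROTON = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
_NA_CATION = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
_K_CATION = MONOISOTOPIC_MASS["K"] - ELECTRON_MASS
_LI_CATION = MONOISOTOPIC_MASS["Li"] - ELECTRON_MASS
_WATER = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]
_METHANOL = (MONOISOTOPIC_MASS["C"] + 4 * MONOISOTOPIC_MASS["H"]
             + MONOISOTOPIC_MASS["O"])

SPECIES_MASS = {
    "H+": _PROTON,
    "Na+": _NA_CATION,
    "K+": _K_CATION,
    "Li+": _LI_CATION,
    "H2O": _WATER,
    "CH3OH": _METHANOL,
}


@dataclass(frozen=True)
class AdductRule:
    """One ESI+ adduct mode: name, charge, and signed carrier terms."""

    name: str
    charge: int
    carrier_terms: tuple[tuple[str, int], ...]   # (species, signed count)
    n_M: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def carrier_mass(self) -> float:
        return sum(SPECIES_MASS[s] * c for s, c in self.carrier_terms)


#: the 14 positive-ionization scan modes used for identification
ADDUCT_RULES: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", 1, (("H+", 1),)),
    AdductRule("[M+Na]+", 1, (("Na+", 1),)),
    AdductRule("[M+H-2H2O]+", 1, (("H+", 1), ("H2O", -2))),
    AdductRule("[M+H-H2O]+", 1, (("H+", 1), ("H2O", -1))),
    AdductRule("[M+K]+", 1, (("K+", 1),)),
    AdductRule("[M+2Na-H]+", 1, (("Na+", 2), ("H+", -1))),
    AdductRule("[M+2H]2+", 2, (("H+", 2),)),
    AdductRule("[M+3H]3+", 3, (("H+", 3),)),
    AdductRule("[M+H+Na]2+", 2, (("H+", 1), ("Na+", 1))),
    AdductRule("[M+2H+Na]3+", 3, (("H+", 2), ("Na+", 1))),
    AdductRule("[M+2Na]2+", 2, (("Na+", 2),)),
    AdductRule("[M+2Na+H]3+", 3, (("Na+", 2), ("H+", 1))),
    AdductRule("[M+Li]+", 1, (("Li+", 1),)),
    AdductRule("[M+CH3OH+H]+", 1, (("CH3OH", 1), ("H+", 1))),
)

ADDUCT_BY_NAME = {r.name: r for r in ADDUCT_RULES}
# tolerate the unicode minus and missing charge suffix in rule lookups
for _r in ADDUCT_RULES:
    ADDUCT_BY_NAME.setdefault(_r.name.replace("-", "−"), _r)


def adduct_mz(M: float, rule: AdductRule) -> float:
    """m/z of the adduct ion formed from a neutral of monoisotopic mass M."""
    if M <= 0:
        raise ValueError("neutral mass must be positive")
    mz = (M + rule.carrier_mass) / rule.charge
    if mz <= 0:
        raise ValueError(f"rule {rule.name} yields non-positive m/z for M={M}")
    return mz


def neutral_mass_from_mz(mz: float, rule: AdductRule) -> float:
    """Invert :func:`adduct_mz`: recover the neutral mass from an ion m/z."""
    return mz * rule.charge - rule.carrier_mass


def dppm(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# -- compound DB and matching ----------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: ElementalFormula
    lipid_category: str

    def __post_init__(self) -> None:
        if self.lipid_category not in LIPID_CATEGORIES:
            raise ValueError(f"unknown lipid category {self.lipid_category!r}")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AnnotationHit:
    query_mz: float
    compound: CompoundRecord | None
    adduct: AdductRule | None
    neutral_mass: float | None
    theoretical_mz: float | None
    dppm: float | None
    broad_class: str

    @property
    def is_nc(self) -> bool:
        return self.compound is None


def assign_broad_class(category: str,
                       mapping: dict[str, str] | None = None) -> str:
    """Map a Lipid Maps category to NP (nonpolar), PL (polar) or NC."""
    mapping = mapping or DEFAULT_BROAD_CLASS_MAP
    if category not in mapping:
        raise ValueError(f"unknown lipid category {category!r}")
    return mapping[category]


def annotate(mz: float, db: list[CompoundRecord],
             rules: tuple[AdductRule, ...] = ADDUCT_RULES,
             tol: float = 10.0,
             broad_class_map: dict[str, str] | None = None
             ) -> list[AnnotationHit]:
    """Match one query m/z against every (compound, adduct) pair.

    Hits with |Dppm| <= ``tol`` are ranked by |Dppm| ascending; exact ties
    are all kept. With no hit inside tolerance, a single NC placeholder
    hit is returned.
    """
    if not db:
        raise ValueError("compound database is empty")
    hits = []
    for compound in db:
        M = compound.neutral_mass
        for rule in rules:
            theo = adduct_mz(M, rule)
            err = dppm(mz, theo)
            if abs(err) <= tol:
                hits.append(AnnotationHit(
                    query_mz=mz, compound=compound, adduct=rule,
                    neutral_mass=M, theoretical_mz=theo, dppm=err,
                    broad_class=assign_broad_class(compound.lipid_category,
                                                   broad_class_map)))
    if not hits:
        return [AnnotationHit(query_mz=mz, compound=None, adduct=None,
                              neutral_mass=None, theoretical_mz=None,
                              dppm=None, broad_class="NC")]
    return sorted(hits, key=lambda h: abs(h.dppm))


def best_hits(hits: list[AnnotationHit]) -> list[AnnotationHit]:
    """Smallest-|Dppm| hit(s); all members of an exact rounded-ppm tie."""
    if hits[0].is_nc:
        return hits
    best = round(abs(hits[0].dppm))
    return [h for h in hits if round(abs(h.dppm)) == best]


# -- bundled reference tables ----------------------------------------------

def read_compound_db(path=None) -> list[CompoundRecord]:
    """Read a compound CSV (name, formula, category).

    Without a path, loads the bundled durum-vs-bread-wheat compound table.
    """
    if path is None:
        ref = resources.files("metaboprof.data") / "durum_bread_compounds.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for col in ("name", "formula", "category"):
        if col not in df.columns:
            raise ValueError(f"compound DB missing column {col!r}")
    return [CompoundRecord(name=str(r["name"]),
                           formula=parse_formula(str(r["formula"])),
                           lipid_category=str(r["category"]))
            for _, r in df.iterrows()]


def load_discriminatory_ion_table() -> pd.DataFrame:
    """Bundled table of the 35 discriminatory ions (one AME-tie ion listed
    twice) from the durum vs. bread wheat comparison, with adduct
    assignments, neutral masses, Lipid Maps categories and the wheat class
    each ion is elevated in."""
    ref = resources.files("metaboprof.data") / "durum_bread_ions.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, dtype={"ion_id": str})
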