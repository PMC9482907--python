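"""Exact-mass chemistry of the NAPS homologous series.

N-Alkylpyridinium-3-sulfonates (NAPS) are zwitterionic retention-index
standards for reversed-phase LC-MS.  The series spans N-alkyl chain lengths
C1-C20; the homolog with an n-carbon chain is assigned retention index
RI = 100 * n, so the series covers RI 100-2000.  The two permanent,
oppositely charged groups (quaternary pyridinium imine and sulfonate) make
retention essentially pH-independent and allow sensitive detection in both
ESI polarities: predominantly [M+H]+ in positive mode and [M+HCOO]- in
negative mode, with sodium adducts and gas-phase multimers ([2M+H]+,
[3M+Na]+, ...) appearing at higher concentrations.

Collision-induced dissociation yields a diagnostic fragment shared by the
whole series in each polarity: the N-methylene-pyridinium sulfonate cation
[C5H6NO3S]+ at m/z 160.0063 in positive mode and the sulfite radical anion
[SO3]-* at m/z 79.9574 in negative mode (theoretical value; instrument
calibration may report a figure a fraction of a mDa away).

All masses are monoisotopic, computed from NIST most-abundant-isotope
atomic masses, with electron-mass correction applied to charged species --
required for agreement with high-resolution instruments at the fourth
decimal.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ADDUCTS",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "ElementalComposition",
    "NapsHomolog",
    "AdductSpec",
    "naps_formula",
    "naps_homolog",
    "monoisotopic_mass",
    "adduct_mz",
    "formula_adduct_mz",
    "naps_mz_table",
]

#: NIST monoisotopic (most abundant isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

#: Electron rest mass, Da (CODATA).
ELECTRON_MASS: float = 0.00054857990907

PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Highest chain length present in the commercial NAPS mixture.
NAPS_MAX_CARBONS = 20

#: Homologs eluting in or close to the void volume under typical
#: reversed-phase gradients (C1-C3, RI 100-300).
LOW_RETENTION_MAX_CARBONS = 3


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> count mapping for a neutral or ionic species.

    Counts are non-negative integers and at least one must be positive.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for elem, cnt in self.counts.items():
            if not isinstance(cnt, int) or cnt < 0:
                raise ValueError(f"count for element {elem!r} must be a non-negative integer, got {cnt!r}")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("composition must contain at least one atom")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a plain molecular formula such as ``"C6H7NO3S"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            if not match.group(0):
                break
            elem, num = match.group(1), match.group(2)
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
            pos = match.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        parts = []
        for elem in order:
            cnt = self.counts[elem]
            if cnt == 0:
                continue
            parts.append(elem if cnt == 1 else f"{elem}{cnt}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formula()


@dataclass(frozen=True)
class NapsHomolog:
    """One member of the NAPS C1-C20 series.

    ``neutral_mass`` is the monoisotopic mass of the zwitterion (net charge
    zero); ``ri`` is the defined retention index, 100 times the alkyl chain
    length.
    """

    n_carbons: int
    composition: ElementalComposition
    neutral_mass: float
    ri: int

    @property
    def low_retention(self) -> bool:
        """True for C1-C3, which elute in or near the void volume."""
        return self.n_carbons <= LOW_RETENTION_MAX_CARBONS


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct/multimer: m/z = (multimer * M + mass_delta) / |charge|.

    ``mass_delta`` is the monoisotopic mass change of the charge carrier,
    already electron-mass corrected.
    """

    name: str
    multimer: int
    charge: int
    mass_delta: float

    def __post_init__(self) -> None:
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")
        if self.charge == 0:
            raise ValueError("charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "pos" if self.charge > 0 else "neg"


def _build_catalogue() -> dict[str, AdductSpec]:
    na = MONOISOTOPIC_MASS["Na"]
    formate = (
        MONOISOTOPIC_MASS["C"]
        + MONOISOTOPIC_MASS["H"]
        + 2 * MONOISOTOPIC_MASS["O"]
        + ELECTRON_MASS
    )
    specs = []
    for m in (1, 2, 3):
        pre = "" if m == 1 else str(m)
        specs += [
            AdductSpec(f"[{pre}M+H]+", m, +1, PROTON_MASS),
            AdductSpec(f"[{pre}M+Na]+", m, +1, na - ELECTRON_MASS),
            AdductSpec(f"[{pre}M-H]-", m, -1, -PROTON_MASS),
            AdductSpec(f"[{pre}M+HCOO]-", m, -1, formate),
        ]
    return {s.name: s for s in specs}


#: The supported adduct catalogue: protonated/deprotonated, sodiated and
#: formate species of the monomer, dimer and trimer in both polarities.
ADDUCTS: dict[str, AdductSpec] = _build_catalogue()
POSITIVE_ADDUCTS = [n for n, s in ADDUCTS.items() if s.charge > 0]
NEGATIVE_ADDUCTS = [n for n, s in ADDUCTS.items() if s.charge < 0]


def naps_formula(n_carbons: int) -> ElementalComposition:
    """Elemental composition of the neutral (zwitterionic) n-carbon NAPS.

    The pyridinium-3-sulfonate core contributes C5H4NO3S; the N-alkyl chain
    adds CnH(2n+1), giving C(5+n)H(5+2n)NO3S overall.
    """
    if n_carbons < 1:
        raise ValueError(f"NAPS chain length must be >= 1, got {n_carbons}")
    if n_carbons > NAPS_MAX_CARBONS:
        warnings.warn(
            f"n_carbons={n_carbons} is outside the C1-C{NAPS_MAX_CARBONS} series "
            "of the standard NAPS mixture",
            stacklevel=2,
        )
    return ElementalComposition(
        {"C": 5 + n_carbons, "H": 5 + 2 * n_carbons, "N": 1, "O": 3, "S": 1}
    )


def monoisotopic_mass(composition: ElementalComposition, charge: int = 0) -> float:
    """Monoisotopic mass (Da) of a composition, electron-corrected for charge.

    For an ion the composition lists the atoms actually present in the ion;
    ``charge`` removes (positive) or adds (negative) electron masses.
    """
    total = 0.0
    for elem, cnt in composition.counts.items():
        try:
            total += MONOISOTOPIC_MASS[elem] * cnt
        except KeyError:
            raise ValueError(f"no monoisotopic mass known for element {elem!r}") from None
    return total - charge * ELECTRON_MASS


def naps_homolog(n_carbons: int) -> NapsHomolog:
    """Construct the n-carbon NAPS homolog record (composition, mass, RI)."""
    comp = naps_formula(n_carbons)
    return NapsHomolog(
        n_carbons=n_carbons,
        composition=comp,
        neutral_mass=monoisotopic_mass(comp, charge=0),
        ri=100 * n_carbons,
    )


def _resolve_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        supported = ", ".join(sorted(ADDUCTS))
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported adducts: {supported}"
        ) from None


def adduct_mz(neutral_mass: float | NapsHomolog, adduct: AdductSpec | str) -> float:
    """m/z of an adduct ion: (multimer * M + mass_delta) / |charge|."""
    spec = _resolve_adduct(adduct)
    mass = neutral_mass.neutral_mass if isinstance(neutral_mass, NapsHomolog) else neutral_mass
    mz = (spec.multimer * mass + spec.mass_delta) / abs(spec.charge)
    if mz <= 0:
        raise ValueError(f"non-positive m/z for adduct {spec.name} of M={mass}")
    return mz


def formula_adduct_mz(formula: str, adduct: AdductSpec | str) -> float:
    """m/z of an adduct of a neutral molecule given as a formula string."""
    comp = ElementalComposition.from_formula(formula)
    return adduct_mz(monoisotopic_mass(comp, charge=0), adduct)


def naps_mz_table(
    n_range: tuple[int, int] = (1, NAPS_MAX_CARBONS),
    adducts: list[AdductSpec | str] | None = None,
) -> pd.DataFrame:
    """Reference m/z table for the NAPS series.

    One row per (homolog, adduct), sorted by chain length then adduct, with
    columns ``n_carbons, ri, adduct, polarity, mz, low_retention``.  The
    ``low_retention`` flag marks C1-C3, which elute in or near the void
    volume and are excluded from robust indexing.
    """
    lo, hi = n_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid n_range {n_range}; need 1 <= lo <= hi")
    if adducts is None:
        adducts = list(ADDUCTS)
    if not adducts:
        raise ValueError("adduct list must not be empty")
    specs = [_resolve_adduct(a) for a in adducts]
    rows = []
    for n in range(lo, hi + 1):
        hom = naps_homolog(n)
        for spec in specs:
            rows.append(
                {
                    "n_carbons": n,
                    "ri": hom.ri,
                    "adduct": spec.name,
                    "polarity": spec.polarity,
                    "mz": adduct_mz(hom, spec),
                    "low_retention": hom.low_retention,
                }
            )
    return pd.DataFrame(rows)
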