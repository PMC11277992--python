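"""Molecular-formula arithmetic for HRESIMS validation.

Parsing of flat molecular formulas, monoisotopic masses, adduct m/z with
electron-mass correction, signed ppm errors, degrees of unsaturation (DBE)
and coarse isotope-pattern simulation (nominal-mass resolution), including
the M+2/M test used to spot a single chlorine atom from its ~3:1 isotope
signature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ELEMENTS",
    "ELECTRON_MASS",
    "MolecularFormula",
    "AdductSpec",
    "IsotopePattern",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "degrees_of_unsaturation",
    "isotope_pattern",
    "chlorine_signature",
]

#: Rest mass of the electron in Da.
ELECTRON_MASS = 0.000548579909


@dataclass(frozen=True)
class ElementData:
    """Monoisotopic mass, isotope distribution and valence of one element.

    ``isotopes`` is a list of ``(exact mass Da, natural abundance)`` pairs;
    abundances sum to 1 and the most abundant isotope defines the
    monoisotopic mass.
    """

    monoisotopic: float
    isotopes: Tuple[Tuple[float, float], ...]
    valence: int

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.isotopes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"isotope abundances sum to {total}, not 1")
        most = max(self.isotopes, key=lambda p: p[1])[0]
        if abs(most - self.monoisotopic) > 1e-6:
            raise ValueError("monoisotopic mass is not the most abundant isotope")
        if any(m <= 0 for m, _ in self.isotopes):
            raise ValueError("isotope masses must be positive")


# IUPAC/CODATA monoisotopic masses and isotopic abundances.
ELEMENTS: Dict[str, ElementData] = {
    "H": ElementData(1.00782503207, ((1.00782503207, 0.999885), (2.01410177785, 0.000115)), 1),
    "C": ElementData(12.0, ((12.0, 0.9893), (13.00335483507, 0.0107)), 4),
    "N": ElementData(14.0030740048, ((14.0030740048, 0.99636), (15.0001088989, 0.00364)), 3),
    "O": ElementData(
        15.9949146196,
        ((15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)),
        2,
    ),
    "F": ElementData(18.99840322, ((18.99840322, 1.0),), 1),
    "Na": ElementData(22.9897692809, ((22.9897692809, 1.0),), 1),
    "S": ElementData(
        31.97207100,
        ((31.97207100, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425), (35.96708076, 0.0001)),
        2,
    ),
    "Cl": ElementData(34.96885268, ((34.96885268, 0.7576), (36.96590259, 0.2424)), 1),
    "P": ElementData(30.97376163, ((30.97376163, 1.0),), 3),
    "Br": ElementData(78.9183371, ((78.9183371, 0.5069), (80.9162906, 0.4931)), 1),
    "I": ElementData(126.904473, ((126.904473, 1.0),), 1),
}


class MolecularFormula(dict):
    """Element → count map for a neutral molecule.

    A thin ``dict`` subclass so that formulas print and compare naturally;
    construction validates element symbols and integer counts and drops
    zero counts.
    """

    def __init__(self, counts: Mapping[str, int]):
        cleaned: Dict[str, int] = {}
        for sym, n in counts.items():
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, (int, np.integer)):
                raise ValueError(f"count for {sym} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
            if n > 0:
                cleaned[sym] = int(n)
        if not cleaned:
            raise ValueError("formula must contain at least one atom")
        super().__init__(cleaned)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        order = [s for s in ("C", "H") if s in self]
        order += sorted(s for s in self if s not in ("C", "H"))
        return "".join(f"{s}{self[s] if self[s] != 1 else ''}" for s in order)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a flat formula string such as ``"C15H24O3"``.

    No parentheses, charges or isotope labels are accepted; repeated
    element symbols accumulate.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    return float(sum(ELEMENTS[s].monoisotopic * n for s, n in formula.items()))


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: formula delta, charge and electron handling.

    ``delta`` maps element symbols to signed counts added to the neutral
    molecule; ``charge`` is +1 or -1.  The electron-mass correction is
    always applied: cations lose one electron mass, anions gain one.
    """

    name: str
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.charge not in (+1, -1):
            raise ValueError("only singly charged adducts are supported")


def _normalize_adduct_name(name: str) -> str:
    return name.replace("−", "-").replace("–", "-").replace(" ", "")


#: Registered adducts, keyed by normalized name.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, +1),
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, +1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
    "[M+Cl]-": AdductSpec("[M+Cl]-", {"Cl": 1}, -1),
}


def register_adduct(name: str, delta: Mapping[str, int], charge: int) -> None:
    """Add or replace an adduct in the registry (used by config files)."""
    key = _normalize_adduct_name(name)
    ADDUCTS[key] = AdductSpec(key, dict(delta), charge)


def get_adduct(name: str) -> AdductSpec:
    key = _normalize_adduct_name(name)
    try:
        return ADDUCTS[key]
    except KeyError:
        known = ", ".join(sorted(ADDUCTS))
        raise ValueError(f"unregistered adduct {name!r}; known adducts: {known}") from None


def adduct_mz(formula: Mapping[str, int], adduct: "AdductSpec | str") -> float:
    """m/z of an adduct ion of a neutral molecule.

    m/z = (M + delta − z·m_e) / |z|; for singly charged ions this is the
    ion mass itself.  Full precision is returned; round to 4 decimals only
    for presentation.
    """
    spec = get_adduct(adduct) if isinstance(adduct, str) else adduct
    m = monoisotopic_mass(formula)
    m += float(sum(ELEMENTS[s].monoisotopic * n for s, n in spec.delta.items()))
    m -= spec.charge * ELECTRON_MASS
    return m / abs(spec.charge)


def ppm_error(observed: float, calculated: float) -> float:
    """Signed mass error in parts per million: 1e6·(obs − calc)/calc."""
    if observed <= 0 or calculated <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed - calculated) / calculated


def degrees_of_unsaturation(formula: Mapping[str, int]) -> float:
    """Degrees of unsaturation (DBE): 1 + Σ n_i(v_i − 2)/2.

    With standard valences (C 4, N/P 3, O/S 2, H/halogen 1) this counts
    rings plus π-bonds; it is an integer for any even-electron neutral
    formula.
    """
    dbe = 1.0
    for sym, n in formula.items():
        v = ELEMENTS[sym].valence
        dbe += n * (v - 2) / 2.0
    return dbe


@dataclass(frozen=True)
class IsotopePattern:
    """Relative isotopologue intensities at nominal mass offsets M+0, M+1, ...

    ``peaks`` is a list of ``(offset, intensity)`` sorted by offset with the
    tallest peak normalized to 1.
    """

    peaks: Tuple[Tuple[int, float], ...]

    def __post_init__(self) -> None:
        offs = [o for o, _ in self.peaks]
        if offs != sorted(offs) or (offs and offs[0] != 0):
            raise ValueError("peaks must start at offset 0 and be sorted")
        if any(not (0.0 <= i <= 1.0 + 1e-12) for _, i in self.peaks):
            raise ValueError("intensities must lie in [0, 1]")

    def intensity(self, offset: int) -> float:
        for o, i in self.peaks:
            if o == offset:
                return i
        raise ValueError(f"pattern has no peak at offset {offset}")

    @property
    def m_plus_2_ratio(self) -> float:
        """Intensity ratio (M+2)/(M+0)."""
        base = self.intensity(0)
        if base <= 0:
            raise ValueError("M+0 intensity is zero")
        return self.intensity(2) / base


def _element_profile(sym: str, n: int, max_offset: int) -> np.ndarray:
    """Isotopologue distribution of n atoms of one element on nominal slots."""
    el = ELEMENTS[sym]
    base = np.zeros(max_offset + 1)
    mono_nominal = round(el.monoisotopic)
    for m, a in el.isotopes:
        off = round(m) - mono_nominal
        if off <= max_offset:
            base[off] += a
    # n-fold self-convolution by binary exponentiation
    out = np.zeros(max_offset + 1)
    out[0] = 1.0
    acc = base
    k = n
    while k:
        if k & 1:
            out = np.convolve(out, acc)[: max_offset + 1]
        k >>= 1
        if k:
            acc = np.convolve(acc, acc)[: max_offset + 1]
    return out


def isotope_pattern(formula: Mapping[str, int], max_offset: int = 4) -> IsotopePattern:
    """Nominal-mass isotope pattern by convolving per-element distributions.

    Isotopes land on integer M+k slots by their integer mass difference
    from the monoisotopic isotope (e.g. 37Cl on M+2, 13C on M+1).  The
    tallest peak is normalized to 1.  Fine structure within a slot is
    deliberately merged — this mirrors what a unit-resolution read of an
    ESI spectrum shows.
    """
    if max_offset < 2:
        raise ValueError("max_offset must be at least 2")
    profile = np.zeros(max_offset + 1)
    profile[0] = 1.0
    for sym, n in formula.items():
        profile = np.convolve(profile, _element_profile(sym, n, max_offset))[: max_offset + 1]
    profile /= profile.max()
    return IsotopePattern(tuple((k, float(v)) for k, v in enumerate(profile)))


#: M+2/M window consistent with exactly one chlorine (theoretical ~0.32).
CHLORINE_M2_WINDOW = (0.24, 0.42)


def chlorine_signature(pattern: IsotopePattern) -> bool:
    """True iff the M+2/M ratio falls in the one-chlorine window [0.24, 0.42].

    The 3:1 ratio of 35Cl:37Cl makes a molecule with one Cl show an M+2
    peak at roughly a third of the monoisotopic peak.
    """
    lo, hi = CHLORINE_M2_WINDOW
    return lo <= pattern.m_plus_2_ratio <= hi
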