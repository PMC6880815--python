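"""Exact monoisotopic mass, adduct m/z, DBE and constrained formula search.

High-resolution ESI-MS annotations are validated by recomputing the
theoretical m/z of the observed adduct ion from the proposed neutral
molecular formula.  The ion m/z is

    m/z = (sum of monoisotopic atomic masses of the adduct-adjusted
           formula  -  z * m_e) / |z|

where ``m_e`` is the electron rest mass; omitting the electron term
shifts a singly-charged ion by ~0.00055 Da, enough to break agreement
with printed values at the fourth decimal.

Double-bond equivalents (rings plus pi bonds) follow the standard CHNO
convention DBE = C - H/2 + N/2 + 1, with monovalent metals (Na) counted
like hydrogen and divalent O/S ignored.  DBE of a sodiated or protonated
ion is always computed on the neutral formula.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "ADDUCTS",
    "parse_formula",
    "adduct_mz",
    "dbe",
    "ppm_error",
    "formula_search",
    "round4",
]

# Monoisotopic masses of the most abundant isotope (Da), IUPAC/CODATA.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "S": 31.9720710015,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "K": 38.96370668,
    "Si": 27.9769265325,
}

ELECTRON_MASS = 0.000548579909  # Da

# Valence contribution to DBE per atom: (valence - 2) / 2.
# Monovalent atoms count -1/2, trivalent +1/2, tetravalent +1; O/S (divalent) zero.
_DBE_WEIGHT: dict[str, float] = {
    "C": 1.0,
    "Si": 1.0,
    "H": -0.5,
    "Na": -0.5,
    "K": -0.5,
    "F": -0.5,
    "Cl": -0.5,
    "Br": -0.5,
    "I": -0.5,
    "N": 0.5,
    "P": 0.5,
    "O": 0.0,
    "S": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element→count map with Hill-order formatting."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty molecular formula")
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        items = {el: int(n) for el, n in counts.items() if n != 0}
        if not items:
            raise ValueError("empty molecular formula")
        return cls(tuple(sorted(items.items(), key=_hill_key)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def add(self, delta: dict[str, int]) -> "MolecularFormula":
        merged = dict(self.counts)
        for el, d in delta.items():
            merged[el] = merged.get(el, 0) + d
            if merged[el] < 0:
                raise ValueError(
                    f"adduct arithmetic gives negative {el} count for {self}"
                )
        return MolecularFormula.from_dict(merged)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts
        )

    def __repr__(self) -> str:
        return f"MolecularFormula({self})"


def _hill_key(item: tuple[str, int]) -> tuple[int, str]:
    # Hill order: C first, H second, then alphabetical (only when C present;
    # formulas handled here are all carbon-bearing or trivially small, so the
    # carbon-first convention is applied unconditionally).
    el = item[0]
    return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula string, e.g. ``C15H22O5``."""
    text = text.strip()
    if not text:
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula at {text[pos:]!r}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula at {text[pos:]!r}")
    return MolecularFormula.from_dict(counts)


@dataclass(frozen=True)
class AdductSpec:
    """Charged-species definition: element delta applied to M, and charge."""

    name: str
    delta: tuple[tuple[str, int], ...]
    charge: int = 1

    def apply(self, neutral: MolecularFormula) -> MolecularFormula:
        try:
            return neutral.add(dict(self.delta))
        except ValueError as exc:
            raise ValueError(f"adduct {self.name} not applicable to {neutral}: {exc}")


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", (("H", 1),)),
    "[M+Na]+": AdductSpec("[M+Na]+", (("Na", 1),)),
    "[M-H2O+H]+": AdductSpec("[M-H2O+H]+", (("H", -1), ("O", -1))),
}


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by name; the Unicode minus sign is accepted."""
    canonical = name.replace("−", "-").replace(" ", "")
    if canonical not in ADDUCTS:
        raise ValueError(
            f"unknown adduct {name!r}; supported: {', '.join(ADDUCTS)}"
        )
    return ADDUCTS[canonical]


def round4(x: float) -> float:
    """Round half-even to 4 decimals, the reporting convention for m/z."""
    return float(np.round(x, 4))


def adduct_mz(
    neutral: MolecularFormula | str,
    adduct: AdductSpec | str,
    *,
    rounded: bool = True,
) -> float:
    """Theoretical m/z of the adduct ion of a neutral formula.

    Full float precision is kept internally; ``rounded=True`` (default)
    applies the 4-decimal half-even reporting convention.
    """
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    ion = adduct.apply(neutral)
    mz = (ion.monoisotopic_mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)
    return round4(mz) if rounded else mz


def dbe(neutral: MolecularFormula | str) -> float:
    """Double-bond equivalents of a neutral formula (rings + pi bonds)."""
    if isinstance(neutral, str):
        neutral = parse_formula(neutral)
    total = 1.0
    for el, n in neutral.counts:
        try:
            total += _DBE_WEIGHT[el] * n
        except KeyError:
            raise ValueError(f"no DBE valence convention for element {el}")
    return total


def ppm_error(calcd: float, found: float) -> float:
    """Relative mass error of an observed ion in parts per million."""
    if calcd <= 0:
        raise ValueError("calculated m/z must be positive")
    return (found - calcd) / calcd * 1e6


@dataclass
class FormulaCandidate:
    formula: MolecularFormula
    mz: float
    ppm: float
    dbe: float


_DEFAULT_BOUNDS = {"C": 40, "H": 80, "N": 5, "O": 15}


def formula_search(
    observed_mz: float,
    adduct: AdductSpec | str,
    tolerance_ppm: float = 5.0,
    element_bounds: dict[str, int] | None = None,
) -> list[FormulaCandidate]:
    """Enumerate neutral CHNO-type formulas whose adduct ion matches a mass.

    Exhaustive grid search over the element bounds (defaults C<=40, H<=80,
    N<=5, O<=15), filtered by |ppm| <= tolerance, 0 <= DBE <= 20, and
    integer DBE (even-electron ion consistency); ranked by |ppm|.
    An empty result is returned as an empty list, not an error.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    bounds = dict(_DEFAULT_BOUNDS)
    if element_bounds is not None:
        bounds = {el: int(n) for el, n in element_bounds.items()}
    for el in bounds:
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol in bounds: {el!r}")

    elements = sorted(bounds, key=_hill_key)
    axes = [np.arange(bounds[el] + 1) for el in elements]
    grids = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)  # (n, k)

    delta = dict(adduct.delta)
    ion_counts = counts.astype(np.int64).copy()
    for j, el in enumerate(elements):
        if el in delta:
            ion_counts[:, j] += delta[el]
    # adducts touching elements outside the search space (e.g. Na)
    extra_mass = sum(
        MONOISOTOPIC_MASS[el] * d for el, d in delta.items() if el not in elements
    )

    valid = np.all(ion_counts >= 0, axis=1) & (counts.sum(axis=1) > 0)

    masses = np.array([MONOISOTOPIC_MASS[el] for el in elements])
    ion_mass = ion_counts @ masses + extra_mass
    mz = (ion_mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)
    ppm = (observed_mz - mz) / np.where(mz > 0, mz, np.nan) * 1e6

    weights = np.array([_DBE_WEIGHT[el] for el in elements])
    dbe_vals = counts @ weights + 1.0

    keep = (
        valid
        & (np.abs(ppm) <= tolerance_ppm)
        & (dbe_vals >= 0.0)
        & (dbe_vals <= 20.0)
        & (np.abs(dbe_vals - np.round(dbe_vals)) < 1e-9)
    )
    idx = np.flatnonzero(keep)
    idx = idx[np.argsort(np.abs(ppm[idx]), kind="stable")]

    out: list[FormulaCandidate] = []
    for i in idx:
        fdict = {el: int(counts[i, j]) for j, el in enumerate(elements) if counts[i, j]}
        out.append(
            FormulaCandidate(
                formula=MolecularFormula.from_dict(fdict),
                mz=round4(float(mz[i])),
                ppm=float(ppm[i]),
                dbe=float(dbe_vals[i]),
            )
        )
    return out
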