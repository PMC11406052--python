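"""Element-property store and binary metal-oxide formula parsing.

Every physical constant the periodic-table descriptors consume comes from a
single curated CSV shipped with the package.  Two valence-electron ("Zv")
conventions are exposed as *profiles*:

``paper_compat``
    Zv is the number of electrons in the outermost occupied shell of the
    ground-state atom: the ns count for s- and d-block metals (Mn -> 2,
    Ru -> 1, Pt -> 1, Au -> 1), ns+np for p-block metals (Pb -> 4, Bi -> 5)
    and 18 for Pd, whose outermost occupied shell is n=4 (4s2 4p6 4d10).
    Vanadium carries a per-element override (Zv=5) stored directly in the
    data table.  This is the convention under which the second-generation
    descriptor chain reproduces published (sum alpha)^2 reference values.

``standard``
    Conventional group-valence counts, provided for comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from fractions import Fraction
from functools import lru_cache

import pandas as pd

__all__ = [
    "ElementRecord",
    "OxideComposition",
    "ElementLookupError",
    "MissingConstantError",
    "FormulaError",
    "get_element",
    "parse_oxide",
    "element_table",
    "PROFILES",
]

PROFILES = ("paper_compat", "standard")

OXYGEN_MASS = 15.999


class ElementLookupError(KeyError):
    """Raised when a symbol is absent from the selected table profile."""


class MissingConstantError(ValueError):
    """Raised when a tabulated constant required by a descriptor is absent.

    Constants are never silently replaced by zero.
    """


class FormulaError(ValueError):
    """Raised for formulas that are not parseable binary metal oxides."""


@dataclass(frozen=True)
class ElementRecord:
    """Physical constants for one element under a given Zv profile.

    Radii are in pm, density in g/cm^3, electron affinity and first
    ionization energy in eV.  ``r_ion`` maps oxidation state -> crystal
    ionic radius (Shannon, coordination VI).
    """

    symbol: str
    Z: int
    atomic_mass: float
    chi: float
    Zv: int
    PN: int
    a0: float
    r_ion: dict[int, float] = field(default_factory=dict)
    d_metal: float | None = None
    Ea: float | None = None
    I1: float | None = None

    def __post_init__(self) -> None:
        if self.Z < 1 or self.PN < 1:
            raise ValueError(f"{self.symbol}: Z and PN must be >= 1")
        if not 1 <= self.Zv <= 18:
            raise ValueError(f"{self.symbol}: Zv={self.Zv} outside [1, 18]")
        if self.symbol != "O" and self.Zv >= self.Z:
            raise ValueError(f"{self.symbol}: no core electrons (Zv >= Z)")
        if self.atomic_mass <= 0 or self.a0 <= 0:
            raise ValueError(f"{self.symbol}: mass and radii must be > 0")

    def ionic_radius(self, ox_state: float) -> float:
        """Crystal ionic radius for ``ox_state``, nearest tabulated state.

        Mixed-valence oxides carry a fractional average oxidation number;
        the nearest tabulated integer state is used (ties toward the lower
        state).
        """
        if not self.r_ion:
            raise MissingConstantError(
                f"{self.symbol}: no ionic radius tabulated (requested state "
                f"{ox_state}); available states: none"
            )
        best = min(self.r_ion, key=lambda s: (abs(s - ox_state), s))
        return self.r_ion[best]


@dataclass(frozen=True)
class OxideComposition:
    """A parsed binary metal oxide M_a O_b.

    ``chi_ox`` is the (average) oxidation number of the metal implied by
    charge balance with O(-II): 2*N_oxy/N_metal, kept exact as a Fraction.
    """

    metal: str
    N_metal: int
    N_oxy: int

    @property
    def chi_ox(self) -> Fraction:
        return Fraction(2 * self.N_oxy, self.N_metal)

    @property
    def formula(self) -> str:
        """Canonical formula string (subscript 1 omitted)."""
        m = self.metal if self.N_metal == 1 else f"{self.metal}{self.N_metal}"
        o = "O" if self.N_oxy == 1 else f"O{self.N_oxy}"
        return m + o


_SUBSCRIPT_MAP = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@lru_cache(maxsize=None)
def element_table() -> pd.DataFrame:
    """The shipped element-property table, indexed by symbol."""
    with resources.files("nanoqrastr.data").joinpath(
        "element_properties.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("symbol", drop=False)


@lru_cache(maxsize=None)
def get_element(symbol: str, profile: str = "paper_compat") -> ElementRecord:
    """Look up one element's constants under the given Zv profile.

    Raises :class:`ElementLookupError` for unknown symbols and
    :class:`ValueError` for unknown profiles.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    table = element_table()
    if symbol not in table.index:
        raise ElementLookupError(
            f"element {symbol!r} not in the {profile} table"
        )
    row = table.loc[symbol]
    zv_col = "Zv_paper" if profile == "paper_compat" else "Zv_standard"
    r_ion = {}
    if pd.notna(row["r_ion_pm"]):
        r_ion[int(row["ox_state_for_r_ion"])] = float(row["r_ion_pm"])

    def _opt(col: str) -> float | None:
        return float(row[col]) if pd.notna(row[col]) else None

    return ElementRecord(
        symbol=symbol,
        Z=int(row["Z"]),
        atomic_mass=float(row["atomic_mass"]),
        chi=float(row["chi_pauling"]),
        Zv=int(row[zv_col]),
        PN=int(row["period"]),
        a0=float(row["a0_pm"]),
        r_ion=r_ion,
        d_metal=_opt("density_gcc"),
        Ea=_opt("Ea_eV"),
        I1=_opt("I1_eV"),
    )


def parse_oxide(formula: str) -> OxideComposition:
    """Parse a binary metal-oxide formula such as ``Al2O3`` or ``Co3O4``.

    Whitespace and unicode subscript digits are tolerated.  The formula must
    contain exactly one metal element and oxygen, both with count >= 1.
    """
    cleaned = re.sub(r"\s+", "", str(formula)).translate(_SUBSCRIPT_MAP)
    if not cleaned:
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    order: list[str] = []
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"unparseable fragment {cleaned[pos:]!r} in formula {formula!r}"
            )
        sym, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero subscript for {sym!r} in {formula!r}")
        if sym not in counts:
            order.append(sym)
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if "O" not in counts:
        raise FormulaError(f"{formula!r} contains no oxygen")
    metals = [s for s in order if s != "O"]
    if len(metals) != 1:
        raise FormulaError(
            f"{formula!r} must contain exactly one metal element, found "
            f"{metals or 'none'}"
        )
    return OxideComposition(
        metal=metals[0], N_metal=counts[metals[0]], N_oxy=counts["O"]
    )
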