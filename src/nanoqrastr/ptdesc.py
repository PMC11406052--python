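"""Periodic-table descriptors for binary metal oxides.

Three descriptor generations are computed for each oxide M_a O_b from the
metal's tabulated constants and the stoichiometry alone:

* first generation (7): molecular weight, atom counts, metal
  electronegativity chi, its total sum_chi = chi * N_metal, sum_chi per
  oxygen, and the oxidation number chi_ox = 2*N_oxy/N_metal;
* second generation (16): the core-environment chain
  lambda = (Z - Zv)/Zv, mu = 1/(PN - 1), alpha = lambda*mu,
  sum_alpha = alpha*N_metal + 0.33*N_oxy (a molecular-bulk measure, also
  squared), and the electronegativity counts
  eps_metal = -alpha + 0.3*Zv, eps_oxy = 1.47 (the oxygen constant
  -0.33 + 0.3*6), sum_eps and sum_eps/N;
* third generation (5): atomic radius a0, crystal ionic radius r_ion
  (resolved by the oxide's oxidation state), elemental density, electron
  affinity, first ionization energy.

The oxygen contribution to sum_alpha uses the literal coefficient 0.33
(not 1/3): reference values such as MgO -> 8.0089 -> 8.01 fix the constant.
"""

from __future__ import annotations

import math

import pandas as pd

from .elements import (
    ElementRecord,
    FormulaError,
    MissingConstantError,
    OxideComposition,
    get_element,
    parse_oxide,
)

__all__ = [
    "COLUMNS",
    "ALPHA_OXY_COEF",
    "EPS_OXY",
    "first_generation",
    "second_generation",
    "third_generation",
    "compute_descriptors",
    "descriptor_table",
    "DescriptorTableError",
]

#: oxygen coefficient in sum_alpha_oxy = N_oxy * 0.33 (literal, not 1/3)
ALPHA_OXY_COEF = 0.33
#: eps for oxygen, -alpha_oxy + 0.3 * Zv_oxy = -0.33 + 0.3 * 6
EPS_OXY = -ALPHA_OXY_COEF + 0.3 * 6

#: deterministic column order of the full 28-descriptor table
COLUMNS = (
    "MW", "N_metal", "N_oxy", "chi", "sum_chi", "sum_chi_per_O", "chi_ox",
    "Z_metal", "Zv_metal", "PN_metal", "lambda", "mu", "V_metal",
    "alpha_metal", "sum_alpha_metal", "sum_alpha_oxy", "sum_alpha",
    "eps_metal", "eps_oxy", "sum_eps", "sum_eps_per_N",
    "sum_alpha_sq", "sum_eps_per_N_sq",
    "a0", "r_ion", "d_metal", "Ea", "I1",
)


class DescriptorTableError(ValueError):
    """Aggregated per-formula failures from :func:`descriptor_table`."""

    def __init__(self, failures: dict[str, Exception]):
        self.failures = failures
        lines = "; ".join(f"{f}: {e}" for f, e in failures.items())
        super().__init__(f"descriptor computation failed for: {lines}")


def first_generation(
    comp: OxideComposition, elem: ElementRecord
) -> dict[str, float]:
    """Stoichiometry / electronegativity descriptors (7 values)."""
    from .elements import OXYGEN_MASS

    mw = comp.N_metal * elem.atomic_mass + comp.N_oxy * OXYGEN_MASS
    sum_chi = elem.chi * comp.N_metal
    return {
        "MW": mw,
        "N_metal": float(comp.N_metal),
        "N_oxy": float(comp.N_oxy),
        "chi": elem.chi,
        "sum_chi": sum_chi,
        "sum_chi_per_O": sum_chi / comp.N_oxy,
        "chi_ox": float(comp.chi_ox),
    }


def second_generation(
    comp: OxideComposition, elem: ElementRecord
) -> dict[str, float]:
    """Core-environment chain descriptors (16 values).

    Undefined for period-1 elements (mu = 1/(PN-1)); no period-1 metal
    oxide is expected, so this raises rather than returning inf.
    """
    if elem.PN < 2:
        raise MissingConstantError(
            f"{elem.symbol}: mu = 1/(PN-1) undefined for period {elem.PN}"
        )
    lam = (elem.Z - elem.Zv) / elem.Zv
    mu = 1.0 / (elem.PN - 1)
    alpha = lam * mu
    sum_alpha_metal = alpha * comp.N_metal
    sum_alpha_oxy = ALPHA_OXY_COEF * comp.N_oxy
    sum_alpha = sum_alpha_metal + sum_alpha_oxy
    eps_metal = -alpha + 0.3 * elem.Zv
    sum_eps = eps_metal * comp.N_metal + EPS_OXY * comp.N_oxy
    n_atoms = comp.N_metal + comp.N_oxy
    sum_eps_per_n = sum_eps / n_atoms
    return {
        "Z_metal": float(elem.Z),
        "Zv_metal": float(elem.Zv),
        "PN_metal": float(elem.PN),
        "lambda": lam,
        "mu": mu,
        # valence of the metal: charge-balance valence (= chi_ox) by default
        "V_metal": float(comp.chi_ox),
        "alpha_metal": alpha,
        "sum_alpha_metal": sum_alpha_metal,
        "sum_alpha_oxy": sum_alpha_oxy,
        "sum_alpha": sum_alpha,
        "eps_metal": eps_metal,
        "eps_oxy": EPS_OXY,
        "sum_eps": sum_eps,
        "sum_eps_per_N": sum_eps_per_n,
        "sum_alpha_sq": sum_alpha ** 2,
        "sum_eps_per_N_sq": sum_eps_per_n ** 2,
    }


def third_generation(
    comp: OxideComposition, elem: ElementRecord
) -> dict[str, float]:
    """Tabulated atomic constants (5 values); r_ion resolved by oxidation state."""
    vals = {
        "a0": elem.a0,
        "r_ion": elem.ionic_radius(float(comp.chi_ox)),
        "d_metal": elem.d_metal,
        "Ea": elem.Ea,
        "I1": elem.I1,
    }
    missing = [k for k, v in vals.items() if v is None or (
        isinstance(v, float) and math.isnan(v))]
    if missing:
        raise MissingConstantError(
            f"{elem.symbol}: missing constants {missing}"
        )
    return vals


def compute_descriptors(
    formula: str, profile: str = "paper_compat"
) -> dict[str, float]:
    """All 28 descriptors for one formula, keyed by :data:`COLUMNS` names."""
    comp = parse_oxide(formula)
    elem = get_element(comp.metal, profile)
    out: dict[str, float] = {}
    out.update(first_generation(comp, elem))
    out.update(second_generation(comp, elem))
    out.update(third_generation(comp, elem))
    return {c: out[c] for c in COLUMNS}


def descriptor_table(
    formulas: list[str], profile: str = "paper_compat"
) -> pd.DataFrame:
    """28-column descriptor table, one row per compound, indexed by formula.

    Per-row failures are aggregated into a single
    :class:`DescriptorTableError` naming every bad formula.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: dict[str, Exception] = {}
    for f in formulas:
        try:
            rows[str(f)] = compute_descriptors(f, profile)
        except (FormulaError, MissingConstantError, KeyError, ValueError) as e:
            failures[str(f)] = e
    if failures:
        raise DescriptorTableError(failures)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(COLUMNS))
    if df.empty:
        df = pd.DataFrame(columns=list(COLUMNS))
    df.index.name = "formula"
    return df
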