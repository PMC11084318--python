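"""Chemical composition and X-ray mass attenuation of contrast materials.

This module models the substances entering the simulation: elements with
tabulated mass attenuation curves (including K-edge discontinuities), compounds
defined by a molecular formula, and aqueous solutions defined by weight
fractions and a measured density.  Mass attenuation of a compound or solution
follows the standard elemental mixture rule

    (mu/rho)_mixture(E) = sum_i  w_i * (mu/rho)_i(E)

with weight fractions ``w_i`` and log-log linear interpolation of the bundled
elemental curves.  The linear attenuation coefficient of a solution is the
weight-fraction average of its components' mass attenuation coefficients
multiplied by the solution density.

The bundled elemental table covers H, C, N, O, Na, Al, Rh and I over
10-150 keV, with duplicated grid rows at the rhodium and iodine K-edges.
Evaluation exactly at a duplicated edge energy returns the above-edge value
(half-open ``[edge, inf)`` convention); pass ``side="below"`` for the limit
from below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Element",
    "Compound",
    "Solution",
    "AttenuationTable",
    "FormulaError",
    "CompositionError",
    "EnergyRangeError",
    "ATOMIC_MASSES",
    "ATOMIC_NUMBERS",
    "element",
    "parse_formula",
    "iodine_concentration",
    "stoichiometric_base_mass",
    "compound_mu_rho",
    "solution_mu",
    "solution_mu_rho",
    "solution_for_iodine_concentration",
    "tabulate_mu_rho",
    "water",
    "iohexol",
    "naditmb",
    "ditmba",
    "pmma",
    "polystyrene",
    "water_solution",
    "pmma_solid",
    "polystyrene_solid",
]


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


class CompositionError(ValueError):
    """Raised when weight fractions are inconsistent."""


class EnergyRangeError(ValueError):
    """Raised when an energy lies outside the tabulated range."""


# IUPAC standard atomic weights, g/mol, rounded to 3 decimals.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Al": 26.982,
    "Rh": 102.906,
    "I": 126.904,
}

ATOMIC_NUMBERS: Dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "Na": 11,
    "Al": 13,
    "Rh": 45,
    "I": 53,
}

# Bulk densities (g/cm^3) of elemental solids used as beam filters.
ELEMENT_DENSITIES: Dict[str, float] = {"Al": 2.699, "Rh": 12.41}


@dataclass(frozen=True)
class Element:
    """An element with its tabulated mass attenuation curve.

    The curve may contain exactly duplicated energies at absorption edges;
    segments between edges are interpolated log-log linearly.
    """

    symbol: str
    atomic_number: int
    atomic_mass: float
    energies: np.ndarray
    mu_rho: np.ndarray

    def __post_init__(self) -> None:
        e, m = self.energies, self.mu_rho
        if len(e) != len(m):
            raise ValueError("energy and attenuation arrays differ in length")
        if np.any(m <= 0):
            raise ValueError(f"non-positive attenuation for {self.symbol}")
        if np.any(np.diff(e) < 0):
            raise ValueError(f"energies not sorted for {self.symbol}")
        if e[0] > 10.0 or e[-1] < 150.0:
            raise ValueError(f"curve for {self.symbol} does not span [10, 150] keV")

    @property
    def edge_energies(self) -> np.ndarray:
        """Energies at which the curve is duplicated (absorption edges)."""
        e = self.energies
        return e[:-1][np.diff(e) == 0]

    def mu_rho_at(self, energy, side: str = "above"):
        """Interpolate mu/rho (cm^2/g) at ``energy`` keV.

        ``side`` selects the branch when ``energy`` coincides exactly with a
        duplicated edge energy: ``"above"`` (default) or ``"below"``.
        """
        e_arr = np.asarray(energy, dtype=float)
        scalar = e_arr.ndim == 0
        e_q = np.atleast_1d(e_arr)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e_q < lo) or np.any(e_q > hi):
            raise EnergyRangeError(
                f"energy outside tabulated range [{lo}, {hi}] keV for {self.symbol}"
            )
        if side not in ("above", "below"):
            raise ValueError("side must be 'above' or 'below'")
        out = np.empty_like(e_q)
        # segment boundaries: edges split the curve into smooth pieces
        edges = self.edge_energies
        seg_bounds = np.concatenate(([lo], edges, [np.inf]))
        # row index where each segment starts in the (duplicated) table
        searcher = "right" if side == "above" else "left"
        seg_of_q = np.searchsorted(edges, e_q, side=searcher)
        for s in np.unique(seg_of_q):
            mask = seg_of_q == s
            sel = (self.energies >= seg_bounds[s]) & (self.energies <= seg_bounds[s + 1])
            # drop the below-edge duplicate at the segment start / above-edge
            # duplicate at the segment end so x is strictly increasing
            idx = np.flatnonzero(sel)
            if s > 0:
                idx = idx[1:] if self.energies[idx[0]] == self.energies[idx[1]] else idx
            if s < len(edges):
                idx = idx[:-1] if self.energies[idx[-1]] == self.energies[idx[-2]] else idx
            xs = np.log(self.energies[idx])
            ys = np.log(self.mu_rho[idx])
            out[mask] = np.exp(np.interp(np.log(e_q[mask]), xs, ys))
        return float(out[0]) if scalar else out


_ELEMENTS: Dict[str, Element] | None = None


def _load_elements() -> Dict[str, Element]:
    global _ELEMENTS
    if _ELEMENTS is None:
        rows: Dict[str, List[Tuple[float, float]]] = {}
        with resources.files("contrastsim.data").joinpath("elemental_mu_rho.tsv").open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("element\t"):
                    continue
                sym, e, mu, _side = line.split("\t")
                rows.setdefault(sym, []).append((float(e), float(mu)))
        _ELEMENTS = {}
        for sym, pts in rows.items():
            pts.sort()
            e = np.array([p[0] for p in pts])
            m = np.array([p[1] for p in pts])
            _ELEMENTS[sym] = Element(sym, ATOMIC_NUMBERS[sym], ATOMIC_MASSES[sym], e, m)
    return _ELEMENTS


def element(symbol: str) -> Element:
    """Return the bundled :class:`Element` for ``symbol``."""
    table = _load_elements()
    if symbol not in table:
        raise FormulaError(f"element {symbol!r} not in bundled attenuation table")
    return table[symbol]


@dataclass(frozen=True)
class Compound:
    """A stoichiometric compound defined by an element-count formula."""

    formula: str
    counts: Tuple[Tuple[str, int], ...]
    molar_mass: float
    mass_fractions: Dict[str, float] = field(hash=False)

    def mass_fraction(self, symbol: str) -> float:
        return self.mass_fractions.get(symbol, 0.0)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Compound:
    """Parse a Hill-style molecular formula into a :class:`Compound`.

    Examples: ``"H2O"``, ``"C19H26I3N3O9"``, ``"Na2CO3"``.  Every element must
    appear in the bundled attenuation table; counts default to 1.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError("formula must be a non-empty string")
    pos = 0
    counts: Dict[str, int] = {}
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        if not m.group(0):
            break
        pos = m.end()
        sym = m.group(1)
        if sym not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
    if pos != len(formula) or not counts:
        raise FormulaError(f"cannot parse formula {formula!r}")
    molar = sum(ATOMIC_MASSES[s] * n for s, n in counts.items())
    fracs = {s: ATOMIC_MASSES[s] * n / molar for s, n in counts.items()}
    return Compound(
        formula=formula,
        counts=tuple(sorted(counts.items())),
        molar_mass=molar,
        mass_fractions=fracs,
    )


# Substances used throughout the pipeline.
def water() -> Compound:
    return parse_formula("H2O")


def iohexol() -> Compound:
    """Iohexol, the active substance of the clinical agent Omnipaque."""
    return parse_formula("C19H26I3N3O9")


def naditmb() -> Compound:
    """Sodium 2,6-diiodo-3,4,5-trimethoxybenzoate (NaDITMB)."""
    return parse_formula("C10H9I2NaO5")


def ditmba() -> Compound:
    """2,6-diiodo-3,4,5-trimethoxybenzoic acid (DITMBA)."""
    return parse_formula("C10H10I2O5")


def pmma() -> Compound:
    """Polymethyl methacrylate (Plexiglas) monomer unit."""
    return parse_formula("C5H8O2")


def polystyrene() -> Compound:
    return parse_formula("C8H8")


@dataclass(frozen=True)
class Solution:
    """A mixture of compounds with weight fractions summing to 1.

    ``density`` is the bulk density of the mixture in g/cm^3.  A single-
    component "solution" models a solid such as PMMA.
    """

    components: Tuple[Tuple[Compound, float], ...]
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"weight fractions sum to {total}, not 1")
        if any(w < 0 for _, w in self.components):
            raise CompositionError("negative weight fraction")
        if self.density <= 0:
            raise CompositionError("density must be positive")

    def element_mass_fractions(self) -> Dict[str, float]:
        fracs: Dict[str, float] = {}
        for comp, w in self.components:
            for sym, f in comp.mass_fractions.items():
                fracs[sym] = fracs.get(sym, 0.0) + w * f
        return fracs


def solution(components: Sequence[Tuple[Compound, float]], density: float,
             label: str = "") -> Solution:
    return Solution(components=tuple(components), density=density, label=label)


def water_solution(density: float = 1.0) -> Solution:
    return solution([(water(), 1.0)], density, label="water")


def pmma_solid(density: float = 1.19) -> Solution:
    return solution([(pmma(), 1.0)], density, label="PMMA")


def polystyrene_solid(density: float = 1.06) -> Solution:
    return solution([(polystyrene(), 1.0)], density, label="polystyrene")


def aqueous(solute: Compound, weight_fraction: float, density: float = 1.0,
            label: str = "") -> Solution:
    """Aqueous solution of a single solute at the given weight fraction."""
    return solution(
        [(solute, weight_fraction), (water(), 1.0 - weight_fraction)],
        density,
        label=label or f"{weight_fraction * 100:.4g}% {solute.formula} (aq)",
    )


def iodine_concentration(sol: Solution) -> float:
    """Iodine concentration of a solution in mg iodine per mL.

    ``1000 * rho * sum_i w_i * f_I(compound_i)`` with ``rho`` in g/cm^3.
    A solution with no iodinated component returns 0.
    """
    f_iodine = sum(w * c.mass_fraction("I") for c, w in sol.components)
    return 1000.0 * sol.density * f_iodine


def solution_for_iodine_concentration(solute: Compound, mg_per_ml: float,
                                      density: float = 1.0,
                                      label: str = "") -> Solution:
    """Aqueous solution of an iodinated solute hitting a target mg I/mL."""
    f_i = solute.mass_fraction("I")
    if f_i <= 0:
        raise CompositionError(f"{solute.formula} contains no iodine")
    w = mg_per_ml / (1000.0 * density * f_i)
    if not 0 < w < 1:
        raise CompositionError("target iodine concentration not reachable")
    return aqueous(solute, w, density, label=label)


def stoichiometric_base_mass(acid_mass_mg: float, acid: Compound, base: Compound,
                             acid_per_base: int = 2) -> float:
    """Mass of base (mg) neutralizing ``acid_mass_mg`` of acid stoichiometrically.

    ``acid_per_base`` is the number of acid molecules consumed per base formula
    unit (2 for a monoprotic acid against Na2CO3).
    """
    if acid_mass_mg < 0:
        raise ValueError("acid mass must be non-negative")
    if acid_per_base < 1:
        raise ValueError("acid_per_base must be >= 1")
    return acid_mass_mg / acid.molar_mass / acid_per_base * base.molar_mass


def compound_mu_rho(compound: Compound, energy, side: str = "above"):
    """Mass attenuation coefficient of a compound (cm^2/g) by the mixture rule."""
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for sym, f in compound.mass_fractions.items():
        out = out + f * np.asarray(element(sym).mu_rho_at(e, side=side))
    return float(out) if out.ndim == 0 else out


def solution_mu_rho(sol: Solution, energy, side: str = "above"):
    """Mass attenuation coefficient of a solution (cm^2/g)."""
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for comp, w in sol.components:
        out = out + w * np.asarray(compound_mu_rho(comp, e, side=side))
    return float(out) if out.ndim == 0 else out


def solution_mu(sol: Solution, energy, side: str = "above"):
    """Linear attenuation coefficient of a solution (1/cm)."""
    mu_rho = solution_mu_rho(sol, energy, side=side)
    return mu_rho * sol.density


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mu/rho of a compound or solution, with edge rows duplicated."""

    energies: np.ndarray
    mu_rho: np.ndarray
    owner: str = ""

    def __post_init__(self) -> None:
        if len(self.energies) != len(self.mu_rho):
            raise ValueError("length mismatch")
        if np.any(self.mu_rho <= 0):
            raise ValueError("non-positive attenuation values")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("energies not sorted")

    @property
    def edge_energies(self) -> np.ndarray:
        e = self.energies
        return e[:-1][np.diff(e) == 0]


def _material_elements(material) -> List[str]:
    if isinstance(material, Compound):
        return list(material.mass_fractions)
    return list(material.element_mass_fractions())


def tabulate_mu_rho(material, e_min: float = 10.0, e_max: float = 150.0,
                    n: int = 60) -> AttenuationTable:
    """Tabulate mu/rho of a compound or solution on a log grid.

    Absorption edges of the constituent elements falling inside the range are
    inserted as duplicated rows carrying the below/above limits, so K-edge
    discontinuities survive tabulation.
    """
    grid = np.geomspace(e_min, e_max, n)
    edges = sorted(
        {float(e) for sym in _material_elements(material)
         for e in element(sym).edge_energies if e_min < e < e_max}
    )
    evaluate = compound_mu_rho if isinstance(material, Compound) else solution_mu_rho
    energies: List[float] = []
    values: List[float] = []
    for e in grid:
        energies.append(float(e))
        values.append(float(evaluate(material, float(e))))
    for edge in edges:
        energies.extend([edge, edge])
        values.extend([float(evaluate(material, edge, side="below")),
                       float(evaluate(material, edge, side="above"))])
    order = np.lexsort((values, energies))
    label = material.formula if isinstance(material, Compound) else (
        material.label or "solution")
    return AttenuationTable(
        energies=np.array(energies)[order],
        mu_rho=np.array(values)[order],
        owner=label,
    )
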