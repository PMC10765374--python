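"""Cholesterol-dependence curves and derived scalar quantities.

Membrane cholesterol is expressed as mol % = 100 * C_T / (C_T + P_T); note
the denominator excludes the protein.  Isotherms sweep mol % across the
physiological range (0-60 by default) at fixed lipid composition, solving
the speciation at every grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    MembraneSystem,
    ParameterError,
    PhospholipidSpecies,
    ProteinLigand,
    SolverError,
)
from .equilibrium import solve_equilibrium

__all__ = [
    "GAS_CONSTANT",
    "Isotherm",
    "IntersectionPoint",
    "mol_percent_to_moles",
    "moles_to_mol_percent",
    "mol_percent_to_mole_fraction",
    "mole_fraction_to_mol_percent",
    "wt_percent_to_mol_percent",
    "default_grid",
    "compute_isotherm",
    "free_cholesterol_curve",
    "equivalence_point",
    "half_saturation_free_mole_fraction",
    "intersection_total_cholesterol",
    "delta_g",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: Molecular weights used when converting weight-percent sterol to mol %.
MW_CHOLESTEROL = 387.0
MW_PHOSPHOLIPID = 740.0


def mol_percent_to_moles(m: float, p_total: float) -> float:
    """Total cholesterol (moles) at ``m`` mol % for ``p_total`` moles lipid.

    mol % is 100 * C_T / (C_T + P_T), so C_T = P_T * m / (100 - m).
    """
    if not (0 <= m < 100):
        raise ParameterError(f"mol % must be in [0, 100), got {m}")
    if p_total <= 0:
        raise ParameterError(f"p_total must be > 0, got {p_total}")
    return p_total * m / (100.0 - m)


def moles_to_mol_percent(c_total: float, p_total: float) -> float:
    if c_total < 0 or p_total <= 0:
        raise ParameterError("amounts must be c_total >= 0 and p_total > 0")
    return 100.0 * c_total / (c_total + p_total)


def mol_percent_to_mole_fraction(m: float) -> float:
    if not (0 <= m <= 100):
        raise ParameterError(f"mol % must be in [0, 100], got {m}")
    return m / 100.0


def mole_fraction_to_mol_percent(x: float) -> float:
    if not (0 <= x <= 1):
        raise ParameterError(f"mole fraction must be in [0, 1], got {x}")
    return 100.0 * x


def wt_percent_to_mol_percent(
    w: float, mw_chol: float = MW_CHOLESTEROL, mw_pl: float = MW_PHOSPHOLIPID
) -> float:
    """Convert cholesterol weight % of total lipid to mol %.

    ``w`` grams of cholesterol per 100 g of lipid gives
    100 * (w/mw_chol) / (w/mw_chol + (100-w)/mw_pl).
    """
    if not (0 <= w <= 100):
        raise ParameterError(f"wt % must be in [0, 100], got {w}")
    if mw_chol <= 0 or mw_pl <= 0:
        raise ParameterError("molecular weights must be positive")
    chol_mol = w / mw_chol
    pl_mol = (100.0 - w) / mw_pl
    if chol_mol + pl_mol == 0:
        return 0.0
    return 100.0 * chol_mol / (chol_mol + pl_mol)


def default_grid(start: float = 0.0, stop: float = 60.0, count: int = 121) -> np.ndarray:
    """Uniform mol % grid over the physiological sweep (0-60 by default)."""
    if count < 2:
        raise ParameterError(f"grid needs >= 2 points, got {count}")
    if not (0 <= start < stop < 100):
        raise ParameterError(f"grid must satisfy 0 <= start < stop < 100, got [{start}, {stop}]")
    return np.linspace(start, stop, count)


@dataclass(frozen=True)
class Isotherm:
    """A solved cholesterol sweep, one row per mol % grid point."""

    table: pd.DataFrame
    lipids: Tuple[PhospholipidSpecies, ...]
    protein: Optional[ProteinLigand] = None

    @property
    def grid(self) -> np.ndarray:
        return self.table["mol_percent"].to_numpy()

    @property
    def occupancy(self) -> np.ndarray:
        return self.table["occupancy"].to_numpy()

    @property
    def frac_free_chol(self) -> np.ndarray:
        return self.table["frac_free_chol"].to_numpy()

    @property
    def free_per_phospholipid(self) -> np.ndarray:
        return self.table["free_per_phospholipid"].to_numpy()

    def lipid_bound_frac(self, name: str) -> np.ndarray:
        return self.table[f"bound_frac_{name}"].to_numpy()


def _sweep(
    lipids: Sequence[PhospholipidSpecies],
    protein: Optional[ProteinLigand],
    grid: Iterable[float],
) -> Isotherm:
    lipids = tuple(lipids)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be non-empty and strictly increasing")
    if grid[0] < 0 or grid[-1] >= 100:
        raise ParameterError("grid must lie in [0, 100) mol %")
    p_total = sum(sp.amount for sp in lipids)
    rows = []
    base = MembraneSystem(lipids, protein, 0.0)
    for m in grid:
        c_t = mol_percent_to_moles(m, p_total)
        try:
            state = solve_equilibrium(base.with_c_total(c_t))
        except SolverError as exc:
            raise SolverError(f"equilibrium failed at {m} mol % (C_T={c_t}): {exc}") from exc
        row = {
            "mol_percent": m,
            "occupancy": state.occupancy,
            "frac_free_chol": state.frac_free_chol,
            "free_per_phospholipid": state.c_free / p_total,
        }
        for sp in lipids:
            row[f"bound_frac_{sp.name}"] = state.lipid_bound_frac[sp.name]
        rows.append(row)
    return Isotherm(table=pd.DataFrame(rows), lipids=lipids, protein=protein)


def compute_isotherm(
    lipids: Sequence[PhospholipidSpecies],
    protein: ProteinLigand,
    grid: Optional[Iterable[float]] = None,
) -> Isotherm:
    """Protein occupancy and speciation fractions across a mol % sweep."""
    if protein is None:
        raise ParameterError("compute_isotherm requires a protein; "
                             "use free_cholesterol_curve for lipid-only sweeps")
    return _sweep(lipids, protein, default_grid() if grid is None else grid)


def free_cholesterol_curve(
    lipids: Sequence[PhospholipidSpecies],
    grid: Optional[Iterable[float]] = None,
) -> Isotherm:
    """Uncomplexed cholesterol per mole phospholipid, protein absent."""
    return _sweep(lipids, None, default_grid() if grid is None else grid)


def equivalence_point(lipids: Sequence[PhospholipidSpecies]) -> float:
    """Stoichiometric equivalence point of the bilayer, in mol %.

    The sterol amount the phospholipids can complex is E = sum(P_i / r_i);
    the equivalence point is 100 * E / (E + sum(P_i)).  Beyond it,
    uncomplexed cholesterol accumulates sharply.  Invariant to rescaling
    all lipid amounts by a common factor.
    """
    lipids = tuple(lipids)
    if not lipids:
        raise ParameterError("equivalence_point requires at least one lipid species")
    p_tot = sum(sp.amount for sp in lipids)
    if p_tot <= 0:
        raise ParameterError("total phospholipid must be positive")
    capacity = sum(sp.amount / sp.r for sp in lipids)
    return 100.0 * capacity / (capacity + p_tot)


def half_saturation_free_mole_fraction(protein: ProteinLigand) -> float:
    """Free-cholesterol mole fraction at half-saturation of the protein.

    At half-saturation C_nL = L_f, so K_Ln * (C_f/alpha)**n = 1 and the
    free mole fraction is K_Ln**(-1/n) = 1/K_L1 — independent of n.
    """
    return 1.0 / protein.k_subunit


@dataclass(frozen=True)
class IntersectionPoint:
    """Total cholesterol at which the protein is half-saturated."""

    c_total: float
    mol_percent: float


def intersection_total_cholesterol(
    protein: ProteinLigand,
    lipids: Sequence[PhospholipidSpecies],
    tol: float = 1e-12,
    max_mol_percent: float = 99.0,
) -> IntersectionPoint:
    """Locate the total cholesterol C_T at which occupancy = 1/2.

    Occupancy is monotone in C_T, so the half-saturation point is found by
    bracketed root-finding on occupancy(C_T) - 1/2.  For a fixed subunit
    constant K_L1 this point is essentially independent of the assumed
    stoichiometry n (the isotherms for different n intersect here).

    Raises
    ------
    SolverError
        If occupancy never reaches 1/2 below ``max_mol_percent``.
    """
    lipids = tuple(lipids)
    p_total = sum(sp.amount for sp in lipids)
    base = MembraneSystem(lipids, protein, 0.0)

    def occ_minus_half(c_t: float) -> float:
        return solve_equilibrium(base.with_c_total(c_t)).occupancy - 0.5

    c_hi = mol_percent_to_moles(max_mol_percent, p_total)
    if occ_minus_half(c_hi) < 0:
        raise SolverError(
            f"occupancy stays below 1/2 up to {max_mol_percent} mol %; "
            "half-saturation point out of range"
        )
    c_star = brentq(occ_minus_half, 0.0, c_hi, xtol=1e-300, rtol=max(tol, 8.9e-16),
                    maxiter=200)
    return IntersectionPoint(c_total=c_star, mol_percent=moles_to_mol_percent(c_star, p_total))


def delta_g(k: float, temperature_k: float = 298.0) -> float:
    """Standard free energy of association, -R*T*ln(k), in kJ/mol."""
    if k <= 0:
        raise ParameterError(f"association constant must be > 0, got {k}")
    if temperature_k <= 0:
        raise ParameterError(f"temperature must be > 0 K, got {temperature_k}")
    return -GAS_CONSTANT * temperature_k * math.log(k) / 1000.0
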