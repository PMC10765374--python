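"""Domain types for sterol partitioning in a phospholipid bilayer.

The model treats one membrane compartment containing cholesterol (total
amount ``C_T``), one or more phospholipid species that sequester the sterol
into stoichiometric complexes ``CP_r`` (one cholesterol per ``r``
phospholipids), and optionally one membrane-embedded protein ligand whose
oligomer binds ``n`` sterol molecules in a single concerted, all-or-none
step.  Chemical activities are ideal mole fractions taken over the
compartment size ``alpha = C_T + sum(P_T) + L_T`` (totals), so all
association constants are dimensionless.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

__all__ = [
    "Direction",
    "PhospholipidSpecies",
    "ProteinLigand",
    "MembraneSystem",
    "EquilibriumState",
    "ParameterError",
    "SolverError",
    "oligomer_constant",
    "subunit_constant",
]


class ParameterError(ValueError):
    """An input violates a model-parameter invariant."""


class SolverError(RuntimeError):
    """The speciation solver failed to bracket or converge."""


class Direction(enum.Enum):
    """Sign convention linking sterol occupancy to measured activity."""

    INCREASING = "increasing"
    DECREASING = "decreasing"

    @classmethod
    def coerce(cls, value: Union["Direction", str]) -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ParameterError(
                f"direction must be 'increasing' or 'decreasing', got {value!r}"
            ) from None


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ParameterError(f"{name} must be a positive finite number, got {value!r}")
    return value


def _check_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def _check_int(value: int, name: str, minimum: int = 1) -> int:
    if isinstance(value, bool) or int(value) != value:
        raise ParameterError(f"{name} must be an integer >= {minimum}, got {value!r}")
    value = int(value)
    if value < minimum:
        raise ParameterError(f"{name} must be an integer >= {minimum}, got {value!r}")
    return value


def oligomer_constant(k_subunit: float, n: int) -> float:
    """Association constant of the concerted n-site oligomer, ``K_Ln = K_L1**n``.

    Under the all-or-none scheme the oligomer equilibrium is the n-th power
    of the per-subunit equilibrium, so the dimensionless oligomer constant
    is the subunit constant raised to the stoichiometry.
    """
    k_subunit = _check_positive(k_subunit, "k_subunit")
    n = _check_int(n, "n")
    k = k_subunit**n
    if not math.isfinite(k):
        raise ParameterError(f"K_L1**n overflows for k_subunit={k_subunit}, n={n}")
    return k


def subunit_constant(k_oligomer: float, n: int) -> float:
    """Per-subunit constant from the oligomer constant, ``K_L1 = K_Ln**(1/n)``."""
    k_oligomer = _check_positive(k_oligomer, "k_oligomer")
    n = _check_int(n, "n")
    return k_oligomer ** (1.0 / n)


@dataclass(frozen=True)
class PhospholipidSpecies:
    """One sterol-complexing phospholipid class.

    Parameters
    ----------
    name : str
        Label (e.g. ``"POPS"``).
    k_assoc : float
        Dimensionless sterol association constant ``K_P`` (> 0) for the
        complexation ``C + r P <-> CP_r`` in mole-fraction activities.
    r : int
        Phospholipid molecules per cholesterol in the complex (>= 1).
    amount : float
        Total moles of this species, ``P_T`` (>= 0).
    """

    name: str
    k_assoc: float
    r: int
    amount: float

    def __post_init__(self) -> None:
        _check_positive(self.k_assoc, "k_assoc")
        object.__setattr__(self, "r", _check_int(self.r, "r"))
        _check_nonnegative(self.amount, "amount")
        object.__setattr__(self, "k_assoc", float(self.k_assoc))
        object.__setattr__(self, "amount", float(self.amount))


@dataclass(frozen=True)
class ProteinLigand:
    """A membrane-embedded oligomer binding ``n`` sterols concertedly.

    ``k_subunit`` is the per-subunit constant ``K_L1``; the oligomer binds
    all ``n`` sterols in one step with constant ``K_Ln = K_L1**n``.
    ``direction`` records whether measured activity rises or falls with
    sterol occupancy.
    """

    name: str
    k_subunit: float
    n: int
    amount: float
    direction: Direction = Direction.INCREASING

    def __post_init__(self) -> None:
        _check_positive(self.k_subunit, "k_subunit")
        object.__setattr__(self, "n", _check_int(self.n, "n"))
        _check_nonnegative(self.amount, "amount")
        object.__setattr__(self, "k_subunit", float(self.k_subunit))
        object.__setattr__(self, "amount", float(self.amount))
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        # forces the overflow check on K_L1**n
        self.k_oligomer

    @property
    def k_oligomer(self) -> float:
        """Oligomer association constant ``K_Ln = K_L1**n``."""
        return oligomer_constant(self.k_subunit, self.n)

    def with_amount(self, amount: float) -> "ProteinLigand":
        return ProteinLigand(self.name, self.k_subunit, self.n, amount, self.direction)


@dataclass(frozen=True)
class MembraneSystem:
    """A membrane compartment: lipids, optional protein, total cholesterol."""

    lipids: Tuple[PhospholipidSpecies, ...]
    protein: Optional[ProteinLigand] = None
    c_total: float = 0.0

    def __post_init__(self) -> None:
        lipids = tuple(self.lipids)
        if not lipids:
            raise ParameterError("MembraneSystem requires at least one lipid species")
        names = [sp.name for sp in lipids]
        if len(set(names)) != len(names):
            raise ParameterError(f"lipid species names must be unique, got {names}")
        object.__setattr__(self, "lipids", lipids)
        _check_nonnegative(self.c_total, "c_total")
        object.__setattr__(self, "c_total", float(self.c_total))

    @property
    def p_total(self) -> float:
        """Total phospholipid, ``sum(P_T)``."""
        return sum(sp.amount for sp in self.lipids)

    @property
    def l_total(self) -> float:
        return self.protein.amount if self.protein is not None else 0.0

    @property
    def alpha(self) -> float:
        """Compartment size: sum of all total amounts (moles)."""
        return self.c_total + self.p_total + self.l_total

    def with_c_total(self, c_total: float) -> "MembraneSystem":
        """Same composition at a different total cholesterol (alpha follows)."""
        return MembraneSystem(self.lipids, self.protein, c_total)


@dataclass(frozen=True)
class EquilibriumState:
    """Solved speciation of a :class:`MembraneSystem` at equilibrium.

    Amounts are in moles; ``cp`` and derived per-species fractions are
    keyed by lipid species name.
    """

    c_free: float
    p_free: Mapping[str, float]
    l_free: float
    cp: Mapping[str, float]
    cnl: float
    occupancy: float
    frac_free_chol: float
    lipid_bound_frac: Mapping[str, float] = field(default_factory=dict)

    def bound_cholesterol(self, system: MembraneSystem) -> float:
        n = system.protein.n if system.protein is not None else 0
        return sum(self.cp.values()) + n * self.cnl
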