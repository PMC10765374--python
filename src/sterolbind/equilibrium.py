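"""Coupled mass-action speciation of cholesterol in a bilayer compartment.

All equilibria are written in ideal mole-fraction activities over the
compartment size ``alpha`` (sum of total amounts).  For each lipid species

    C + r P <-> CP_r        K_P = (CP_r/alpha) / ((C_f/alpha) (P_f/alpha)^r)

and for the protein oligomer (concerted, all-or-none)

    n C + L <-> C_nL        K_Ln = (C_nL/alpha) / ((C_f/alpha)^n (L_f/alpha))

Given total amounts, the solver finds the free cholesterol ``C_f`` zeroing
the cholesterol balance; the lipid and ligand balances then fix every other
species.  The balance residual g(C_f) = C_f + bound(C_f) - C_T is strictly
increasing, so the root on [0, C_T] is unique and bracketed bisection/Brent
is unconditionally robust.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .core import (
    EquilibriumState,
    MembraneSystem,
    ParameterError,
    PhospholipidSpecies,
    ProteinLigand,
    SolverError,
)

__all__ = [
    "free_phospholipid",
    "free_ligand",
    "bound_cholesterol",
    "solve_equilibrium",
]

_MAXITER = 200


def free_phospholipid(
    c_free: float, species: PhospholipidSpecies, alpha: float
) -> float:
    """Free phospholipid ``P_f`` of one species at a given free cholesterol.

    Solves the per-species balance ``P_f + r*K_P*c_free*P_f**r / alpha**r
    = P_T``: closed form for r = 1 (linear) and r = 2 (quadratic, stable
    positive root), guarded monotone Brent for r > 2.
    """
    if c_free < 0:
        raise ParameterError(f"c_free must be >= 0, got {c_free}")
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    p_t, r, k_p = species.amount, species.r, species.k_assoc
    if p_t == 0.0 or c_free == 0.0:
        return p_t
    if r == 1:
        return p_t / (1.0 + k_p * c_free / alpha)
    if r == 2:
        # a*P^2 + P - P_T = 0 with a = 2 K_P c/alpha^2; cancellation-free root
        a = 2.0 * k_p * c_free / alpha**2
        return 2.0 * p_t / (1.0 + math.sqrt(1.0 + 4.0 * a * p_t))
    coef = r * k_p * c_free / alpha**r

    def balance(p_f: float) -> float:
        return p_f + coef * p_f**r - p_t

    if balance(p_t) <= 0:  # cannot happen for valid inputs
        raise SolverError("free_phospholipid: no root in [0, P_T]")
    return brentq(balance, 0.0, p_t, xtol=1e-300, rtol=8.9e-16, maxiter=_MAXITER)


def free_ligand(c_free: float, protein: ProteinLigand, alpha: float) -> float:
    """Free ligand ``L_f = L_T / (1 + K_Ln (c_free/alpha)**n)``."""
    if c_free < 0:
        raise ParameterError(f"c_free must be >= 0, got {c_free}")
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    x = c_free / alpha
    return protein.amount / (1.0 + protein.k_oligomer * x**protein.n)


def bound_cholesterol(c_free: float, system: MembraneSystem) -> float:
    """Total sterol held in complexes (lipid ``CP_r`` plus protein ``C_nL``).

    Strictly increasing in ``c_free`` for positive constants; evaluated from
    the per-species balances so mass conservation is exact by construction.
    """
    alpha = system.alpha
    total = 0.0
    for sp in system.lipids:
        p_f = free_phospholipid(c_free, sp, alpha)
        total += (sp.amount - p_f) / sp.r
    if system.protein is not None and system.protein.amount > 0:
        l_f = free_ligand(c_free, system.protein, alpha)
        total += system.protein.n * (system.protein.amount - l_f)
    return total


def _all_free_state(system: MembraneSystem) -> EquilibriumState:
    return EquilibriumState(
        c_free=0.0,
        p_free={sp.name: sp.amount for sp in system.lipids},
        l_free=system.l_total,
        cp={sp.name: 0.0 for sp in system.lipids},
        cnl=0.0,
        occupancy=0.0,
        frac_free_chol=0.0,
        lipid_bound_frac={sp.name: 0.0 for sp in system.lipids},
    )


def solve_equilibrium(
    system: MembraneSystem, rel_tol: float = 1e-12
) -> EquilibriumState:
    """Solve the coupled equilibria of a compartment for all species.

    Finds the unique free cholesterol ``C_f`` in [0, C_T] zeroing the
    cholesterol balance by bracketed root-finding, then assembles the full
    state.  The three mass balances (cholesterol, per-species phospholipid,
    ligand) are verified at ``rel_tol`` before returning.

    Raises
    ------
    SolverError
        If the root cannot be bracketed or a balance check fails.
    """
    if not (0 < rel_tol <= 1e-6):
        raise ParameterError(f"rel_tol must be in (0, 1e-6], got {rel_tol}")
    c_t = system.c_total
    if c_t == 0.0:
        return _all_free_state(system)
    alpha = system.alpha

    def g(c_f: float) -> float:
        return c_f + bound_cholesterol(c_f, system) - c_t

    g_hi = g(c_t)
    if g_hi < 0:  # bound() >= 0 makes this impossible for valid systems
        raise SolverError(f"cannot bracket root: g(C_T)={g_hi} < 0")
    try:
        c_free = brentq(g, 0.0, c_t, xtol=1e-300, rtol=8.9e-16, maxiter=_MAXITER)
    except RuntimeError as exc:
        raise SolverError(
            f"free-cholesterol root-finding did not converge for C_T={c_t}: {exc}"
        ) from exc

    p_free, cp, bound_frac = {}, {}, {}
    chol_in_lipid = 0.0
    for sp in system.lipids:
        p_f = free_phospholipid(c_free, sp, alpha)
        complexed = max((sp.amount - p_f) / sp.r, 0.0)
        p_free[sp.name] = p_f
        cp[sp.name] = complexed
        bound_frac[sp.name] = (
            min(sp.r * complexed / sp.amount, 1.0) if sp.amount > 0 else 0.0
        )
        chol_in_lipid += complexed

    protein = system.protein
    if protein is not None and protein.amount > 0:
        l_free = free_ligand(c_free, protein, alpha)
        cnl = max(protein.amount - l_free, 0.0)
        occupancy = min(cnl / protein.amount, 1.0)
        n = protein.n
    else:
        l_free, cnl, occupancy, n = system.l_total, 0.0, 0.0, 0

    scale_c = max(c_t, 1.0)
    if abs(c_free + chol_in_lipid + n * cnl - c_t) > rel_tol * scale_c:
        raise SolverError("cholesterol balance violated after solve")
    for sp in system.lipids:
        if abs(p_free[sp.name] + sp.r * cp[sp.name] - sp.amount) > rel_tol * max(
            sp.amount, 1.0
        ):
            raise SolverError(f"phospholipid balance violated for {sp.name!r}")
    if abs(l_free + cnl - system.l_total) > rel_tol * max(system.l_total, 1.0):
        raise SolverError("ligand balance violated after solve")

    return EquilibriumState(
        c_free=c_free,
        p_free=p_free,
        l_free=l_free,
        cp=cp,
        cnl=cnl,
        occupancy=occupancy,
        frac_free_chol=min(c_free / c_t, 1.0),
        lipid_bound_frac=bound_frac,
    )
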