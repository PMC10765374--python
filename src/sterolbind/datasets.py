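"""Membrane and protein presets, plus seeded synthetic activity isotherms.

The membrane presets encode the bilayer compositions (species amounts,
sterol stoichiometries r and association constants K_P) used for the six
transporter analyses and the two whole-membrane predictions; the protein
presets carry the corresponding subunit constants, stoichiometries and
activity directions.  ``generate_activity_data`` produces noisy activity
curves from known ground truth so that the fitting machinery can be
exercised and validated without any external data.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import Direction, ParameterError, PhospholipidSpecies, ProteinLigand
from .equilibrium import solve_equilibrium
from .fitting import ActivityDataset, occupancy_to_activity
from .isotherm import mol_percent_to_moles
from .core import MembraneSystem

__all__ = [
    "MEMBRANE_PRESETS",
    "PROTEIN_PRESETS",
    "membrane_preset",
    "protein_preset",
    "gat_lipid_affinity_sweep",
    "generate_activity_data",
]

#: Protein abundances (moles): trace levels for cell membranes / vesicles
#: and for planar bilayers; occupancy is insensitive to the choice.
L_TOTAL_CELL = 1e-3
L_TOTAL_PLANAR = 1e-5


def _lipids(*specs: Tuple[str, float, int, float]) -> Tuple[PhospholipidSpecies, ...]:
    return tuple(PhospholipidSpecies(n, k, r, a) for (n, k, r, a) in specs)


MEMBRANE_PRESETS: Dict[str, Tuple[PhospholipidSpecies, ...]] = {
    # GAT reconstituted in liposomes: equal 1:1 and 1:2 species, best-match
    # K_P = 200 for both (see gat_lipid_affinity_sweep for the alternatives).
    "gat_liposome": _lipids(("PL_r1", 200.0, 1, 0.5), ("PL_r2", 200.0, 2, 0.5)),
    # Planar POPS/POPE bilayers (Kir3.4*, BK, Kir3.4* M182I): POPS 1:2 with
    # K_P = 210, the PE species 1:1 with K_P = 130.
    "planar_pops_pope": _lipids(("POPS", 210.0, 2, 0.5), ("POPE", 130.0, 1, 0.5)),
    # Plasma-membrane surrogate: equal 1:1 / 1:2 species with K_P 5000 / 2500.
    "plasma_membrane": _lipids(("PM_r1", 5000.0, 1, 0.5), ("PM_r2", 2500.0, 2, 0.5)),
    # AChR in 3:1 DOPC/DOPA vesicles, both 1:2, K_P 930 and 200.
    "achr_vesicle": _lipids(("DOPC", 930.0, 2, 0.75), ("DOPA", 200.0, 2, 0.25)),
    # Hypothetical weakly avid endomembrane: 30/70 of 1:1 / 1:2, K_P 21 / 10.
    "endomembrane": _lipids(("EM_r1", 21.0, 1, 0.3), ("EM_r2", 10.0, 2, 0.7)),
}

#: (K_L1, n, direction, default amount, native membrane preset key)
_PROTEIN_TABLE: Dict[str, Tuple[float, int, Direction, float, str]] = {
    "GAT": (100.0, 1, Direction.INCREASING, L_TOTAL_CELL, "gat_liposome"),
    "Kir3.4*": (35.0, 1, Direction.INCREASING, L_TOTAL_PLANAR, "planar_pops_pope"),
    "Kir2": (100.0, 1, Direction.DECREASING, L_TOTAL_CELL, "plasma_membrane"),
    "BK": (563.0, 4, Direction.DECREASING, L_TOTAL_PLANAR, "planar_pops_pope"),
    "Kir3.4*_M182I": (700.0, 4, Direction.DECREASING, L_TOTAL_PLANAR, "planar_pops_pope"),
    "AChR": (950.0, 2, Direction.INCREASING, L_TOTAL_CELL, "achr_vesicle"),
}

PROTEIN_PRESETS: Dict[str, ProteinLigand] = {
    key: ProteinLigand(key, k, n, amount, direction)
    for key, (k, n, direction, amount, _) in _PROTEIN_TABLE.items()
}


def membrane_preset(key: str) -> Tuple[PhospholipidSpecies, ...]:
    """Bilayer composition for a named membrane preparation."""
    try:
        return MEMBRANE_PRESETS[key]
    except KeyError:
        raise ParameterError(
            f"unknown membrane preset {key!r}; choose from {sorted(MEMBRANE_PRESETS)}"
        ) from None


def protein_preset(key: str) -> ProteinLigand:
    """Characterised transporter/channel ligand by name."""
    try:
        return PROTEIN_PRESETS[key]
    except KeyError:
        raise ParameterError(
            f"unknown protein preset {key!r}; choose from {sorted(PROTEIN_PRESETS)}"
        ) from None


def native_membrane_key(protein_key: str) -> str:
    """Preset key of the bilayer in which the protein was characterised."""
    if protein_key not in _PROTEIN_TABLE:
        raise ParameterError(f"unknown protein preset {protein_key!r}")
    return _PROTEIN_TABLE[protein_key][4]


def gat_lipid_affinity_sweep() -> Dict[int, float]:
    """The K_P values explored for the GAT liposome bilayer, by curve index.

    Both species take the same K_P per curve; index 3 (K_P = 200) is the
    best match encoded in the ``gat_liposome`` preset.  Index 1 is the
    vanishing-affinity control."""
    return {1: 1e-6, 2: 100.0, 3: 200.0, 4: 400.0, 5: 1000.0}


def generate_activity_data(
    protein: ProteinLigand,
    lipids: Sequence[PhospholipidSpecies],
    n_points: int = 12,
    noise: str = "multiplicative",
    sd: float = 0.02,
    seed: Optional[int] = None,
    baseline: float = 0.0,
    amplitude: float = 1.0,
    span: Tuple[float, float] = (0.0, 60.0),
    name: str = "",
) -> ActivityDataset:
    """Synthesise a noisy activity isotherm with known ground truth.

    Solves the exact competitive model at ``n_points`` uniformly spaced
    mol % values, maps occupancy through the affine activity scale, and
    perturbs with the chosen noise model: ``"none"``, ``"additive"``
    (Gaussian, sd in activity units) or ``"multiplicative"`` (Gaussian,
    relative sd; the default 2 % mimics the scatter of single-channel and
    transport assays).  Activities are floored at zero.  The generating
    parameters are recorded in the dataset's provenance.
    """
    if n_points < 3:
        raise ParameterError(f"n_points must be >= 3, got {n_points}")
    if noise not in ("none", "additive", "multiplicative"):
        raise ParameterError(
            f"noise must be 'none', 'additive' or 'multiplicative', got {noise!r}"
        )
    if sd < 0:
        raise ParameterError(f"noise sd must be >= 0, got {sd}")
    if noise != "none" and sd > 0 and seed is None:
        raise ParameterError("a seed is required when noise is active")
    lo, hi = span
    if not (0 <= lo < hi < 100):
        raise ParameterError(f"span must satisfy 0 <= lo < hi < 100, got {span}")

    lipids = tuple(lipids)
    grid = np.linspace(lo, hi, n_points)
    p_total = sum(sp.amount for sp in lipids)
    base = MembraneSystem(lipids, protein, 0.0)
    occ = np.array(
        [
            solve_equilibrium(base.with_c_total(mol_percent_to_moles(m, p_total))).occupancy
            for m in grid
        ]
    )
    activity = np.asarray(
        occupancy_to_activity(occ, baseline, amplitude, protein.direction), dtype=float
    )
    if noise != "none" and sd > 0:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n_points)
        if noise == "additive":
            activity = activity + sd * z
        else:
            activity = activity * (1.0 + sd * z)
        activity = np.maximum(activity, 0.0)

    return ActivityDataset(
        mol_percent=tuple(grid),
        activity=tuple(activity),
        direction=protein.direction,
        name=name or f"synthetic_{protein.name}",
        provenance={
            "synthetic": True,
            "protein": protein.name,
            "true_k_subunit": protein.k_subunit,
            "true_n": protein.n,
            "protein_amount": protein.amount,
            "baseline": baseline,
            "amplitude": amplitude,
            "noise": noise,
            "sd": sd,
            "seed": seed,
            "span": [lo, hi],
            "n_points": n_points,
            "lipids": [
                {"name": sp.name, "k_assoc": sp.k_assoc, "r": sp.r, "amount": sp.amount}
                for sp in lipids
            ],
        },
    )
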