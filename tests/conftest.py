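import numpy as np
import pytest

from sterolbind import (
    MembraneSystem,
    PhospholipidSpecies,
    ProteinLigand,
)


@pytest.fixture
def single_r1_lipid():
    """One 1:1 lipid, K_P = 100, unit amount (the hand-derived quadratic case)."""
    return PhospholipidSpecies("PL", 100.0, 1, 1.0)


@pytest.fixture
def gat_bilayer():
    """Equal 1:1 and 1:2 species, both K_P = 200 (liposome best match)."""
    return (
        PhospholipidSpecies("PL_r1", 200.0, 1, 0.5),
        PhospholipidSpecies("PL_r2", 200.0, 2, 0.5),
    )


@pytest.fixture
def weak_protein():
    return ProteinLigand("P", 100.0, 1, 1e-3)


def random_system(rng: np.random.Generator, with_protein: bool = True) -> MembraneSystem:
    """Randomised small compartment within the model's working ranges."""
    n_lipids = rng.integers(1, 3)
    lipids = tuple(
        PhospholipidSpecies(
            f"L{i}",
            float(10.0 ** rng.uniform(-6, 4)),
            int(rng.integers(1, 3)),
            float(rng.uniform(0.1, 1.0)),
        )
        for i in range(n_lipids)
    )
    protein = None
    if with_protein:
        protein = ProteinLigand(
            "P",
            float(10.0 ** rng.uniform(0, 4)),
            int(rng.integers(1, 6)),
            float(rng.choice([1e-3, 1e-5])),
        )
    p_tot = sum(sp.amount for sp in lipids)
    chol_frac = float(rng.uniform(0.0, 0.6))
    c_total = p_tot * chol_frac / (1.0 - chol_frac)
    return MembraneSystem(lipids, protein, c_total)
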