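"""Estimating sterol affinity constants from activity-vs-cholesterol data.

The measured activity of a membrane protein is modelled as an affine map of
its sterol occupancy: ``activity = baseline + amplitude * occ`` (or
``baseline + amplitude * (1 - occ)`` when sterol inhibits).  For a candidate
oligomer constant K_Ln the occupancy at each observed mol % follows from the
full competitive speciation solve, the two affine nuisance parameters are
profiled out by linear least squares, and K_Ln is located by a coarse grid
over log10 K followed by bounded scalar minimisation — a reproducible,
deterministic surrogate for matching simulated isotherms to data by eye on
dual axes.  Goodness of fit is the ordinary coefficient of determination.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .core import (
    Direction,
    MembraneSystem,
    ParameterError,
    PhospholipidSpecies,
    ProteinLigand,
    subunit_constant,
)
from .equilibrium import solve_equilibrium
from .isotherm import delta_g, mol_percent_to_moles

__all__ = [
    "ActivityDataset",
    "FitResult",
    "NonIdentifiableError",
    "occupancy_to_activity",
    "r_squared",
    "SterolAffinityRegressor",
    "fit_affinity",
    "scan_stoichiometry",
    "sensitivity_to_lipid_affinity",
]


class NonIdentifiableError(RuntimeError):
    """The data carry no information about the affinity constant."""


@dataclass(frozen=True)
class ActivityDataset:
    """An observed activity isotherm: (mol % cholesterol, activity) pairs."""

    mol_percent: Tuple[float, ...]
    activity: Tuple[float, ...]
    direction: Direction = Direction.INCREASING
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.mol_percent)
        a = tuple(float(v) for v in self.activity)
        if len(m) != len(a):
            raise ParameterError("mol_percent and activity must have equal length")
        if len(m) < 3:
            raise ParameterError(f"a dataset needs >= 3 points, got {len(m)}")
        if any(not math.isfinite(v) for v in m + a):
            raise ParameterError("dataset contains non-finite values")
        if any(not (0 <= v < 100) for v in m):
            raise ParameterError("cholesterol values must lie in [0, 100) mol %")
        order = sorted(range(len(m)), key=lambda i: m[i])
        m = tuple(m[i] for i in order)
        a = tuple(a[i] for i in order)
        if any(m[i] >= m[i + 1] for i in range(len(m) - 1)):
            raise ParameterError("duplicate cholesterol abscissae are not allowed")
        object.__setattr__(self, "mol_percent", m)
        object.__setattr__(self, "activity", a)
        object.__setattr__(self, "direction", Direction.coerce(self.direction))

    def __len__(self) -> int:
        return len(self.mol_percent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cholesterol": self.mol_percent, "activity": self.activity}
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted constants for one stoichiometry n, with goodness of fit."""

    n: int
    k_oligomer: float
    k_subunit: float
    baseline: float
    amplitude: float
    r_squared: float
    delta_g_subunit: float
    predicted: Tuple[float, ...]
    sse: float
    log10_k_oligomer: float
    dataset_name: str = ""
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k_oligomer": self.k_oligomer,
            "k_subunit": self.k_subunit,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "r_squared": self.r_squared,
            "delta_g_subunit_kj_mol": self.delta_g_subunit,
            "sse": self.sse,
            "log10_k_oligomer": self.log10_k_oligomer,
            "predicted": list(self.predicted),
            "dataset_name": self.dataset_name,
            "options": dict(self.options),
        }


def occupancy_to_activity(
    occ: Union[float, np.ndarray],
    baseline: float,
    amplitude: float,
    direction: Union[Direction, str] = Direction.INCREASING,
) -> Union[float, np.ndarray]:
    """Affine map from fractional occupancy to measured activity."""
    direction = Direction.coerce(direction)
    occ = np.asarray(occ, dtype=float)
    if np.any((occ < 0) | (occ > 1)):
        raise ParameterError("occupancy must lie in [0, 1]")
    eff = occ if direction is Direction.INCREASING else 1.0 - occ
    out = baseline + amplitude * eff
    return float(out) if out.ndim == 0 else out


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (about the mean)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ParameterError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise NonIdentifiableError("R^2 undefined: observed values are all identical")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@functools.lru_cache(maxsize=200_000)
def _occupancy_profile(
    lipids: Tuple[PhospholipidSpecies, ...],
    n: int,
    l_total: float,
    mol_percents: Tuple[float, ...],
    k_oligomer: float,
) -> Tuple[float, ...]:
    """Model occupancy at each observed mol % for one candidate K_Ln.

    Pure and deterministic in its arguments, hence safely memoised: the
    profile search and replicated refits revisit identical (composition, K)
    pairs many times.
    """
    protein = ProteinLigand(
        "candidate", subunit_constant(k_oligomer, n), n, l_total
    )
    p_total = sum(sp.amount for sp in lipids)
    base = MembraneSystem(lipids, protein, 0.0)
    occ = []
    for m in mol_percents:
        c_t = mol_percent_to_moles(m, p_total)
        occ.append(solve_equilibrium(base.with_c_total(c_t)).occupancy)
    return tuple(occ)


def _profile_sse(
    eff: np.ndarray, activity: np.ndarray, fit_baseline: bool
) -> Tuple[float, float, float]:
    """Closed-form least squares for (baseline, amplitude) given occupancy.

    Returns (sse, baseline, amplitude)."""
    if fit_baseline:
        design = np.column_stack([np.ones_like(eff), eff])
    else:
        design = eff[:, None]
    coef, _, _, _ = np.linalg.lstsq(design, activity, rcond=None)
    resid = activity - design @ coef
    sse = float(resid @ resid)
    if fit_baseline:
        return sse, float(coef[0]), float(coef[1])
    return sse, 0.0, float(coef[0])


class SterolAffinityRegressor(RegressorMixin, BaseEstimator):
    """Estimate a protein's sterol association constant from an activity curve.

    Fits the oligomer constant K_Ln of a concerted n-site ligand embedded
    in a stated phospholipid bilayer, given observed activity at a set of
    membrane cholesterol concentrations.  The affine activity scale
    (baseline, amplitude) is profiled out in closed form at each candidate
    K; the search minimises the sum of squared residuals over log10 K_Ln by
    a coarse grid then bounded scalar refinement, and is fully
    deterministic.

    Parameters
    ----------
    lipids : sequence of PhospholipidSpecies
        Bilayer composition (association constants K_P, stoichiometries r,
        amounts); the competitive backdrop against which the protein binds.
    n : int, default 1
        Sterols bound per oligomer in the concerted step.
    direction : {"increasing", "decreasing"}, default "increasing"
        Whether activity rises or falls with occupancy.
    protein_amount : float, default 1e-3
        Total ligand in moles (1e-3 for cell membranes, 1e-5 for planar
        bilayers); results are insensitive to it at these trace levels.
    fit_baseline : bool, default True
        If False the baseline is pinned at zero activity.
    log10_k_bounds : tuple, default (-2.0, 16.0)
        Search window for log10 K_Ln.
    grid_step : float, default 0.1
        Coarse-grid spacing in log10 K.
    refine_tol : float, default 1e-4
        Absolute tolerance of the bounded refinement in log10 K.

    Attributes
    ----------
    k_oligomer_ : float
        Fitted K_Ln.
    k_subunit_ : float
        K_Ln ** (1/n).
    baseline_, amplitude_ : float
        Fitted affine activity scale.
    r_squared_ : float
        Coefficient of determination on the training data.
    delta_g_subunit_ : float
        -RT ln K_L1 at 298 K, kJ/mol.
    fit_result_ : FitResult
        Full record of the fit.
    """

    def __init__(
        self,
        lipids: Sequence[PhospholipidSpecies] = (),
        n: int = 1,
        direction: Union[Direction, str] = Direction.INCREASING,
        protein_amount: float = 1e-3,
        fit_baseline: bool = True,
        log10_k_bounds: Tuple[float, float] = (-2.0, 16.0),
        grid_step: float = 0.1,
        refine_tol: float = 1e-4,
    ):
        self.lipids = lipids
        self.n = n
        self.direction = direction
        self.protein_amount = protein_amount
        self.fit_baseline = fit_baseline
        self.log10_k_bounds = log10_k_bounds
        self.grid_step = grid_step
        self.refine_tol = refine_tol

    def _validated(self):
        lipids = tuple(self.lipids)
        if not lipids:
            raise ParameterError("lipids must be a non-empty sequence")
        if isinstance(self.n, bool) or int(self.n) != self.n or self.n < 1:
            raise ParameterError(f"n must be an integer >= 1, got {self.n!r}")
        lo, hi = self.log10_k_bounds
        if not (lo < hi):
            raise ParameterError("log10_k_bounds must be (low, high) with low < high")
        if self.grid_step <= 0 or self.refine_tol <= 0:
            raise ParameterError("grid_step and refine_tol must be positive")
        if self.protein_amount < 0:
            raise ParameterError("protein_amount must be >= 0")
        return lipids, int(self.n), Direction.coerce(self.direction), float(lo), float(hi)

    def fit(self, X, y):
        """Fit K_Ln to activities ``y`` observed at mol % values ``X``."""
        lipids, n, direction, lo, hi = self._validated()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ParameterError("X must be 1-dimensional mol % values")
            X = X.ravel()
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.size < 3:
            raise ParameterError("need >= 3 paired (mol %, activity) observations")
        if np.unique(X).size != X.size:
            raise ParameterError("duplicate cholesterol abscissae are not allowed")
        mol = tuple(float(v) for v in X)
        if float(np.ptp(y)) == 0.0:
            raise NonIdentifiableError("activities are all identical")

        def eff_at(log10_k: float) -> np.ndarray:
            occ = np.array(
                _occupancy_profile(lipids, n, float(self.protein_amount), mol, 10.0**log10_k)
            )
            return occ if direction is Direction.INCREASING else 1.0 - occ

        def sse_at(log10_k: float) -> float:
            return _profile_sse(eff_at(log10_k), y, self.fit_baseline)[0]

        grid = np.arange(lo, hi + 0.5 * self.grid_step, self.grid_step)
        sse_grid = np.array([sse_at(g) for g in grid])
        i_best = int(np.argmin(sse_grid))
        lo_ref = grid[max(i_best - 1, 0)]
        hi_ref = grid[min(i_best + 1, grid.size - 1)]
        res = minimize_scalar(
            sse_at, bounds=(lo_ref, hi_ref), method="bounded",
            options={"xatol": self.refine_tol},
        )
        log10_k = float(res.x) if res.fun <= sse_grid[i_best] else float(grid[i_best])

        eff = eff_at(log10_k)
        if float(np.ptp(eff)) < 1e-9:
            raise NonIdentifiableError(
                "model occupancy is flat over the observed cholesterol range; "
                "K_Ln is not identifiable from these data"
            )
        sse, baseline, amplitude = _profile_sse(eff, y, self.fit_baseline)
        predicted = baseline + amplitude * eff
        k_oligomer = 10.0**log10_k
        k_sub = subunit_constant(k_oligomer, n)
        self.k_oligomer_ = k_oligomer
        self.k_subunit_ = k_sub
        self.baseline_ = baseline
        self.amplitude_ = amplitude
        self.r_squared_ = r_squared(y, predicted)
        self.delta_g_subunit_ = delta_g(k_sub)
        self.n_features_in_ = 1
        self.fit_result_ = FitResult(
            n=n,
            k_oligomer=k_oligomer,
            k_subunit=k_sub,
            baseline=baseline,
            amplitude=amplitude,
            r_squared=self.r_squared_,
            delta_g_subunit=self.delta_g_subunit_,
            predicted=tuple(float(v) for v in predicted),
            sse=sse,
            log10_k_oligomer=log10_k,
            options={
                "fit_baseline": self.fit_baseline,
                "log10_k_bounds": [lo, hi],
                "grid_step": self.grid_step,
                "refine_tol": self.refine_tol,
                "protein_amount": self.protein_amount,
                "direction": direction.value,
            },
        )
        return self

    def predict(self, X):
        """Predicted activity at mol % values ``X`` under the fitted model."""
        if not hasattr(self, "k_oligomer_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        lipids, n, direction, _, _ = self._validated()
        X = np.asarray(X, dtype=float)
        shape = X.shape
        mol = tuple(float(v) for v in X.ravel())
        occ = np.array(
            _occupancy_profile(lipids, n, float(self.protein_amount), mol, self.k_oligomer_)
        )
        eff = occ if direction is Direction.INCREASING else 1.0 - occ
        out = self.baseline_ + self.amplitude_ * eff
        return out.reshape(shape[0] if len(shape) == 2 else shape)


def fit_affinity(
    dataset: ActivityDataset,
    lipids: Sequence[PhospholipidSpecies],
    n: int = 1,
    protein_amount: float = 1e-3,
    **search_options,
) -> FitResult:
    """Fit the oligomer constant K_Ln of an n-site ligand to one dataset."""
    est = SterolAffinityRegressor(
        lipids=tuple(lipids),
        n=n,
        direction=dataset.direction,
        protein_amount=protein_amount,
        **search_options,
    )
    est.fit(np.array(dataset.mol_percent), np.array(dataset.activity))
    result = est.fit_result_
    return FitResult(**{**result.__dict__, "dataset_name": dataset.name})


def scan_stoichiometry(
    dataset: ActivityDataset,
    lipids: Sequence[PhospholipidSpecies],
    n_values: Sequence[int] = (1, 2, 3, 4, 5),
    protein_amount: float = 1e-3,
    **search_options,
) -> List[FitResult]:
    """Fit each candidate stoichiometry; rank by R^2 (ties -> smaller n)."""
    if not n_values:
        raise ParameterError("n_values must be non-empty")
    results = [
        fit_affinity(dataset, lipids, n=n, protein_amount=protein_amount, **search_options)
        for n in n_values
    ]
    return sorted(results, key=lambda r: (-r.r_squared, r.n))


def sensitivity_to_lipid_affinity(
    dataset: ActivityDataset,
    lipids: Sequence[PhospholipidSpecies],
    scale_factors: Sequence[float] = (0.5, 1.0, 2.0),
    n: int = 1,
    protein_amount: float = 1e-3,
    **search_options,
) -> pd.DataFrame:
    """Refit with every lipid K_P rescaled; report the spread of K_L1 and dG.

    More avid lipids force a more avid protein to match the same curve, so
    the fitted K_L1 rises with the scale factor; the logarithm compresses
    the corresponding free-energy spread.
    """
    if any(f <= 0 for f in scale_factors):
        raise ParameterError("scale factors must be positive")
    rows = []
    for factor in scale_factors:
        scaled = tuple(
            PhospholipidSpecies(sp.name, sp.k_assoc * factor, sp.r, sp.amount)
            for sp in lipids
        )
        res = fit_affinity(dataset, scaled, n=n, protein_amount=protein_amount,
                           **search_options)
        rows.append(
            {
                "kp_scale": factor,
                "k_subunit": res.k_subunit,
                "delta_g_subunit_kj_mol": res.delta_g_subunit,
                "r_squared": res.r_squared,
            }
        )
    return pd.DataFrame(rows)
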