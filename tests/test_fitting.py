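"""Affinity estimation: profile least squares, model selection, determinism."""

import numpy as np
import pytest
from sklearn.base import clone

from sterolbind import (
    ActivityDataset,
    NonIdentifiableError,
    ParameterError,
    PhospholipidSpecies,
    ProteinLigand,
    SterolAffinityRegressor,
    fit_affinity,
    generate_activity_data,
    membrane_preset,
    occupancy_to_activity,
    r_squared,
    scan_stoichiometry,
    sensitivity_to_lipid_affinity,
)


class TestOccupancyToActivity:
    def test_affine_endpoints(self):
        assert occupancy_to_activity(0.0, 2.0, 5.0, "increasing") == 2.0
        assert occupancy_to_activity(1.0, 2.0, 5.0, "increasing") == 7.0

    def test_direction_flip_symmetry(self):
        occ = np.linspace(0, 1, 11)
        assert np.allclose(
            occupancy_to_activity(occ, 0.3, 1.7, "decreasing"),
            occupancy_to_activity(1.0 - occ, 0.3, 1.7, "increasing"),
        )

    def test_occupancy_range_checked(self):
        with pytest.raises(ParameterError):
            occupancy_to_activity(1.2, 0.0, 1.0)


class TestRSquared:
    def test_perfect_prediction(self):
        obs = [1.0, 2.0, 3.0]
        assert r_squared(obs, obs) == 1.0

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        assert r_squared([1.0, 2.0, 3.0], [3.0, 1.0, 5.0]) < 0

    def test_degenerate_observations(self):
        with pytest.raises(NonIdentifiableError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_invariant_to_affine_rescaling(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="multiplicative",
                                    sd=0.02, seed=11)
        base = fit_affinity(ds, gat_bilayer, n=1)
        rescaled = ActivityDataset(
            ds.mol_percent,
            tuple(5.0 + 3.0 * a for a in ds.activity),
            ds.direction,
        )
        shifted = fit_affinity(rescaled, gat_bilayer, n=1)
        assert shifted.r_squared == pytest.approx(base.r_squared, abs=1e-9)
        assert shifted.k_subunit == pytest.approx(base.k_subunit, rel=1e-6)


class TestFitAffinity:
    def test_noiseless_recovery(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, n_points=12, noise="none", sd=0.0)
        res = fit_affinity(ds, gat_bilayer, n=1, protein_amount=1e-3)
        assert res.k_subunit == pytest.approx(100.0, rel=0.02)
        assert res.r_squared > 0.9999

    def test_cooperative_data_prefers_matching_stoichiometry(self):
        lipids = membrane_preset("planar_pops_pope")
        prot = ProteinLigand("p", 700.0, 4, 1e-5, "decreasing")
        ds = generate_activity_data(prot, lipids, noise="none", sd=0.0)
        fit4 = fit_affinity(ds, lipids, n=4, protein_amount=1e-5)
        fit1 = fit_affinity(ds, lipids, n=1, protein_amount=1e-5)
        assert fit4.r_squared > fit1.r_squared

    def test_deterministic(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="multiplicative",
                                    sd=0.02, seed=5)
        a = fit_affinity(ds, gat_bilayer, n=1)
        b = fit_affinity(ds, gat_bilayer, n=1)
        assert a.k_oligomer == b.k_oligomer
        assert a.predicted == b.predicted

    def test_pinned_baseline(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        res = fit_affinity(ds, gat_bilayer, n=1, fit_baseline=False)
        assert res.baseline == 0.0
        assert res.k_subunit == pytest.approx(100.0, rel=0.02)

    def test_flat_data_flagged(self, gat_bilayer):
        ds = ActivityDataset((0.0, 10.0, 20.0), (1.0, 1.0, 1.0))
        with pytest.raises(NonIdentifiableError):
            fit_affinity(ds, gat_bilayer, n=1)


class TestScanStoichiometry:
    def test_singleton(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        results = scan_stoichiometry(ds, gat_bilayer, [2])
        assert len(results) == 1 and results[0].n == 2

    def test_achr_like_data_prefers_n2(self):
        lipids = membrane_preset("achr_vesicle")
        prot = ProteinLigand("p", 950.0, 2, 1e-3)
        ds = generate_activity_data(prot, lipids, noise="none", sd=0.0)
        ranked = scan_stoichiometry(ds, lipids, [1, 2, 5])
        assert ranked[0].n == 2

    def test_ranking_invariant_to_point_order(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="multiplicative",
                                    sd=0.02, seed=9)
        perm = np.random.default_rng(0).permutation(len(ds))
        shuffled = ActivityDataset(
            tuple(ds.mol_percent[i] for i in perm),
            tuple(ds.activity[i] for i in perm),
            ds.direction,
        )
        a = [r.n for r in scan_stoichiometry(ds, gat_bilayer, [1, 2, 3])]
        b = [r.n for r in scan_stoichiometry(shuffled, gat_bilayer, [1, 2, 3])]
        assert a == b

    def test_empty_scan_rejected(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        with pytest.raises(ParameterError):
            scan_stoichiometry(ds, gat_bilayer, [])


class TestSensitivity:
    def test_lipid_affinity_scaling(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        table = sensitivity_to_lipid_affinity(ds, gat_bilayer, (0.5, 1.0, 2.0), n=1)
        ks = table["k_subunit"].to_numpy()
        # factor 1 reproduces the base fit
        assert ks[1] == pytest.approx(100.0, rel=0.02)
        # more avid lipids demand a more avid protein
        assert ks[0] < ks[1] < ks[2]
        # the logarithm compresses the free-energy spread
        dg = table["delta_g_subunit_kj_mol"].to_numpy()
        assert abs(dg[2] - dg[0]) / abs(dg[1]) < (ks[2] - ks[0]) / ks[1]

    def test_nonpositive_factor_rejected(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        with pytest.raises(ParameterError):
            sensitivity_to_lipid_affinity(ds, gat_bilayer, (0.0,))


class TestSklearnInterface:
    def test_get_set_params_and_clone(self, gat_bilayer):
        est = SterolAffinityRegressor(lipids=gat_bilayer, n=2, protein_amount=1e-5)
        params = est.get_params()
        assert params["n"] == 2
        cloned = clone(est)
        assert cloned.get_params()["protein_amount"] == 1e-5
        est.set_params(n=3)
        assert est.n == 3

    def test_fit_predict_score(self, gat_bilayer):
        prot = ProteinLigand("p", 100.0, 1, 1e-3)
        ds = generate_activity_data(prot, gat_bilayer, noise="none", sd=0.0)
        X = np.array(ds.mol_percent)[:, None]
        y = np.array(ds.activity)
        est = SterolAffinityRegressor(lipids=gat_bilayer, n=1).fit(X, y)
        assert est.k_subunit_ == pytest.approx(100.0, rel=0.02)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert est.score(X, y) > 0.9999
        assert est.delta_g_subunit_ == pytest.approx(-11.4, abs=0.05)

    def test_unfitted_predict_raises(self, gat_bilayer):
        est = SterolAffinityRegressor(lipids=gat_bilayer)
        with pytest.raises(RuntimeError):
            est.predict([10.0, 20.0])

    def test_dataset_validation(self):
        with pytest.raises(ParameterError):
            ActivityDataset((0.0, 1.0), (0.0, 1.0))  # too few
        with pytest.raises(ParameterError):
            ActivityDataset((0.0, 1.0, 1.0), (0.0, 1.0, 2.0))  # duplicate abscissae
        with pytest.raises(ParameterError):
            ActivityDataset((0.0, 1.0, 150.0), (0.0, 1.0, 2.0))  # out of range
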