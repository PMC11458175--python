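"""Powder averaging and parameter-estimation round trips."""

import numpy as np
import pytest

from subdki import (
    AcquisitionScheme,
    DKIParams,
    FitConfig,
    SubDiffParams,
    connectome_scheme,
    dki_signal,
    fit_dki,
    fit_subdiffusion,
    fit_volume,
    k_star,
    powder_average,
    simulate_signal,
)


class TestPowderAverage:
    def test_identical_values(self):
        np.testing.assert_allclose(powder_average([[3.0, 3.0, 3.0]]), [3.0])

    def test_exact_geometric_means(self):
        np.testing.assert_allclose(powder_average([[1.0, 4.0], [2.0, 8.0, 4.0]]),
                                   [2.0, 4.0], rtol=1e-14)

    def test_single_direction_passthrough(self):
        np.testing.assert_allclose(powder_average([[0.7]]), [0.7])

    def test_empty_shell_rejected(self):
        with pytest.raises(ValueError):
            powder_average([[]])

    def test_nonpositive_needs_floor(self):
        with pytest.raises(ValueError):
            powder_average([[1.0, -0.1]])
        val = powder_average([[1.0, -0.1]], floor=1e-6)
        assert val[0] == pytest.approx(np.sqrt(1e-6))


class TestSubdiffusionFit:
    def test_noiseless_round_trip_connectome(self, connectome):
        truth = SubDiffParams(d_beta=3e-4, beta=0.75)
        sig = simulate_signal(truth, connectome, 0.0, 0)
        fr = fit_subdiffusion(sig, connectome)
        assert fr.converged
        assert fr.params.d_beta == pytest.approx(3e-4, rel=1e-4)
        assert fr.params.beta == pytest.approx(0.75, rel=1e-4)
        assert fr.rmse < 1e-7

    def test_monoexponential_boundary(self, connectome):
        truth = SubDiffParams(d_beta=1e-3, beta=1.0)
        sig = simulate_signal(truth, connectome, 0.0, 0)
        fr = fit_subdiffusion(sig, connectome)
        assert fr.params.beta >= 0.999

    def test_flat_signal_flags_lower_bound(self, connectome):
        sig = np.ones(len(connectome))
        fr = fit_subdiffusion(sig, connectome)
        assert fr.at_bounds
        assert fr.params.d_beta == pytest.approx(
            FitConfig().d_beta_bounds[0], rel=1e-6)

    def test_too_few_observations(self):
        sch = connectome_scheme().subset([0, 1])
        with pytest.raises(ValueError):
            fit_subdiffusion([1.0, 0.9], sch)

    def test_permutation_invariance(self, connectome, rng):
        truth = SubDiffParams(d_beta=5e-4, beta=0.85)
        sig = simulate_signal(truth, connectome, 0.0125, rng)
        perm = rng.permutation(len(connectome))
        fr1 = fit_subdiffusion(sig, connectome)
        fr2 = fit_subdiffusion(sig[perm], connectome.subset(perm))
        assert fr1.params.d_beta == pytest.approx(fr2.params.d_beta,
                                                  rel=1e-10)
        assert fr1.params.beta == pytest.approx(fr2.params.beta, rel=1e-10)

    def test_joint_fit_matches_single_delta_when_consistent(self):
        # both Delta blocks generated by one (D_beta, beta): the joint fit
        # and either single-Delta fit must agree on noiseless data
        truth = SubDiffParams(d_beta=4e-4, beta=0.8)
        full = connectome_scheme()
        sig = simulate_signal(truth, full, 0.0, 0)
        joint = fit_subdiffusion(sig, full)
        d19 = np.nonzero(full.is_b0 | (full.big_delta_ms == 19.0))[0]
        single = fit_subdiffusion(sig[d19], full.subset(d19))
        assert joint.params.beta == pytest.approx(single.params.beta,
                                                  abs=1e-6)
        assert joint.params.d_beta == pytest.approx(single.params.d_beta,
                                                    rel=1e-6)

    def test_unnormalized_fits_s0(self, connectome):
        truth = SubDiffParams(d_beta=3e-4, beta=0.75, s0=3.7)
        sig = 3.7 * simulate_signal(
            SubDiffParams(d_beta=3e-4, beta=0.75), connectome, 0.0, 0)
        fr = fit_subdiffusion(sig, connectome,
                              FitConfig(normalize=False))
        assert fr.params.s0 == pytest.approx(3.7, rel=1e-4)
        assert fr.params.beta == pytest.approx(0.75, rel=1e-4)


class TestDKIFit:
    def test_noiseless_round_trip(self):
        truth = DKIParams(d_dki=1e-3, k_dki=0.8)
        b = np.array([0.0, 1000.0, 2000.0])
        fr = fit_dki(dki_signal(truth, b), b)
        assert fr.params.d_dki == pytest.approx(1e-3, rel=1e-4)
        assert fr.params.k_dki == pytest.approx(0.8, rel=1e-4)

    def test_gaussian_limit(self):
        b = np.array([0.0, 800.0, 1600.0, 2400.0])
        sig = np.exp(-b * 1e-3)
        fr = fit_dki(sig, b)
        assert fr.params.k_dki <= 1e-3

    def test_high_b_guard(self):
        b = np.array([0.0, 1000.0, 4250.0])
        with pytest.raises(ValueError, match="4250"):
            fit_dki(np.ones(3), b)


class TestVolumeFit:
    def test_uniform_block_recovers_kstar(self, connectome):
        truth = SubDiffParams(d_beta=3e-4, beta=0.75)
        sig = simulate_signal(truth, connectome, 0.0, 0)
        data = np.tile(sig, (2, 2, 1, 1))
        maps = fit_volume(data, connectome)
        np.testing.assert_allclose(maps["Kstar"], k_star(0.75), atol=1e-3)
        assert maps["rmse"].max() < 1e-6

    def test_two_tissue_plateaus(self, noiseless_phantom):
        ds, truth = noiseless_phantom
        maps = fit_volume(ds.data, ds.scheme, mask=ds.mask)
        wm = truth["labels"] == 1
        np.testing.assert_allclose(maps["Kstar"][wm], 0.8125, atol=1e-3)
        np.testing.assert_allclose(maps["Kstar"][~wm], 0.4733, atol=1e-3)

    def test_masked_voxels_filled(self, connectome):
        sig = simulate_signal(SubDiffParams(d_beta=3e-4, beta=0.75),
                              connectome, 0.0, 0)
        data = np.tile(sig, (2, 1, 1, 1))
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[0] = True
        maps = fit_volume(data, connectome, mask=mask)
        assert np.isfinite(maps["Kstar"][0, 0, 0])
        assert np.isnan(maps["Kstar"][1, 0, 0])

    def test_shape_mismatch(self, connectome):
        with pytest.raises(ValueError):
            fit_volume(np.ones((2, 2, 1, 3)), connectome)

    def test_dki_volume_single_delta_only(self, connectome):
        data = np.ones((1, 1, 1, len(connectome)))
        with pytest.raises(ValueError):
            fit_volume(data, connectome, model="dki")
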