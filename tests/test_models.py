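"""Forward models, closed-form transforms and scheme handling."""

import math

import numpy as np
import pytest

from subdki import (
    AcquisitionScheme,
    DKIParams,
    SubDiffParams,
    b_from_protocol,
    connectome_b_table,
    connectome_scheme,
    d_star,
    d_sub,
    dki_signal,
    k_star,
    k_star_inverse,
    ml_series,
    sub_signal_b,
    sub_signal_q,
)
from subdki.models import GAMMA_PROTON, read_scheme, write_scheme


class TestKStar:
    def test_printed_tissue_values(self):
        # closed-form kurtosis at the idealised WM/GM/extreme orders
        assert k_star(0.75) == pytest.approx(0.8125, abs=5e-5)
        assert k_star(0.85) == pytest.approx(0.4733, abs=5e-5)
        assert k_star(0.5) == pytest.approx(1.7124, abs=5e-5)
        assert k_star(1.0) == pytest.approx(0.0, abs=1e-15)

    def test_strictly_decreasing(self):
        betas = np.linspace(0.5, 1.0, 101)
        vals = k_star(betas)
        assert np.all(np.diff(vals) < 0)

    def test_inverse_round_trip(self):
        for beta in (0.5, 0.62, 0.75, 0.9, 1.0):
            assert k_star_inverse(k_star(beta)) == pytest.approx(beta, abs=1e-8)

    def test_inverse_of_printed_values(self):
        # 4-d.p. printing limits how sharply beta can be pinned down
        assert k_star_inverse(0.8125) == pytest.approx(0.75, abs=1e-4)
        assert k_star_inverse(0.4733) == pytest.approx(0.85, abs=1e-4)
        assert k_star_inverse(0.0) == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            k_star(1.2)
        with pytest.raises(ValueError):
            k_star_inverse(2.5)


class TestDiffusivities:
    def test_d_sub_beta_one_identity(self):
        assert d_sub(7e-4, 1.0, 0.123) == pytest.approx(7e-4, rel=1e-15)

    @pytest.mark.parametrize("d_beta,beta,dbar", [
        (3e-4, 0.75, 0.016333), (5e-4, 0.85, 0.046333)])
    def test_d_sub_power_law(self, d_beta, beta, dbar):
        expect = math.exp(math.log(d_beta) + (beta - 1.0) * math.log(dbar))
        assert d_sub(d_beta, beta, dbar) == pytest.approx(expect, rel=1e-12)

    def test_d_star_gamma_scaling(self):
        assert d_star(1.0, 1.0) == pytest.approx(1.0)
        assert d_star(1.0, 0.5) == pytest.approx(2.0 / math.sqrt(math.pi),
                                                 rel=1e-12)
        for beta in np.linspace(0.05, 1.0, 20):
            v = d_star(1e-3, beta)
            assert np.isfinite(v) and v > 0


class TestSignals:
    def test_q_zero_returns_s0(self):
        p = SubDiffParams(d_beta=4e-4, beta=0.7, s0=2.5)
        assert sub_signal_q(p, 0.0, 0.016) == pytest.approx(2.5)

    def test_beta_one_monoexponential(self):
        p = SubDiffParams(d_beta=1e-3, beta=1.0)
        val = sub_signal_q(p, 10.0, 0.0163)
        assert val == pytest.approx(math.exp(-1e-3 * 100 * 0.0163), rel=1e-14)

    def test_against_series_oracle(self):
        p = SubDiffParams(d_beta=3e-4, beta=0.75)
        z = -3e-4 * 20.0 ** 2 * 0.016333 ** 0.75
        assert sub_signal_q(p, 20.0, 0.016333) == pytest.approx(
            ml_series(0.75, z), rel=1e-10)
        p2 = SubDiffParams(d_beta=5e-4, beta=0.85)
        z2 = -1000.0 * 5e-4 * 0.016333 ** (0.85 - 1.0)
        assert sub_signal_b(p2, 1000.0, 0.016333) == pytest.approx(
            ml_series(0.85, z2), rel=1e-10)

    def test_b_and_q_forms_agree(self, rng):
        p = SubDiffParams(d_beta=4e-4, beta=0.8)
        q = rng.uniform(1.0, 40.0, 25)
        dbar = 0.0163
        b = q ** 2 * dbar
        np.testing.assert_allclose(sub_signal_b(p, b, dbar),
                                   sub_signal_q(p, q, dbar), rtol=1e-12)

    def test_decay_monotone_in_b(self):
        p = SubDiffParams(d_beta=5e-4, beta=0.85)
        b = np.linspace(0.0, 17800.0, 60)
        s = sub_signal_b(p, b, 0.046333)
        assert np.all(np.diff(s) < 0)
        assert np.all(s > 0) and s[0] == pytest.approx(1.0)

    def test_unit_rescaling_invariance(self):
        # expressing dbar in ms with D_beta rescaled by 1000^(1-beta)
        # leaves the signal unchanged
        beta, d_beta, dbar_s = 0.75, 3e-4, 0.016333
        p_s = SubDiffParams(d_beta=d_beta, beta=beta)
        p_ms = SubDiffParams(d_beta=d_beta * 1000.0 ** (1.0 - beta), beta=beta)
        b = np.array([500.0, 2400.0, 6000.0])
        np.testing.assert_allclose(
            sub_signal_b(p_s, b, dbar_s),
            sub_signal_b(p_ms, b, dbar_s * 1000.0), rtol=1e-10)

    def test_dki_signal_values(self):
        p = DKIParams(d_dki=1e-3, k_dki=1.0)
        assert dki_signal(p, 0.0) == pytest.approx(1.0)
        assert dki_signal(p, 1000.0) == pytest.approx(
            math.exp(-1.0 + 1.0 / 6.0), rel=1e-14)
        p0 = DKIParams(d_dki=1e-3, k_dki=1e-12)
        assert dki_signal(p0, 2000.0) == pytest.approx(math.exp(-2.0),
                                                       rel=1e-9)

    def test_small_b_expansion_third_order(self):
        # log S_sub(b) = -b D* + b^2 D*^2 K*/6 + O(b^3): the residual must
        # shrink by ~8x per b-halving (Richardson ratio test)
        p = SubDiffParams(d_beta=3e-4, beta=0.75)
        dbar = 0.016333
        dstar = p.d_star(dbar)
        kstar = p.k_star
        bs = 400.0 / 2 ** np.arange(4)
        resid = []
        for b in bs:
            quad = -b * dstar + b ** 2 * dstar ** 2 * kstar / 6.0
            resid.append(abs(math.log(sub_signal_b(p, b, dbar)) - quad))
        ratios = np.array(resid[:-1]) / np.array(resid[1:])
        assert np.all(ratios > 6.0) and np.all(ratios < 10.0)


class TestProtocol:
    def test_zero_gradient(self):
        assert b_from_protocol(GAMMA_PROTON, 8e-3, 0.0, 19e-3) == 0.0

    def test_quadratic_in_gradient(self):
        b1 = b_from_protocol(GAMMA_PROTON, 8e-3, 31e-3, 19e-3)
        b2 = b_from_protocol(GAMMA_PROTON, 8e-3, 62e-3, 19e-3)
        assert b2 / b1 == pytest.approx(4.0, rel=1e-12)

    def test_connectome_first_rung(self):
        # nominal table says 50 s/mm^2 but the pulse formula gives ~71.9;
        # nominal values stay authoritative for acquired data
        b = b_from_protocol(GAMMA_PROTON, 8e-3, 31e-3, 19e-3)
        assert b == pytest.approx(71.9, rel=5e-3)


class TestScheme:
    def test_connectome_layout(self, connectome):
        assert len(connectome) == 17
        assert connectome.is_b0.sum() == 1
        assert sorted(set(connectome.big_delta_ms)) == [19.0, 49.0]
        table = connectome_b_table()
        assert len(table) == 16

    def test_delta_bar(self, connectome):
        np.testing.assert_allclose(
            np.unique(connectome.delta_bar_s),
            [(19 - 8 / 3) * 1e-3, (49 - 8 / 3) * 1e-3])

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionScheme(b=[100.0], big_delta_ms=[2.0],
                              small_delta_ms=[8.0])

    def test_q_consistency_enforced(self):
        dbar = (19 - 8 / 3) * 1e-3
        q = np.sqrt(1000.0 / dbar)
        AcquisitionScheme(b=[1000.0], big_delta_ms=[19.0],
                          small_delta_ms=[8.0], q=[q])  # consistent: fine
        with pytest.raises(ValueError):
            AcquisitionScheme(b=[1000.0], big_delta_ms=[19.0],
                              small_delta_ms=[8.0], q=[q * 1.1])

    def test_serialization_round_trip(self, tmp_path, connectome):
        paths = write_scheme(connectome, tmp_path / "scheme")
        back = read_scheme(paths["bval"], paths["bvec"], paths["timing"])
        np.testing.assert_allclose(back.b, connectome.b)
        np.testing.assert_array_equal(back.big_delta_ms,
                                      connectome.big_delta_ms)
        np.testing.assert_array_equal(back.n_dirs, connectome.n_dirs)
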