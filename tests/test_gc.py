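import dataclasses

import numpy as np
import pytest

import specgc as sg


def identity_factor(N=64, fs=1000.0):
    eye = np.tile(np.eye(2, dtype=complex), (N, 1, 1))
    coeffs = np.zeros((N // 2 + 1, 2, 2), dtype=complex)
    coeffs[0] = np.eye(2)
    return sg.SpectralFactor(
        coeffs=coeffs, grid_values=eye, backend="wilson", labels=("X", "Y"), fs=fs
    )


def random_unitary(seed):
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2)))
    return Q * (np.diagonal(R) / np.abs(np.diagonal(R)))


class TestTransferNoise:
    def test_identity_factor(self):
        tn = sg.transfer_noise(identity_factor())
        np.testing.assert_allclose(tn.Sigma, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tn.H, np.tile(np.eye(2), (64, 1, 1)), atol=1e-12)

    def test_recovers_generative_noise_covariance(self, coupled_factor_wilson):
        tn = sg.transfer_noise(coupled_factor_wilson)
        np.testing.assert_allclose(tn.Sigma.real, np.eye(2), atol=1e-4)

    def test_invariant_under_constant_unitary(self, coupled_factor_wilson):
        Q = random_unitary(3)
        rot = dataclasses.replace(
            coupled_factor_wilson,
            coeffs=coupled_factor_wilson.coeffs @ Q,
            grid_values=coupled_factor_wilson.grid_values @ Q,
        )
        a, b = sg.transfer_noise(coupled_factor_wilson), sg.transfer_noise(rot)
        np.testing.assert_allclose(a.Sigma, b.Sigma, atol=1e-10)
        np.testing.assert_allclose(a.H, b.H, atol=1e-10)

    def test_zeroth_coefficient_of_h_is_identity(self, coupled_factor_wilson):
        tn = sg.transfer_noise(coupled_factor_wilson)
        B0 = np.fft.ifft(tn.H, axis=0)[0]
        np.testing.assert_allclose(B0, np.eye(2), atol=1e-8)

    def test_h_sigma_reconstructs_spectrum(self, coupled_spectrum, coupled_factor_wilson):
        tn = sg.transfer_noise(coupled_factor_wilson)
        rec = tn.H @ tn.Sigma[None] @ np.conj(np.swapaxes(tn.H, 1, 2))
        np.testing.assert_allclose(rec, coupled_spectrum.values, atol=1e-8)


class TestMultilagGC:
    def test_independent_white_noise_gives_unity(self):
        res = sg.multilag_gc(identity_factor(), "X", "Y", L_max=10)
        np.testing.assert_allclose(res.I_vals, 1.0, atol=1e-12)
        res = sg.multilag_gc(identity_factor(), "Y", "X", L_max=10)
        np.testing.assert_allclose(res.I_vals, 1.0, atol=1e-12)

    def test_matches_exact_oracle(self, coupled_model, coupled_factor_fine):
        """Nonparametric I^L from the analytic spectrum equals the
        Levinson/companion-matrix oracle."""
        orc = sg.oracle_multilag_gc(coupled_model, 20, target="X", fs=1.0)
        est = sg.multilag_gc(coupled_factor_fine, "Y", "X", L_max=20)
        np.testing.assert_allclose(est.I_vals, orc.I_vals, rtol=1e-3)

    def test_uncoupled_direction_is_unity(self, coupled_factor_fine):
        res = sg.multilag_gc(coupled_factor_fine, "X", "Y", L_max=20)
        np.testing.assert_allclose(res.I_vals, 1.0, atol=1e-6)

    def test_ratio_nonnegative_and_invariants(self, coupled_factor_fine):
        res = sg.multilag_gc(coupled_factor_fine, "Y", "X", L_max=50)
        assert np.all(res.I_vals >= 0)
        assert np.all(res.joint_var > 0)
        np.testing.assert_allclose(res.I_vals, res.uni_var / res.joint_var)
        # on analytic spectra the joint predictor can never lose to the marginal
        assert np.all(res.I_vals >= 1 - 1e-12)

    def test_gc_invariant_under_constant_unitary(self, coupled_factor_fine):
        Q = random_unitary(7)
        rot = dataclasses.replace(
            coupled_factor_fine,
            coeffs=coupled_factor_fine.coeffs @ Q,
            grid_values=coupled_factor_fine.grid_values @ Q,
        )
        a = sg.multilag_gc(coupled_factor_fine, "Y", "X", L_max=10)
        b = sg.multilag_gc(rot, "Y", "X", L_max=10)
        np.testing.assert_allclose(a.I_vals, b.I_vals, atol=1e-10)

    def test_lag_axis_in_milliseconds(self, coupled_factor_wilson):
        f500 = dataclasses.replace(coupled_factor_wilson, fs=500.0)
        res = sg.multilag_gc(f500, "Y", "X", L_max=3)
        assert res.step_ms == pytest.approx(2.0)
        np.testing.assert_allclose(res.lag_ms, [2.0, 4.0, 6.0])
        f1k = dataclasses.replace(coupled_factor_wilson, fs=1000.0)
        assert sg.multilag_gc(f1k, "Y", "X", L_max=1).step_ms == pytest.approx(1.0)

    def test_unknown_channel_and_horizon_errors(self, coupled_factor_wilson):
        with pytest.raises(KeyError, match="T99"):
            sg.multilag_gc(coupled_factor_wilson, "T99", "X", L_max=5)
        with pytest.raises(ValueError, match="exceeds"):
            sg.multilag_gc(coupled_factor_wilson, "Y", "X", L_max=1000)

    def test_tidy_csv_export(self, tmp_path, coupled_factor_fine):
        res = sg.multilag_gc(coupled_factor_fine, "Y", "X", L_max=5)
        p = tmp_path / "gc.csv"
        res.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == [
            "pair", "source", "target", "L", "lag_ms", "I", "lnI", "uni_var", "joint_var",
        ]
        assert len(df) == 5
        np.testing.assert_allclose(df["lnI"], np.log(df["I"]))


class TestOnestep:
    def test_identity_gives_one(self):
        assert sg.onestep_gc(identity_factor(), "Y", "X") == pytest.approx(1.0)

    def test_bit_identical_to_multilag_l1(self, coupled_factor_fine):
        one = sg.onestep_gc(coupled_factor_fine, "Y", "X")
        multi = sg.multilag_gc(coupled_factor_fine, "Y", "X", L_max=1)
        assert one == multi.I_vals[0]

    def test_matches_levinson_oracle(self, coupled_model, coupled_factor_fine):
        orc = sg.oracle_multilag_gc(coupled_model, 1, target="X")
        est = sg.onestep_gc(coupled_factor_fine, "Y", "X")
        assert est == pytest.approx(orc.I_vals[0], rel=1e-4)


class TestDominantDirection:
    def _result(self, source, target, I, lags=(1, 2)):
        lags = np.asarray(lags)
        vals = np.full(lags.size, I, dtype=float)
        return sg.GCResult(
            source=source, target=target, lags=lags, step_ms=1.0,
            I_vals=vals, uni_var=vals, joint_var=np.ones(lags.size),
        )

    def test_larger_ratio_wins(self):
        call = sg.dominant_direction(
            self._result("Y", "X", 1.3), self._result("X", "Y", 1.0), L=1
        )
        assert call.dominant == "Y->X" and call.reverse == "X->Y"
        assert not call.tie
        assert call.values == {"Y->X": 1.3, "X->Y": 1.0}

    def test_tie_breaks_lexicographically_and_flags(self):
        call = sg.dominant_direction(
            self._result("Y", "X", 1.0), self._result("X", "Y", 1.0), L=1
        )
        assert call.tie
        assert call.dominant == "X->Y"  # smaller source label

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="different channel pairs"):
            sg.dominant_direction(
                self._result("Y", "X", 1.0), self._result("A", "B", 1.0), L=1
            )
        with pytest.raises(ValueError, match="lag grids"):
            sg.dominant_direction(
                self._result("Y", "X", 1.0),
                self._result("X", "Y", 1.0, lags=(1, 2, 3)),
                L=1,
            )
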