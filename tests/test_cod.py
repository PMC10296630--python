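import numpy as np
import pytest

from anguilliform.cod import (
    MidlineField,
    analytic_signal,
    decompose,
    split_standing_traveling,
    traveling_index,
)
from conftest import traveling_wave_field


def field_from(y, L=0.2, periods=2.0):
    M, Nt = y.shape
    return MidlineField(
        stations=np.linspace(0, L, M), times=np.arange(Nt) * periods / Nt, y=y
    )


class TestAnalyticSignal:
    def test_textbook_pairs(self):
        t = np.arange(64) / 64 * 2 * np.pi
        z = analytic_signal(np.cos(4 * t))
        assert np.allclose(z, np.exp(1j * 4 * t), atol=1e-10)
        z = analytic_signal(np.sin(4 * t))
        assert np.allclose(z, -1j * np.exp(1j * 4 * t), atol=1e-10)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            z = analytic_signal(np.ones(32))
        assert np.allclose(z, 0.0)

    def test_finite_sample_error_small_off_edges(self):
        """A non-integer number of cycles leaks at the record edges only."""
        t = np.linspace(0, 2.35, 64)
        om = 2 * np.pi * 3.0
        z = analytic_signal(np.cos(om * t))
        ref = np.exp(1j * om * t)
        ref = ref - ref.mean()
        interior = slice(8, -8)
        err = np.abs(z - ref)[interior] / np.abs(ref).max()
        assert np.median(err) < 0.02


class TestDecompose:
    def test_pure_traveling_wave_is_rank_one(self):
        field = traveling_wave_field()
        res = decompose(field)
        assert res.energy_fractions[0] > 0.99

    def test_two_orthogonal_waves_split_energy(self):
        """Spatially orthogonal waves produce eigenvalues in the squared-
        amplitude ratio."""
        M, Nt = 32, 256
        x = np.linspace(0, 1, M, endpoint=False)
        t = np.arange(Nt) / Nt * 2
        y = 1.0 * np.sin(2 * np.pi * (2 * x[:, None] - t)) + 0.5 * np.sin(
            2 * np.pi * (4 * x[:, None] + 3 * t)
        )
        res = decompose(field_from(y))
        fr = res.energy_fractions
        assert fr[0] / fr[1] == pytest.approx(4.0, rel=0.05)
        assert fr[:2].sum() > 0.99

    def test_eigenvalues_sum_to_signal_energy(self):
        field = traveling_wave_field(standing=0.4)
        res = decompose(field)
        Z = analytic_signal(field.y)
        assert res.eigenvalues.sum() == pytest.approx(
            np.mean(np.abs(Z) ** 2, axis=1).sum(), rel=1e-9
        )

    def test_modes_orthonormal(self):
        field = traveling_wave_field(standing=0.7)
        W = decompose(field).modes
        G = W.conj().T @ W
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-10)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal((8, 256))
        res = decompose(field_from(y))
        fr = res.energy_fractions
        assert fr[0] < 3.5 * fr[-1]  # no dominant coherent mode


class TestTravelingIndex:
    def test_pure_traveling_is_one(self):
        res = decompose(traveling_wave_field())
        assert res.traveling_index == pytest.approx(1.0, abs=1e-6)

    def test_pure_standing_is_zero(self):
        x = np.linspace(0, 1, 24)
        t = np.arange(128) / 128 * 2
        y = np.sin(2 * np.pi * x)[:, None] * np.cos(2 * np.pi * t)[None, :]
        res = decompose(field_from(y))
        assert res.traveling_index == pytest.approx(0.0, abs=1e-6)

    def test_zero_mode_rejected(self):
        with pytest.raises(ValueError):
            traveling_index(np.zeros(8, dtype=complex))

    @pytest.mark.parametrize(
        "transform",
        ["scale", "time_shift", "reflect", "time_reverse"],
        ids=["amplitude-scaling", "whole-sample-shift", "spatial-reflection", "time-reversal"],
    )
    def test_invariances(self, transform):
        base = traveling_wave_field(standing=0.5)
        y = base.y
        if transform == "scale":
            y2 = 3.7 * y
        elif transform == "time_shift":
            y2 = np.roll(y, 17, axis=1)
        elif transform == "reflect":
            y2 = y[::-1]
        elif transform == "time_reverse":
            y2 = y[:, ::-1]
        xi1 = decompose(base).traveling_index
        xi2 = decompose(field_from(y2)).traveling_index
        assert xi2 == pytest.approx(xi1, abs=1e-9)


class TestSplit:
    def test_pure_inputs_have_trivial_remainders(self):
        trav = traveling_wave_field()
        res = decompose(trav)
        standing, traveling = split_standing_traveling(res.dominant, trav)
        assert np.abs(standing["y"]).max() < 1e-6 * np.abs(traveling["y"]).max()

        x = np.linspace(0, 1, 24)
        t = np.arange(128) / 128 * 2
        ys = np.sin(2 * np.pi * x)[:, None] * np.cos(2 * np.pi * t)[None, :]
        fs = field_from(ys)
        res = decompose(fs)
        standing, traveling = split_standing_traveling(res.dominant, fs)
        assert np.abs(traveling["y"]).max() < 1e-6 * np.abs(standing["y"]).max()

    def test_parts_sum_to_mode_motion(self):
        field = traveling_wave_field(standing=0.5)
        res = decompose(field)
        standing, traveling = split_standing_traveling(res.dominant, field)
        Z = analytic_signal(field.y)
        a1 = res.dominant.conj() @ Z
        mode_motion = np.real(np.outer(res.dominant, a1))
        assert np.allclose(standing["y"] + traveling["y"], mode_motion, atol=1e-12)

    def test_round_trip_indices(self):
        """The traveling part decomposes as pure traveling, the standing part
        as pure standing."""
        field = traveling_wave_field(standing=0.6)
        res = decompose(field)
        standing, traveling = split_standing_traveling(res.dominant, field)
        xi_t = decompose(field_from(traveling["y"])).traveling_index
        xi_s = decompose(field_from(standing["y"])).traveling_index
        assert xi_t > 0.99
        assert xi_s < 0.01

    def test_known_composition_recovered(self):
        """sin(kx - wt) + 0.5 sin(kx)cos(wt): split amplitudes within 5%."""
        M, Nt = 48, 256
        L = 1.0
        x = np.linspace(0, L, M, endpoint=False)
        t = np.arange(Nt) / Nt * 2
        k, om = 2 * np.pi / L, 2 * np.pi
        y = np.sin(k * x[:, None] - om * t) + 0.5 * np.sin(k * x[:, None]) * np.cos(
            om * t
        )
        field = field_from(y)
        res = decompose(field)
        standing, traveling = split_standing_traveling(res.dominant, field)
        # reconstruct dominant-mode motion only (covers ~all energy here)
        amp_t = np.abs(traveling["y"]).max()
        amp_s = np.abs(standing["y"]).max()
        assert amp_t == pytest.approx(1.0, rel=0.05)
        assert amp_s == pytest.approx(0.5, rel=0.05)
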