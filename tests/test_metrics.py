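import numpy as np
import pytest

from medfuse import DimensionError, MetricsReport, entropy, evaluate, fmi, mssim, piella, qabf, qy, scd

from conftest import random_image
from oracles import fmi_loop, piella_loop, qabf_loop, qy_loop, scd_loop, ssim_windowed_loop


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(np.full((16, 16), 0.25)) == 0.0

    def test_fair_two_level_image_one_bit(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        assert entropy(img) == pytest.approx(1.0)

    def test_uniform_256_levels_eight_bits(self):
        img = (np.arange(256 * 4) % 256).reshape(32, 32) / 255.0
        assert entropy(img) == 8.0


class TestMssim:
    def test_identity(self, rng):
        x = rng.random((32, 32))
        assert mssim(x, x, x) == pytest.approx(1.0)

    def test_matches_windowed_ssim_oracle(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        expected = (1.0 + ssim_windowed_loop(b, a)) / 2.0
        assert mssim(a, b, a) == pytest.approx(expected, abs=1e-8)

    def test_inverted_structure_scores_below_one(self, rng):
        a = rng.random((32, 32))
        assert mssim(a, a, 1.0 - a) < 1.0


class TestScd:
    def test_sum_construction_recovers_two(self):
        rng = np.random.default_rng(0)
        a = rng.random((64, 64))
        b = rng.random((64, 64))
        assert scd(a, b, a + b) == pytest.approx(2.0, abs=0.05)

    def test_matches_correlation_oracle(self):
        a = random_image(1, (16, 16))
        b = random_image(2, (16, 16))
        f = b.copy()  # one difference image vanishes -> that term is 0
        assert scd(a, b, f) == pytest.approx(scd_loop(a, b, f), abs=1e-12)

    def test_equal_sources_symmetric_terms(self):
        a = random_image(3, (16, 16))
        f = random_image(4, (16, 16))
        from oracles import pearson_loop

        assert scd(a, a, f) == pytest.approx(2.0 * pearson_loop(a, f - a), abs=1e-12)


class TestQabf:
    def test_identity_reaches_the_sigmoid_plateau(self, rng):
        """Perfect edge transfer scores the plateau of the two sigmoids,
        Qg(1)*Qa(1) ~= 0.9748 with the standard constants."""
        x = rng.random((16, 16))
        plateau = (0.9994 / (1 + np.exp(-15 * 0.5))) * (0.9879 / (1 + np.exp(-22 * 0.2)))
        assert qabf(x, x, x) == pytest.approx(plateau, abs=1e-12)

    def test_constant_fused_image_transfers_no_edges(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        assert qabf(a, b, np.full((16, 16), 0.5)) < 0.05

    def test_matches_scalar_transcription_oracle(self):
        a = random_image(5, (16, 16))
        b = random_image(6, (16, 16))
        f = 0.5 * (a + b)
        assert qabf(a, b, f) == pytest.approx(qabf_loop(a, b, f), abs=1e-10)


class TestPiella:
    def test_identity(self, rng):
        x = rng.random((24, 24))
        assert piella(x, x, x) == pytest.approx(1.0, abs=1e-6)

    def test_flat_second_source_gives_full_weight_to_first(self):
        a = random_image(7, (24, 24))
        b = np.full((24, 24), 0.5)  # zero saliency everywhere
        assert piella(a, b, a) == pytest.approx(1.0, abs=1e-10)

    def test_matches_window_loop_oracle(self):
        a = random_image(8, (24, 24))
        b = random_image(9, (24, 24))
        f = 0.5 * (a + b)
        assert piella(a, b, f) == pytest.approx(piella_loop(a, b, f), abs=1e-10)


class TestQy:
    def test_identity(self, rng):
        x = rng.random((24, 24))
        assert qy(x, x, x) == pytest.approx(1.0, abs=1e-6)

    def test_conflicting_sources_take_the_better_ssim(self):
        """Anti-correlated sources fall below the 0.75 agreement gate, and
        f = a then scores max(SSIM(a,f), SSIM(b,f)) = 1."""
        a = random_image(10, (16, 16))
        b = 1.0 - a
        assert qy(a, b, a) == pytest.approx(1.0, abs=1e-10)

    def test_matches_window_loop_oracle(self):
        a = random_image(11, (20, 20))
        b = random_image(12, (20, 20))
        f = 0.5 * (a + b)
        assert qy(a, b, f) == pytest.approx(qy_loop(a, b, f), abs=1e-10)


class TestFmi:
    def test_identity(self, rng):
        x = rng.random((24, 24))
        assert fmi(x, x, x) == pytest.approx(1.0, abs=1e-6)

    def test_independent_fused_image_has_little_shared_information(self):
        """MI of independent fields tends to 0; at 256x256 the finite-
        sample bias of the 256-bin histogram estimator is small enough to
        sit below 0.1."""
        rng = np.random.default_rng(13)
        a = rng.random((256, 256))
        b = rng.random((256, 256))
        f = rng.random((256, 256))
        assert fmi(a, b, f) < 0.1

    def test_matches_joint_histogram_oracle(self):
        a = random_image(14, (16, 16))
        b = random_image(15, (16, 16))
        f = 0.5 * (a + b)
        assert fmi(a, b, f) == pytest.approx(fmi_loop(a, b, f), abs=1e-10)


class TestEvaluate:
    def test_identity_certificates(self, rng):
        x = rng.random((32, 32))
        r = evaluate(x, x, x)
        for name in ("piella", "qy", "mssim", "fmi"):
            assert getattr(r, name) == pytest.approx(1.0, abs=1e-6)
        assert r.qabf > 0.97
        assert r.scd == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_range_bounds_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, f = (rng.random((24, 24)) for _ in range(3))
        r = evaluate(a, b, f)
        assert all(np.isfinite(v) for v in r.to_dict().values())
        assert 0.0 <= r.entropy <= 8.0
        for name in ("piella", "qy", "qabf", "mssim"):
            assert -1.0 <= getattr(r, name) <= 1.0
        assert -2.0 <= r.scd <= 2.0
        assert 0.0 <= r.fmi <= 1.0 + 1e-12

    @pytest.mark.parametrize("metric", [mssim, scd, qabf, piella, qy, fmi])
    def test_symmetry_under_source_swap(self, metric):
        a = random_image(16, (24, 24))
        b = random_image(17, (24, 24))
        f = 0.5 * (a + b)
        assert metric(a, b, f) == pytest.approx(metric(b, a, f), abs=1e-12)

    def test_csv_roundtrip_six_decimals(self, tmp_path):
        rng = np.random.default_rng(18)
        a, b, f = (rng.random((24, 24)) for _ in range(3))
        r = evaluate(a, b, f)
        back = MetricsReport.from_csv(r.to_csv(tmp_path / "m.csv"))
        for k in MetricsReport.FIELDS:
            assert getattr(back, k) == pytest.approx(getattr(r, k), abs=5e-7)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            evaluate(np.zeros((16, 16)), np.zeros((16, 16)), np.zeros((16, 17)))
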