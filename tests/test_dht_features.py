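import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert as analytic_signal

from ppidht.dht_features import (
    DHTDescriptor,
    dht_1d,
    dht_2d,
    feature_matrix,
    pair_descriptor,
    protein_descriptor,
    signum_multiplier,
    spatial_kernel_1d,
)
from ppidht.pssm_io import PSSM, ProteinRecord, pseudo_pssm
from ppidht.synthetic_data import SyntheticDatasetSpec, gen_proteins


def circular_convolve(x, p):
    """Direct O(N^2) circular convolution — the spatial-route oracle."""
    n = len(x)
    return np.array(
        [sum(x[m] * p[(k - m) % n] for m in range(n)) for k in range(n)]
    )


def random_pssm(rng, length=60):
    rec = ProteinRecord(
        f"r{length}", "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=length))
    )
    base = pseudo_pssm(rec)
    return PSSM(
        protein_id=base.protein_id,
        scores=base.scores + rng.normal(size=base.scores.shape),
        sequence=base.sequence,
    )


class TestSignumMultiplier:
    @pytest.mark.parametrize("n", [2, 3, 8, 15, 16])
    def test_antisymmetric_zero_dc_unit_magnitude(self, n):
        m = signum_multiplier(n)
        assert m[0] == 0
        if n % 2 == 0:
            assert m[n // 2] == 0
        for k in range(1, n):
            assert m[k] == -np.conj(m[(n - k) % n]) or m[k] == -m[n - k]
        assert set(np.round(np.abs(m), 12)) <= {0.0, 1.0}


class TestDHT1D:
    def test_cosine_maps_to_sine(self):
        n = np.arange(16)
        out = dht_1d(np.cos(2 * np.pi * n / 16))
        assert np.abs(out - np.sin(2 * np.pi * n / 16)).max() < 1e-12

    def test_constant_maps_to_zero(self):
        assert np.abs(dht_1d(np.full(16, 3.7))).max() == 0.0

    def test_double_application_negates_clean_signals(self, rng):
        # random signal with DC and Nyquist removed
        x = rng.normal(size=32)
        spec = np.fft.fft(x)
        spec[0] = 0
        spec[16] = 0
        x = np.real(np.fft.ifft(spec))
        assert np.abs(dht_1d(dht_1d(x)) + x).max() < 1e-10

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            dht_1d(np.array([1.0]))

    def test_matches_analytic_signal_imaginary_part(self, rng):
        x = rng.normal(size=64)
        assert np.abs(dht_1d(x) - np.imag(analytic_signal(x))).max() < 1e-10

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=24), r.normal(size=24)
        a, b = r.normal(), r.normal()
        lhs = dht_1d(a * x + b * y)
        rhs = a * dht_1d(x) + b * dht_1d(y)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_energy_preserved_without_dc_and_nyquist(self, rng):
        x = rng.normal(size=40)
        spec = np.fft.fft(x)
        spec[0] = 0
        spec[20] = 0
        x = np.real(np.fft.ifft(spec))
        assert abs(np.linalg.norm(dht_1d(x)) - np.linalg.norm(x)) < 1e-10


class TestSpatialKernel:
    def test_convolution_route_matches_frequency_route(self, rng):
        p = spatial_kernel_1d(16)
        for _ in range(5):
            x = rng.normal(size=16)
            assert np.abs(circular_convolve(x, p) - dht_1d(x)).max() < 1e-9

    def test_zero_mean(self):
        assert abs(spatial_kernel_1d(16).sum()) < 1e-12

    @pytest.mark.parametrize("n", [8, 15, 16])
    def test_antisymmetric(self, n):
        p = spatial_kernel_1d(n)
        for k in range(1, n):
            assert abs(p[k] + p[n - k]) < 1e-12


class TestDHT2D:
    def test_separable_cosine_pair(self):
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        out = dht_2d(np.cos(2 * np.pi * i / 8) * np.cos(2 * np.pi * j / 8)).transformed
        expected = np.sin(2 * np.pi * i / 8) * np.sin(2 * np.pi * j / 8)
        assert np.abs(out - expected).max() < 1e-12

    def test_zero_matrix(self):
        assert np.abs(dht_2d(np.zeros((4, 6))).transformed).max() == 0.0

    def test_total_equals_rows_then_cols(self, rng):
        a = rng.normal(size=(6, 10))
        via_modes = dht_2d(dht_2d(a, "rows").transformed, "cols").transformed
        assert np.abs(dht_2d(a, "total").transformed - via_modes).max() < 1e-10

    def test_rows_mode_is_per_row_1d_transform(self, rng):
        a = rng.normal(size=(5, 12))
        out = dht_2d(a, "rows").transformed
        for r in range(5):
            assert np.abs(out[r] - dht_1d(a[r])).max() < 1e-10

    def test_total_matches_2d_convolution_oracle(self, rng):
        p1, p2 = spatial_kernel_1d(8), spatial_kernel_1d(8)
        kernel = np.outer(p1, p2)
        for _ in range(5):
            a = rng.normal(size=(8, 8))
            direct = np.zeros((8, 8))
            for k in range(8):
                for l in range(8):
                    direct[k, l] = sum(
                        a[m, n] * kernel[(k - m) % 8, (l - n) % 8]
                        for m in range(8)
                        for n in range(8)
                    )
            assert np.abs(direct - dht_2d(a, "total").transformed).max() < 1e-9

    @pytest.mark.parametrize("shape", [(1, 5), (5, 1)])
    def test_degenerate_dimension_rejected(self, shape):
        with pytest.raises(ValueError):
            dht_2d(np.zeros(shape))


class TestDescriptors:
    def test_protein_descriptor_length(self, rng):
        assert protein_descriptor(random_pssm(rng)).shape == (200,)

    def test_zero_pssm_gives_zero_descriptor(self):
        p = PSSM(protein_id="z", scores=np.zeros((60, 20)))
        assert np.abs(protein_descriptor(p)).max() == 0.0

    def test_padding_equivalence(self, rng):
        p = random_pssm(rng, length=55)
        manually_padded = np.zeros((80, 20))
        manually_padded[:55] = p.scores
        q = PSSM(protein_id="q", scores=manually_padded)
        assert np.array_equal(
            protein_descriptor(p, pad_len=128), protein_descriptor(q, pad_len=128)
        )

    def test_long_sequences_truncated_at_pad_len(self, rng):
        p = random_pssm(rng, length=70)
        trunc = PSSM(protein_id="t", scores=p.scores[:64])
        assert np.array_equal(
            protein_descriptor(p, pad_len=64), protein_descriptor(trunc, pad_len=64)
        )

    def test_pair_descriptor_is_400_and_order_sensitive(self, rng):
        a, b = random_pssm(rng, 52), random_pssm(rng, 90)
        ab = pair_descriptor(a, b)
        ba = pair_descriptor(b, a)
        assert ab.features.shape == (400,)
        assert np.array_equal(ab.features[:200], ba.features[200:])
        assert np.array_equal(ab.features[200:], ba.features[:200])

    def test_dimension_is_400_regardless_of_lengths(self, rng):
        spec = SyntheticDatasetSpec(n_proteins=6, length_range=(50, 200))
        recs = gen_proteins(spec, rng=rng)
        pssms = [pseudo_pssm(r) for r in recs]
        for a, b in zip(pssms[::2], pssms[1::2]):
            assert pair_descriptor(a, b).features.shape == (400,)

    def test_feature_matrix_missing_id_names_it(self, rng):
        p = random_pssm(rng)
        with pytest.raises(KeyError, match="ghost"):
            feature_matrix({p.protein_id: p}, [(p.protein_id, "ghost")])

    def test_transformer_matches_function_route(self, rng):
        a, b = random_pssm(rng, 60), random_pssm(rng, 61)
        est = DHTDescriptor().fit([(a, b)])
        out = est.transform([(a, b)])
        assert np.array_equal(out[0], pair_descriptor(a, b).features)
        assert est.get_feature_names_out()[0] == "d0001"
        assert len(est.get_feature_names_out()) == 400
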