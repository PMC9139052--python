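"""Discrete Hilbert transform (DHT) featurization of PSSM profiles.

The discrete Hilbert transform is the linear filter whose frequency response
multiplies each Fourier component by -j*sgn(Omega): cosines map to sines, the
DC component vanishes, and (for even length) so does the Nyquist component —
the convention used when forming analytic signals.  Applied separably along
both axes of an L x 20 PSSM it yields a phase-shifted conservation profile
whose low-order frequency content summarizes the global evolutionary signal
of the protein.

Each protein is reduced to 200 features: the PSSM is zero-padded along the
sequence axis to a fixed length, transformed (2-D total-mode DHT), and the
magnitudes of the 10 lowest row-frequency bins x 20 amino-acid channel bins
of the result's 2-D spectrum are flattened.  A protein pair is the
concatenation of its two protein descriptors: 400 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .pssm_io import PSSM

__all__ = [
    "signum_multiplier",
    "spatial_kernel_1d",
    "dht_1d",
    "dht_2d",
    "protein_descriptor",
    "pair_descriptor",
    "feature_matrix",
    "PairDescriptor",
    "DHTDescriptor",
]


def signum_multiplier(n: int) -> np.ndarray:
    """Frequency-domain multiplier -j*sgn(Omega) for an n-point transform.

    sgn is +1 on positive-frequency bins, -1 on negative-frequency bins, and
    0 at DC and (for even n) the Nyquist bin.  The returned complex vector is
    indexed in :func:`numpy.fft.fft` bin order.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    sgn = np.zeros(n)
    half = n // 2
    if n % 2 == 0:
        sgn[1:half] = 1.0
        sgn[half + 1 :] = -1.0
    else:
        sgn[1 : half + 1] = 1.0
        sgn[half + 1 :] = -1.0
    return -1j * sgn


def spatial_kernel_1d(n: int) -> np.ndarray:
    """Periodic spatial-domain convolution kernel of the n-point DHT.

    The inverse transform of the signum multiplier: circular convolution of a
    signal with this kernel equals :func:`dht_1d` of the signal.  It is the
    discrete periodic analogue of the classical odd-sample kernel
    (1-(-1)^a)/(a*pi).  Zero-mean and anti-symmetric (p[k] = -p[n-k]).
    """
    return _real_part(np.fft.ifft(signum_multiplier(n)))


def _real_part(z: np.ndarray) -> np.ndarray:
    """Take the real part of an inverse-transform result, asserting the
    imaginary residue is numerically negligible rather than silently
    dropping it."""
    scale = max(1.0, float(np.max(np.abs(z))) if z.size else 1.0)
    resid = float(np.max(np.abs(z.imag))) if z.size else 0.0
    if resid > 1e-10 * scale:
        raise FloatingPointError(
            f"imaginary residue {resid:.3e} exceeds tolerance after inverse FFT"
        )
    return np.ascontiguousarray(z.real)


def dht_1d(signal: np.ndarray) -> np.ndarray:
    """1-D discrete Hilbert transform via the frequency route.

    DFT, multiply by -j*sgn(Omega), inverse DFT, real part.  Maps cos to sin;
    annihilates DC and Nyquist; applying it twice negates any signal free of
    those components.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("dht_1d expects a 1-D signal")
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal has non-finite entries")
    return _real_part(np.fft.ifft(np.fft.fft(x) * signum_multiplier(x.size)))


@dataclass
class DHTResult:
    """Transformed matrix, same shape as the input."""

    transformed: np.ndarray
    mode: str


def dht_2d(matrix: np.ndarray, mode: str = "total") -> DHTResult:
    """2-D discrete Hilbert transform of an H1 x H2 matrix.

    mode="rows" transforms along each row, "cols" along each column, and
    "total" (the featurization default) applies both — equivalently a single
    2-D frequency multiplication by the outer product of the two 1-D signum
    multipliers.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("dht_2d expects a 2-D matrix")
    h1, h2 = a.shape
    if h1 < 2 or h2 < 2:
        raise ValueError(f"both dimensions must be >= 2, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix has non-finite entries")

    spec = np.fft.fft2(a)
    if mode == "rows":
        spec = spec * signum_multiplier(h2)[None, :]
    elif mode == "cols":
        spec = spec * signum_multiplier(h1)[:, None]
    elif mode == "total":
        spec = spec * signum_multiplier(h1)[:, None] * signum_multiplier(h2)[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DHTResult(transformed=_real_part(np.fft.ifft2(spec)), mode=mode)


def protein_descriptor(
    pssm: PSSM, pad_len: int = 512, block_rows: int = 10, mode: str = "total"
) -> np.ndarray:
    """Reduce one PSSM to a fixed-length descriptor (block_rows * 20 values).

    The L x 20 profile is zero-padded along the sequence axis to
    ``pad_len`` rows (sequences longer than ``pad_len`` are truncated), the
    2-D DHT is applied, and the magnitude spectrum of the transformed matrix
    is computed.  The ``block_rows`` lowest row-frequency bins across all 20
    channel-frequency bins, flattened row-major, form the descriptor: the
    low-order coefficients summarize the global conservation profile
    independently of where along the sequence it sits.
    """
    if pssm.length < 2:
        raise ValueError(f"PSSM {pssm.protein_id!r} has fewer than 2 rows")
    if pad_len < 2:
        raise ValueError("pad_len must be >= 2")
    if block_rows < 1 or block_rows > pad_len:
        raise ValueError("block_rows must be in [1, pad_len]")
    padded = np.zeros((pad_len, 20))
    use = min(pssm.length, pad_len)
    padded[:use] = pssm.scores[:use]
    transformed = dht_2d(padded, mode=mode).transformed
    magnitude = np.abs(np.fft.fft2(transformed))
    return magnitude[:block_rows, :].ravel()


@dataclass
class PairDescriptor:
    """400-dimensional feature vector for one protein pair (A first)."""

    features: np.ndarray
    pair_ids: Tuple[str, str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (400,):
            raise ValueError(
                f"pair descriptor must have 400 entries, got {self.features.shape}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("pair descriptor has non-finite entries")


def pair_descriptor(
    pssm_a: PSSM,
    pssm_b: PSSM,
    pad_len: int = 512,
    block_rows: int = 10,
    mode: str = "total",
) -> PairDescriptor:
    """Concatenate the two protein descriptors into the 400-dim pair vector."""
    feats = np.concatenate(
        [
            protein_descriptor(pssm_a, pad_len, block_rows, mode),
            protein_descriptor(pssm_b, pad_len, block_rows, mode),
        ]
    )
    return PairDescriptor(features=feats, pair_ids=(pssm_a.protein_id, pssm_b.protein_id))


def feature_matrix(
    pssms: Mapping[str, PSSM],
    pairs: Iterable[Tuple[str, str]],
    pad_len: int = 512,
    block_rows: int = 10,
    mode: str = "total",
) -> np.ndarray:
    """Stack pair descriptors for a pair list into an (n_pairs, 400) matrix.

    Protein descriptors are computed once per distinct id and reused.  A pair
    id without a PSSM raises ``KeyError`` naming the id.
    """
    pairs = list(pairs)
    cache: dict[str, np.ndarray] = {}

    def desc(pid: str) -> np.ndarray:
        if pid not in cache:
            if pid not in pssms:
                raise KeyError(f"no PSSM for protein id {pid!r}")
            cache[pid] = protein_descriptor(pssms[pid], pad_len, block_rows, mode)
        return cache[pid]

    return np.array([np.concatenate([desc(a), desc(b)]) for a, b in pairs])


class DHTDescriptor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: pairs of PSSMs -> 400-dim descriptors.

    ``transform`` accepts a sequence of ``(PSSM, PSSM)`` tuples and returns
    an (n_pairs, 2 * block_rows * 20) array.  Stateless (``fit`` only
    validates parameters), so it composes with sklearn pipelines and model
    selection.
    """

    def __init__(self, pad_len: int = 512, block_rows: int = 10, mode: str = "total"):
        self.pad_len = pad_len
        self.block_rows = block_rows
        self.mode = mode

    def fit(self, X: Sequence[Tuple[PSSM, PSSM]], y=None) -> "DHTDescriptor":
        if self.mode not in ("rows", "cols", "total"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_features_out_ = 2 * self.block_rows * 20
        return self

    def transform(self, X: Sequence[Tuple[PSSM, PSSM]]) -> np.ndarray:
        return np.array(
            [
                np.concatenate(
                    [
                        protein_descriptor(a, self.pad_len, self.block_rows, self.mode),
                        protein_descriptor(b, self.pad_len, self.block_rows, self.mode),
                    ]
                )
                for a, b in X
            ]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        n = 2 * self.block_rows * 20
        return np.array([f"d{i + 1:04d}" for i in range(n)])
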