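"""Power-spectral-density featurization of DNA-shape profiles.

The classifier does not see shape values directly: each of the four shape
series of a 147-bp sequence is turned into a smoothed periodogram, and the
one-sided spectra are concatenated into a 288-dimensional feature vector.
Working in the frequency domain makes the representation tolerant to where
exactly a periodic dinucleotide pattern sits within the window — the property
that motivates the transform.

Pipeline per channel: extract the defined shape values, standardize the
series to an even length of 144 (see :func:`featurize`), subtract the mean,
apply a split-cosine-bell taper, compute the periodogram ``|DFT|^2 / n``, and
smooth it with a modified Daniell kernel (half-weight endpoints, reflection
at the spectrum boundaries).  Bins 1..72 are retained per channel (bin 0 is
annihilated by demeaning; bin 72 is the Nyquist bin), for 4 x 72 = 288
features named ``MGW_1 .. Roll_72``; frequency index k corresponds to about
k cycles per 147 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .shape import FEATURES, ShapeProfile

#: Series length every channel is standardized to before the transform.
STANDARD_LENGTH = 144

#: Number of retained one-sided frequency bins per channel.
N_BINS = STANDARD_LENGTH // 2

#: The 288 feature names, channel-major then frequency-ascending.
FEATURE_NAMES = [f"{feat}_{k}" for feat in FEATURES for k in range(1, N_BINS + 1)]

DEFAULT_SPAN = 10
DEFAULT_TAPER = 0.1


def cosine_taper(series: np.ndarray, p: float) -> np.ndarray:
    """Split-cosine-bell taper: ramp the first and last ``floor(p*n)`` points.

    The ramp is the half-cosine ``(1 - cos(pi*(k - 1/2)/m)) / 2`` rising from
    near 0 to near 1 over the m tapered points at each end; the middle of the
    series is untouched.  ``p`` is the tapered fraction per end, at most 0.5.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"taper fraction must be in [0, 0.5], got {p}")
    x = np.asarray(series, dtype=float)
    n = x.size
    m = int(p * n)
    if m == 0:
        return x.copy()
    ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, m + 1) - 0.5) / m))
    out = x.copy()
    out[:m] *= ramp
    out[n - m:] *= ramp[::-1]
    return out


def modified_daniell_kernel(span: int) -> np.ndarray:
    """Modified Daniell smoothing weights of total span ``span``.

    ``span`` must be even (half-width m = span/2) or 1 (no smoothing).  The
    2m+1 weights are uniform ``1/(2m)`` with the two endpoints halved, so they
    sum to one.
    """
    if span == 1:
        return np.array([1.0])
    if span < 1 or span % 2:
        raise ValueError(f"span must be 1 or an even integer, got {span}")
    m = span // 2
    w = np.full(2 * m + 1, 1.0 / (2 * m))
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


@dataclass
class PowerSpectrum:
    """One-sided smoothed periodogram: bins 1..n_used/2 of an even-length series."""

    n_used: int
    freq_index: np.ndarray
    power: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        """Frequency in cycles per position."""
        return self.freq_index / self.n_used


def _raw_power_matrix(rows: np.ndarray, taper_p: float) -> np.ndarray:
    """Row-wise demean, taper, and one-sided raw periodogram |DFT|^2/n."""
    x = rows - rows.mean(axis=1, keepdims=True)
    n = x.shape[1]
    m = int(taper_p * n)
    if m:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, m + 1) - 0.5) / m))
        weights = np.ones(n)
        weights[:m] = ramp
        weights[n - m:] = ramp[::-1]
        x = x * weights
    spec = np.fft.rfft(x, axis=1)
    return (spec.real**2 + spec.imag**2) / n


def _smooth_rows(power: np.ndarray, span: int) -> np.ndarray:
    """Smooth each row with the modified Daniell kernel, reflecting at the ends."""
    kernel = modified_daniell_kernel(span)
    if kernel.size == 1:
        return power
    # ndimage 'mirror' reflects about the edge sample without repeating it
    return convolve1d(power, kernel, axis=-1, mode="mirror")


def smoothed_periodogram(series, span: int = DEFAULT_SPAN,
                         taper_p: float = DEFAULT_TAPER) -> PowerSpectrum:
    """Smoothed periodogram of an even-length series.

    Demeans, applies :func:`cosine_taper`, computes the discrete-Fourier
    periodogram normalized as ``|DFT|^2 / n``, and smooths bins ``1..n/2``
    with a modified Daniell kernel of the given total span, reflecting the
    spectrum at its boundaries.  The zero-frequency bin is dropped (it is
    identically ~0 after demeaning); the Nyquist bin is kept.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"series too short for spectral estimation: {n} < 8")
    if n % 2:
        raise ValueError(f"series length must be even, got {n}")
    if span != 1 and n // 2 < modified_daniell_kernel(span).size:
        raise ValueError(f"series of length {n} shorter than kernel support")
    if not 0.0 <= taper_p <= 0.5:
        raise ValueError(f"taper fraction must be in [0, 0.5], got {taper_p}")
    raw = _raw_power_matrix(x[None, :], taper_p)[0]
    one_sided = raw[1:]  # bins 1..n/2
    power = _smooth_rows(one_sided[None, :], span)[0]
    return PowerSpectrum(
        n_used=n, freq_index=np.arange(1, n // 2 + 1), power=power
    )


def standardize_channel(values: np.ndarray) -> np.ndarray:
    """Bring a channel's defined values to the uniform even length of 144.

    MGW/ProT contribute 143 defined values for a 147-bp sequence: the central
    value is replicated once.  HelT/Roll contribute 145: the central value is
    dropped.  A uniform even per-channel length is what yields exactly 576
    two-sided DFT coefficients and 288 retained one-sided features; adjusting
    at the series *center* (rather than at an end) keeps standardization
    symmetric under positional reversal, so the PSD of a sequence and of its
    reverse complement agree exactly for a reverse-complement-symmetric
    shape table.
    """
    v = np.asarray(values, dtype=float)
    if v.size == STANDARD_LENGTH:
        return v.copy()
    if v.size == STANDARD_LENGTH - 1:
        mid = v.size // 2  # 71 for 143
        return np.insert(v, mid + 1, v[mid])
    if v.size == STANDARD_LENGTH + 1:
        return np.delete(v, v.size // 2)  # drop index 72 of 145
    raise ValueError(
        f"cannot standardize a channel of {v.size} values to {STANDARD_LENGTH}"
    )


def featurize(profile: ShapeProfile, span: int = DEFAULT_SPAN,
              taper_p: float = DEFAULT_TAPER) -> pd.Series:
    """288-dimensional PSD feature vector of a 147-bp shape profile.

    Returns a Series indexed by :data:`FEATURE_NAMES`; deterministic in its
    inputs.  ``HelT_5``, for instance, is the smoothed power of the HelT
    series at ~5 cycles per 147 bp.
    """
    if profile.seq_length != 147:
        raise ValueError(
            f"featurize expects a 147-bp profile, got {profile.seq_length}"
        )
    blocks = []
    for feat in FEATURES:
        series = standardize_channel(profile.defined(feat))
        spec = smoothed_periodogram(series, span=span, taper_p=taper_p)
        blocks.append(spec.power[:N_BINS])
    return pd.Series(np.concatenate(blocks), index=FEATURE_NAMES)


def featurize_sequences(sequences, table, span: int = DEFAULT_SPAN,
                        taper_p: float = DEFAULT_TAPER,
                        ids=None) -> pd.DataFrame:
    """Featurize many sequences into an (n, 288) feature matrix."""
    from .shape import compute_shape

    rows = [featurize(compute_shape(s, table), span=span, taper_p=taper_p).to_numpy()
            for s in sequences]
    index = ids if ids is not None else range(len(rows))
    return pd.DataFrame(np.asarray(rows), columns=FEATURE_NAMES, index=index)


def write_feature_matrix(path, features: pd.DataFrame, labels=None) -> None:
    """Write a feature matrix as TSV, with a ``label`` column for training files."""
    out = features.copy()
    if labels is not None:
        out["label"] = np.asarray(labels, dtype=int)
    out.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    df = pd.read_csv(path, sep="\t", index_col="id")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns, e.g. {missing[0]}")
    return df[FEATURE_NAMES], labels
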