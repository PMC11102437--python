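"""Projection-kernel features built from dynamic modes.

Two trials can be compared through the subspaces their (L2-normalized)
mode matrices span, using the Grassmann *projection kernel*

    k_p(Phi_i, Phi_j) = || Phi_i^dagger Phi_j ||_F^2 ,

which admits the explicit feature map ``psi(Phi) = vec(Phi Phi^dagger)``
so that ``k_p = <psi_i, psi_j>``.  Because real signals yield
conjugate-closed mode sets, the P x P matrix ``Phi Phi^dagger`` — the
*spatial dynamic-mode (sDM) feature* — is real and symmetric: its diagonal
gives the per-channel *snDM* features and its strict upper triangle the
channel-pair *seDM* features.  Modes can additionally be grouped by
|frequency| into conventional bands to form frequency-filtered variants.

PSD/band-power features (Hamming-windowed 512-point periodogram) are
provided as the conventional baseline the sDM features are compared with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .data import TrialSignal
from .dmd import DMDResults
from .exceptions import ConjugateClosureError, InvalidInputError

__all__ = [
    "SDMFeature",
    "BandSpec",
    "DEFAULT_BANDS",
    "GramMatrix",
    "PowerFeature",
    "projection_kernel",
    "sdm_features",
    "feature_map",
    "band_filtered_sdm",
    "gram_matrix",
    "psd",
    "band_power",
]

#: Conventional electrophysiology bands (Hz), up to the 1-kHz Nyquist.
DEFAULT_BANDS = ((0.0, 1.0), (1.0, 4.0), (4.0, 8.0), (8.0, 13.0),
                 (13.0, 30.0), (30.0, 80.0), (80.0, 150.0), (150.0, 500.0))


@dataclass(frozen=True)
class SDMFeature:
    """Real symmetric P x P sDM feature matrix ``Phi Phi^dagger``.

    ``sndm`` is the diagonal (one value per channel); ``sedm`` the strict
    upper triangle in row-major channel order.
    """

    matrix: np.ndarray
    n_modes: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("sDM matrix must be square")
        scale = np.max(np.abs(m), initial=0.0)
        if np.max(np.abs(m - m.T), initial=0.0) > 1e-10 * max(scale, 1.0):
            raise InvalidInputError("sDM matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def sndm(self) -> np.ndarray:
        """Per-channel (node) features: the diagonal."""
        return np.diag(self.matrix).copy()

    @property
    def sedm(self) -> np.ndarray:
        """Channel-pair (edge) features: strict upper triangle, row-major."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.matrix[iu].copy()

    @property
    def vector(self) -> np.ndarray:
        """Column-major vectorization psi(Phi) = vec(Phi Phi^dagger)."""
        return self.matrix.flatten(order="F")


@dataclass(frozen=True)
class BandSpec:
    """Ordered, non-overlapping frequency intervals in Hz.

    Intervals are half-open [low, high); the final band additionally
    includes its upper edge, so a partition reaching Nyquist covers every
    admissible |frequency|.
    """

    edges: tuple = DEFAULT_BANDS

    def __post_init__(self):
        edges = tuple((float(lo), float(hi)) for lo, hi in self.edges)
        if len(edges) == 0:
            raise InvalidInputError("need at least one band")
        for lo, hi in edges:
            if not (0.0 <= lo < hi):
                raise InvalidInputError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi:
                raise InvalidInputError("bands must be ascending and non-overlapping")
        object.__setattr__(self, "edges", edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def labels(self) -> tuple:
        return tuple(f"{lo:g}-{hi:g}Hz" for lo, hi in self.edges)

    def assign(self, frequencies: np.ndarray) -> np.ndarray:
        """Band index for each |frequency|; -1 where no band contains it."""
        f = np.abs(np.asarray(frequencies, dtype=float))
        out = np.full(f.shape, -1, dtype=int)
        for i, (lo, hi) in enumerate(self.edges):
            inside = (f >= lo) & (f < hi)
            if i == len(self.edges) - 1:
                inside |= f == hi  # last band is closed at the top
            out[inside] = i
        return out


@dataclass(frozen=True)
class GramMatrix:
    """N x N projection-kernel similarity matrix over trials."""

    values: np.ndarray
    trial_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("Gram matrix must be square")
        object.__setattr__(self, "values", v)
        if self.trial_ids is not None:
            object.__setattr__(self, "trial_ids", tuple(self.trial_ids))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PowerFeature:
    """One-sided PSD per channel on a regular frequency grid."""

    psd: np.ndarray          # (P, F)
    frequencies: np.ndarray  # (F,) Hz


def _as_modes(x) -> np.ndarray:
    m = np.asarray(x, dtype=complex)
    if m.ndim != 2:
        raise InvalidInputError("mode matrix must be 2-D (P, K)")
    return m


def projection_kernel(modes_i, modes_j) -> float:
    """Grassmann projection kernel ``||Phi_i^dagger Phi_j||_F^2``.

    Symmetric and nonnegative; equals K when both arguments are the same
    orthonormal K-column matrix.
    """
    A, B = _as_modes(modes_i), _as_modes(modes_j)
    if A.shape[0] != B.shape[0]:
        raise InvalidInputError(
            f"channel mismatch: {A.shape[0]} vs {B.shape[0]}"
        )
    M = A.conj().T @ B
    return float(np.real(np.vdot(M, M)))


def sdm_features(modes, imag_tol: float = 1e-8) -> SDMFeature:
    """sDM feature matrix ``Re(Phi Phi^dagger)`` from unit-norm modes.

    The mode set must be conjugate-closed (as DMD of a real signal always
    produces); an imaginary residue above ``imag_tol`` (relative to the
    largest real entry) signals a broken mode set and raises.
    """
    Phi = _as_modes(modes)
    M = Phi @ Phi.conj().T
    re_scale = np.max(np.abs(M.real), initial=0.0)
    if np.max(np.abs(M.imag), initial=0.0) > imag_tol * max(re_scale, 1e-300):
        raise ConjugateClosureError(
            "Phi Phi^dagger has a non-negligible imaginary part; "
            "the mode set is not closed under conjugation"
        )
    M = 0.5 * (M.real + M.real.T)  # kill asymmetric rounding residue
    return SDMFeature(matrix=M, n_modes=Phi.shape[1])


def feature_map(modes, imag_tol: float = 1e-8) -> np.ndarray:
    """Explicit feature map ``psi(Phi) = vec(Phi Phi^dagger)`` (column-major).

    Inner products of outputs reproduce :func:`projection_kernel`.
    """
    return sdm_features(modes, imag_tol=imag_tol).vector


def band_filtered_sdm(result: DMDResults, bands: BandSpec | None = None,
                      imag_tol: float = 1e-8) -> list:
    """One sDM feature per frequency band, from the modes whose |f| falls in it.

    ``result`` should carry L2-normalized modes.  A band containing no
    modes yields an all-zero matrix; modes outside every band are excluded
    with a warning.  Over a partition covering [0, Nyquist] the band
    matrices sum exactly to the unfiltered sDM matrix.
    """
    if bands is None:
        bands = BandSpec()
    elif not isinstance(bands, BandSpec):
        bands = BandSpec(tuple(bands))
    idx = bands.assign(result.frequencies)
    if np.any(idx < 0):
        warnings.warn(
            f"{np.count_nonzero(idx < 0)} mode(s) fall outside every band "
            "and are excluded",
            RuntimeWarning,
        )
    P = result.modes.shape[0]
    out = []
    for i in range(len(bands)):
        cols = idx == i
        if not np.any(cols):
            out.append(SDMFeature(matrix=np.zeros((P, P)), n_modes=0))
        else:
            out.append(sdm_features(result.modes[:, cols], imag_tol=imag_tol))
    return out


def gram_matrix(trial_modes, trial_ids=None) -> GramMatrix:
    """Pairwise projection-kernel matrix over a list of mode matrices."""
    mats = [_as_modes(m) for m in trial_modes]
    if len(mats) == 0:
        raise InvalidInputError("need at least one trial")
    P = mats[0].shape[0]
    for m in mats:
        if m.shape[0] != P:
            raise InvalidInputError("all trials must share the channel count")
    n = len(mats)
    G = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            G[i, j] = G[j, i] = projection_kernel(mats[i], mats[j])
    return GramMatrix(values=G, trial_ids=trial_ids)


def psd(signal: TrialSignal, nfft: int = 512) -> PowerFeature:
    """Single-window Hamming periodogram, zero-padded to ``nfft`` points.

    Each channel is multiplied by a Hamming window of the trial length and
    transformed with an ``nfft``-point FFT, giving the one-sided density on
    an ``nfft // 2 + 1``-point grid spanning [0, Nyquist].  Trials longer
    than ``nfft`` are rejected (no Welch averaging in this mode).
    """
    if signal.n_samples > nfft:
        raise InvalidInputError(
            f"trial length {signal.n_samples} exceeds the {nfft}-point FFT; "
            "crop the trial or raise nfft"
        )
    freqs, pxx = scipy.signal.periodogram(
        signal.values, fs=signal.fs, window="hamming", nfft=nfft,
        detrend=False, axis=-1,
    )
    return PowerFeature(psd=pxx, frequencies=freqs)


def band_power(power: PowerFeature, band) -> np.ndarray:
    """Mean PSD within [low, high) Hz, per channel."""
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo < hi):
        raise InvalidInputError(f"invalid band ({lo}, {hi})")
    sel = (power.frequencies >= lo) & (power.frequencies < hi)
    if not np.any(sel):
        raise InvalidInputError(f"no PSD bins inside ({lo}, {hi}) Hz")
    return power.psd[..., sel].mean(axis=-1)
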