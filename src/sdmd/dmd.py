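"""Exact dynamic mode decomposition (DMD) with Hankel signal stacking.

DMD fits the best linear one-step propagator ``x(t + dt) = A x(t)`` to a
multichannel time series and diagonalises it, decomposing the signal into
K oscillatory components::

    x(t) ~ sum_k  phi_k  r_k**t  exp(2 pi i f_k t)  b_k

where each *dynamic mode* ``phi_k`` is a complex spatial pattern, ``f_k``
its frequency in Hz, ``r_k`` its per-second amplitude multiplier
(decay for r < 1, growth for r > 1) and ``b_k`` the complex initial
amplitude.  For neural recordings the channel count P is typically much
smaller than the sample count L, so the data matrix is first augmented by
Hankel stacking: h time-shifted copies of the signal are stacked so the
snapshot matrices become tall, with h the smallest integer satisfying
``h >= (L + 1) / (P + 1)``.

The module follows a model/results split: :class:`DMD` holds the data and
cached intermediate factorizations, :meth:`DMD.fit` returns a
:class:`DMDResults` with the spectral estimates, reconstruction, mode
normalization and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .data import TrialSignal
from .exceptions import InvalidInputError, NumericalRankError

__all__ = ["compute_h", "stack_signals", "truncated_svd", "StackedPair", "DMD", "DMDResults", "exact_dmd"]


def compute_h(n_channels: int, n_samples: int) -> int:
    """Smallest stacking factor h with ``h >= (L + 1) / (P + 1)``.

    Guarantees the stacked snapshot matrix (shape hP x (L - h)) is at
    least as tall as it is wide, the regime exact DMD was designed for.
    Always at least 1.
    """
    P, L = int(n_channels), int(n_samples)
    if P < 1:
        raise InvalidInputError(f"need P >= 1 channels; got {P}")
    if L < 3:
        raise InvalidInputError(f"need L >= 3 samples; got {L}")
    return max(1, -((L + 1) // -(P + 1)))  # ceil division


@dataclass(frozen=True)
class StackedPair:
    """Hankel-stacked snapshot matrices X and X' (one step ahead)."""

    X: np.ndarray        # (h P, L - h)
    X_prime: np.ndarray  # (h P, L - h)
    h: int


def stack_signals(signal: TrialSignal, h: int) -> StackedPair:
    """Augment a (P, L) signal into Hankel-stacked snapshot matrices.

    Row-block j (j = 0..h-1) of column c holds sample ``x_{c+j}``; X' is X
    advanced one sample.  With h = 1 this collapses to the plain snapshot
    pair ``X = [x_1 ... x_{L-1}]``, ``X' = [x_2 ... x_L]``.
    """
    h = int(h)
    L = signal.n_samples
    if h < 1:
        raise InvalidInputError(f"stacking factor must be >= 1; got {h}")
    if h >= L:
        raise InvalidInputError(f"stacking factor h={h} must be < L={L}")
    v = signal.values
    ncol = L - h
    X = np.vstack([v[:, j:j + ncol] for j in range(h)])
    Xp = np.vstack([v[:, j + 1:j + 1 + ncol] for j in range(h)])
    return StackedPair(X=X, X_prime=Xp, h=h)


def _sv_floor(shape, s) -> float:
    """Relative singular-value floor: max(m, n) * eps * s_max."""
    if len(s) == 0:
        return 0.0
    return max(shape) * np.finfo(float).eps * s[0]


def truncated_svd(X: np.ndarray, rank: int | None = None, floor: float | None = None):
    """Rank-truncated thin SVD ``X ~ U diag(s) V*``.

    Components beyond ``rank`` are discarded, as are components whose
    singular value falls below ``floor`` (default
    ``max(m, n) * eps * s_max``) — the latter prevents blow-up when
    inverting S on numerically rank-deficient data.

    Returns
    -------
    U : ndarray (m, K_eff)
    s : ndarray (K_eff,), descending
    V : ndarray (n, K_eff)
        Right singular vectors as columns.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("matrix must be finite")
    m, n = X.shape
    if rank is not None:
        rank = int(rank)
        if rank < 1 or rank > min(m, n):
            raise InvalidInputError(
                f"rank must be in [1, {min(m, n)}]; got {rank}"
            )
    U, s, Vh = scipy.linalg.svd(X, full_matrices=False)
    if floor is None:
        floor = _sv_floor(X.shape, s)
    keep = int(np.count_nonzero(s > floor))
    if rank is not None:
        keep = min(keep, rank)
    if keep == 0:
        raise NumericalRankError("all singular values are below the numerical floor")
    return U[:, :keep], s[:keep], Vh[:keep].T


@dataclass(frozen=True)
class DMDResults:
    """Spectral estimates from an exact DMD fit.

    Attributes
    ----------
    modes : complex ndarray (P, K)
        Dynamic modes, truncated to the first P stacked coordinates
        (the first block of the Hankel-stacked state).
    stacked_modes : complex ndarray (hP, K)
        Full modes on the stacked state space; used for amplitudes and
        reconstruction.
    eigenvalues : complex ndarray (K,)
        Discrete-time eigenvalues lambda_k of the propagator.
    frequencies : ndarray (K,)
        f_k = arg(lambda_k) / (2 pi dt), in Hz, within (-Nyquist, Nyquist].
    rates : ndarray (K,)
        r_k = |lambda_k| ** (1 / dt), per-second amplitude multipliers.
    continuous_rates : complex ndarray (K,)
        omega_k = ln(lambda_k) / dt (principal branch), in 1/s.
    amplitudes : complex ndarray (K,)
        b = pinv(stacked_modes) @ x_stacked(0).
    singular_values : ndarray
        Full singular spectrum of the stacked X (descending), kept as a
        diagnostic; ``n_nonzero_singular_values`` counts those above the
        numerical floor.
    mode_scales : ndarray (K,) or None
        L2 norms removed from ``modes`` by :meth:`normalize_modes`.
    """

    modes: np.ndarray
    stacked_modes: np.ndarray
    eigenvalues: np.ndarray
    frequencies: np.ndarray
    rates: np.ndarray
    continuous_rates: np.ndarray
    amplitudes: np.ndarray
    singular_values: np.ndarray
    rank: int
    h: int
    dt: float
    mode_scales: np.ndarray = None

    @property
    def n_modes(self) -> int:
        return self.rank

    @property
    def n_nonzero_singular_values(self) -> int:
        s = self.singular_values
        return int(np.count_nonzero(s > _sv_floor((len(s), len(s)), s)))

    @property
    def n_svd_components(self) -> int:
        """Number of SVD components offered by the stacked data (L - h)."""
        return len(self.singular_values)

    @property
    def is_normalized(self) -> bool:
        return self.mode_scales is not None

    def normalize_modes(self) -> "DMDResults":
        """L2-normalize each (P-row) mode column; idempotent.

        The removed scale factors are recorded in ``mode_scales`` and the
        stacked modes are left untouched, so reconstruction is unaffected.
        Zero-norm modes are dropped with a warning.
        """
        norms = np.linalg.norm(self.modes, axis=0)
        keep = norms > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {np.count_nonzero(~keep)} zero-norm mode(s)",
                RuntimeWarning,
            )
        prior = self.mode_scales if self.mode_scales is not None else np.ones(self.rank)
        return replace(
            self,
            modes=self.modes[:, keep] / norms[keep],
            stacked_modes=self.stacked_modes[:, keep],
            eigenvalues=self.eigenvalues[keep],
            frequencies=self.frequencies[keep],
            rates=self.rates[keep],
            continuous_rates=self.continuous_rates[keep],
            amplitudes=self.amplitudes[keep],
            rank=int(np.count_nonzero(keep)),
            mode_scales=(prior * norms)[keep],
        )

    def reconstruct(self, times: np.ndarray = None, initial_state: np.ndarray = None) -> np.ndarray:
        """Superpose the K components, ``sum_k phi~_k exp(omega_k t) b_k``.

        Evaluated on the stacked modes and reduced to the first P
        coordinates; the imaginary residue (tiny for conjugate-closed mode
        sets) is asserted negligible and discarded.

        Parameters
        ----------
        times : array of seconds, default the fitted sample grid.
        initial_state : optional stacked state (hP,) from which to re-derive
            the amplitudes by least squares.
        """
        if times is None:
            n = self.n_svd_components
            times = np.arange(n) * self.dt
        times = np.atleast_1d(np.asarray(times, dtype=float))
        b = self.amplitudes
        if initial_state is not None:
            initial_state = np.asarray(initial_state, dtype=float)
            if initial_state.shape != (self.stacked_modes.shape[0],):
                raise InvalidInputError(
                    f"initial_state must have shape ({self.stacked_modes.shape[0]},)"
                )
            b = np.linalg.lstsq(self.stacked_modes, initial_state, rcond=None)[0]
        # guard against exp overflow for strongly growing modes
        max_exp = np.max(np.abs(np.real(self.continuous_rates))[:, None] * np.abs(times)[None, :], initial=0.0)
        if max_exp > 700.0:
            raise OverflowError(
                "reconstruction horizon overflows exp(); shorten the time grid"
            )
        dyn = np.exp(np.outer(self.continuous_rates, times)) * b[:, None]
        P = self.modes.shape[0]
        rec = self.stacked_modes[:P] @ dyn
        scale = np.max(np.abs(rec.real), initial=1e-300)
        if np.max(np.abs(rec.imag), initial=0.0) > 1e-6 * max(scale, 1e-12):
            warnings.warn("reconstruction has a non-negligible imaginary part", RuntimeWarning)
        return rec.real

    def summary(self) -> str:
        """Human-readable per-mode table."""
        df = self.to_frame()
        lines = [
            "Exact DMD results",
            f"  stacking factor h = {self.h}, rank K = {self.rank}, dt = {self.dt:g} s",
            f"  singular values above floor: {self.n_nonzero_singular_values}"
            f" of {self.n_svd_components}",
            "",
            df.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-mode parameter table (frequency, rate, |amplitude|)."""
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "rate_per_s": self.rates,
                "abs_amplitude": np.abs(self.amplitudes),
                "abs_eigenvalue": np.abs(self.eigenvalues),
            },
            index=pd.RangeIndex(self.rank, name="mode"),
        )

    def to_hdf5(self, group) -> None:
        """Dump into an open h5py group (complex arrays split real/imag)."""
        for name, arr in [
            ("modes", self.modes),
            ("stacked_modes", self.stacked_modes),
            ("eigenvalues", self.eigenvalues),
            ("amplitudes", self.amplitudes),
        ]:
            group.create_dataset(f"{name}_real", data=np.real(arr))
            group.create_dataset(f"{name}_imag", data=np.imag(arr))
        group.create_dataset("singular_values", data=self.singular_values)
        group.create_dataset("frequencies", data=self.frequencies)
        group.create_dataset("rates", data=self.rates)
        group.attrs["h"] = self.h
        group.attrs["rank"] = self.rank
        group.attrs["dt"] = self.dt


class DMD:
    """Exact DMD model for one trial.

    Parameters
    ----------
    signal : TrialSignal
    h : int, optional
        Stacking factor; defaults to :func:`compute_h`.

    The Hankel stacking and the (expensive) SVD of the stacked snapshot
    matrix are computed once and cached, so refitting at several ranks —
    as the decoding harness does when tuning rank by cross-validation —
    costs only the small eigendecompositions.
    """

    def __init__(self, signal: TrialSignal, h: int | None = None):
        if not isinstance(signal, TrialSignal):
            signal = TrialSignal(np.atleast_2d(np.asarray(signal, dtype=float)), dt=1.0)
        self.signal = signal
        self.h = int(h) if h is not None else compute_h(signal.n_channels, signal.n_samples)
        if self.h >= signal.n_samples:
            raise InvalidInputError("stacking factor must leave at least one snapshot pair")
        self._stacked: StackedPair | None = None
        self._svd = None  # (U, s, V) untruncated thin SVD of stacked X

    @property
    def max_rank(self) -> int:
        return min(self.h * self.signal.n_channels, self.signal.n_samples - self.h)

    @property
    def stacked(self) -> StackedPair:
        if self._stacked is None:
            self._stacked = stack_signals(self.signal, self.h)
        return self._stacked

    def _full_svd(self):
        if self._svd is None:
            X = self.stacked.X
            U, s, Vh = scipy.linalg.svd(X, full_matrices=False)
            self._svd = (U, s, Vh.T)
        return self._svd

    def fit(self, rank: int | None = None) -> DMDResults:
        """Estimate the propagator's spectral decomposition.

        Ranks are truncated both at ``rank`` and at the numerical
        singular-value floor; the effective rank is reported on the
        results.  Modes are ordered canonically: ascending |f|, ties by
        sign of f, then descending |b|.
        """
        pair = self.stacked
        X, Xp = pair.X, pair.X_prime
        U, s, V = self._full_svd()
        floor = _sv_floor(X.shape, s)
        keep = int(np.count_nonzero(s > floor))
        if keep == 0:
            raise NumericalRankError("signal is numerically zero: no usable singular values")
        if rank is not None:
            rank = int(rank)
            if rank < 1 or rank > self.max_rank:
                raise InvalidInputError(
                    f"rank must be in [1, {self.max_rank}]; got {rank}"
                )
            keep = min(keep, rank)
        Uk, sk, Vk = U[:, :keep], s[:keep], V[:, :keep]

        # reduced propagator and its eigendecomposition
        XpV_Sinv = (Xp @ Vk) / sk[None, :]
        A_tilde = Uk.conj().T @ XpV_Sinv
        lam, W = scipy.linalg.eig(A_tilde)

        stacked_modes = XpV_Sinv @ W  # exact-DMD modes on the stacked space
        alive = np.abs(lam) > 1e-12 * max(np.max(np.abs(lam)), 1.0)
        if not np.all(alive):
            warnings.warn(
                f"dropping {np.count_nonzero(~alive)} mode(s) with lambda ~ 0",
                RuntimeWarning,
            )
            lam, stacked_modes = lam[alive], stacked_modes[:, alive]
        if lam.size == 0:
            raise NumericalRankError("no modes with nonzero eigenvalue")

        dt = self.signal.dt
        freqs = np.angle(lam) / (2.0 * np.pi * dt)
        rates = np.abs(lam) ** (1.0 / dt)
        omegas = np.log(lam) / dt
        b = np.linalg.lstsq(stacked_modes, X[:, 0].astype(complex), rcond=None)[0]

        # canonical deterministic ordering
        order = np.lexsort((-np.abs(b), np.sign(freqs), np.abs(freqs)))
        P = self.signal.n_channels
        return DMDResults(
            modes=stacked_modes[:P, order],
            stacked_modes=stacked_modes[:, order],
            eigenvalues=lam[order],
            frequencies=freqs[order],
            rates=rates[order],
            continuous_rates=omegas[order],
            amplitudes=b[order],
            singular_values=s.copy(),
            rank=int(lam.size),
            h=self.h,
            dt=dt,
        )


def exact_dmd(signal: TrialSignal, rank: int | None = None, h: int | None = None) -> DMDResults:
    """One-call convenience wrapper: ``DMD(signal, h).fit(rank)``."""
    return DMD(signal, h=h).fit(rank=rank)
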