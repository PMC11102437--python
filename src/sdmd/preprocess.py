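"""Trial preprocessing: common-average referencing and epoch cropping."""

from __future__ import annotations

import numpy as np

from .data import TrialSignal
from .exceptions import InvalidInputError

__all__ = ["common_average_reference", "crop"]


def common_average_reference(signal: TrialSignal) -> TrialSignal:
    """Subtract the across-channel mean at every time sample (CAR).

    Removes reference-electrode and globally shared artefacts; after the
    call every column sums to ~0.  Needs at least two channels.
    """
    if signal.n_channels < 2:
        raise InvalidInputError("common averaging needs at least 2 channels")
    return signal.with_values(signal.values - signal.values.mean(axis=0, keepdims=True))


def crop(signal: TrialSignal, t0: float, t1: float) -> TrialSignal:
    """Keep samples with ``t0 <= t < t1`` (seconds, half-open).

    Sample times are ``l * dt`` for l = 0..L-1; the window must lie within
    [0, L*dt] and contain at least 3 samples.
    """
    dur = signal.n_samples * signal.dt
    if not (0.0 <= t0 < t1 <= dur + 1e-12):
        raise InvalidInputError(
            f"window [{t0}, {t1}) must satisfy 0 <= t0 < t1 <= {dur}"
        )
    i0 = int(np.ceil(t0 / signal.dt - 1e-9))
    i1 = int(np.ceil(t1 / signal.dt - 1e-9))
    if i1 - i0 < 3:
        raise InvalidInputError("cropped window holds fewer than 3 samples")
    return signal.with_values(signal.values[:, i0:i1])
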