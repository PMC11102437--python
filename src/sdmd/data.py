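"""In-memory containers for trial-wise multichannel time series.

A *trial* is one epoch of a P-channel recording sampled on a regular grid:
a real matrix of shape (P, L) plus the sampling interval ``dt`` in seconds.
A :class:`TrialSet` bundles many trials of identical geometry together with
categorical labels (classification) or continuous targets (regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["TrialSignal", "TrialSet"]


@dataclass(frozen=True)
class TrialSignal:
    """One trial of a multichannel signal.

    Parameters
    ----------
    values : ndarray, shape (P, L)
        Real signal, channels by samples, in the recording's native units
        (typically microvolts for ECoG).
    dt : float
        Sampling interval in seconds (1/fs).
    channel_ids : tuple of str, optional
        Ordered channel identifiers; defaults to ``ch0 .. ch{P-1}``.
    """

    values: np.ndarray
    dt: float
    channel_ids: tuple = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InvalidInputError(f"values must be 2-D (P, L); got shape {values.shape}")
        P, L = values.shape
        if P < 1:
            raise InvalidInputError("need at least one channel")
        if L < 3:
            raise InvalidInputError(f"need at least 3 samples; got {L}")
        if not self.dt > 0:
            raise InvalidInputError(f"dt must be positive; got {self.dt}")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dt", float(self.dt))
        ids = self.channel_ids
        if ids is None:
            ids = tuple(f"ch{i}" for i in range(P))
        else:
            ids = tuple(str(c) for c in ids)
            if len(ids) != P:
                raise InvalidInputError(
                    f"{len(ids)} channel_ids for {P} channels"
                )
        object.__setattr__(self, "channel_ids", ids)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def with_values(self, values: np.ndarray) -> "TrialSignal":
        """Return a copy with ``values`` replaced, geometry metadata kept."""
        return TrialSignal(values=values, dt=self.dt, channel_ids=self.channel_ids)


@dataclass
class TrialSet:
    """A labelled collection of trials with identical geometry.

    Exactly one of ``labels`` (categorical, length N) or ``targets``
    (real, shape (N, D)) is normally set; both may be absent for
    unlabelled feature extraction.
    """

    trials: list
    labels: np.ndarray = None
    targets: np.ndarray = None
    class_names: tuple = None
    task: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.trials) == 0:
            raise InvalidInputError("TrialSet needs at least one trial")
        ref = self.trials[0]
        for t in self.trials:
            if not isinstance(t, TrialSignal):
                raise InvalidInputError("trials must be TrialSignal instances")
            if t.values.shape != ref.values.shape or t.dt != ref.dt:
                raise InvalidInputError(
                    "all trials must share channel count, length and dt"
                )
        n = len(self.trials)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise InvalidInputError(
                    f"labels must have shape ({n},); got {self.labels.shape}"
                )
        if self.targets is not None:
            self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
            if self.targets.shape[0] != n:
                raise InvalidInputError(
                    f"targets must have {n} rows; got {self.targets.shape[0]}"
                )
        if self.class_names is not None:
            self.class_names = tuple(self.class_names)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def dt(self) -> float:
        return self.trials[0].dt

    @property
    def channel_ids(self) -> tuple:
        return self.trials[0].channel_ids

    def signals(self) -> np.ndarray:
        """Stack all trials into an (N, P, L) array."""
        return np.stack([t.values for t in self.trials])

    def map_trials(self, func) -> "TrialSet":
        """Apply ``func`` (TrialSignal -> TrialSignal) to every trial."""
        return TrialSet(
            trials=[func(t) for t in self.trials],
            labels=None if self.labels is None else self.labels.copy(),
            targets=None if self.targets is None else self.targets.copy(),
            class_names=self.class_names,
            task=self.task,
            metadata=dict(self.metadata),
        )
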