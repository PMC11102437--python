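"""Persistence: HDF5 trial-set containers, CSV trials and feature tables.

The HDF5 layout is::

    /signals   float64, (N, P, L)
    /labels    int codes, (N,)            [classification sets]
    /targets   float64, (N, D)            [regression sets]
    attrs: dt_seconds, channel_ids, class_names, task, generator (JSON)

Round-trips are bit-exact (float64 throughout; complex arrays are stored
as separate real/imag datasets).  A CSV fallback covers single trials
(rows = channels) and flat feature tables.  Adapters for clinical formats
(EDF, BrainVision) are intentionally out of scope: convert externally to
these containers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import h5py
import numpy as np
import pandas as pd

from .data import TrialSet, TrialSignal
from .exceptions import FormatError
from .features import BandSpec

__all__ = [
    "write_trialset",
    "read_trialset",
    "write_trial_csv",
    "read_trial_csv",
    "write_features_csv",
    "feature_column_names",
]


def _json_default(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def write_trialset(trialset: TrialSet, path) -> None:
    """Write a TrialSet to the HDF5 container (lossless float64)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=trialset.signals())
        if trialset.labels is not None:
            classes, codes = np.unique(trialset.labels, return_inverse=True)
            f.create_dataset("labels", data=codes.astype(np.int64))
            names = trialset.class_names or tuple(str(c) for c in classes)
            f.attrs["class_names"] = [str(c) for c in names]
        if trialset.targets is not None:
            f.create_dataset("targets", data=trialset.targets)
        f.attrs["dt_seconds"] = trialset.dt
        f.attrs["channel_ids"] = list(trialset.channel_ids)
        f.attrs["task"] = trialset.task
        f.attrs["generator"] = json.dumps(trialset.metadata, default=_json_default)


def read_trialset(path) -> TrialSet:
    """Read the HDF5 container back into a TrialSet.

    Raises :class:`FormatError` naming the offending field on schema
    violations (missing datasets/attributes, inconsistent shapes).
    """
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError("missing dataset 'signals'")
        signals = np.asarray(f["signals"])
        if signals.ndim != 3:
            raise FormatError(f"'signals' must be (N, P, L); got shape {signals.shape}")
        if "dt_seconds" not in f.attrs:
            raise FormatError("missing attribute 'dt_seconds'")
        dt = float(f.attrs["dt_seconds"])
        if dt <= 0:
            raise FormatError(f"'dt_seconds' must be positive; got {dt}")
        channel_ids = None
        if "channel_ids" in f.attrs:
            channel_ids = tuple(str(c) for c in f.attrs["channel_ids"])
            if len(channel_ids) != signals.shape[1]:
                raise FormatError("'channel_ids' length does not match signals")
        labels = targets = class_names = None
        if "labels" in f:
            codes = np.asarray(f["labels"])
            if codes.shape != (signals.shape[0],):
                raise FormatError("'labels' length does not match signals")
            labels = codes.astype(int)
            if "class_names" in f.attrs:
                class_names = tuple(str(c) for c in f.attrs["class_names"])
        if "targets" in f:
            targets = np.asarray(f["targets"], dtype=float)
            if targets.shape[0] != signals.shape[0]:
                raise FormatError("'targets' row count does not match signals")
        task = str(f.attrs.get("task", ""))
        meta = {}
        if "generator" in f.attrs:
            try:
                meta = json.loads(f.attrs["generator"])
            except (json.JSONDecodeError, TypeError) as exc:
                raise FormatError(f"attribute 'generator' is not valid JSON: {exc}")
    trials = [TrialSignal(values=s, dt=dt, channel_ids=channel_ids) for s in signals]
    return TrialSet(trials=trials, labels=labels, targets=targets,
                    class_names=class_names, task=task, metadata=meta)


def write_trial_csv(signal: TrialSignal, path) -> None:
    """Single-trial CSV fallback: one row per channel, columns = samples.

    The sampling interval is recorded in a ``# dt_seconds = ...`` header
    comment.
    """
    with open(path, "w") as fh:
        fh.write(f"# dt_seconds = {signal.dt!r}\n")
        pd.DataFrame(signal.values, index=list(signal.channel_ids)).to_csv(
            fh, header=False
        )


def read_trial_csv(path, dt: float = None) -> TrialSignal:
    """Read a single-trial CSV (rows = channels); dt from the header comment
    unless given explicitly."""
    header_dt = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "dt_seconds" in first:
            header_dt = float(first.split("=")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, header=None, index_col=0)
    dt = dt if dt is not None else header_dt
    if dt is None:
        raise FormatError("missing 'dt_seconds': not in the CSV header and not given")
    return TrialSignal(values=df.to_numpy(dtype=float), dt=dt,
                       channel_ids=tuple(str(i) for i in df.index))


def feature_column_names(channel_ids, feature: str,
                         bands: BandSpec = None) -> list:
    """Column names for flat feature tables.

    snDM columns are the channel ids; seDM columns ``{chi}_{chj}`` for
    i < j in row-major order; band-filtered variants are prefixed with the
    band label.
    """
    ids = list(channel_ids)
    P = len(ids)

    def base(kind):
        if kind == "sndm":
            return list(ids)
        if kind == "sedm":
            return [f"{ids[i]}_{ids[j]}" for i in range(P) for j in range(i + 1, P)]
        if kind == "sndm+sedm":
            return base("sndm") + base("sedm")
        if kind == "sdm":  # column-major vec of the P x P matrix
            return [f"{ids[i]}_{ids[j]}" for j in range(P) for i in range(P)]
        if kind == "high-gamma-power":
            return list(ids)
        raise FormatError(f"no column naming for feature kind {feature!r}")

    if not feature.startswith("band-"):
        return base(feature)
    bands = bands or BandSpec()
    kind = {"band-sndm": "sndm", "band-sedm": "sedm",
            "band-filtered": "sndm+sedm"}[feature]
    return [f"{lab}:{c}" for lab in bands.labels() for c in base(kind)]


def write_features_csv(features: np.ndarray, path, channel_ids, feature: str,
                       bands: BandSpec = None, trial_ids=None) -> None:
    """Write an (N, D) feature matrix as a CSV with named columns."""
    cols = feature_column_names(channel_ids, feature, bands)
    features = np.asarray(features)
    if features.shape[1] != len(cols):
        raise FormatError(
            f"feature matrix has {features.shape[1]} columns; "
            f"naming scheme expects {len(cols)}"
        )
    index = trial_ids if trial_ids is not None else range(features.shape[0])
    pd.DataFrame(features, columns=cols, index=pd.Index(index, name="trial")).to_csv(path)
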