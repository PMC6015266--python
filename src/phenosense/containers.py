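"""Shared in-memory containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SensorStream:
    """Uniformly sampled wearable stream for one participant.

    Attributes
    ----------
    participant_id : str
    sample_rate : float
        Samples per second (Hz).
    t0 : pd.Timestamp
        Local wall-clock time of the first sample (naive timestamp).
    sc : np.ndarray
        Skin conductance, microsiemens.
    st : np.ndarray
        Skin temperature, degrees Celsius.
    acc : np.ndarray, shape (n, 3)
        Three-axis acceleration (arbitrary g-scaled units).
    valid_mask : np.ndarray of bool
        True where the device was worn and the sample is trusted; range
        filters are applied on top of this mask.
    """

    participant_id: str
    sample_rate: float
    t0: pd.Timestamp
    sc: np.ndarray
    st: np.ndarray
    acc: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.sc = np.asarray(self.sc, dtype=float)
        self.st = np.asarray(self.st, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.sc.shape[0], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = self.sc.shape[0]
        if not (self.st.shape[0] == n == self.acc.shape[0] == self.valid_mask.shape[0]):
            raise ValueError("all stream series must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.t0 = pd.Timestamp(self.t0)

    @property
    def n_samples(self) -> int:
        return self.sc.shape[0]

    def seconds_since_midnight(self) -> np.ndarray:
        """Local second-of-day of every sample (float)."""
        off = (self.t0 - self.t0.normalize()).total_seconds()
        return (off + np.arange(self.n_samples) / self.sample_rate) % 86400.0

    def absolute_seconds(self) -> np.ndarray:
        """Seconds of every sample since the local midnight of ``t0``."""
        off = (self.t0 - self.t0.normalize()).total_seconds()
        return off + np.arange(self.n_samples) / self.sample_rate

    def copy(self) -> "SensorStream":
        return SensorStream(
            participant_id=self.participant_id,
            sample_rate=self.sample_rate,
            t0=self.t0,
            sc=self.sc.copy(),
            st=self.st.copy(),
            acc=self.acc.copy(),
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class FeatureBlock:
    """A participants x features matrix plus per-column metadata.

    ``data`` is indexed by participant id.  ``meta`` is indexed by column
    name and tags every feature with its provenance: ``block`` (sensor /
    phone / diary / sleep / trait), ``signal``, ``statistic``, ``window``
    and across-day ``aggregate`` where applicable.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.data.columns)
        if list(self.meta.index) != list(self.data.columns):
            raise ValueError("metadata rows must match data columns")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"FeatureBlock({self.data.shape[0]} participants x {self.n_features} features)"


def concat_blocks(blocks: list[FeatureBlock]) -> FeatureBlock:
    """Column-wise concatenation of feature blocks (inner join on participants)."""
    data = pd.concat([b.data for b in blocks], axis=1, join="inner")
    meta = pd.concat([b.meta for b in blocks], axis=0)
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names across blocks: {dup[:5]}")
    return FeatureBlock(data=data, meta=meta.loc[data.columns])
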