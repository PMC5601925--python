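"""Event-level container for mass-cytometry data.

An :class:`EventTable` couples the measured intensity matrix (events x metal
channels, non-negative counts) with an acquisition-time index and an optional
*hidden* ground-truth table produced by the simulator.  Inference code never
reads the truth table; it exists so that tests and QC reports can score
recovered labels against the generator.

The on-disk text representation is a UTF-8 CSV with one header row: channel
columns first, then ``time``, then truth columns prefixed with ``truth.``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

TRUTH_PREFIX = "truth."
TIME_COLUMN = "time"

#: canonical truth columns written by the simulator
TRUTH_COLUMNS = ("population", "antigen", "cluster", "sample_id", "is_bead", "is_dead")


@dataclass
class EventTable:
    """Events x channels intensity matrix plus sidecar metadata."""

    intensities: pd.DataFrame
    time: np.ndarray | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.time is None:
            self.time = np.arange(len(self.intensities), dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) != len(self.intensities):
            raise ValidationError("time index length does not match event count")
        if self.truth is not None and len(self.truth) != len(self.intensities):
            raise ValidationError("truth table length does not match event count")
        # keep positional indexing simple and unambiguous
        self.intensities = self.intensities.reset_index(drop=True)
        if self.truth is not None:
            self.truth = self.truth.reset_index(drop=True)

    # ------------------------------------------------------------------ basic
    @property
    def n_events(self) -> int:
        return len(self.intensities)

    @property
    def channels(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_events

    def copy(self) -> "EventTable":
        return EventTable(
            self.intensities.copy(),
            self.time.copy(),
            None if self.truth is None else self.truth.copy(),
        )

    def values(self, channels: Sequence[str] | None = None) -> np.ndarray:
        df = self.intensities if channels is None else self.intensities[list(channels)]
        return df.to_numpy(dtype=float)

    # --------------------------------------------------------------- subsets
    def take(self, indices: np.ndarray) -> "EventTable":
        indices = np.asarray(indices)
        return EventTable(
            self.intensities.iloc[indices].reset_index(drop=True),
            self.time[indices],
            None if self.truth is None else self.truth.iloc[indices].reset_index(drop=True),
        )

    def filter(self, mask: np.ndarray) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_events,):
            raise ValidationError("mask shape does not match event count")
        return self.take(np.flatnonzero(mask))

    @classmethod
    def concat(cls, tables: Iterable["EventTable"]) -> "EventTable":
        tables = list(tables)
        if not tables:
            raise ValidationError("cannot concatenate zero tables")
        cols = tables[0].channels
        for t in tables[1:]:
            if t.channels != cols:
                raise ValidationError("channel sets differ between tables")
        truth = None
        if all(t.truth is not None for t in tables):
            truth = pd.concat([t.truth for t in tables], ignore_index=True)
        return cls(
            pd.concat([t.intensities for t in tables], ignore_index=True),
            np.concatenate([t.time for t in tables]),
            truth,
        )

    # ------------------------------------------------------------------- csv
    def to_csv(self, path) -> None:
        df = self.intensities.copy()
        df[TIME_COLUMN] = self.time
        if self.truth is not None:
            for col in self.truth.columns:
                df[TRUTH_PREFIX + col] = self.truth[col].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            raise DataError(f"cannot parse event CSV {path!r}: {exc}") from exc
        truth_cols = [c for c in df.columns if c.startswith(TRUTH_PREFIX)]
        truth = None
        if truth_cols:
            truth = df[truth_cols].rename(columns=lambda c: c[len(TRUTH_PREFIX):])
        time = df[TIME_COLUMN].to_numpy(float) if TIME_COLUMN in df else None
        chan_cols = [c for c in df.columns if c not in truth_cols and c != TIME_COLUMN]
        return cls(df[chan_cols].astype(float), time, truth)
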