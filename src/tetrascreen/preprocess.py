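"""Signal normalization and sample deconvolution.

Order of application in the standard pipeline: bead-based normalization of
the raw counts, randomization of exact zeros into Uniform(-1, 0), then
barcode deconvolution on the logicle scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import BarcodeScheme, Panel
from .errors import ConfigurationError, ValidationError
from .events import EventTable
from .profiling import LogicleParams, logicle_transform

logger = logging.getLogger(__name__)


# -------------------------------------------------------------------- beads
def identify_beads(events: EventTable, bead_channels: Sequence[str],
                   thresholds: dict[str, float] | float | None = None,
                   logicle: LogicleParams | None = None) -> np.ndarray:
    """Flag events positive in *all* bead channels.

    ``thresholds`` may be a per-channel dict or a scalar on the transformed
    scale; when omitted, each bead channel gets an exact 1-D two-means split
    (see :func:`tetrascreen.gating.fit_threshold`).
    """
    from .gating import fit_threshold  # local import to avoid cycle

    bead_channels = list(bead_channels)
    if not bead_channels:
        raise ConfigurationError("no bead channels supplied")
    trans = logicle_transform(events.intensities[bead_channels], logicle)
    mask = np.ones(events.n_events, dtype=bool)
    for ch in bead_channels:
        if isinstance(thresholds, dict):
            thr = thresholds[ch]
        elif thresholds is not None:
            thr = float(thresholds)
        else:
            thr = fit_threshold(trans[ch].to_numpy(), ch, method="two_component_split")
        mask &= trans[ch].to_numpy() > thr
    logger.info("flagged %d/%d events (%.3f%%) as beads",
                mask.sum(), events.n_events, 100.0 * mask.mean())
    return mask


@dataclass
class NormalizationFit:
    """Piecewise-linear per-channel gain curve over event time."""

    window_centers: np.ndarray            # time of each bead window centre
    gains: pd.DataFrame                   # windows x channels (bead channels + __global__)
    baseline: pd.Series                   # per-bead-channel baseline medians
    window_size: int

    def gain_at(self, channel: str, times: np.ndarray) -> np.ndarray:
        key = channel if channel in self.gains.columns else "__global__"
        return np.interp(times, self.window_centers, self.gains[key].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = self.gains.copy()
        df.insert(0, "window_center", self.window_centers)
        return df


def normalize_beads(events: EventTable, mask: np.ndarray, window_size: int = 500,
                    bead_channels: Sequence[str] | None = None,
                    ) -> tuple[EventTable, NormalizationFit]:
    """Undo acquisition drift using spiked-in calibration beads.

    Beads are split into consecutive windows of ``window_size`` events along
    acquisition time; per window and bead channel, gain = baseline median /
    window median.  Gains are linearly interpolated between window centres
    and applied to every event; non-bead channels receive the geometric mean
    of the bead-channel gains.  Windows with fewer than 2 beads are merged
    into their neighbour (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    bead_idx = np.flatnonzero(mask)
    if len(bead_idx) < 2:
        raise ValidationError("need at least 2 bead events to normalize")
    order = bead_idx[np.argsort(events.time[bead_idx])]

    if bead_channels is None:
        # channels where the bead events carry signal well above the rest
        med_beads = events.intensities.iloc[order].median()
        med_rest = events.intensities.iloc[~mask].median() if (~mask).any() else med_beads * 0
        bead_channels = [c for c in events.channels
                         if med_beads[c] > max(1.0, 5.0 * med_rest[c])]
    bead_channels = list(bead_channels)
    if not bead_channels:
        raise ValidationError("beads carry no signal in any channel")

    edges = list(range(0, len(order), window_size))
    windows = [order[s:s + window_size] for s in edges]
    if len(windows) > 1 and len(windows[-1]) < 2:
        logger.warning("merging trailing bead window of %d event(s) into neighbour",
                       len(windows[-1]))
        windows[-2] = np.concatenate([windows[-2], windows[-1]])
        windows.pop()

    raw = events.intensities[bead_channels].to_numpy()
    baseline = pd.Series(np.median(raw[order], axis=0), index=bead_channels)
    centers = np.array([float(np.median(events.time[w])) for w in windows])
    gain_rows = []
    for w in windows:
        med = np.median(events.intensities[bead_channels].iloc[w].to_numpy(), axis=0)
        with np.errstate(divide="ignore"):
            g = np.where(med > 0, baseline.to_numpy() / med, 1.0)
        gain_rows.append(g)
    gains = pd.DataFrame(gain_rows, columns=bead_channels)
    gains["__global__"] = np.exp(np.log(gains[bead_channels]).mean(axis=1))
    fit = NormalizationFit(window_centers=centers, gains=gains,
                           baseline=baseline, window_size=window_size)

    out = events.copy()
    for ch in out.channels:
        out.intensities[ch] = out.intensities[ch].to_numpy() * fit.gain_at(ch, out.time)
    return out, fit


# -------------------------------------------------------------------- zeros
def randomize_zeros(events: EventTable, seed: int) -> EventTable:
    """Replace exact zeros with independent Uniform(-1, 0) draws."""
    out = events.copy()
    vals = out.intensities.to_numpy()
    zero = vals == 0.0
    rng = np.random.default_rng(seed)
    vals[zero] = rng.uniform(-1.0, 0.0, int(zero.sum()))
    out.intensities = pd.DataFrame(vals, columns=out.channels)
    return out


# ----------------------------------------------------------------- barcodes
@dataclass
class BarcodeAssignment:
    sample_ids: np.ndarray        # object array; None = unassigned
    separation: np.ndarray        # rank-2 minus rank-3 transformed intensity

    @property
    def assigned(self) -> np.ndarray:
        return np.array([s is not None for s in self.sample_ids])

    @property
    def assignment_rate(self) -> float:
        return float(self.assigned.mean()) if len(self.sample_ids) else 0.0


def debarcode(events: EventTable, scheme: BarcodeScheme,
              separation_cutoff: float = 0.3,
              positive_threshold: float | None = None,
              logicle: LogicleParams | None = None) -> BarcodeAssignment:
    """Assign each event to a sample by its top-2 barcode channels.

    Works on the logicle scale.  An event is assigned iff its top-2 barcode
    channel set matches a scheme code and the gap between the 2nd- and
    3rd-ranked intensities is at least ``separation_cutoff``; events with
    three or more channels above ``positive_threshold`` (doublet-like) stay
    unassigned.
    """
    if not scheme.code_map:
        raise ConfigurationError("empty barcode scheme")
    channels = scheme.channels
    missing = [c for c in channels if c not in events.channels]
    if missing:
        raise ConfigurationError(f"barcode channels missing from data: {missing}")

    trans = logicle_transform(events.intensities[channels], logicle).to_numpy()
    order = np.argsort(trans, axis=1)
    sorted_vals = np.take_along_axis(trans, order, axis=1)
    gap = sorted_vals[:, -2] - sorted_vals[:, -3]
    decode = scheme.decode_table
    chan_arr = np.array(channels)
    top2 = chan_arr[order[:, -2:]]

    sample_ids = np.full(events.n_events, None, dtype=object)
    ok = gap >= separation_cutoff
    if positive_threshold is not None:
        ok &= (trans > positive_threshold).sum(axis=1) < 3
    for code_set, sid in decode.items():
        code = sorted(code_set)
        hit = ok & (np.sort(top2, axis=1) == np.array(code)).all(axis=1)
        sample_ids[hit] = sid
    return BarcodeAssignment(sample_ids=sample_ids, separation=gap)
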