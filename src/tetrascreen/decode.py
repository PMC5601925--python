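"""Combinatorial triple-tetramer decoding and hit calling.

A CD8+ T cell is assigned to an antigen iff, on the logicle scale, the set
S of its three brightest reporter channels (a) is everywhere above the
positivity threshold, (b) clears the 3rd-vs-4th rank separation cutoff, and
(c) is a code in the active scheme.  Cells passing (a)+(b) whose S matches
an *unused* code are recorded as decoy positives for QC.  Antigen
frequencies are fractions of gated CD8+ T cells; a hit requires frequency
strictly greater than the 0.15% cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodingScheme
from .errors import ConfigurationError, EmptyInputError, ValidationError
from .events import EventTable
from .gating import fit_threshold
from .profiling import LogicleParams, logicle_transform

HIT_CUTOFF = 0.0015
UNASSIGNED = ""
DECOY = "__decoy__"


@dataclass
class DecodeParams:
    positivity_threshold: float | None = None   # transformed scale; None = fit
    separation_cutoff: float = 0.5              # rank3 - rank4 gap, decades
    hit_cutoff: float = HIT_CUTOFF
    require_dual_config: bool = False
    min_tissues: int | None = None              # consistent-hit rule; None = all

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_cutoff < 1.0:
            raise ValidationError("hit_cutoff must be in (0, 1)")
        if self.positivity_threshold is not None and not np.isfinite(self.positivity_threshold):
            raise ValidationError("positivity threshold must be finite")


@dataclass
class DecodeResult:
    antigen: np.ndarray           # per-cell antigen_id, DECOY, or "" (unassigned)
    top3: np.ndarray              # (n, 3) channel labels, sorted
    separation: np.ndarray        # rank3 - rank4 gap
    threshold: float
    config_id: str

    @property
    def n_cells(self) -> int:
        return len(self.antigen)

    @property
    def assigned_mask(self) -> np.ndarray:
        return (self.antigen != UNASSIGNED) & (self.antigen != DECOY)

    @property
    def decoy_rate(self) -> float:
        if not self.n_cells:
            return 0.0
        return float((self.antigen == DECOY).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "antigen": self.antigen,
            "code": ["+".join(row) for row in self.top3],
            "separation": self.separation,
        })


def decode_cells(cd8_events: EventTable, scheme: CodingScheme,
                 params: DecodeParams | None = None,
                 reporter_channels: Sequence[str] | None = None,
                 logicle: LogicleParams | None = None) -> DecodeResult:
    """Assign each gated CD8+ T cell to an antigen code (or leave unassigned)."""
    params = params or DecodeParams()
    if not scheme.code_map:
        raise ConfigurationError("empty coding scheme")
    if reporter_channels is None:
        reporter_channels = sorted({c for code in scheme.code_map.values() for c in code})
    reporters = list(reporter_channels)
    missing = [c for c in reporters if c not in cd8_events.channels]
    if missing:
        raise ConfigurationError(f"reporter channels missing from data: {missing}")

    trans = logicle_transform(cd8_events.intensities[reporters], logicle).to_numpy()
    n = trans.shape[0]
    if params.positivity_threshold is not None:
        threshold = float(params.positivity_threshold)
    else:
        threshold = fit_threshold(trans.ravel(), "tetramer_reporters")

    order = np.argsort(trans, axis=1)
    svals = np.take_along_axis(trans, order, axis=1)
    top3_idx = np.sort(order[:, -3:], axis=1)       # sorted channel indices
    top3 = np.array(reporters, dtype=object)[top3_idx]
    min_top3 = svals[:, -3]
    separation = svals[:, -3] - svals[:, -4] if trans.shape[1] > 3 else np.full(n, np.inf)

    passes = (min_top3 > threshold) & (separation >= params.separation_cutoff)
    antigen = np.full(n, UNASSIGNED, dtype=object)
    decode = {tuple(sorted(code)): aid for aid, code in scheme.code_map.items()}
    if n:
        # group identical top-3 sets and match against the code book
        keys = pd.Series(map(tuple, top3))
        for key, idx in keys.groupby(keys).groups.items():
            rows = np.asarray(idx)
            rows = rows[passes[rows]]
            if not len(rows):
                continue
            antigen[rows] = decode.get(key, DECOY)
    return DecodeResult(antigen=antigen, top3=top3, separation=separation,
                        threshold=threshold, config_id=scheme.config_id)


def compute_frequencies(result: DecodeResult, n_cd8: int | None = None,
                        antigens: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-antigen decoded frequency among CD8+ T cells.

    Frequencies plus the unassigned fraction (incl. decoys) sum to 1.
    """
    n_cd8 = result.n_cells if n_cd8 is None else int(n_cd8)
    if n_cd8 <= 0:
        raise EmptyInputError("n_cd8 must be > 0")
    counts = pd.Series(result.antigen[result.assigned_mask]).value_counts()
    if antigens is None:
        antigens = sorted(counts.index)
    rows = [{"antigen": a, "count": int(counts.get(a, 0)),
             "frequency": counts.get(a, 0) / n_cd8} for a in antigens]
    df = pd.DataFrame(rows, columns=["antigen", "count", "frequency"])
    assigned = int(df["count"].sum())
    extra = int(counts.sum()) - int(counts[counts.index.isin(antigens)].sum())
    df.attrs["n_cd8"] = n_cd8
    df.attrs["unassigned_fraction"] = (n_cd8 - assigned - extra) / n_cd8
    df.attrs["decoy_count"] = int((result.antigen == DECOY).sum())
    return df


def call_hits(freqs_by_tissue: Mapping[str, pd.DataFrame],
              params: DecodeParams | None = None,
              arm: str = "isotype") -> pd.DataFrame:
    """Apply the strict >cutoff rule per tissue and flag cross-tissue consistency.

    ``freqs_by_tissue`` maps tissue name to a frequency table from
    :func:`compute_frequencies` (possibly pooled over replicates).  A
    "consistent hit" is an antigen that is a hit in at least ``min_tissues``
    tissues (default: all supplied).
    """
    params = params or DecodeParams()
    if not freqs_by_tissue:
        raise ValidationError("no frequency tables supplied")
    rows = []
    for tissue, df in freqs_by_tissue.items():
        for r in df.itertuples():
            rows.append({"antigen": r.antigen, "tissue": tissue, "arm": arm,
                         "frequency": float(r.frequency),
                         "n_cells": int(df.attrs.get("n_cd8", 0)),
                         "is_hit": bool(r.frequency > params.hit_cutoff)})
    hits = pd.DataFrame(rows)
    need = params.min_tissues or len(freqs_by_tissue)
    per_antigen = hits.groupby("antigen")["is_hit"].sum()
    consistent = set(per_antigen.index[per_antigen >= need])
    hits["consistent_hit"] = hits["antigen"].isin(consistent)
    return hits


def concordance(hits_config_a: pd.DataFrame,
                hits_config_b: pd.DataFrame) -> pd.DataFrame:
    """Merge dual-configuration hit tables; concordant = hit in both."""
    key = ["antigen", "tissue"]
    a = hits_config_a.set_index(key)
    b = hits_config_b.set_index(key)
    if set(a.index) != set(b.index):
        raise ValidationError("hit tables cover different antigen/tissue sets")
    out = a.copy()
    out["is_hit_b"] = b.loc[a.index, "is_hit"]
    out["concordant"] = out["is_hit"] & out["is_hit_b"]
    return out.reset_index()
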