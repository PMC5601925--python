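"""Sequential gating hierarchy isolating live CD8+ T cells.

Manual gates are replaced by reproducible 1-D thresholds on the logicle
scale: an exact two-means split of the channel values (threshold = midpoint
of the two cluster means), or a configured quantile, with per-channel
overrides.  The default tree is

    exclude beads -> cisplatin- -> DNA+ -> CD45+ -> CD19- ->
    TCRb+ & CD90+ -> CD8+ & CD4-
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coding import Panel, ROLE_BEAD, ROLE_DNA
from .errors import ConfigurationError, ValidationError
from .events import EventTable

MIN_EVENTS = 100


def _two_means_split(x: np.ndarray) -> tuple[float, float, float]:
    """Exact optimal 1-D 2-means partition via sorted prefix sums.

    Returns (threshold, lower mean, upper mean).
    """
    xs = np.sort(x)
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    k = np.arange(1, n)                       # size of the lower cluster
    lower_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    upper_sum = csum[-1] - csum[k - 1]
    upper_ss = (csq[-1] - csq[k - 1]) - upper_sum ** 2 / (n - k)
    best = int(np.argmin(lower_ss + upper_ss))
    m_lo = csum[best] / (best + 1)
    m_hi = (csum[-1] - csum[best]) / (n - best - 1)
    return float((m_lo + m_hi) / 2.0), float(m_lo), float(m_hi)


def fit_threshold(values: np.ndarray, channel: str = "",
                  method: str = "two_component_split", q: float = 0.5,
                  min_separation: float = 0.0) -> float:
    """Fit a 1-D gate threshold on transformed intensities.

    ``two_component_split``: midpoint of the two cluster means of the exact
    1-D 2-means partition.  If the cluster means are closer than
    ``min_separation`` the channel is treated as unimodal background and the
    threshold falls back to mean + 3 SD.  ``quantile``: the configured
    quantile.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < MIN_EVENTS:
        raise ValidationError(f"need >= {MIN_EVENTS} events to fit a threshold "
                              f"on {channel or 'channel'}")
    if np.ptp(x) == 0.0:
        raise ValidationError(f"channel {channel or '?'} is constant; cannot fit")
    if method == "quantile":
        return float(np.quantile(x, q))
    if method != "two_component_split":
        raise ConfigurationError(f"unknown threshold method {method!r}")
    thr, m_lo, m_hi = _two_means_split(x)
    if (m_hi - m_lo) < min_separation:
        return float(x.mean() + 3.0 * x.std())
    return thr


@dataclass
class GateNode:
    """One gate: conjunction over 1–2 channels, or a not-all rejection gate."""

    name: str
    channels: Sequence[str]
    polarities: Sequence[str]          # '+' keeps above threshold, '-' below
    thresholds: Sequence[float]
    combine: str = "and"               # "and" | "not_all" (bead exclusion)

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.polarities) == len(self.thresholds)):
            raise ValidationError(f"gate {self.name}: field lengths differ")
        if self.combine == "and" and not 1 <= len(self.channels) <= 2:
            raise ValidationError(f"gate {self.name}: 1 or 2 channels required")
        if any(not np.isfinite(t) for t in self.thresholds):
            raise ValidationError(f"gate {self.name}: thresholds must be finite")

    def mask(self, values: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.channels if c not in values.columns]
        if missing:
            raise ConfigurationError(f"gate {self.name}: missing channels {missing}")
        parts = []
        for ch, pol, thr in zip(self.channels, self.polarities, self.thresholds):
            x = values[ch].to_numpy()
            parts.append(x > thr if pol == "+" else x <= thr)
        stacked = np.logical_and.reduce(parts)
        if self.combine == "not_all":
            # reject events positive in every listed channel (e.g. beads)
            return ~np.logical_and.reduce([values[c].to_numpy() > t
                                           for c, t in zip(self.channels, self.thresholds)])
        return stacked


@dataclass
class GateTree:
    nodes: list[GateNode]
    counts: pd.DataFrame | None = None


def default_gate_tree(panel: Panel, thresholds: dict[str, float]) -> GateTree:
    """Build the live-CD8 gating hierarchy with fitted/overridden thresholds."""
    lab = panel.label_for
    t = thresholds

    def thr(*names: str) -> list[float]:
        missing = [n for n in names if lab(n) not in t and n not in t]
        if missing:
            raise ConfigurationError(f"no threshold for gate channel(s) {missing}")
        return [t.get(lab(n), t.get(n)) for n in names]

    nodes = [
        GateNode("beads_excluded", panel.bead_labels, ["+"] * len(panel.bead_labels),
                 [t[c] for c in panel.bead_labels], combine="not_all"),
        GateNode("live", [lab("cisplatin")], ["-"], thr("cisplatin")),
        GateNode("dna_pos", [lab("DNA1")], ["+"], thr("DNA1")),
        GateNode("cd45_pos", [lab("CD45")], ["+"], thr("CD45")),
        GateNode("cd19_neg", [lab("CD19")], ["-"], thr("CD19")),
        GateNode("t_cells", [lab("TCRb"), lab("CD90")], ["+", "+"], thr("TCRb", "CD90")),
        GateNode("cd8_t", [lab("CD8"), lab("CD4")], ["+", "-"], thr("CD8", "CD4")),
    ]
    return GateTree(nodes=nodes)


def fit_gate_thresholds(transformed: pd.DataFrame, panel: Panel,
                        overrides: dict[str, float] | None = None,
                        min_separation: float = 0.0) -> dict[str, float]:
    """Fit per-channel thresholds for every channel the default tree uses."""
    overrides = overrides or {}
    needed = panel.bead_labels + [panel.label_for(m) for m in
                                  ("cisplatin", "DNA1", "CD45", "CD19", "TCRb",
                                   "CD90", "CD8", "CD4")]
    out: dict[str, float] = {}
    for ch in needed:
        if ch in overrides:
            out[ch] = overrides[ch]
        elif panel.label_for(ch) in overrides:
            out[ch] = overrides[panel.label_for(ch)]
        else:
            out[ch] = fit_threshold(transformed[ch].to_numpy(), ch,
                                    min_separation=min_separation)
    return out


def apply_gate_tree(events: EventTable | pd.DataFrame,
                    tree: GateTree) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the gates sequentially on transformed values.

    Returns the final boolean mask and a per-gate count table (counts are
    monotonically non-increasing; conjunctive semantics, so the final mask is
    the intersection of the single-gate masks).
    """
    values = events.intensities if isinstance(events, EventTable) else events
    mask = np.ones(len(values), dtype=bool)
    rows = [{"gate": "input", "events": int(mask.sum())}]
    for node in tree.nodes:
        mask &= node.mask(values)
        rows.append({"gate": node.name, "events": int(mask.sum())})
    counts = pd.DataFrame(rows)
    tree.counts = counts
    return mask, counts
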