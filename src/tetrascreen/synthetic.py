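"""Ground-truth event simulator.

Generates multi-tissue mass-cytometry event tables containing CD8+ T cells
that carry 3-of-9 coded tetramer signals at tissue-specific frequencies,
ten phenotype archetype clusters, 2-of-6 sample barcodes, calibration
beads, dead cells and lineage contaminants, under a zero-inflated
log-normal signal model.  Truth labels ride along in a sidecar table that
inference code never reads.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coding
from .coding import BarcodeScheme, CodingScheme, Panel
from .errors import ConfigurationError, ValidationError
from .events import EventTable
from .profiling import LogicleParams, RuleThresholds, logicle_transform

LEVELS = ("negative", "low", "high")
POPULATIONS = ("cd8_t", "cd4_t", "b_cell", "other_cd45", "dead", "bead")
CLUSTER_IDS = tuple(f"C{i}" for i in range(1, 11))

PHENOTYPE_MARKERS = ("PD-1", "KLRG-1", "Sca-1", "Tim-3", "CD39", "CD27", "CD160",
                     "GITR", "Lag-3", "CD25", "CD38", "CD127", "CD44", "CD62L",
                     "CXCR3", "ICOS")


# ----------------------------------------------------------------- archetypes
@dataclass(frozen=True)
class PhenotypeArchetype:
    cluster_id: str
    levels: Mapping[str, str]  # marker -> negative | low | high

    def __post_init__(self) -> None:
        bad = {m: l for m, l in self.levels.items() if l not in LEVELS}
        if bad:
            raise ValidationError(f"invalid levels in {self.cluster_id}: {bad}")


def _arch(cid: str, **kw: str) -> PhenotypeArchetype:
    base = {m: "negative" for m in PHENOTYPE_MARKERS}
    base["CD44"] = "high"  # antigen-experienced cells throughout
    alias = {m.replace("-", "_").replace("Sca_1", "Sca1"): m for m in PHENOTYPE_MARKERS}
    for key, lvl in kw.items():
        base[alias.get(key, key)] = lvl
    return PhenotypeArchetype(cid, base)


#: the ten cluster archetypes; signature-marker pattern drives the rule table
DEFAULT_ARCHETYPES: dict[str, PhenotypeArchetype] = {a.cluster_id: a for a in [
    _arch("C1", CD27="high", CD38="low", CD127="high", CD62L="low", CXCR3="low",
          ICOS="low"),
    _arch("C2", CD127="low"),
    _arch("C3", PD_1="high", Sca1="high", CD39="low", CD27="low", GITR="high",
          Lag_3="low", CD25="low", CD38="high", ICOS="high", CXCR3="low"),
    _arch("C4", PD_1="high", Sca1="high", Tim_3="low", CD39="low", CD160="low",
          GITR="high", Lag_3="high", CD25="low", CD38="high", ICOS="high"),
    _arch("C5", PD_1="high", Sca1="high", Tim_3="high", CD39="high", CD160="low",
          GITR="high", Lag_3="high", CD25="high", CD38="high", ICOS="high"),
    _arch("C6", KLRG_1="high", Tim_3="low", CD38="low", CD127="low", CXCR3="low"),
    _arch("C7", Sca1="high", CD27="low", CD127="high", CD62L="low", CXCR3="high"),
    _arch("C8", Sca1="high", Tim_3="high", CD39="low", GITR="low", CD38="low",
          CD127="low", CXCR3="low", ICOS="low"),
    _arch("C9", Sca1="high", CD160="high", CD127="low", CXCR3="low"),
    _arch("C10", KLRG_1="high", Sca1="high", CD127="low", CXCR3="low"),
]}


# ---------------------------------------------------------------- noise model
@dataclass(frozen=True)
class NoiseModel:
    """Zero-inflated log-normal signal model plus acquisition artifacts."""

    high_loc: float = math.log(200.0)   # log-normal location of "high"
    high_scale: float = 0.40
    low_loc: float = math.log(22.0)
    low_scale: float = 0.40
    bg_zero_prob: float = 0.60          # P(exact zero) for background
    bg_rate: float = 1.0                # exponential mean of nonzero background
    bead_scale: float = 0.10            # calibration beads are near-uniform
    drift_coefficient: float = 0.0      # linear gain 1 -> 1+c over the run
    spillover: float = 0.0              # optional linear neighbour spillover
    doublet_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bg_zero_prob <= 1.0:
            raise ValidationError("bg_zero_prob must be in [0, 1]")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValidationError("doublet_rate must be in [0, 1)")
        if self.drift_coefficient <= -1.0:
            raise ValidationError("drift coefficient must keep gains positive")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        """Degenerate model: constant signals, exactly-zero background."""
        return cls(high_scale=0.0, low_scale=0.0, bg_zero_prob=1.0)

    def level_median(self, level: str) -> float:
        if level == "high":
            return math.exp(self.high_loc)
        if level == "low":
            return math.exp(self.low_loc)
        return 0.0

    # vectorized draws -----------------------------------------------------
    def draw_background(self, rng: np.random.Generator, shape) -> np.ndarray:
        out = np.zeros(shape)
        if self.bg_zero_prob < 1.0:
            nz = rng.random(shape) >= self.bg_zero_prob
            out[nz] = rng.exponential(self.bg_rate, int(nz.sum()))
        return out

    def draw_level(self, rng: np.random.Generator, level: str, size: int) -> np.ndarray:
        if level == "negative":
            return self.draw_background(rng, size)
        loc, scale = ((self.high_loc, self.high_scale) if level == "high"
                      else (self.low_loc, self.low_scale))
        if scale == 0.0:
            return np.full(size, math.exp(loc))
        return rng.lognormal(loc, scale, size)

    def draw_bead(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.high_scale == 0.0:
            return np.full(size, math.exp(self.high_loc))
        return rng.lognormal(self.high_loc, self.bead_scale, size)


def archetype_thresholds(noise: NoiseModel,
                         logicle: LogicleParams | None = None,
                         markers: Sequence[str] = PHENOTYPE_MARKERS) -> RuleThresholds:
    """Calibration thresholds: transformed-scale midpoints between level medians."""
    logicle = logicle or LogicleParams()
    t_neg, t_low, t_high = logicle_transform(
        np.array([noise.bg_rate * math.log(2.0),
                  noise.level_median("low"), noise.level_median("high")]), logicle)
    pos = float((t_neg + t_low) / 2.0)
    split = float((t_low + t_high) / 2.0)
    return RuleThresholds(positive={m: pos for m in markers},
                          split={m: split for m in markers})


# --------------------------------------------------------------- tissue specs
@dataclass
class TissueSpec:
    tissue: str
    n_cells: int
    composition: dict[str, float]                 # population -> fraction
    antigen_freq: dict[str, float]                # antigen -> fraction of CD8
    cluster_mix: dict[str, dict[str, float]]      # antigen -> archetype dist
    tetneg_mix: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.composition) - set(POPULATIONS)
        if unknown:
            raise ValidationError(f"unknown populations: {sorted(unknown)}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"composition fractions sum to {total}, not 1")
        if any(not 0.0 <= v <= 1.0 for v in self.composition.values()):
            raise ValidationError("composition fractions must lie in [0, 1]")
        ag_total = sum(self.antigen_freq.values())
        if ag_total >= 1.0:
            raise ValidationError("antigen frequencies must sum to < 1")
        for aid, mix in self.cluster_mix.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-6:
                raise ValidationError(f"cluster mix for {aid} sums to {s}")


@dataclass
class ExperimentSpec:
    tissues: list[TissueSpec]
    arm: str = "isotype"
    replicates: int = 5
    barcode_assignment: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.barcode_assignment:
            self.barcode_assignment = {t.tissue: t.tissue for t in self.tissues}
        sids = list(self.barcode_assignment.values())
        if len(set(sids)) != len(sids):
            raise ValidationError("each tissue needs a distinct sample barcode")

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.tissue == name:
                return t
        raise ConfigurationError(f"no tissue named {name!r}")


_PERIPHERAL_MIX = {"C1": 0.35, "C2": 0.35, "C3": 0.05, "C7": 0.10,
                   "C8": 0.05, "C9": 0.05, "C10": 0.05}
_TUMOUR_MLAMA4_MIX = {"C1": 0.22, "C2": 0.20, "C3": 0.28, "C4": 0.08, "C5": 0.07,
                      "C6": 0.02, "C7": 0.04, "C8": 0.03, "C9": 0.03, "C10": 0.03}
_TUMOUR_MALG8_MIX = {"C1": 0.05, "C2": 0.05, "C3": 0.20, "C4": 0.18, "C5": 0.15,
                     "C6": 0.17, "C7": 0.05, "C8": 0.05, "C9": 0.05, "C10": 0.05}
_TUMOUR_TETNEG_MIX = {"C1": 0.15, "C2": 0.15, "C3": 0.10, "C4": 0.05, "C5": 0.05,
                      "C6": 0.10, "C7": 0.15, "C8": 0.10, "C9": 0.05, "C10": 0.10}
_NAIVE_MIX = {"C1": 0.45, "C2": 0.45, "C7": 0.10}


def _tissue(name: str, n_cells: int, composition: dict[str, float],
            freqs: dict[str, float], tumour_like: bool) -> TissueSpec:
    mixes = ({"mLama4": dict(_TUMOUR_MLAMA4_MIX), "mAlg8": dict(_TUMOUR_MALG8_MIX)}
             if tumour_like else
             {"mLama4": dict(_PERIPHERAL_MIX), "mAlg8": dict(_PERIPHERAL_MIX)})
    mixes = {a: mixes[a] for a in freqs if a in mixes}
    tetneg = dict(_TUMOUR_TETNEG_MIX) if tumour_like else dict(_NAIVE_MIX)
    return TissueSpec(name, n_cells, composition, dict(freqs), mixes, tetneg)


def default_tumour_spec(n_cells: int = 100_000) -> TissueSpec:
    """Tumour: mLama4 10.2% / mAlg8 9.9% of CD8 TILs."""
    comp = {"cd8_t": 0.20, "cd4_t": 0.15, "b_cell": 0.10, "other_cd45": 0.48,
            "dead": 0.06, "bead": 0.01}
    return _tissue("tumour", n_cells, comp, {"mLama4": 0.102, "mAlg8": 0.099}, True)


def default_spleen_spec(n_cells: int = 60_000) -> TissueSpec:
    comp = {"cd8_t": 0.25, "cd4_t": 0.25, "b_cell": 0.25, "other_cd45": 0.18,
            "dead": 0.06, "bead": 0.01}
    return _tissue("spleen", n_cells, comp, {"mLama4": 0.008, "mAlg8": 0.006}, False)


_LN_COMP = {"cd8_t": 0.30, "cd4_t": 0.30, "b_cell": 0.25, "other_cd45": 0.08,
            "dead": 0.06, "bead": 0.01}


def default_dln_spec(n_cells: int = 60_000) -> TissueSpec:
    return _tissue("dLN", n_cells, dict(_LN_COMP), {"mLama4": 0.010, "mAlg8": 0.003}, False)


def default_ndln_spec(n_cells: int = 60_000) -> TissueSpec:
    return _tissue("ndLN", n_cells, dict(_LN_COMP), {"mLama4": 0.004, "mAlg8": 0.002}, False)


def dln_worked_example(n_cells: int = 170_000) -> TissueSpec:
    """Draining-lymph-node worked example: mLama4 0.89%, mAlg8 0.23% of CD8."""
    return _tissue("dLN", n_cells, dict(_LN_COMP), {"mLama4": 0.0089, "mAlg8": 0.0023}, False)


def default_experiment(arm: str = "isotype", replicates: int = 5,
                       seed: int = 0,
                       n_cells: Mapping[str, int] | None = None) -> ExperimentSpec:
    sizes = {"tumour": 100_000, "spleen": 60_000, "dLN": 60_000, "ndLN": 60_000}
    if n_cells:
        sizes.update(n_cells)
    tissues = [default_tumour_spec(sizes["tumour"]),
               default_spleen_spec(sizes["spleen"]),
               default_dln_spec(sizes["dLN"]),
               default_ndln_spec(sizes["ndLN"])]
    return ExperimentSpec(tissues=tissues, arm=arm, replicates=replicates, seed=seed)


# ------------------------------------------------------------------ treatment
TREATMENT_ARMS = ("anti-CTLA-4", "anti-PD-1")
DEFAULT_TREATMENT_EFFECTS = {"mLama4": 2.0, "mAlg8": 1.5}


def _shift_mix(mix: dict[str, float], shift_fraction: float) -> dict[str, float]:
    src = [c for c in ("C1", "C2", "C3", "C4", "C5") if mix.get(c, 0) > 0]
    dst = ["C7", "C8", "C9", "C10"]
    moved = sum(mix[c] * shift_fraction for c in src)
    out = dict(mix)
    for c in src:
        out[c] = mix[c] * (1.0 - shift_fraction)
    weights = np.array([mix.get(c, 0.0) for c in dst])
    weights = weights / weights.sum() if weights.sum() > 0 else np.full(4, 0.25)
    for c, w in zip(dst, weights):
        out[c] = out.get(c, 0.0) + moved * float(w)
    return out


def apply_treatment_effect(spec: ExperimentSpec, arm: str,
                           effects: Mapping[str, float] | None = None,
                           shift_fraction: float = 0.95) -> ExperimentSpec:
    """Encode checkpoint-blockade ground truth into a copy of ``spec``.

    Tumour antigen frequencies scale (mLama4 x2.0, mAlg8 x1.5 by default) and
    tumour cluster mass moves from C1–C5 to C7–C10; peripheral tissues are
    untouched.  ``arm="isotype"`` returns an unmodified copy.
    """
    if arm == "isotype":
        return copy.deepcopy(spec)
    if arm not in TREATMENT_ARMS:
        raise ValidationError(f"unknown treatment arm {arm!r}")
    effects = dict(effects or DEFAULT_TREATMENT_EFFECTS)
    out = copy.deepcopy(spec)
    out.arm = arm
    for tis in out.tissues:
        if tis.tissue != "tumour":
            continue
        tis.antigen_freq = {a: f * effects.get(a, 1.0)
                            for a, f in tis.antigen_freq.items()}
        if sum(tis.antigen_freq.values()) >= 1.0:
            raise ValidationError("treatment effect pushes frequencies past 1")
        tis.cluster_mix = {a: _shift_mix(m, shift_fraction)
                           for a, m in tis.cluster_mix.items()}
    return out


# ------------------------------------------------------------------ simulator
def spike_drift(events: EventTable, coefficient: float) -> EventTable:
    """Multiply intensities by the linear gain 1 + c * t/t_max (truth untouched)."""
    if coefficient <= -1.0:
        raise ValidationError("drift coefficient must keep gain positive")
    out = events.copy()
    tmax = float(out.time.max()) if out.n_events and out.time.max() > 0 else 1.0
    gain = 1.0 + coefficient * out.time / tmax
    out.intensities = out.intensities.mul(gain, axis=0)
    return out


def _simulate_tissue(tis: TissueSpec, scheme: CodingScheme, sample_id: str,
                     barcodes: BarcodeScheme, noise: NoiseModel, panel: Panel,
                     rng: np.random.Generator) -> EventTable:
    for aid, f in tis.antigen_freq.items():
        if f > 0 and aid not in scheme.code_map:
            raise ConfigurationError(
                f"antigen {aid!r} has nonzero frequency but no code in scheme "
                f"{scheme.config_id}")
    if sample_id not in barcodes.code_map:
        raise ConfigurationError(f"sample {sample_id!r} missing from barcode scheme")

    pops = list(POPULATIONS)
    probs = np.array([tis.composition.get(p, 0.0) for p in pops])
    counts = rng.multinomial(tis.n_cells, probs)
    n = int(counts.sum())
    pop_arr = np.repeat(pops, counts)

    labels = panel.labels()
    col = {lab: i for i, lab in enumerate(labels)}
    X = noise.draw_background(rng, (n, len(labels)))

    slices: dict[str, np.ndarray] = {}
    start = 0
    for p, c in zip(pops, counts):
        slices[p] = np.arange(start, start + c)
        start += c

    def set_high(rows: np.ndarray, channel_names: Sequence[str]) -> None:
        for name in channel_names:
            X[rows, col[name]] = noise.draw_level(rng, "high", len(rows))

    beads = slices["bead"]
    cells = np.concatenate([slices[p] for p in pops if p != "bead"])
    dna = [c.label for c in panel.channels if c.role == coding.ROLE_DNA]
    for name in panel.bead_labels:
        X[beads, col[name]] = noise.draw_bead(rng, len(beads))
    set_high(cells, dna)
    set_high(slices["dead"], [panel.label_for("cisplatin")])
    immune = cells  # dead cells modeled as dying immune cells (CD45+)
    set_high(immune, [panel.label_for("CD45")])
    set_high(slices["b_cell"], [panel.label_for("CD19")])
    tcells = np.concatenate([slices["cd8_t"], slices["cd4_t"]])
    set_high(tcells, [panel.label_for("TCRb"), panel.label_for("CD90")])
    set_high(slices["cd8_t"], [panel.label_for("CD8")])
    set_high(slices["cd4_t"], [panel.label_for("CD4")])
    set_high(cells, list(barcodes.code_map[sample_id]))

    # antigen assignment among CD8 T cells
    cd8 = slices["cd8_t"]
    antigens = [a for a in tis.antigen_freq]
    p_vec = np.array([tis.antigen_freq[a] for a in antigens] +
                     [1.0 - sum(tis.antigen_freq.values())])
    choice = rng.choice(len(antigens) + 1, size=len(cd8), p=p_vec)
    antigen_arr = np.full(n, "", dtype=object)
    cluster_arr = np.full(n, "", dtype=object)
    for i, aid in enumerate(antigens):
        rows = cd8[choice == i]
        antigen_arr[rows] = aid
        if len(rows):
            set_high(rows, scheme.code_map[aid])

    # phenotype archetypes for CD8 T cells
    def draw_clusters(rows: np.ndarray, mix: Mapping[str, float]) -> None:
        if not len(rows) or not mix:
            return
        cids = list(mix)
        assign = rng.choice(len(cids), size=len(rows), p=np.array([mix[c] for c in cids]))
        for j, cid in enumerate(cids):
            sub = rows[assign == j]
            cluster_arr[sub] = cid
            arch = DEFAULT_ARCHETYPES[cid]
            for m in PHENOTYPE_MARKERS:
                lvl = arch.levels[m]
                if lvl != "negative":
                    X[sub, col[panel.label_for(m)]] = noise.draw_level(rng, lvl, len(sub))

    for i, aid in enumerate(antigens):
        draw_clusters(cd8[choice == i], tis.cluster_mix.get(aid, {}))
    draw_clusters(cd8[choice == len(antigens)], tis.tetneg_mix)

    truth = pd.DataFrame({
        "population": pop_arr,
        "antigen": antigen_arr,
        "cluster": cluster_arr,
        "sample_id": sample_id,
        "is_bead": pop_arr == "bead",
        "is_dead": pop_arr == "dead",
    })

    # doublets: coincident pairs of non-bead events summed into one record
    if noise.doublet_rate > 0:
        m = int(noise.doublet_rate * n)
        if m:
            pick = rng.choice(cells, size=2 * m, replace=False)
            a, b = pick[:m], pick[m:]
            X[a] += X[b]
            truth.loc[a, "population"] = "doublet"
            keep = np.setdiff1d(np.arange(n), b)
            X = X[keep]
            truth = truth.iloc[keep].reset_index(drop=True)
            n = len(keep)

    if noise.spillover > 0:
        X = X + noise.spillover * np.roll(X, 1, axis=1)

    order = rng.permutation(n)
    table = EventTable(pd.DataFrame(X[order], columns=labels),
                       np.arange(n, dtype=float),
                       truth.iloc[order].reset_index(drop=True))
    if noise.drift_coefficient:
        table = spike_drift(table, noise.drift_coefficient)
    return table


def simulate_experiment(
    spec: ExperimentSpec,
    schemes: CodingScheme | tuple[CodingScheme, CodingScheme | None],
    noise: NoiseModel,
    seed: int,
    panel: Panel | None = None,
    barcodes: BarcodeScheme | None = None,
) -> dict[str, dict[str, EventTable]]:
    """Simulate one replicate: ``{config_id: {tissue: EventTable}}``.

    Deterministic under ``seed``.  ``schemes`` is a single configuration or an
    (A, B) pair; the B slot may be None.
    """
    if isinstance(schemes, CodingScheme):
        schemes = (schemes, None)
    panel = panel or coding.default_channels()
    barcodes = barcodes or coding.default_barcode_scheme(
        sorted(set(spec.barcode_assignment.values())), panel)
    out: dict[str, dict[str, EventTable]] = {}
    for ci, scheme in enumerate(schemes):
        if scheme is None:
            continue
        per_tissue: dict[str, EventTable] = {}
        for ti, tis in enumerate(spec.tissues):
            rng = np.random.default_rng([seed, ci, ti])
            per_tissue[tis.tissue] = _simulate_tissue(
                tis, scheme, spec.barcode_assignment[tis.tissue], barcodes,
                noise, panel, rng)
        out[scheme.config_id] = per_tissue
    return out
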