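"""Display transform, embedding, clustering and cluster phenotype profiles.

The logicle (biexponential) transform is implemented from its definition:
the scale value y of a data value x solves B(y) = x where

    B(y) = a e^{b y} - c e^{-d y} - f,   y in [0, 1] over m + a decades,

with coefficients fixed by (t, m, w, a) so that B is continuous, strictly
increasing, linear near zero and logarithmic at the top of scale, B(x1) = 0
at the linearization centre and B(1) = t.  Inversion uses a grid-seeded
Newton iteration (tolerance < 1e-10 on the scale value).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .errors import ConfigurationError, ValidationError
from .events import EventTable

LN10 = np.log(10.0)


@dataclass(frozen=True)
class LogicleParams:
    """Parks–Moore logicle parameters (display decades)."""

    w: float = 0.25      # linearization width in decades
    t: float = 16409.0   # top of scale
    m: float = 4.5       # total display decades
    a: float = 0.0       # additional negative decades

    def __post_init__(self) -> None:
        if self.t <= 0 or self.m <= 0:
            raise ValidationError("logicle requires t > 0 and m > 0")
        if not 0 <= self.w <= self.m / 2:
            raise ValidationError("logicle requires 0 <= w <= m/2")
        if self.a < 0:
            raise ValidationError("logicle requires a >= 0")


class _LogicleSolver:
    """Coefficients and vectorized forward/inverse evaluation for one parameter set."""

    GRID = 4096

    def __init__(self, p: LogicleParams):
        span = p.m + p.a
        w = p.w / span
        x2 = p.a / span
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        b = span * LN10
        if w > 0:
            # d solves 2(ln d - ln b) + w(b + d) = 0 on (0, b)
            d = brentq(lambda dd: 2.0 * (np.log(dd) - np.log(b)) + w * (b + dd),
                       1e-12, b, xtol=1e-14, rtol=1e-14)
        else:
            d = b
        c_a = np.exp(x0 * (b + d))
        mf_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
        self.a_ = p.t / ((np.exp(b) - mf_a) - c_a * np.exp(-d))
        self.b_ = b
        self.d_ = d
        self.c_ = c_a * self.a_
        self.f_ = mf_a * self.a_
        self.span = span
        # bracket covering raw values down to -t and up to 1.5*t
        y_lo = x1
        while self._biexp(y_lo) > -p.t:
            y_lo -= 0.1
        y_hi = 1.0
        while self._biexp(y_hi) < 1.5 * p.t:
            y_hi += 0.1
        self._grid_y = np.linspace(y_lo, y_hi, self.GRID)
        self._grid_x = self._biexp(self._grid_y)

    def _biexp(self, y):
        return self.a_ * np.exp(self.b_ * y) - self.c_ * np.exp(-self.d_ * y) - self.f_

    def _biexp_deriv(self, y):
        return self.a_ * self.b_ * np.exp(self.b_ * y) + self.c_ * self.d_ * np.exp(-self.d_ * y)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Scale values (in decades) for raw values ``x``."""
        x = np.asarray(x, dtype=float)
        flat = x.ravel()
        y = np.interp(flat, self._grid_x, self._grid_y)
        for _ in range(40):
            fy = self._biexp(y) - flat
            step = fy / self._biexp_deriv(y)
            y -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        return (y * self.span).reshape(x.shape)

    def inverse(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return self._biexp(v / self.span)


@lru_cache(maxsize=16)
def _solver(params: LogicleParams) -> _LogicleSolver:
    return _LogicleSolver(params)


def logicle_transform(values, params: LogicleParams | None = None):
    """Apply the logicle transform; accepts array-likes or DataFrames."""
    params = params or LogicleParams()
    solver = _solver(params)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(solver.forward(values.to_numpy(float)),
                            columns=values.columns, index=values.index)
    return solver.forward(np.asarray(values, dtype=float))


def inverse_logicle(values, params: LogicleParams | None = None):
    params = params or LogicleParams()
    solver = _solver(params)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(solver.inverse(values.to_numpy(float)),
                            columns=values.columns, index=values.index)
    return solver.inverse(np.asarray(values, dtype=float))


def transform_events(events: EventTable, params: LogicleParams | None = None,
                     channels: Sequence[str] | None = None) -> EventTable:
    """Return a copy of ``events`` with (selected) channels logicle-transformed."""
    out = events.copy()
    cols = list(channels) if channels is not None else out.channels
    out.intensities[cols] = logicle_transform(out.intensities[cols], params)
    return out


def marker_matrix(events: EventTable, panel, markers: Sequence[str]) -> pd.DataFrame:
    """Extract a marker-named view of the event intensities."""
    labels = panel.labels_for(markers)
    df = events.intensities[labels].copy()
    df.columns = list(markers)
    return df


# ----------------------------------------------------------------- sampling
def downsample(events, cap: int, seed: int):
    """Uniform subsample without replacement to at most ``cap`` rows."""
    if cap < 1:
        raise ValidationError("downsample cap must be >= 1")
    n = len(events)
    if n <= cap:
        return events.copy() if hasattr(events, "copy") else events
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=cap, replace=False))
    if isinstance(events, EventTable):
        return events.take(idx)
    if isinstance(events, pd.DataFrame):
        return events.iloc[idx].reset_index(drop=True)
    return np.asarray(events)[idx]


# -------------------------------------------------------------------- t-SNE
@dataclass
class ProfileParams:
    """Embedding / clustering hyper-parameters."""

    downsample_cap: int = 10_000
    markers: Sequence[str] | None = None      # default: all phenotype markers
    exclude_markers: Sequence[str] = ()       # e.g. PD-1 under anti-PD-1
    perplexity: float = 30.0
    n_iter: int = 1000
    theta: float = 0.5
    k: int = 10
    restarts: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample_cap < 1 or self.k < 2 or self.restarts < 1:
            raise ValidationError("invalid profile parameters")


@dataclass
class TsneResult:
    embedding: np.ndarray                      # (n, 2)
    kl_checkpoints: list[float]                # final KL divergence (single checkpoint)


def run_tsne(matrix, params: ProfileParams | None = None) -> TsneResult:
    """Barnes–Hut t-SNE to 2-D; deterministic under the params seed."""
    params = params or ProfileParams()
    X = np.asarray(matrix, dtype=float)
    min_rows = int(params.perplexity * 3) + 1
    if X.shape[0] < min_rows:
        raise ValidationError(
            f"t-SNE needs at least {min_rows} rows at perplexity {params.perplexity}")
    tsne = TSNE(n_components=2, perplexity=params.perplexity, max_iter=params.n_iter,
                angle=params.theta, method="barnes_hut", init="pca",
                random_state=params.seed)
    emb = tsne.fit_transform(X)
    return TsneResult(embedding=np.asarray(emb, dtype=float),
                      kl_checkpoints=[float(tsne.kl_divergence_)])


# ------------------------------------------------------------------- kmeans
@dataclass
class ClusterModel:
    labels: np.ndarray          # 1-based labels, 1..k
    centers: np.ndarray
    wcss: float                 # best within-cluster sum of squares
    k: int
    restarts: int


def cluster_embedding(embedding, k: int = 10, restarts: int = 1000,
                      seed: int = 0) -> ClusterModel:
    """Best-of-``restarts`` k-means on the 2-D embedding."""
    X = np.asarray(embedding, dtype=float)
    if X.shape[0] < k:
        raise ValidationError(f"need at least k={k} rows, got {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, init="random",
                random_state=seed).fit(X)
    return ClusterModel(labels=km.labels_ + 1, centers=km.cluster_centers_,
                        wcss=float(km.inertia_), k=k, restarts=restarts)


# ------------------------------------------------------------- rule clusters
CLUSTER_IDS = tuple(f"C{i}" for i in range(1, 11))
UNCLASSIFIED = "unclassified"


@dataclass
class RuleThresholds:
    """Positivity and low/high split thresholds on the transformed scale."""

    positive: Mapping[str, float]
    split: Mapping[str, float]


class ClusterRuleSet:
    """Sequential biaxial rules mapping marker patterns to C1–C10.

    The default table: KLRG-1+ cells split into C10 (Sca-1+ Tim-3−) and C6;
    PD-1+ KLRG-1− Sca-1+ cells into C3 (Tim-3−), C5 (Tim-3 and CD39 both
    high) and C4 (remaining Tim-3+); PD-1− KLRG-1− Sca-1+ into C8 (Tim-3+),
    C9 (CD160+) and C7; PD-1− KLRG-1− Sca-1− into C1/C2 by CD27.
    """

    markers = ("PD-1", "KLRG-1", "Sca-1", "Tim-3", "CD39", "CD27", "CD160")

    def assign(self, values: pd.DataFrame, thresholds: RuleThresholds) -> np.ndarray:
        missing = [m for m in self.markers if m not in values.columns]
        if missing:
            raise ConfigurationError(f"rule markers missing from data: {missing}")
        missing_thr = [m for m in self.markers if m not in thresholds.positive]
        if missing_thr:
            raise ConfigurationError(f"no positivity threshold for: {missing_thr}")

        pos = {m: values[m].to_numpy() > thresholds.positive[m] for m in self.markers}
        hi = {m: values[m].to_numpy() > thresholds.split.get(m, np.inf)
              for m in ("Tim-3", "CD39")}

        n = len(values)
        labels = np.full(n, UNCLASSIFIED, dtype=object)
        klrg = pos["KLRG-1"]
        labels[klrg] = "C6"
        labels[klrg & pos["Sca-1"] & ~pos["Tim-3"]] = "C10"

        pd1 = ~klrg & pos["PD-1"]
        c345 = pd1 & pos["Sca-1"]
        labels[c345 & ~pos["Tim-3"]] = "C3"
        c45 = c345 & pos["Tim-3"]
        labels[c45] = "C4"
        labels[c45 & hi["Tim-3"] & hi["CD39"]] = "C5"
        # PD-1+ Sca-1− matches no published cluster -> stays unclassified

        rest = ~klrg & ~pos["PD-1"]
        sca = rest & pos["Sca-1"]
        labels[sca & ~pos["Tim-3"] & ~pos["CD160"]] = "C7"
        labels[sca & pos["Tim-3"]] = "C8"
        labels[sca & ~pos["Tim-3"] & pos["CD160"]] = "C9"

        neg = rest & ~pos["Sca-1"]
        labels[neg & pos["CD27"]] = "C1"
        labels[neg & ~pos["CD27"]] = "C2"
        return labels


DEFAULT_RULESET = ClusterRuleSet()


def assign_rule_clusters(values: pd.DataFrame, thresholds: RuleThresholds,
                         ruleset: ClusterRuleSet | None = None) -> np.ndarray:
    """Label each event C1..C10 (or unclassified) from transformed marker values."""
    return (ruleset or DEFAULT_RULESET).assign(values, thresholds)


# -------------------------------------------------------------- concordance
def compare_clusterings(labels_a, labels_b) -> tuple[float, int, float]:
    """Pearson chi-square of the contingency table of two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("labelings must have the same length")
    table = pd.crosstab(pd.Series(a), pd.Series(b))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("chi-square undefined: fewer than 2 categories")
    stat, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), int(dof), float(p)


# ------------------------------------------------------------------ profile
@dataclass
class ClusterProfile:
    """Per-cluster marker medians and percent-positive (transformed scale)."""

    n: pd.Series                 # cluster -> cell count
    medians: pd.DataFrame        # clusters x markers
    percent_positive: pd.DataFrame

    @property
    def clusters(self) -> list:
        return list(self.n.index)

    def to_frame(self) -> pd.DataFrame:
        med = self.medians.add_suffix(":median")
        pct = self.percent_positive.add_suffix(":pct_pos")
        out = pd.concat([self.n.rename("n").to_frame(), med, pct], axis=1)
        return out


def cluster_profile(values: pd.DataFrame, labels,
                    positive_thresholds: Mapping[str, float] | None = None,
                    cluster_order: Sequence | None = None) -> ClusterProfile:
    """Summarize transformed marker values per cluster.

    Empty clusters (present in ``cluster_order`` but with no cells) are
    emitted with n = 0 and NaN medians.
    """
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValidationError("labels must align with events")
    order = list(cluster_order) if cluster_order is not None else sorted(pd.unique(labels))
    markers = list(values.columns)
    n = pd.Series(0, index=pd.Index(order, name="cluster"), dtype=int)
    med = pd.DataFrame(np.nan, index=n.index, columns=markers)
    pct = pd.DataFrame(np.nan, index=n.index, columns=markers)
    for cl in order:
        mask = labels == cl
        cnt = int(mask.sum())
        n.loc[cl] = cnt
        if cnt == 0:
            continue
        sub = values.loc[mask]
        med.loc[cl] = sub.median()
        if positive_thresholds is not None:
            for m in markers:
                thr = positive_thresholds.get(m)
                if thr is not None:
                    pct.loc[cl, m] = 100.0 * float((sub[m] > thr).mean())
    return ClusterProfile(n=n, medians=med, percent_positive=pct)
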