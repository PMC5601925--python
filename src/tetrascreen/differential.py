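"""Marker summaries, z-scores and multiplicity-corrected tests.

Conventions: z-scores use the sample SD (ddof=1) by default; the Holm–Šidák
family defaults to all markers within one tissue/specificity comparison;
BH uses the standard step-up at FDR 0.25.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, ValidationError


# ------------------------------------------------------------------ summary
def summarize_markers(values: pd.DataFrame, groups: pd.DataFrame | pd.Series,
                      positive_thresholds: Mapping[str, float] | None = None,
                      ) -> pd.DataFrame:
    """Per-group marker medians and percent-positive.

    ``values``: transformed marker matrix (events x markers).  ``groups``:
    per-event key columns (e.g. specificity, tissue, arm, replicate).  Rows
    for empty groups are flagged (``n = 0``), never dropped.
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_frame()
    if len(groups) != len(values):
        raise ValidationError("groups must align with events")
    markers = list(values.columns)
    joined = pd.concat([groups.reset_index(drop=True),
                        values.reset_index(drop=True)], axis=1)
    keycols = list(groups.columns)
    out_rows = []
    for key, sub in joined.groupby(keycols, dropna=False, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row: dict = dict(zip(keycols, key))
        row["n"] = len(sub)
        for m in markers:
            row[f"{m}:median"] = float(sub[m].median()) if len(sub) else np.nan
            if positive_thresholds and m in positive_thresholds:
                row[f"{m}:pct_pos"] = (100.0 * float((sub[m] > positive_thresholds[m]).mean())
                                       if len(sub) else np.nan)
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# ------------------------------------------------------------------ z-score
@dataclass
class ZScoreMatrix:
    z: pd.DataFrame                  # observations x markers
    constant_markers: list[str]      # flagged, not silently zeroed

    def averaged(self, by: pd.Series | Sequence) -> pd.DataFrame:
        """Average z rows per group (e.g. per T-cell specificity)."""
        return self.z.groupby(pd.Series(list(by), index=self.z.index)).mean()


def zscore(matrix: pd.DataFrame, ddof: int = 1) -> ZScoreMatrix:
    """Column-wise (X - m) / s standardization.

    Markers with zero SD are flagged in ``constant_markers`` and left as NaN.
    """
    if len(matrix) < 2:
        raise ValidationError("z-score needs at least 2 observations per marker")
    m = matrix.mean(axis=0)
    s = matrix.std(axis=0, ddof=ddof)
    constant = [c for c in matrix.columns if s[c] == 0 or not np.isfinite(s[c])]
    z = (matrix - m) / s.replace(0.0, np.nan)
    return ZScoreMatrix(z=z, constant_markers=constant)


# -------------------------------------------------------------------- tests
def t_test_holm_sidak(groups: Sequence[tuple[np.ndarray, np.ndarray]],
                      labels: Sequence[str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Pooled-variance two-sample t-tests with Holm–Šidák step-down adjustment.

    ``groups`` is the declared family: one (x, y) pair per comparison.
    """
    if not groups:
        raise ValidationError("empty test family")
    stats_, pvals = [], []
    for x, y in groups:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < 2 or len(y) < 2:
            raise ValidationError("each group needs n >= 2")
        t, p = stats.ttest_ind(x, y, equal_var=True)
        if np.isnan(p):  # identical constant groups -> no evidence
            t, p = 0.0, 1.0
        stats_.append(float(t))
        pvals.append(float(p))
    # clip p=1 by an ulp so the Sidak log1p term stays finite
    clipped = np.clip(pvals, 0.0, 1.0 - 1e-16)
    reject, p_adj, _, _ = multipletests(clipped, alpha=alpha, method="holm-sidak")
    return pd.DataFrame({
        "comparison": list(labels) if labels is not None else list(range(len(groups))),
        "statistic": stats_,
        "p_raw": pvals,
        "p_adj": np.minimum(p_adj, 1.0),
        "reject": reject,
        "procedure": "holm_sidak",
    })


def bh_fdr(pvalues, q: float = 0.25) -> np.ndarray:
    """Benjamini–Hochberg step-up: reject all p(i) with i <= max{i: p(i) <= i q/m}."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if ok.any():
        k = int(np.max(np.flatnonzero(ok)))
        reject[order[:k + 1]] = True
    return reject


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a non-negative integer 2x2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("Fisher exact needs a 2x2 table")
    if not np.all(np.equal(np.mod(arr, 1), 0)) or np.any(arr < 0):
        raise ValidationError("table entries must be non-negative integers")
    _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(p)


# -------------------------------------------------------------- fold change
def frequency_fold_change(hit_treated: pd.DataFrame,
                          hit_control: pd.DataFrame) -> pd.DataFrame:
    """Treated/control frequency ratios per antigen and tissue.

    Inputs need columns antigen, tissue, frequency and optionally replicate;
    with replicates, per-replicate ratios are averaged and an SEM reported.
    Zero control frequencies yield a flagged undefined ratio (NaN).
    """
    key = ["antigen", "tissue"]
    if "replicate" in hit_treated.columns and "replicate" in hit_control.columns:
        merged = hit_treated.merge(hit_control, on=key + ["replicate"],
                                   suffixes=("_t", "_c"))
        if merged.empty:
            raise ValidationError("no matched antigen/tissue/replicate rows")
        with np.errstate(divide="ignore", invalid="ignore"):
            merged["ratio"] = np.where(merged["frequency_c"] > 0,
                                       merged["frequency_t"] / merged["frequency_c"],
                                       np.nan)
        g = merged.groupby(key)["ratio"]
        out = g.mean().rename("fold_change").to_frame()
        out["sem"] = g.sem()
        out["n_replicates"] = g.count()
        out["undefined"] = g.apply(lambda s: bool(s.isna().any()))
        return out.reset_index()
    merged = hit_treated.merge(hit_control, on=key, suffixes=("_t", "_c"))
    if merged.empty:
        raise ValidationError("no matched antigen/tissue rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["fold_change"] = np.where(merged["frequency_c"] > 0,
                                         merged["frequency_t"] / merged["frequency_c"],
                                         np.nan)
    merged["undefined"] = ~(merged["frequency_c"] > 0)
    return merged[key + ["fold_change", "undefined"]]
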