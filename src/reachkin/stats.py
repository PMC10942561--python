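"""Group-statistics battery.

One-way ANOVA across groups per kinematic parameter, Welch post-hoc
t-tests for parameters whose ANOVA is significant, and per-group Pearson
correlations between kinematic parameters and adaptive-function scores
with Benjamini-Hochberg FDR flagging over the whole correlation table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateVarianceError, UndefinedCorrelationError
from .kinematics import FEATURE_COLUMNS

__all__ = [
    "AnovaResult",
    "PairwiseT",
    "BatteryResult",
    "anova_oneway",
    "posthoc_ttests",
    "pearson_r",
    "benjamini_hochberg",
    "run_battery",
]


@dataclass(frozen=True)
class AnovaResult:
    parameter: Optional[str]
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class PairwiseT:
    parameter: Optional[str]
    pair: tuple
    t: float
    df: float
    p: float


@dataclass
class BatteryResult:
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame


def _as_groups(groups: Sequence) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in out:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    return out


def anova_oneway(groups: Sequence, parameter: Optional[str] = None) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA (between/within decomposition)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    n_total = sum(g.size for g in gs)
    df_between, df_within = len(gs) - 1, n_total - len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0.0:
        if ssb > 0.0:
            raise DegenerateVarianceError(
                "zero within-group variance with distinct group means")
        return AnovaResult(parameter, 0.0, (df_between, df_within), 1.0)
    F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(parameter, float(F), (df_between, df_within), p)


def posthoc_ttests(groups: Sequence, pairs: Optional[Sequence[tuple]] = None,
                   labels: Optional[Sequence] = None,
                   parameter: Optional[str] = None) -> list[PairwiseT]:
    """Welch's unequal-variance t-test for each requested group pair."""
    gs = _as_groups(groups)
    if pairs is None:
        pairs = list(itertools.combinations(range(len(gs)), 2))
    out = []
    for i, j in pairs:
        res = sps.ttest_ind(gs[i], gs[j], equal_var=False)
        name = (labels[i], labels[j]) if labels is not None else (i, j)
        out.append(PairwiseT(parameter, name, float(res.statistic),
                             float(res.df), float(res.pvalue)))
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with p from the t transform (n-2 df)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise UndefinedCorrelationError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise UndefinedCorrelationError("inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def run_battery(features: pd.DataFrame, *, group_col: str = "group",
                feature_cols: Sequence[str] = FEATURE_COLUMNS,
                score_cols: Sequence[str] = ("vabs_com", "vabs_dl", "vabs_soc"),
                alpha: float = 0.05, q: float = 0.05,
                subject_level: bool = False) -> BatteryResult:
    """Run the full battery on a trials x features table.

    Post-hoc Welch tests are computed only for parameters whose ANOVA
    reaches ``alpha``.  Correlations are computed per group x feature x
    score domain (skipping groups with no scores) and FDR-flagged jointly.
    ``subject_level=True`` first averages trials within subject.
    """
    df = features
    if subject_level:
        agg = {c: "mean" for c in (*feature_cols, *score_cols) if c in df.columns}
        df = (df.groupby(["subject_id", group_col], as_index=False, sort=True)
                .agg(agg))
    group_names = sorted(df[group_col].astype(str).unique())
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups in the feature table")
    by_group = {g: df[df[group_col].astype(str) == g] for g in group_names}

    anova_rows, posthoc_rows = [], []
    for feat in feature_cols:
        groups = [by_group[g][feat].to_numpy() for g in group_names]
        res = anova_oneway(groups, parameter=feat)
        anova_rows.append({"parameter": feat, "F": res.F,
                           "df_between": res.df[0], "df_within": res.df[1],
                           "p": res.p})
        if res.p < alpha:
            for pt in posthoc_ttests(groups, labels=group_names, parameter=feat):
                posthoc_rows.append({"parameter": feat,
                                     "group_a": pt.pair[0], "group_b": pt.pair[1],
                                     "t": pt.t, "df": pt.df, "p": pt.p})

    corr_rows = []
    for g in group_names:
        sub = by_group[g]
        for score in score_cols:
            if score not in sub.columns:
                continue
            mask = np.isfinite(sub[score].to_numpy(dtype=float))
            if mask.sum() < 3:
                continue
            for feat in feature_cols:
                x = sub.loc[mask, feat].to_numpy(dtype=float)
                y = sub.loc[mask, score].to_numpy(dtype=float)
                if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                    continue
                r, p = pearson_r(x, y)
                corr_rows.append({"group": g, "feature": feat, "score": score,
                                  "r": r, "p": p})
    correlations = pd.DataFrame(corr_rows,
                                columns=["group", "feature", "score", "r", "p"])
    if len(correlations):
        correlations["fdr_pass"] = benjamini_hochberg(correlations["p"], q=q)
    else:
        correlations["fdr_pass"] = pd.Series(dtype=bool)

    return BatteryResult(
        anova=pd.DataFrame(anova_rows),
        posthoc=pd.DataFrame(posthoc_rows,
                             columns=["parameter", "group_a", "group_b",
                                      "t", "df", "p"]),
        correlations=correlations,
    )
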