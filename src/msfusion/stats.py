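"""Group-level statistics: channel-wise Welch t-tests with BH-FDR on the
10-s HbO responses, Shapiro-Wilk normality checks, and a two-way ANOVA
(skill level x microstate) on duration proportions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .containers import MsfusionError


@dataclass
class ChannelTestTable:
    """Per-channel two-sample test results (one row per LS channel)."""

    table: pd.DataFrame

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant_fdr"].to_numpy()


@dataclass
class AnovaTable:
    table: pd.DataFrame
    normality_p: dict


def channel_ttest(group_a: np.ndarray, group_b: np.ndarray,
                  q: float = 0.05) -> ChannelTestTable:
    """Welch two-sample t per channel on subject-level response summaries.

    ``group_a`` / ``group_b`` are (n_subjects, n_channels) arrays of each
    subject's mean HbO over the 10-s response window. Unequal variances
    are assumed (Welch); BH-FDR flags are attached at level ``q``.
    """
    A = np.atleast_2d(np.asarray(group_a, float))
    B = np.atleast_2d(np.asarray(group_b, float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise MsfusionError("need at least 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise MsfusionError("channel count mismatch between groups")
    t, p = scipy.stats.ttest_ind(A, B, axis=0, equal_var=False)
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    same_mean = np.isclose(A.mean(axis=0), B.mean(axis=0))
    t = np.where(degenerate & same_mean, 0.0, t)
    p = np.where(degenerate & same_mean, 1.0, p)
    undefined = degenerate & ~same_mean
    flags = np.zeros(p.size, bool)
    valid = ~undefined
    if valid.any():
        flags[valid] = fdr_bh(p[valid], q=q)
    table = pd.DataFrame({
        "channel": np.arange(1, p.size + 1),
        "mean_a": A.mean(axis=0),
        "mean_b": B.mean(axis=0),
        "t": t,
        "p": p,
        "significant_fdr": flags,
        "undefined": undefined,
    })
    return ChannelTestTable(table=table)


def fdr_bh(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any(~np.isfinite(p)):
        raise MsfusionError("p-values must be finite")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(x, float)
    if not (3 <= x.size <= 5000):
        raise MsfusionError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise MsfusionError("constant sample; W undefined")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def anova_two_way(table: pd.DataFrame, response: str = "proportion",
                  factor_a: str = "skill", factor_b: str = "state"
                  ) -> AnovaTable:
    """Two-way ANOVA with interaction, type-II sums of squares.

    ``table`` holds one observation per subject x state: the proportion of
    total time spent in each microstate, with the subject's skill group.
    Shapiro-Wilk p-values per skill group are reported alongside (they do
    not gate the ANOVA).
    """
    for colname in (response, factor_a, factor_b):
        if colname not in table.columns:
            raise MsfusionError(f"missing column '{colname}'")
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise MsfusionError(f"factor '{f}' has a single level")
    normality = {}
    for level, sub in table.groupby(factor_a):
        vals = sub[response].to_numpy()
        try:
            _, normality[str(level)] = shapiro_wilk(vals)
        except MsfusionError:
            normality[str(level)] = np.nan
    model = smf.ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": "interaction",
        "Residual": "residual",
    })
    return AnovaTable(table=aov, normality_p=normality)


def duration_proportion_table(stats_by_subject: dict, groups: dict
                              ) -> pd.DataFrame:
    """Long-format table of per-subject, per-state coverage proportions.

    ``stats_by_subject`` maps subject id -> coverage vector (length K);
    ``groups`` maps subject id -> group label.
    """
    rows = []
    for sub, cov in stats_by_subject.items():
        for j, c in enumerate(np.asarray(cov, float)):
            rows.append({"subject": sub, "skill": groups[sub],
                         "state": j + 1, "proportion": c})
    return pd.DataFrame(rows)
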