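"""Downstream statistics on untargeted metabolite feature tables.

The pipeline consumes an intensity matrix (samples x features, missing
allowed) with each sample tagged as community spent medium or fresh-medium
reference. Features missing in more than 80% of samples are removed; each
retained feature is tested spent vs fresh with a two-sided Welch t-test and
called consumed (significantly lower in spent medium), produced
(significantly higher) or unchanged. Dissimilarity analysis of whole
metabolite profiles reuses the community-structure chain with missing
values imputed as 0 (not detected); t-tests always use observed values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .structure import OrdinationResult, ordination
from .types import ValidationError

ROLES = ("community_spent", "fresh_medium")


@dataclass
class FeatureMatrix:
    """Intensity matrix with per-sample roles and optional annotations."""

    intensities: pd.DataFrame  # samples x features, NaN = missing
    roles: pd.Series  # sample -> role
    environments: pd.Series | None = None  # sample -> environment label
    communities: pd.Series | None = None  # sample -> community label
    annotation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_roles = self.intensities.index.difference(self.roles.index)
        if len(missing_roles):
            raise ValidationError(f"samples without a role: {list(missing_roles)[:5]}")
        bad = set(self.roles.loc[self.intensities.index]) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown sample role(s): {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def subset_environment(self, environment: str) -> "FeatureMatrix":
        if self.environments is None:
            return self
        idx = self.environments.index[self.environments == environment]
        idx = self.intensities.index.intersection(idx)
        return FeatureMatrix(
            self.intensities.loc[idx],
            self.roles.loc[idx],
            self.environments.loc[idx],
            self.communities.loc[idx] if self.communities is not None else None,
            self.annotation,
        )


def filter_features(matrix: FeatureMatrix, max_na_frac: float = 0.8) -> tuple[FeatureMatrix, list[str]]:
    """Drop features missing in strictly more than ``max_na_frac`` of samples.

    Returns (filtered matrix, list of dropped feature ids).
    """
    na_frac = matrix.intensities.isna().mean(axis=0)
    dropped = list(na_frac.index[na_frac > max_na_frac])
    kept = matrix.intensities.drop(columns=dropped)
    out = FeatureMatrix(kept, matrix.roles, matrix.environments, matrix.communities, matrix.annotation)
    return out, dropped


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Zero variance in both groups with equal means gives p = 1 (no evidence
    of change); zero variance with different means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 observed values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def call_consumption_production(
    matrix: FeatureMatrix,
    environment: str | None = None,
    alpha: float = 0.05,
    log: bool = False,
) -> pd.DataFrame:
    """Per-feature consumed / produced / unchanged calls, spent vs fresh medium.

    ``log=True`` tests log-transformed intensities (variance-stabilized
    mode, invariant to global rescaling); the default tests raw values.
    Tests use observed values only — missing entries are never imputed here.
    Returns a DataFrame with columns feature, call, p_raw, p_adjusted (BH),
    mean_spent, mean_fresh.
    """
    m = matrix.subset_environment(environment) if environment is not None else matrix
    spent = m.intensities.loc[m.roles.loc[m.intensities.index] == "community_spent"]
    fresh = m.intensities.loc[m.roles.loc[m.intensities.index] == "fresh_medium"]
    if len(spent) < 2 or len(fresh) < 2:
        raise ValidationError("need >= 2 spent and >= 2 fresh replicates")
    rows = []
    for feat in m.feature_ids:
        a = spent[feat].dropna().to_numpy(float)
        b = fresh[feat].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            rows.append((feat, "unchanged", np.nan, np.nan, np.nan))
            continue
        ta, tb = (np.log(a + 1e-12), np.log(b + 1e-12)) if log else (a, b)
        p = welch_ttest(ta, tb)
        mean_spent, mean_fresh = float(a.mean()), float(b.mean())
        if p < alpha and mean_spent < mean_fresh:
            call = "consumed"
        elif p < alpha and mean_spent > mean_fresh:
            call = "produced"
        else:
            call = "unchanged"
        rows.append((feat, call, p, mean_spent, mean_fresh))
    df = pd.DataFrame(rows, columns=["feature", "call", "p_raw", "mean_spent", "mean_fresh"])
    ok = df["p_raw"].notna()
    df["p_adjusted"] = np.nan
    if ok.any():
        df.loc[ok, "p_adjusted"] = multipletests(df.loc[ok, "p_raw"], method="fdr_bh")[1]
    if matrix.annotation:
        df["metabolite"] = df["feature"].map(dict(matrix.annotation)).fillna("")
    return df[["feature", "call", "p_raw", "p_adjusted", "mean_spent", "mean_fresh"]
              + (["metabolite"] if matrix.annotation else [])]


def profile_dissimilarity(
    matrix: FeatureMatrix,
    groups: pd.Series | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> OrdinationResult:
    """Bray-Curtis ordination of metabolite profiles (missing imputed as 0)."""
    filled = matrix.intensities.fillna(0.0)
    if groups is None and matrix.environments is not None:
        groups = matrix.environments
    return ordination(filled, groups=groups, n_perm=n_perm, seed=seed)
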