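"""Pairwise strain relationships from dropout experiments, and keystone impact.

The core statistic is r_abs: the ratio of a strain y's absolute abundance in
the dropout community lacking strain x to its abundance in the full
consortium (replicate medians). r_abs > 1 means x affects y negatively
(y increases when x is removed); r_abs < 1 means the relationship is
positive. Detection-limit logic supplies two further categories: exclusion
(y detected only when x is absent) and positive dependency (y detectable
only when x is present); pairs undetected in both communities are below_DTL.

Significance of abundance shifts uses the two-sided Wilcoxon rank-sum test
(exact enumeration for small tie-free samples); keystone impact counts the
species significantly affected by one strain's removal in one environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceTable, ValidationError

CATEGORIES = ("negative", "positive", "exclusion", "positive_dependency", "below_DTL")


@dataclass(frozen=True)
class StrainRelationship:
    """r_abs plus categorical call for one (focal x, affected y, environment)."""

    focal_x: str
    affected_y: str
    environment: str
    r_abs: float  # NaN when undefined (exclusion / positive_dependency / below_DTL)
    category: str
    p_raw: float
    p_adjusted: float
    significant: bool
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "focal_x": self.focal_x,
            "affected_y": self.affected_y,
            "environment": self.environment,
            "r_abs": self.r_abs,
            "category": self.category,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
            "note": self.note,
        }


@dataclass(frozen=True)
class KeystoneImpact:
    """How many (and which) species a strain's removal significantly affects."""

    focal_x: str
    environment: str
    n_affected: int
    affected_set: tuple[str, ...]
    n_affected_wilcoxon: int  # Wilcoxon-significant shifts only
    n_affected_bh: int  # count using BH-adjusted p instead of raw


def compute_r_abs(
    y_dropout: Sequence[float],
    y_full: Sequence[float],
    stat: str = "median",
) -> float:
    """r_abs = median(y in dropout) / median(y in full consortium).

    Censored replicates enter as 0 (their reported value). Returns NaN when
    the full-consortium median is 0 (ratio undefined; classification then
    falls to the detection-limit categories). ``stat="mean"`` switches both
    aggregates to arithmetic means.
    """
    a = np.asarray(y_dropout, dtype=float)
    b = np.asarray(y_full, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("replicate vectors must be non-empty")
    agg = np.median if stat == "median" else np.mean
    denom = float(agg(b))
    if denom == 0:
        return float("nan")
    return float(agg(a)) / denom


def _detected(censored: np.ndarray) -> bool:
    """Strictly more than half of the replicates above the detection limit."""
    c = np.asarray(censored, dtype=bool)
    return (~c).sum() > c.size / 2


def _never(censored: np.ndarray) -> bool:
    return bool(np.asarray(censored, dtype=bool).all())


def classify_relationship(
    y_dropout: Sequence[float],
    dropout_censored: Sequence[bool],
    y_full: Sequence[float],
    full_censored: Sequence[bool],
    stat: str = "median",
) -> tuple[str, float, str]:
    """Assign exactly one relationship category; returns (category, r_abs, note).

    Rules, in order: both never detected -> below_DTL; never in full but
    detected in dropout -> exclusion; never in dropout but detected in full
    -> positive_dependency; otherwise the sign of r_abs decides (r_abs > 1
    negative, r_abs < 1 positive; exactly 1 is called positive — the weaker
    claim — and flagged neutral in the note).
    """
    dc = np.asarray(dropout_censored, dtype=bool)
    fc = np.asarray(full_censored, dtype=bool)
    if dc.size == 0 or fc.size == 0:
        raise ValidationError("replicate vectors must be non-empty")
    if _never(dc) and _never(fc):
        return "below_DTL", float("nan"), ""
    if _never(fc) and _detected(dc):
        return "exclusion", float("nan"), ""
    if _never(dc) and _detected(fc):
        return "positive_dependency", float("nan"), ""
    r = compute_r_abs(y_dropout, y_full, stat=stat)
    if np.isnan(r):
        # detected in neither group by the majority rule but not "never":
        # fall back to below_DTL-like degenerate call
        return "below_DTL", float("nan"), "degenerate: zero median in full consortium"
    if r > 1:
        return "negative", r, ""
    note = "neutral: r_abs exactly 1" if r == 1 else ""
    return "positive", r, note


def wilcoxon_rank_sum(y_dropout: Sequence[float], y_full: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p for a shift between the two replicate groups.

    Exact enumeration of the rank-sum distribution when both groups have at
    most 12 replicates and the pooled data are tie-free; otherwise the normal
    approximation with continuity correction. Two identical constant groups
    give p = 1.
    """
    a = np.asarray(y_dropout, dtype=float)
    b = np.asarray(y_full, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("need >= 3 replicates per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and a.size <= 12 and b.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def _pairs_in(
    table: AbundanceTable,
    dropout_community: str,
    full_community: str,
    environment: str,
    strains: Iterable[str],
    level: str,
):
    for y in strains:
        yd, cd = table.replicate_values(y, dropout_community, environment, level=level)
        yf, cf = table.replicate_values(y, full_community, environment, level=level)
        yield y, (yd, cd), (yf, cf)


def relationship_records(
    table: AbundanceTable,
    focal_x: str,
    environment: str,
    full_community: str = "full",
    dropout_community: str | None = None,
    alpha: float = 0.05,
    level: str = "well",
    stat: str = "median",
) -> list[StrainRelationship]:
    """All (focal_x -> y) relationships in one environment, BH-adjusted within the family."""
    if dropout_community is None:
        dropout_community = f"minus_{focal_x}"
    strains = sorted(set(table.data["strain_id"]) - {focal_x})
    if not strains:
        raise ValidationError("no affected strains to evaluate")
    envs = set(table.samples["environment"])
    if environment not in envs:
        raise ValidationError(f"environment {environment!r} not present in the table")
    comms = set(table.samples["community"])
    if full_community not in comms:
        raise ValidationError(f"missing full-consortium reference for environment {environment!r}")

    rows = []
    for y, (yd, cd), (yf, cf) in _pairs_in(
        table, dropout_community, full_community, environment, strains, level
    ):
        if y == focal_x:
            raise ValidationError("self-relationship is undefined")
        category, r, note = classify_relationship(yd, cd, yf, cf, stat=stat)
        p = wilcoxon_rank_sum(yd, yf)
        rows.append((y, category, r, note, p))
    p_adj = multipletests([p for *_, p in rows], method="fdr_bh")[1]
    return [
        StrainRelationship(
            focal_x=focal_x,
            affected_y=y,
            environment=environment,
            r_abs=r,
            category=category,
            p_raw=p,
            p_adjusted=float(pa),
            significant=p < alpha,
            note=note,
        )
        for (y, category, r, note, p), pa in zip(rows, p_adj)
    ]


def keystone_impact(
    table: AbundanceTable,
    focal_x: str,
    environment: str,
    full_community: str = "full",
    alpha: float = 0.05,
    level: str = "well",
) -> KeystoneImpact:
    """Count species significantly affected by removing ``focal_x`` in one environment.

    A species y counts as affected when its dropout-vs-full Wilcoxon p (raw,
    matching per-panel asterisk conventions) is below ``alpha`` OR its
    category is exclusion / positive dependency. The Wilcoxon-only and
    BH-adjusted counts are reported alongside.
    """
    recs = relationship_records(
        table, focal_x, environment, full_community=full_community, alpha=alpha, level=level
    )
    affected = [
        r.affected_y
        for r in recs
        if r.p_raw < alpha or r.category in ("exclusion", "positive_dependency")
    ]
    n_wilcoxon = sum(r.p_raw < alpha for r in recs)
    n_bh = sum(
        1
        for r in recs
        if r.p_adjusted < alpha or r.category in ("exclusion", "positive_dependency")
    )
    return KeystoneImpact(
        focal_x=focal_x,
        environment=environment,
        n_affected=len(affected),
        affected_set=tuple(affected),
        n_affected_wilcoxon=n_wilcoxon,
        n_affected_bh=n_bh,
    )


def relationship_matrix(
    table: AbundanceTable,
    environments: Sequence[str] | None = None,
    full_community: str = "full",
    alpha: float = 0.05,
    level: str = "well",
) -> pd.DataFrame:
    """One record per ordered (x, y, environment) across every dropout community.

    Dropout communities are recognized by the ``minus_<strain>`` label.
    BH adjustment is applied within each (x, environment) family.
    """
    if environments is None:
        environments = table.environments
    dropouts = sorted(
        c.removeprefix("minus_") for c in table.communities if c.startswith("minus_")
    )
    records: list[StrainRelationship] = []
    for env in environments:
        for x in dropouts:
            records.extend(
                relationship_records(
                    table, x, env, full_community=full_community, alpha=alpha, level=level
                )
            )
    return pd.DataFrame([r.as_dict() for r in records])


def conserved_relationships(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairs whose category is identical across every environment in the matrix."""
    n_env = matrix["environment"].nunique()
    g = matrix.groupby(["focal_x", "affected_y"])["category"]
    agg = g.agg(["nunique", "first", "count"])
    keep = agg[(agg["nunique"] == 1) & (agg["count"] == n_env)]
    out = keep.reset_index()[["focal_x", "affected_y", "first"]]
    return out.rename(columns={"first": "category"})


def delta_ph(records: Iterable) -> pd.DataFrame:
    """Per-record ΔpH = spent-culture pH minus fresh-medium pH.

    Accepts PHRecord objects or a DataFrame with columns sample_id,
    ph_spent, ph_fresh. Returns the per-sample ΔpH table; aggregate with
    :func:`delta_ph_summary` for community x environment medians.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [{"sample_id": r.sample_id, "ph_spent": r.ph_spent, "ph_fresh": r.ph_fresh} for r in records]
        )
    df["delta_ph"] = df["ph_spent"] - df["ph_fresh"]
    return df


def delta_ph_summary(ph_df: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Median ΔpH per (community, environment)."""
    df = delta_ph(ph_df).merge(samples[["sample_id", "community", "environment"]], on="sample_id")
    out = (
        df.groupby(["community", "environment"], as_index=False)["delta_ph"]
        .median()
        .rename(columns={"delta_ph": "median_delta_ph"})
    )
    return out
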