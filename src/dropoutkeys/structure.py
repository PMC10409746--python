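"""Community-structure analysis: Bray-Curtis, PCoA, confidence ellipses, PERMANOVA.

Ordination runs on raw absolute abundances (no transformation) by default;
a log10(x + dtl) variant is available behind a flag. Outlier flagging uses
each group's own 95% confidence ellipse in the first two principal
coordinate axes. PERMANOVA follows the one-way pseudo-F construction from
within/between sums of squared dissimilarities with a permutation p-value
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); pairwise comparisons are
Benjamini-Hochberg adjusted. Permutations are reproducible regardless of
evaluation order: each comparison derives its own RNG substream from the
master seed and a hash of the comparison label.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .types import ValidationError


@dataclass
class OrdinationResult:
    bc_matrix: pd.DataFrame
    coords: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    group_ellipses: dict = field(default_factory=dict)
    outlier_flags: pd.Series | None = None
    permanova: pd.DataFrame | None = None


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample rows.

    BC(u, v) = 1 - 2 sum_i min(u_i, v_i) / sum_i (u_i + v_i). Censored
    entries are expected to already carry 0. Raises when a sample is
    all-zero (BC undefined), naming the sample.
    """
    X = profiles.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("abundance profiles must be non-negative")
    zero = profiles.index[X.sum(axis=1) == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s) have undefined Bray-Curtis: {list(zero)}")
    # explicit min-sum form (equivalent to scipy's braycurtis for x >= 0)
    n = X.shape[0]
    mins = np.zeros((n, n))
    for i in range(n):
        mins[i] = np.minimum(X[i], X[:, :]).sum(axis=1)
    totals = X.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    bc = 1.0 - 2.0 * mins / denom
    np.fill_diagonal(bc, 0.0)
    bc = np.clip(bc, 0.0, 1.0)
    return pd.DataFrame(bc, index=profiles.index, columns=profiles.index)


def log_transform(profiles: pd.DataFrame, dtl_map: Mapping[str, float]) -> pd.DataFrame:
    """log10(x + dtl) variance-stabilized variant for ordination."""
    offs = np.array([dtl_map.get(c, 1.0) for c in profiles.columns], dtype=float)
    return np.log10(profiles + offs)


def pcoa(bc_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical metric MDS (principal coordinates) of a dissimilarity matrix.

    Returns (coords, eigenvalues, proportion_explained). Eigenvalues are
    reported in decreasing order including any negative ones; coordinates
    keep only positive-eigenvalue axes. Proportions of explained variance
    use positive eigenvalues only. The sign of each axis is fixed by making
    its largest-magnitude coordinate positive.
    """
    D = bc_matrix.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else np.zeros(n, bool)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    prop = np.where(evals > 0, evals, 0.0)
    prop = prop / prop.sum() if prop.sum() > 0 else prop
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=bc_matrix.index, columns=cols), evals, prop


@dataclass(frozen=True)
class GroupEllipse:
    center: np.ndarray
    covariance: np.ndarray
    quantile: float  # chi-square(2) quantile bounding the ellipse


def confidence_ellipse_outliers(
    coords: pd.DataFrame,
    groups: pd.Series,
    level: float = 0.95,
) -> tuple[dict[str, GroupEllipse], pd.Series]:
    """Per-group bivariate-normal 95% ellipses on the first two axes, plus outlier flags.

    A sample is an outlier when its squared Mahalanobis distance to its own
    group's (mean, covariance) exceeds the chi-square(2 df) quantile at
    ``level`` (5.991 at 0.95). Singular group covariances get a small ridge
    (1e-9 x trace) and a warning.
    """
    import warnings

    xy = coords.iloc[:, :2].to_numpy(dtype=float)
    groups = groups.loc[coords.index]
    q = float(chi2.ppf(level, df=2))
    ellipses: dict[str, GroupEllipse] = {}
    flags = pd.Series(False, index=coords.index)
    for g, idx in groups.groupby(groups).groups.items():
        pts = coords.loc[idx].iloc[:, :2].to_numpy(dtype=float)
        if pts.shape[0] < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 samples")
        mu = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
            ridge = 1e-9 * max(np.trace(cov), 1e-30)
            cov = cov + ridge * np.eye(2)
            warnings.warn(f"singular covariance for group {g!r}; ridge added")
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", pts - mu, inv, pts - mu)
        ellipses[str(g)] = GroupEllipse(center=mu, covariance=cov, quantile=q)
        flags.loc[idx] = d2 > q
    return ellipses, flags


def _pseudo_f(D2: np.ndarray, labels: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from a squared-dissimilarity matrix."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    a = groups.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _comparison_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def permanova(
    bc_matrix: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
    label: str = "overall",
) -> dict:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Returns a dict with pseudo-F, R² (between-group sum of squares over
    total), and the permutation p-value. Samples are put into a canonical
    order before permuting so the result is invariant to input row order.
    """
    order = sorted(bc_matrix.index)
    D = bc_matrix.loc[order, order].to_numpy(dtype=float)
    labels = groups.loc[order].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise ValidationError(f"group(s) with a single sample: {list(bad)}")
    D2 = D**2
    n, a = D.shape[0], uniq.size
    f_obs = _pseudo_f(D2, labels)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    r2 = (ss_total - ssw) / ss_total
    rng = _comparison_rng(seed, label)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(D2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"comparison": label, "pseudo_F": float(f_obs), "R2": float(r2), "p": float(p), "n_perm": n_perm}


def pairwise_permanova(
    bc_matrix: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise group comparisons, BH-adjusted."""
    levels = sorted(pd.unique(groups.loc[bc_matrix.index]))
    rows = []
    for g1, g2 in combinations(levels, 2):
        idx = groups.index[groups.isin([g1, g2])].intersection(bc_matrix.index)
        sub = bc_matrix.loc[idx, idx]
        rows.append(permanova(sub, groups, n_perm=n_perm, seed=seed, label=f"{g1} vs {g2}"))
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def ordination(
    profiles: pd.DataFrame,
    groups: pd.Series | None = None,
    level: float = 0.95,
    n_perm: int = 9999,
    seed: int = 0,
    pairwise: bool = False,
) -> OrdinationResult:
    """Full chain: Bray-Curtis -> PCoA -> per-group ellipses/outliers -> PERMANOVA."""
    bc = bray_curtis(profiles)
    coords, evals, prop = pcoa(bc)
    result = OrdinationResult(bc_matrix=bc, coords=coords, eigenvalues=evals, proportion_explained=prop)
    if groups is not None:
        groups = groups.loc[coords.index]
        if coords.shape[1] >= 2 and groups.value_counts().min() >= 3:
            result.group_ellipses, result.outlier_flags = confidence_ellipse_outliers(
                coords, groups, level=level
            )
        if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
            overall = permanova(bc, groups, n_perm=n_perm, seed=seed)
            rows = [overall]
            if pairwise and groups.nunique() > 2:
                pw = pairwise_permanova(bc, groups, n_perm=n_perm, seed=seed)
                rows.extend(pw.to_dict("records"))
            df = pd.DataFrame(rows)
            if "p_adjusted" not in df:
                df["p_adjusted"] = df["p"]
            df.loc[df["comparison"] == "overall", "p_adjusted"] = df.loc[
                df["comparison"] == "overall", "p"
            ]
            result.permanova = df
    return result
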