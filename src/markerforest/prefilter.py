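"""Pre-filtering of mass features before model-based selection.

Three stages: a minimum-observation filter, a one-way ANOVA significance
filter used purely for ranking (no multiple-testing correction), and a
redundancy reduction that keeps one representative mass feature per group of
co-eluting, correlated features of the same compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_matrix import FeatureMatrix


@dataclass(frozen=True)
class FeatureGroup:
    """Group of same-fraction, co-eluting mass features of one compound."""

    group_id: str
    feature_ids: tuple[str, ...]
    fraction: str
    retention_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ValueError("empty feature group")


@dataclass
class FilterReport:
    """Per-feature ANOVA p-values and filter outcomes.

    ``table`` columns: p_value, n_missing, degenerate, passed.  A degenerate
    feature (no variance at all after imputation) is flagged and never passes.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def passed_ids(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def to_tsv(self, path: str | Path, groups: Sequence[FeatureGroup] | None = None) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        if groups is not None:
            gid = {f: g.group_id for g in groups for f in g.feature_ids}
            out["group_id"] = [gid.get(f, "") for f in out.index]
        out.to_csv(path, sep="\t")


def _labels_of(matrix: FeatureMatrix, labels) -> pd.Series:
    if labels is None:
        return matrix.class_labels
    if isinstance(labels, pd.Series):
        return labels.reindex(matrix.sample_ids)
    return pd.Series(list(labels), index=matrix.sample_ids)


def min_observation_filter(
    matrix: FeatureMatrix, labels=None, min_obs: int = 10
) -> FeatureMatrix:
    """Drop sparse features using the pre-imputation missing mask.

    A feature is kept iff it has at least ``min_obs`` observations across the
    complete set of samples *and* there exists at least one sample class in
    which it is observed in 100 % of that class's samples.
    """
    lab = _labels_of(matrix, labels)
    observed = ~matrix.missing.to_numpy()
    n_obs = observed.sum(axis=1)
    complete_somewhere = np.zeros(matrix.n_features, dtype=bool)
    for cls in lab.unique():
        cols = np.flatnonzero((lab == cls).to_numpy())
        complete_somewhere |= observed[:, cols].all(axis=1)
    keep = (n_obs >= min_obs) & complete_somewhere
    return matrix.subset_features(list(matrix.values.index[keep]))


def anova_filter(
    matrix: FeatureMatrix, labels=None, alpha: float = 1e-5
) -> FilterReport:
    """One-way fixed-effects F-test per feature; pass iff ``p < alpha``.

    Runs on the imputed matrix.  Used for ranking only: no normality or
    homoscedasticity checks and no multiple-testing correction.  Features with
    zero variance everywhere are flagged degenerate and never pass.
    """
    lab = _labels_of(matrix, labels)
    classes = lab.unique()
    if len(classes) < 2:
        raise ValueError("anova_filter needs >= 2 classes")
    counts = lab.value_counts()
    small = counts.index[counts < 2].tolist()
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    if not matrix.is_imputed:
        raise ValueError("anova_filter expects an imputed matrix")

    col_groups = [np.flatnonzero((lab == c).to_numpy()) for c in classes]
    V = matrix.values.to_numpy()
    pvals = np.empty(matrix.n_features)
    degenerate = np.zeros(matrix.n_features, dtype=bool)
    for i in range(matrix.n_features):
        samples = [V[i, cols] for cols in col_groups]
        if np.ptp(V[i]) == 0:
            degenerate[i] = True
            pvals[i] = np.nan
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*samples)
        if not np.isfinite(p):
            degenerate[i] = True
            pvals[i] = np.nan
        else:
            pvals[i] = p

    n_missing = matrix.missing.to_numpy().sum(axis=1)
    table = pd.DataFrame(
        {
            "p_value": pvals,
            "n_missing": n_missing,
            "degenerate": degenerate,
            "passed": (~degenerate) & (pvals < alpha),
        },
        index=matrix.values.index,
    )
    return FilterReport(table=table, alpha=alpha)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_redundant(
    matrix: FeatureMatrix, retention_tol: float = 1.0, min_corr: float = 0.8
) -> list[FeatureGroup]:
    """Single-linkage grouping of redundant (co-eluting, correlated) features.

    Two same-fraction features are linked when their retentions differ by at
    most ``retention_tol`` and the Pearson correlation of their jointly
    observed values is at least ``min_corr`` (requires >= 3 joint
    observations).  Connected components become groups; singletons allowed.
    """
    fids = matrix.feature_ids
    frac = matrix.features["fraction"].to_numpy()
    ret = matrix.features["retention"].to_numpy(dtype=float)
    V = matrix.values.to_numpy()
    M = matrix.missing.to_numpy()
    n = len(fids)
    uf = _UnionFind(n)
    order = np.argsort(ret, kind="stable")
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if ret[j] - ret[i] > retention_tol:
                break
            if frac[i] != frac[j]:
                continue
            both = ~(M[i] | M[j])
            if both.sum() < 3:
                continue
            x, y = V[i, both], V[j, both]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r >= min_corr:
                uf.union(i, j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(uf.find(i), []).append(i)
    groups: list[FeatureGroup] = []
    for k, (root, idxs) in enumerate(sorted(members.items(), key=lambda kv: min(kv[1]))):
        ids = tuple(fids[i] for i in sorted(idxs))
        rets = ret[idxs]
        groups.append(
            FeatureGroup(
                group_id=f"G{k + 1:04d}",
                feature_ids=ids,
                fraction=str(frac[idxs[0]]),
                retention_window=(float(rets.min()), float(rets.max())),
            )
        )
    return groups


def reduce_redundancy(
    matrix: FeatureMatrix, report: FilterReport, groups: Sequence[FeatureGroup]
) -> FeatureMatrix:
    """Keep one representative per group: the most significant member.

    Ties on p-value are broken by fewest missing values, then lexicographic
    feature_id.  Members missing from the report are a hard error.
    """
    reps: list[str] = []
    for g in groups:
        absent = [f for f in g.feature_ids if f not in report.table.index]
        if absent:
            raise ValueError(f"group {g.group_id} members not in ANOVA report: {absent}")
        sub = report.table.loc[list(g.feature_ids)]
        # degenerate features sort last via +inf p
        key = pd.DataFrame(
            {
                "p": sub["p_value"].fillna(np.inf),
                "miss": sub["n_missing"],
            },
            index=sub.index,
        )
        key = key.sort_values(["p", "miss"], kind="stable")
        best_p, best_m = key.iloc[0]["p"], key.iloc[0]["miss"]
        tied = key.index[(key["p"] == best_p) & (key["miss"] == best_m)]
        reps.append(sorted(tied)[0])
    order = [f for f in matrix.feature_ids if f in set(reps)]
    return matrix.subset_features(order)


def redundancy_map(groups: Sequence[FeatureGroup]) -> dict[str, str]:
    """feature_id → group_id mapping used by the selection stages."""
    return {f: g.group_id for g in groups for f in g.feature_ids}
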