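"""Min/Max ratio marker statistic, rule trees and correlation screening.

The Min/Max ratio of a mass feature for a target class is the minimum
abundance observed within that class divided by the maximum abundance
observed in all other classes, after missing values have been substituted by
the fraction's detection-limit estimate.  A ratio above 1 certifies a gap
between non-overlapping class abundance distributions; ranking compounds by
their best ratio extracts "positive" markers — compounds unique to, or
strongly enriched in, a single class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_matrix import DetectionLimits, FeatureMatrix, impute_detection_limit


@dataclass
class MinMaxTable:
    """Per-(feature, target class) Min/Max ratios after limit substitution.

    ``ratios`` is features × classes; ``best_class`` / ``best_ratio`` give the
    per-feature maximum over target classes.
    """

    ratios: pd.DataFrame
    best_class: pd.Series
    best_ratio: pd.Series

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.ratios.copy()
        out.columns = [f"ratio_{c}" for c in out.columns]
        out["best_class"] = self.best_class
        out["best_ratio"] = self.best_ratio
        out.index.name = "feature_id"
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            out.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class Marker:
    """A selected marker compound with its target class and score."""

    compound: str
    feature_ids: tuple[str, ...]
    target_class: str
    ratio: float
    source: str = "minmax"


@dataclass
class RuleNode:
    """One node of a threshold rule tree.

    Leaves carry ``label``; internal nodes carry ``feature_id``/``threshold``
    and ``below``/``above`` children (value <= threshold goes below).
    """

    label: str | None = None
    feature_id: str | None = None
    threshold: float | None = None
    below: "RuleNode | None" = None
    above: "RuleNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class RuleTree:
    """Ordered threshold rules of depth <= 3 plus training error.

    ``rules`` lists tuples ``(feature_id, threshold, below_label,
    above_label)`` in pre-order; a label of the form ``"rule:<i>"`` refers to
    a deeper rule in the list, anything else is a class label.
    """

    root: RuleNode
    training_errors: int
    n_samples: int

    @property
    def rules(self) -> list[tuple[str, float, str, str]]:
        out: list[tuple[str, float, str, str]] = []

        def label_of(node: RuleNode) -> str:
            if node.is_leaf:
                return node.label  # type: ignore[return-value]
            return f"rule:{walk(node)}"

        def walk(node: RuleNode) -> int:
            idx = len(out)
            out.append(None)  # type: ignore[arg-type]
            below, above = label_of(node.below), label_of(node.above)
            out[idx] = (node.feature_id, node.threshold, below, above)
            return idx

        if not self.root.is_leaf:
            walk(self.root)
        return out

    @property
    def depth(self) -> int:
        def d(node: RuleNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.below), d(node.above))

        return d(self.root)

    def predict(self, matrix: FeatureMatrix) -> pd.Series:
        if not matrix.is_imputed:
            raise ValueError("rule prediction needs an imputed matrix")

        def walk(node: RuleNode, sid: str) -> str:
            if node.is_leaf:
                return node.label  # type: ignore[return-value]
            v = matrix.values.at[node.feature_id, sid]
            return walk(node.below if v <= node.threshold else node.above, sid)

        return pd.Series(
            {sid: walk(self.root, sid) for sid in matrix.sample_ids}, name="predicted"
        )

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: RuleNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}-> {node.label}")
                return
            lines.append(f"{pad}if {node.feature_id} <= {node.threshold:g}:")
            walk(node.below, indent + 1)
            lines.append(f"{pad}else:")
            walk(node.above, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


@dataclass
class CorrelationTable:
    """Per-feature Pearson r/r² against the added-ingredient percentage."""

    table: pd.DataFrame
    threshold_r2: float

    @property
    def passed_ids(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def minmax_ratio(
    matrix: FeatureMatrix, labels=None, limits: DetectionLimits | None = None
) -> MinMaxTable:
    """Min/Max ratio per feature and target class on the substituted matrix.

    ratio(feature, class) = min over class samples / max over all other
    samples, with every missing cell first substituted by its fraction's
    detection limit.  A feature missing everywhere therefore scores exactly 1.
    """
    if labels is None:
        labels = matrix.class_labels
    lab = pd.Series(list(labels), index=matrix.sample_ids) \
        if not isinstance(labels, pd.Series) else labels.reindex(matrix.sample_ids)
    classes = [c for c in dict.fromkeys(lab)]
    if len(classes) < 2:
        raise ValueError("minmax_ratio needs >= 2 classes")
    counts = lab.value_counts()
    empty = [c for c in classes if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"classes with zero samples: {empty}")
    if limits is None:
        from .feature_matrix import estimate_detection_limits

        limits = estimate_detection_limits(matrix)
    sub = impute_detection_limit(matrix, limits)
    V = sub.values.to_numpy()

    ratios = {}
    for c in classes:
        inside = (lab == c).to_numpy()
        mn = V[:, inside].min(axis=1)
        mx = V[:, ~inside].max(axis=1)
        ratios[c] = mn / mx
    table = pd.DataFrame(ratios, index=matrix.values.index)
    best_class = table.idxmax(axis=1)
    best_ratio = table.max(axis=1)
    return MinMaxTable(ratios=table, best_class=best_class, best_ratio=best_ratio)


def select_top_markers(
    table: MinMaxTable,
    k: int = 15,
    fold: float = 10.0,
    groups: Mapping[str, str] | None = None,
) -> list[Marker]:
    """Top-``k`` marker compounds with best Min/Max ratio above ``fold``.

    Redundant features of one compound (per the redundancy map) collapse to a
    single marker carrying the best member ratio; compounds are ranked by
    that best ratio pooled over all target classes.  May return fewer than
    ``k`` markers.
    """
    groups = dict(groups or {})
    best: dict[str, tuple[float, str, list[str]]] = {}
    for fid in table.ratios.index:
        gid = groups.get(fid, fid)
        ratio = float(table.best_ratio[fid])
        cls = str(table.best_class[fid])
        if gid not in best or ratio > best[gid][0]:
            members = best[gid][2] if gid in best else []
            best[gid] = (ratio, cls, members)
        best[gid][2].append(fid)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    markers = []
    for gid, (ratio, cls, members) in ranked[: int(k)]:
        if ratio > fold:
            markers.append(
                Marker(
                    compound=gid,
                    feature_ids=tuple(sorted(members)),
                    target_class=cls,
                    ratio=ratio,
                    source="minmax",
                )
            )
    return markers


def markers_to_tsv(markers: Sequence[Marker], path: str | Path) -> None:
    rows = [
        {
            "compound": m.compound,
            "feature_ids": ",".join(m.feature_ids),
            "target_class": m.target_class,
            "ratio": m.ratio,
            "source": m.source,
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _majority(labels: np.ndarray) -> tuple[str, int]:
    vals, counts = np.unique(labels, return_counts=True)
    i = int(np.argmax(counts))
    return str(vals[i]), int(len(labels) - counts[i])


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    fids: list[str],
    depth_left: int,
) -> tuple[RuleNode, int]:
    label, err = _majority(y[rows])
    leaf = RuleNode(label=label)
    if depth_left == 0 or err == 0:
        return leaf, err

    best: tuple[int, int, float] | None = None  # (errors, feature index, threshold)
    for j in range(X.shape[1]):
        vals = np.unique(X[rows, j])
        if len(vals) < 2:
            continue
        for t in (vals[:-1] + vals[1:]) / 2.0:
            below = rows[X[rows, j] <= t]
            above = rows[X[rows, j] > t]
            e = _majority(y[below])[1] + _majority(y[above])[1]
            if best is None or e < best[0]:
                best = (e, j, float(t))
    if best is None or best[0] >= err:
        return leaf, err  # no split improves on the majority vote
    e, j, t = best
    below_rows = rows[X[rows, j] <= t]
    above_rows = rows[X[rows, j] > t]
    below, eb = _grow(X, y, below_rows, fids, depth_left - 1)
    above, ea = _grow(X, y, above_rows, fids, depth_left - 1)
    node = RuleNode(feature_id=fids[j], threshold=t, below=below, above=above)
    return node, eb + ea


def fit_rule_tree(
    matrix: FeatureMatrix,
    labels=None,
    candidate_features: Sequence[str] | None = None,
    max_depth: int = 3,
) -> RuleTree:
    """Derive a shallow threshold rule set over candidate marker features.

    At each node the split over every candidate feature and every midpoint
    between consecutive observed values is searched exhaustively, minimizing
    training misclassifications; ties prefer fewer rules (no split unless it
    strictly improves) and then the earlier candidate feature.  Thresholds lie
    strictly between two observed values.
    """
    if labels is None:
        labels = matrix.class_labels
    y = np.asarray([str(v) for v in (labels if not isinstance(labels, pd.Series)
                                     else labels.reindex(matrix.sample_ids))])
    fids = list(candidate_features) if candidate_features is not None else matrix.feature_ids
    sub = matrix.subset_features(fids)
    if not sub.is_imputed:
        raise ValueError("fit_rule_tree expects an imputed matrix")
    X = sub.X()
    rows = np.arange(len(y))
    root, errors = _grow(X, y, rows, fids, max_depth)
    return RuleTree(root=root, training_errors=int(errors), n_samples=len(y))


def correlation_screen(
    matrix: FeatureMatrix, amounts=None, threshold_r2: float = 0.450
) -> CorrelationTable:
    """Pearson correlation of abundance with the % of added ingredient.

    Computed over samples with a non-missing amount; a feature passes iff
    r² exceeds ``threshold_r2``.  Features (or amounts) without variance are
    flagged undefined and excluded from the pass list rather than set to 0.
    """
    if amounts is None:
        amounts = pd.to_numeric(matrix.samples["addition_percent"])
    a = pd.Series(list(amounts), index=matrix.sample_ids, dtype=float) \
        if not isinstance(amounts, pd.Series) else amounts.reindex(matrix.sample_ids).astype(float)
    use = a.notna().to_numpy()
    if use.sum() < 3:
        raise ValueError("correlation_screen needs >= 3 samples with amounts")
    x = a.to_numpy()[use]
    if not matrix.is_imputed:
        raise ValueError("correlation_screen expects an imputed matrix")
    V = matrix.values.to_numpy()[:, use]

    if np.std(x) == 0:
        r = np.full(matrix.n_features, np.nan)
    else:
        xc = x - x.mean()
        Vc = V - V.mean(axis=1, keepdims=True)
        denom = np.sqrt((Vc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Vc @ xc) / denom
        r[denom == 0] = np.nan
    r2 = r**2
    table = pd.DataFrame(
        {
            "r": r,
            "r_squared": r2,
            "undefined": ~np.isfinite(r),
            "passed": np.isfinite(r) & (r2 > threshold_r2),
            "n": int(use.sum()),
        },
        index=matrix.values.index,
    )
    return CorrelationTable(table=table, threshold_r2=threshold_r2)


def heatmap_transform(matrix: FeatureMatrix, mode: str = "max_scale_log10") -> pd.DataFrame:
    """Per-feature heat-map transform of a strictly positive imputed matrix.

    ``max_scale_log10``: divide by the feature maximum, then log10.
    ``mean_center_log10``: divide by the feature mean (centring in log
    space), then log10.  Both are order-preserving per feature.  Returns a
    plain features × samples frame (log values may be negative, so the result
    is no longer an abundance matrix).
    """
    if not matrix.is_imputed:
        raise ValueError("heatmap_transform expects an imputed matrix")
    V = matrix.values.to_numpy()
    bad = np.argwhere(V <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive value at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}: log transform undefined"
        )
    if mode == "max_scale_log10":
        T = np.log10(V / V.max(axis=1, keepdims=True))
    elif mode == "mean_center_log10":
        T = np.log10(V / V.mean(axis=1, keepdims=True))
    else:
        raise ValueError(f"unknown heat-map mode {mode!r}")
    return pd.DataFrame(T, index=matrix.values.index, columns=matrix.values.columns)
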