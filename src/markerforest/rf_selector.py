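"""Repeated random-forest training and importance-based feature selection.

The selection strategy: train many forests on repeated random training
splits, aggregate two variable-importance measures — permutation-based mean
decrease in accuracy (MDA) on the held-out half and impurity-based mean
decrease in Gini (MDG) — across the repeats, check that the ranking and the
MDA↔MDG correlation have stabilized, and extract markers with a
take-the-top-variable-out loop: remove the currently most important feature
(plus its redundant partners among the top ranks), retrain, and repeat until
the overall classification error exceeds a ceiling.

scikit-learn provides the forest itself; the MDA here is a vectorized
held-out permutation pass (one stacked ``predict`` per permutation round)
so the iterated selection loop stays fast.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_matrix import FeatureMatrix


@dataclass
class RFConfig:
    """Hyperparameters of the repeated-forest selection procedure.

    ``n_trees`` and ``max_vars_per_node`` follow the study design (1e4 trees,
    up to 500 variables tested per node, i.e. effective mtry =
    min(500, n_features)).  ``train_count`` defaults to half the samples.
    A nonpositive ``error_ceiling`` stops the take-top-out loop after its
    first iteration.
    """

    n_trees: int = 10_000
    max_vars_per_node: int = 500
    n_repeats: int = 10
    train_count: int | None = None
    stratified: bool = True
    error_ceiling: float = 0.33
    top_window: int = 30
    max_iterations: int = 12
    base_seed: int = 0
    mda_permutations: int = 3
    max_split_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class RepeatResults:
    """Raw per-repeat outputs: importance vectors and held-out confusions."""

    mda: pd.DataFrame  # repeats × features
    mdg: pd.DataFrame  # repeats × features
    confusions: list[pd.DataFrame]  # true class rows × predicted class columns
    errors: list[float]  # held-out overall error per repeat, in [0, 1]
    classes: list[str]


@dataclass
class ImportanceTable:
    """Aggregated importance: per-feature mean ± SE of MDA and MDG.

    ``table`` columns: mda_mean, mda_se, mdg_mean, mdg_se, rank (by mean MDA
    descending, ties broken lexicographically).  ``r_squared`` is the squared
    Pearson correlation between the two aggregated measures over features,
    ``None`` when degenerate (either measure constant).
    """

    table: pd.DataFrame
    r_squared: float | None
    n_repeats: int

    def top_ids(self, k: int) -> set[str]:
        return set(self.table.index[self.table["rank"] <= k])

    @property
    def top_feature(self) -> str:
        return str(self.table.index[self.table["rank"] == 1][0])

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# r_squared={'' if self.r_squared is None else repr(self.r_squared)}"
                     f"\tn_repeats={self.n_repeats}\n")
            out.to_csv(fh, sep="\t")


@dataclass
class ConfusionSummary:
    """Aggregated per-class FNR/FDR and overall error over repeated models.

    FNR_c = FN_c/(FN_c+TP_c) over true members; FDR_c = FP_c/(FP_c+TP_c)
    over predicted members.  Models in which a class is never predicted have
    an undefined FDR for that class; those models are excluded from the FDR
    average and counted in ``per_class['n_fdr_defined']`` rather than being
    treated as zero.
    """

    per_class: pd.DataFrame
    overall_error_mean_pct: float
    overall_error_sd_pct: float
    n_models: int
    confusions: list[pd.DataFrame] = field(default_factory=list)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.per_class.copy()
        out.index.name = "class"
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(
                f"# overall_error_mean_pct={self.overall_error_mean_pct!r}"
                f"\toverall_error_sd_pct={self.overall_error_sd_pct!r}"
                f"\tn_models={self.n_models}\n"
            )
            out.to_csv(fh, sep="\t")

    def confusions_to_tsv(self, path: str | Path) -> None:
        rows = []
        for m, cm in enumerate(self.confusions):
            for t in cm.index:
                for p in cm.columns:
                    rows.append({"model": m, "true_class": t, "predicted_class": p,
                                 "count": int(cm.loc[t, p])})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SelectionStep:
    iteration: int
    selected_feature: str
    co_removed: tuple[str, ...]
    overall_error: float
    n_features_remaining: int


@dataclass
class SelectionTrace:
    """Full record of the take-the-top-variable-out iterations."""

    steps: list[SelectionStep]
    stop_reason: str

    def selected_features(self, include_over_ceiling: bool = True,
                          error_ceiling: float | None = None) -> list[str]:
        out: list[str] = []
        for s in self.steps:
            if not include_over_ceiling and error_ceiling is not None \
                    and s.overall_error > error_ceiling:
                continue
            out.append(s.selected_feature)
            out.extend(s.co_removed)
        return out

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        rows = [
            {
                "iteration": s.iteration,
                "selected_feature": s.selected_feature,
                "co_removed": ",".join(s.co_removed),
                "overall_error": s.overall_error,
                "n_features_remaining": s.n_features_remaining,
            }
            for s in self.steps
        ]
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# stop_reason={self.stop_reason}\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# training splits
# ---------------------------------------------------------------------------

def _draw_split(
    labels: np.ndarray, train_count: int, stratified: bool,
    rng: np.random.Generator, max_retries: int,
) -> np.ndarray:
    """Indices of the training subset; guarantees every class is in training."""
    n = len(labels)
    if not 0 < train_count < n:
        raise ValueError(f"train_count must be in (0, {n}), got {train_count}")
    classes, counts = np.unique(labels, return_counts=True)
    if stratified:
        if train_count < len(classes):
            raise ValueError("train_count smaller than the number of classes")
        # proportional allocation with at least one sample per class,
        # largest-remainder rounding to hit train_count exactly
        quota = train_count * counts / n
        base = np.maximum(np.floor(quota).astype(int), 1)
        base = np.minimum(base, counts)
        while base.sum() > train_count:
            i = int(np.argmax(base - quota))
            base[i] -= 1
        rem = quota - base
        while base.sum() < train_count:
            order = np.argsort(-rem, kind="stable")
            for i in order:
                if base[i] < counts[i]:
                    base[i] += 1
                    rem[i] = -np.inf
                    break
            else:  # pragma: no cover - all classes exhausted
                raise ValueError("cannot allocate stratified training split")
        idx = []
        for c, k in zip(classes, base):
            members = np.flatnonzero(labels == c)
            idx.append(rng.choice(members, size=k, replace=False))
        return np.sort(np.concatenate(idx))
    for _ in range(max_retries):
        idx = np.sort(rng.choice(n, size=train_count, replace=False))
        if len(np.unique(labels[idx])) == len(classes):
            return idx
    raise ValueError(
        f"no training split of size {train_count} covered all classes "
        f"after {max_retries} retries; use a stratified split"
    )


def _held_out_mda(
    clf: RandomForestClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation importance on held-out data via stacked predictions.

    For each feature, its held-out column is shuffled and the drop in
    accuracy recorded; one stacked predict call per permutation round covers
    all features at once.
    """
    n_test, p = X_test.shape
    baseline = float(np.mean(clf.predict(X_test) == y_test))
    drops = np.zeros(p)
    # chunk features so the stacked block stays modest in memory
    chunk = max(1, int(5_000_000 // max(1, n_test * p)))
    for _ in range(n_permutations):
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            blocks = []
            for f in feats:
                Xp = X_test.copy()
                Xp[:, f] = Xp[rng.permutation(n_test), f]
                blocks.append(Xp)
            pred = clf.predict(np.vstack(blocks))
            for k, f in enumerate(feats):
                acc = float(np.mean(pred[k * n_test:(k + 1) * n_test] == y_test))
                drops[f] += baseline - acc
    return drops / n_permutations


def train_rf_repeats(
    matrix: FeatureMatrix, labels=None, config: RFConfig | None = None
) -> RepeatResults:
    """Train ``n_repeats`` forests on random training splits of the samples.

    Each repeat r draws its training subset with seed ``base_seed + r``,
    fits a forest (``n_trees`` trees, mtry = min(max_vars_per_node, p)),
    and records permutation MDA, impurity MDG and the held-out confusion
    matrix.  Bit-reproducible under a fixed ``base_seed``.
    """
    config = config or RFConfig()
    if labels is None:
        labels = matrix.class_labels
    y = np.asarray(pd.Series(labels).reindex(matrix.sample_ids)
                   if isinstance(labels, pd.Series) else list(labels))
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    X = matrix.X()
    n, p = X.shape
    train_count = config.train_count if config.train_count is not None else n // 2
    mtry = min(config.max_vars_per_node, p)

    mda_rows, mdg_rows, confusions, errors = [], [], [], []
    for r in range(config.n_repeats):
        seed = int((config.base_seed + r) % 2**31)
        rng = np.random.default_rng(seed)
        train_idx = _draw_split(y, train_count, config.stratified, rng,
                                config.max_split_retries)
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=mtry,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X[train_idx], y[train_idx])
        mdg_rows.append(clf.feature_importances_)
        X_test, y_test = X[test_idx], y[test_idx]
        mda_rows.append(_held_out_mda(clf, X_test, y_test,
                                      config.mda_permutations, rng))
        pred = clf.predict(X_test)
        errors.append(float(np.mean(pred != y_test)))
        cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, q in zip(y_test, pred):
            cm.loc[t, q] += 1
        confusions.append(cm)

    fids = matrix.feature_ids
    return RepeatResults(
        mda=pd.DataFrame(mda_rows, columns=fids),
        mdg=pd.DataFrame(mdg_rows, columns=fids),
        confusions=confusions,
        errors=errors,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_importance(repeats: RepeatResults) -> ImportanceTable:
    """Mean ± standard error of MDA and MDG across repeats, MDA ranking, r²."""
    mda, mdg = repeats.mda, repeats.mdg
    if len(mda) < 2:
        raise ValueError("aggregate_importance needs >= 2 repeats")
    n = len(mda)
    table = pd.DataFrame(
        {
            "mda_mean": mda.mean(axis=0),
            "mda_se": mda.std(axis=0, ddof=1) / np.sqrt(n),
            "mdg_mean": mdg.mean(axis=0),
            "mdg_se": mdg.std(axis=0, ddof=1) / np.sqrt(n),
        }
    )
    order = table.sort_values("mda_mean", ascending=False, kind="stable")
    # ties broken lexicographically: stable sort on index first
    order = (
        table.assign(_fid=table.index)
        .sort_values(["mda_mean", "_fid"], ascending=[False, True], kind="stable")
        .drop(columns="_fid")
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["rank"] = ranks.reindex(table.index).astype(int)

    x, ygini = table["mda_mean"].to_numpy(), table["mdg_mean"].to_numpy()
    if len(x) < 2 or np.std(x) == 0 or np.std(ygini) == 0:
        r2 = None
    else:
        r = float(np.corrcoef(x, ygini)[0, 1])
        r2 = r * r
    return ImportanceTable(table=table, r_squared=r2, n_repeats=n)


def stability_check(history: Sequence[ImportanceTable], k: int = 10,
                    eps: float = 0.01) -> bool:
    """Have the importance aggregates stabilized?

    True iff for the two most recent aggregates the change in MDA↔MDG r² is
    at most ``eps`` and the sets of top-``k`` ranked features are identical.
    """
    if len(history) < 2:
        raise ValueError("stability_check needs >= 2 successive aggregates")
    prev, cur = history[-2], history[-1]
    if prev.r_squared is None and cur.r_squared is None:
        r2_ok = True
    elif prev.r_squared is None or cur.r_squared is None:
        r2_ok = False
    else:
        r2_ok = abs(cur.r_squared - prev.r_squared) <= eps
    kk = min(k, len(cur.table), len(prev.table))
    return bool(r2_ok and prev.top_ids(kk) == cur.top_ids(kk))


def aggregate_confusion(confusions: Sequence[pd.DataFrame]) -> ConfusionSummary:
    """Per-class FNR/FDR (average and maximum) and overall error over models."""
    if not confusions:
        raise ValueError("no confusion matrices")
    classes = list(confusions[0].index)
    for cm in confusions:
        if list(cm.index) != classes or list(cm.columns) != classes:
            raise ValueError("confusion matrices do not share one class set")

    fnr: dict[str, list[float]] = {c: [] for c in classes}
    fdr: dict[str, list[float]] = {c: [] for c in classes}
    overall = []
    for cm in confusions:
        A = cm.to_numpy(dtype=float)
        total = A.sum()
        overall.append(1.0 - np.trace(A) / total)
        for i, c in enumerate(classes):
            tp = A[i, i]
            fn = A[i, :].sum() - tp
            fp = A[:, i].sum() - tp
            if fn + tp > 0:
                fnr[c].append(fn / (fn + tp))
            if fp + tp > 0:
                fdr[c].append(fp / (fp + tp))

    per_class = pd.DataFrame(
        {
            "fnr_avg": [np.mean(fnr[c]) if fnr[c] else np.nan for c in classes],
            "fnr_max": [np.max(fnr[c]) if fnr[c] else np.nan for c in classes],
            "fdr_avg": [np.mean(fdr[c]) if fdr[c] else np.nan for c in classes],
            "fdr_max": [np.max(fdr[c]) if fdr[c] else np.nan for c in classes],
            "n_fnr_defined": [len(fnr[c]) for c in classes],
            "n_fdr_defined": [len(fdr[c]) for c in classes],
        },
        index=classes,
    )
    overall = np.asarray(overall) * 100.0
    sd = float(overall.std(ddof=1)) if len(overall) > 1 else 0.0
    return ConfusionSummary(
        per_class=per_class,
        overall_error_mean_pct=float(overall.mean()),
        overall_error_sd_pct=sd,
        n_models=len(confusions),
        confusions=list(confusions),
    )


# ---------------------------------------------------------------------------
# take-the-top-variable-out selection
# ---------------------------------------------------------------------------

def take_top_out_selection(
    matrix: FeatureMatrix,
    labels=None,
    groups: Mapping[str, str] | None = None,
    config: RFConfig | None = None,
) -> SelectionTrace:
    """Iterative marker extraction by removing the top feature each round.

    Each iteration trains ``n_repeats`` forests on the remaining features,
    records the mean overall held-out error, selects the rank-1 MDA feature
    together with every same-compound feature among the top ``top_window``
    ranks (per the redundancy map), and removes them.  The loop stops when
    the overall error exceeds ``error_ceiling`` (a nonpositive ceiling stops
    after the first iteration), when ``max_iterations`` is reached, or when
    fewer than two features remain ("exhausted").
    """
    config = config or RFConfig()
    groups = dict(groups or {})
    remaining = matrix
    steps: list[SelectionStep] = []
    stop_reason = "max_iterations"
    for it in range(1, config.max_iterations + 1):
        iter_cfg = dataclasses.replace(
            config, base_seed=int((config.base_seed + (it - 1) * 100_003) % 2**31)
        )
        res = train_rf_repeats(remaining, labels, iter_cfg)
        agg = aggregate_importance(res)
        err = float(np.mean(res.errors))
        top = agg.top_feature
        window = agg.top_ids(config.top_window)
        gid = groups.get(top)
        co = tuple(
            sorted(f for f in window if f != top and gid is not None and groups.get(f) == gid)
        )
        removed = [top, *co]
        steps.append(
            SelectionStep(
                iteration=it,
                selected_feature=top,
                co_removed=co,
                overall_error=err,
                n_features_remaining=remaining.n_features,
            )
        )
        if err > config.error_ceiling or config.error_ceiling <= 0:
            stop_reason = "error_ceiling"
            break
        keep = [f for f in remaining.feature_ids if f not in removed]
        if len(keep) < 2:
            stop_reason = "exhausted"
            break
        remaining = remaining.subset_features(keep)
    return SelectionTrace(steps=steps, stop_reason=stop_reason)


def augment_features(
    matrix: FeatureMatrix, parent: FeatureMatrix, extra_ids: Sequence[str]
) -> FeatureMatrix:
    """Union of a selected matrix with manually chosen features of its parent.

    Order-stable: existing features first, then the extras in given order.
    Adding an already-present id warns and does not duplicate; an id unknown
    to the parent is a hard error.
    """
    unknown = [f for f in extra_ids if f not in parent.values.index]
    if unknown:
        raise KeyError(f"unknown feature_id in parent matrix: {unknown}")
    present = set(matrix.feature_ids)
    new_ids = []
    for f in extra_ids:
        if f in present or f in new_ids:
            warnings.warn(f"feature {f!r} already present; not duplicated", stacklevel=2)
        else:
            new_ids.append(f)
    if not new_ids:
        return matrix.copy()
    extra = parent.subset_features(new_ids).subset_samples(matrix.sample_ids)
    values = pd.concat([matrix.values, extra.values], axis=0)
    missing = pd.concat([matrix.missing, extra.missing], axis=0)
    features = pd.concat([matrix.features, extra.features], axis=0)
    return FeatureMatrix(values, missing, features, matrix.samples.copy())
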