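"""Data model and I/O for GC-MS mass-feature abundance matrices.

A *mass feature* is a (retention, nominal m/z) signal extracted from a GC-MS
chromatogram; one compound typically yields several redundant mass features
through electron-impact fragmentation.  This module holds the central
container of the pipeline, :class:`FeatureMatrix` — nonnegative normalized
abundances of mass features (rows) across samples (columns) with an explicit
missing mask — plus the standard manipulations every downstream stage relies
on: reading/writing delimited text, normalization to sample weight and
internal standard, the 100 %-replicate averaging rule, detection-limit
estimation and left-censored imputation, and merging of the chemical
fractions (VOC, POL, SOL) into one joint matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Chemical sub-metabolomes analysed separately.
FRACTIONS = ("VOC", "POL", "SOL")

#: Columns of the per-feature annotation table.
FEATURE_COLUMNS = ("fraction", "retention", "nominal_mz", "compound_group", "annotation")

#: Columns of the per-sample metadata table.
SAMPLE_COLUMNS = (
    "class_label",
    "batch_id",
    "replicate_index",
    "sample_amount",
    "istd_abundance",
    "addition_percent",
)

_FEATURE_ID_RE = re.compile(
    r"^(?P<fraction>[A-Za-z]+)_(?P<retention>\d+(?:\.\d+)?)_(?P<mz>\d+)$"
)


def parse_feature_id(feature_id: str) -> tuple[str, float, int]:
    """Split a ``FRACTION_RETENTION_MZ`` key, e.g. ``"POL_3402.72_191"``.

    Returns ``(fraction, retention, nominal_mz)``.  Raises ``ValueError`` for
    keys that do not follow the convention.
    """
    m = _FEATURE_ID_RE.match(str(feature_id))
    if m is None:
        raise ValueError(f"feature_id {feature_id!r} does not follow FRACTION_RETENTION_MZ")
    return m.group("fraction"), float(m.group("retention")), int(m.group("mz"))


def make_feature_id(fraction: str, retention: float, nominal_mz: int) -> str:
    """Build the canonical ``FRACTION_RETENTION_MZ`` key (retention to 2 dp)."""
    if retention <= 0:
        raise ValueError("retention must be positive")
    if nominal_mz < 1:
        raise ValueError("nominal_mz must be >= 1")
    return f"{fraction}_{retention:.2f}_{int(nominal_mz)}"


@dataclass(frozen=True)
class MassFeature:
    """One mass feature: fraction, retention (RT or RI) and nominal m/z."""

    feature_id: str
    fraction: str
    retention: float
    nominal_mz: int
    compound_group: str | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.retention <= 0:
            raise ValueError(f"{self.feature_id}: retention must be > 0")
        if self.nominal_mz < 1:
            raise ValueError(f"{self.feature_id}: nominal_mz must be >= 1")

    @classmethod
    def from_id(cls, feature_id: str, **kwargs) -> "MassFeature":
        fraction, retention, mz = parse_feature_id(feature_id)
        return cls(feature_id, fraction, retention, mz, **kwargs)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one analysed sample (one chromatogram)."""

    sample_id: str
    class_label: str
    batch_id: str
    replicate_index: int = 1
    sample_amount: float = np.nan
    istd_abundance: float = np.nan
    addition_percent: float = np.nan


class DetectionLimits(dict):
    """Per-fraction detection-limit estimates (minimal observed abundance).

    A thin ``dict`` mapping fraction name to the positive limit, with a
    convenience constructor from a matrix in :func:`estimate_detection_limits`.
    """

    def __init__(self, limits: Mapping[str, float]):
        for frac, lim in limits.items():
            if not np.isfinite(lim) or lim <= 0:
                raise ValueError(f"detection limit for {frac} must be finite and > 0, got {lim}")
        super().__init__(limits)

    def scaled(self, c: float) -> "DetectionLimits":
        return DetectionLimits({f: c * v for f, v in self.items()})


@dataclass
class FeatureMatrix:
    """Mass features × samples abundance matrix with an explicit missing mask.

    ``values`` holds floats with ``NaN`` at missing cells until imputation;
    ``missing`` keeps the original observation mask as provenance even after
    imputation filled the values.  ``features`` / ``samples`` are annotation
    tables indexed by feature_id / sample_id, aligned with ``values``.
    """

    values: pd.DataFrame
    missing: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        missing: np.ndarray,
        features: Sequence[MassFeature],
        samples: Sequence[SampleMeta],
    ) -> "FeatureMatrix":
        fids = [f.feature_id for f in features]
        sids = [s.sample_id for s in samples]
        vals = pd.DataFrame(np.asarray(values, dtype=float), index=fids, columns=sids)
        mask = pd.DataFrame(np.asarray(missing, dtype=bool), index=fids, columns=sids)
        vals = vals.mask(mask)
        feat = pd.DataFrame(
            {
                "fraction": [f.fraction for f in features],
                "retention": [f.retention for f in features],
                "nominal_mz": [f.nominal_mz for f in features],
                "compound_group": [f.compound_group for f in features],
                "annotation": [f.annotation for f in features],
            },
            index=fids,
        )
        samp = pd.DataFrame(
            {
                "class_label": [s.class_label for s in samples],
                "batch_id": [s.batch_id for s in samples],
                "replicate_index": [s.replicate_index for s in samples],
                "sample_amount": [s.sample_amount for s in samples],
                "istd_abundance": [s.istd_abundance for s in samples],
                "addition_percent": [s.addition_percent for s in samples],
            },
            index=sids,
        )
        return cls(vals, mask, feat, samp)

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        fids = self.values.index
        sids = self.values.columns
        if fids.has_duplicates:
            dup = fids[fids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature_id: {dup}")
        if sids.has_duplicates:
            dup = sids[sids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id: {dup}")
        if not (self.missing.index.equals(fids) and self.missing.columns.equals(sids)):
            raise ValueError("missing mask not aligned with values")
        if not self.features.index.equals(fids):
            raise ValueError("feature table not aligned with values")
        if not self.samples.index.equals(sids):
            raise ValueError("sample table not aligned with values")
        observed = self.values.to_numpy()[~self.missing.to_numpy()]
        if observed.size and (np.isnan(observed).any() or (observed < 0).any()):
            raise ValueError("observed cells must be nonnegative finite abundances")

    # -- accessors -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> pd.Series:
        return self.samples["class_label"]

    @property
    def fractions(self) -> list[str]:
        seen: list[str] = []
        for f in self.features["fraction"]:
            if f not in seen:
                seen.append(f)
        return seen

    @property
    def is_imputed(self) -> bool:
        return not self.values.isna().to_numpy().any()

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.missing.copy(), self.features.copy(), self.samples.copy()
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        unknown = [f for f in feature_ids if f not in self.values.index]
        if unknown:
            raise KeyError(f"unknown feature_id: {unknown}")
        idx = list(feature_ids)
        return FeatureMatrix(
            self.values.loc[idx].copy(),
            self.missing.loc[idx].copy(),
            self.features.loc[idx].copy(),
            self.samples.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        unknown = [s for s in sample_ids if s not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown sample_id: {unknown}")
        idx = list(sample_ids)
        return FeatureMatrix(
            self.values[idx].copy(),
            self.missing[idx].copy(),
            self.features.copy(),
            self.samples.loc[idx].copy(),
        )

    def X(self) -> np.ndarray:
        """Samples × features design matrix for model fitting (imputed only)."""
        if not self.is_imputed:
            raise ValueError("matrix still holds missing cells; impute first")
        return self.values.to_numpy().T.copy()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = ["", "NA", "NaN", "nan"]


def read_matrix(
    path: str | Path,
    metadata_path: str | Path,
    zero_is_missing: bool = True,
) -> FeatureMatrix:
    """Read a feature matrix from delimited text plus a sample-metadata table.

    The matrix is TSV with a header row of sample_ids; the first column is
    ``feature_id`` and optional annotation columns (``fraction``,
    ``retention``, ``nominal_mz``, ``compound_group``, ``annotation``) may
    precede the sample columns.  Cells encoded as the empty string, ``NA`` or
    — under the default dialect — a literal ``0`` are treated as missing.
    Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={0: str},
        na_values=_MISSING_TOKENS, keep_default_na=False,
        float_precision="round_trip",
    )
    first = df.columns[0]
    if df[first].duplicated().any():
        dup = df.loc[df[first].duplicated(), first].unique().tolist()
        raise ValueError(f"duplicate feature_id in {path}: {dup}")
    df = df.set_index(first)
    df.index.name = "feature_id"

    ann_cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    sample_cols = [c for c in df.columns if c not in ann_cols]
    if len(set(sample_cols)) != len(sample_cols):
        dup = pd.Index(sample_cols)
        raise ValueError(f"duplicate sample_id in {path}: {dup[dup.duplicated()].unique().tolist()}")

    values = df[sample_cols].apply(pd.to_numeric)
    if zero_is_missing:
        values = values.mask(values == 0)
    mask = values.isna()
    values = values.mask(mask)

    features = pd.DataFrame(index=df.index, columns=list(FEATURE_COLUMNS), dtype=object)
    for c in ann_cols:
        features[c] = df[c]
    # fall back to parsing the id convention for anything not given explicitly
    parsed = [parse_feature_id(fid) for fid in df.index]
    if "fraction" not in ann_cols:
        features["fraction"] = [p[0] for p in parsed]
    if "retention" not in ann_cols:
        features["retention"] = [p[1] for p in parsed]
    if "nominal_mz" not in ann_cols:
        features["nominal_mz"] = [p[2] for p in parsed]
    features["retention"] = pd.to_numeric(features["retention"])
    features["nominal_mz"] = pd.to_numeric(features["nominal_mz"]).astype(int)

    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {metadata_path} lacks a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dup}")
    meta = meta.set_index("sample_id")
    absent = [s for s in meta.index if s not in sample_cols]
    if absent:
        raise ValueError(f"metadata samples absent from matrix: {absent}")
    missing_meta = [s for s in sample_cols if s not in meta.index]
    if missing_meta:
        raise ValueError(f"matrix samples lacking metadata: {missing_meta}")
    samples = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"),
                           columns=list(SAMPLE_COLUMNS), dtype=object)
    for c in SAMPLE_COLUMNS:
        if c in meta.columns:
            samples[c] = meta.loc[sample_cols, c].to_numpy()
    for c in ("sample_amount", "istd_abundance", "addition_percent"):
        samples[c] = pd.to_numeric(samples[c])
    samples["replicate_index"] = pd.to_numeric(samples["replicate_index"]).fillna(1).astype(int)

    return FeatureMatrix(values, mask, features, samples)


def write_matrix(
    matrix: FeatureMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a matrix (and optionally its metadata) as re-readable TSV.

    Missing cells are written as ``NA``.  Float values round-trip bit-exactly
    through ``repr``.
    """
    out = matrix.features[["fraction", "retention", "nominal_mz"]].copy()
    vals = matrix.values.mask(matrix.missing)
    body = pd.concat([out, vals], axis=1)
    body.index.name = "feature_id"
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        body.to_csv(fh, sep="\t", na_rep="NA")
    if metadata_path is not None:
        write_metadata(matrix, metadata_path, header_comment=header_comment)


def write_metadata(
    matrix: FeatureMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        meta.to_csv(fh, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# normalization / replicate handling / imputation / merging
# ---------------------------------------------------------------------------

def normalize(raw: FeatureMatrix) -> FeatureMatrix:
    """Normalize abundances to sample weight and internal-standard abundance.

    ``value' = value / (sample_amount × istd_abundance)``, per sample.  The
    missing mask is unchanged.  Units of the sample amount (mg or g) are
    treated as opaque scalars declared once per matrix.
    """
    amount = pd.to_numeric(raw.samples["sample_amount"])
    istd = pd.to_numeric(raw.samples["istd_abundance"])
    bad = raw.samples.index[~((amount > 0) & (istd > 0))].tolist()
    if bad:
        raise ValueError(f"nonpositive or missing sample_amount/istd_abundance for samples: {bad}")
    divisor = (amount * istd).to_numpy()[np.newaxis, :]
    out = raw.copy()
    out.values = raw.values / divisor
    return FeatureMatrix(out.values, out.missing, out.features, out.samples)


def average_replicates(matrix: FeatureMatrix, group_by: str = "batch_id") -> FeatureMatrix:
    """Average technical replicates per batch under the 100 %-occurrence rule.

    A batch cell is the arithmetic mean of the replicate values iff the
    feature is observed in *every* replicate of that batch; otherwise the
    batch cell is set to not-detected (missing).  The resulting matrix has one
    column per batch.
    """
    if group_by not in matrix.samples.columns:
        raise KeyError(f"unknown batch key {group_by!r}; sample table has {list(matrix.samples.columns)}")
    groups = matrix.samples[group_by]
    batch_order: list[str] = []
    for b in groups:
        if b not in batch_order:
            batch_order.append(b)

    vals = np.empty((matrix.n_features, len(batch_order)))
    mask = np.empty((matrix.n_features, len(batch_order)), dtype=bool)
    meta_rows = []
    V = matrix.values.to_numpy()
    M = matrix.missing.to_numpy()
    for j, b in enumerate(batch_order):
        cols = np.flatnonzero((groups == b).to_numpy())
        sub_mask = M[:, cols]
        fully_observed = ~sub_mask.any(axis=1)
        mean = np.where(sub_mask, 0.0, np.nan_to_num(V[:, cols])).sum(axis=1) / len(cols)
        vals[:, j] = np.where(fully_observed, mean, np.nan)
        mask[:, j] = ~fully_observed
        sub = matrix.samples.iloc[cols]
        labels = sub["class_label"].unique()
        if len(labels) > 1:
            raise ValueError(f"batch {b!r} mixes class labels {labels.tolist()}")
        adds = pd.to_numeric(sub["addition_percent"]).dropna().unique()
        meta_rows.append(
            {
                "class_label": labels[0],
                "batch_id": b,
                "replicate_index": 1,
                "sample_amount": pd.to_numeric(sub["sample_amount"]).mean(),
                "istd_abundance": pd.to_numeric(sub["istd_abundance"]).mean(),
                "addition_percent": adds[0] if len(adds) == 1 else np.nan,
                "n_replicates": len(cols),
            }
        )

    values = pd.DataFrame(vals, index=matrix.values.index, columns=batch_order)
    missing = pd.DataFrame(mask, index=matrix.values.index, columns=batch_order)
    samples = pd.DataFrame(meta_rows, index=pd.Index(batch_order, name="sample_id"))
    return FeatureMatrix(values, missing, matrix.features.copy(), samples)


def estimate_detection_limits(matrix: FeatureMatrix) -> DetectionLimits:
    """Per-fraction minimum of observed (non-missing) normalized abundances."""
    limits: dict[str, float] = {}
    for frac in matrix.fractions:
        rows = matrix.features.index[matrix.features["fraction"] == frac]
        vals = matrix.values.loc[rows].to_numpy()
        mask = matrix.missing.loc[rows].to_numpy()
        observed = vals[~mask]
        if observed.size == 0:
            raise ValueError(f"fraction {frac} has no observed values; cannot estimate a detection limit")
        limits[frac] = float(observed.min())
    return DetectionLimits(limits)


def impute_detection_limit(matrix: FeatureMatrix, limits: DetectionLimits) -> FeatureMatrix:
    """Replace every missing cell by its fraction's detection limit.

    Idempotent; the original missing mask is retained as provenance.
    """
    present = set(matrix.fractions)
    uncovered = sorted(present - set(limits))
    if uncovered:
        raise ValueError(f"detection limits missing for fractions: {uncovered}")
    out = matrix.copy()
    fill = matrix.features["fraction"].map(limits).to_numpy(dtype=float)[:, np.newaxis]
    vals = out.values.to_numpy()
    mask = out.missing.to_numpy()
    vals = np.where(mask & np.isnan(vals), fill, vals)
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return FeatureMatrix(out.values, out.missing, out.features, out.samples)


def combine_fractions(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Row-wise concatenation of per-fraction matrices over a shared sample set."""
    if not matrices:
        raise ValueError("no matrices to combine")
    ref = matrices[0]
    ref_samples = set(ref.sample_ids)
    for m in matrices[1:]:
        diff = ref_samples.symmetric_difference(m.sample_ids)
        if diff:
            raise ValueError(f"sample sets differ between matrices: {sorted(diff)}")
    aligned = [m.subset_samples(ref.sample_ids) for m in matrices]
    all_ids = pd.Index(np.concatenate([m.values.index for m in aligned]))
    if all_ids.has_duplicates:
        dup = all_ids[all_ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature_id across fractions: {dup}")
    values = pd.concat([m.values for m in aligned], axis=0)
    missing = pd.concat([m.missing for m in aligned], axis=0)
    features = pd.concat([m.features for m in aligned], axis=0)
    return FeatureMatrix(values, missing, features, ref.samples.copy())


def split_by_fraction(matrix: FeatureMatrix) -> dict[str, FeatureMatrix]:
    """Inverse of :func:`combine_fractions`: one matrix per fraction present."""
    out: dict[str, FeatureMatrix] = {}
    for frac in matrix.fractions:
        rows = matrix.features.index[matrix.features["fraction"] == frac]
        out[frac] = matrix.subset_features(list(rows))
    return out
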