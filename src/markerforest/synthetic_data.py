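"""Synthetic GC-MS feature matrices with known ground truth.

The generator emulates the statistical structure the marker-discovery
pipeline assumes: compounds represented by several redundant mass features
with correlated abundances (electron-impact fragments with distinct response
factors), class-unique and class-enriched marker compounds next to shared
background and near-limit noise compounds, multiplicative lognormal noise at
the batch and technical-replicate levels, and fraction-specific detection
limits that left-censor low abundances into missing values.  A second
scenario mixes a processed-food background with seed compound profiles
scaled by the percentage of added seed material, with heat-labile compounds
lost and processing-generated compounds appearing in proportion to the
addition.

Every generated matrix comes with a :class:`SyntheticTruth` ledger of the
planted compounds, so recovery tests can compare pipeline output against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_matrix import (
    FeatureMatrix,
    MassFeature,
    SampleMeta,
    make_feature_id,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the raw-seed scenario.

    Defaults mirror a three-class seed study: chia/linseed/sesame with
    12/8/8 marketed batches (28 in total) and 5 technical replicates each;
    one unique and one enriched marker compound per class, planted at 20×
    the fraction's detection limit (enriched markers sit ``enriched_fold``
    lower outside their class); a body of shared background compounds and
    near-limit noise compounds; every compound represented by redundant
    co-eluting features.  Noise is multiplicative lognormal with batch- and
    replicate-level sigmas (natural-log scale).
    """

    class_names: tuple[str, ...] = ("chia", "linseed", "sesame")
    batches_per_class: tuple[int, ...] = (12, 8, 8)
    replicates_per_batch: int = 5
    n_unique_per_class: int = 1
    n_enriched_per_class: int = 1
    n_shared_background: int = 30
    n_noise: int = 20
    redundant_features_per_compound: int = 2
    fraction_probs: tuple[tuple[str, float], ...] = (("VOC", 0.2), ("POL", 0.6), ("SOL", 0.2))
    detection_limit: tuple[tuple[str, float], ...] = (("VOC", 0.1), ("POL", 1.0), ("SOL", 0.5))
    sigma_batch: float = 0.15
    sigma_replicate: float = 0.10
    sigma_feature: float = 0.05
    marker_multiple: float = 20.0
    enriched_fold: float = 5.0
    background_mean_range: tuple[float, float] = (5.0, 100.0)
    noise_mean_range: tuple[float, float] = (1.0, 4.0)
    heat_labile_per_class: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.replicates_per_batch,
            self.n_unique_per_class,
            self.n_enriched_per_class,
            self.n_shared_background,
            self.n_noise,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if len(self.batches_per_class) != len(self.class_names):
            raise ValueError("batches_per_class must align with class_names")
        if min(self.sigma_batch, self.sigma_replicate, self.sigma_feature) < 0:
            raise ValueError("sigmas must be >= 0")
        if self.marker_multiple <= 1 or self.enriched_fold <= 1:
            raise ValueError("marker folds must be > 1")
        if self.redundant_features_per_compound < 1:
            raise ValueError("redundant_features_per_compound must be >= 1")
        total = sum(self.batches_per_class) * self.replicates_per_batch
        if total == 0:
            raise ValueError("configuration implies zero samples")


@dataclass(frozen=True)
class CompoundTruth:
    """Ground truth of one planted compound."""

    compound_id: str
    category: str  # unique | enriched | shared | noise | background | processing
    target_class: str | None
    fraction: str
    feature_ids: tuple[str, ...]
    response_factors: tuple[float, ...]
    retention: float
    class_means: tuple[tuple[str, float], ...]
    heat_labile: bool = False
    processing_product: bool = False

    def class_mean(self, class_label: str) -> float:
        return dict(self.class_means).get(class_label, 0.0)


@dataclass
class SyntheticTruth:
    """Ledger of planted compounds and the limits used for censoring."""

    compounds: list[CompoundTruth]
    detection_limits: dict[str, float]

    def feature_to_compound(self) -> dict[str, str]:
        return {f: c.compound_id for c in self.compounds for f in c.feature_ids}

    def compounds_by_category(self, *categories: str) -> list[CompoundTruth]:
        return [c for c in self.compounds if c.category in categories]

    def marker_compound_ids(self, *categories: str) -> set[str]:
        cats = categories or ("unique", "enriched")
        return {c.compound_id for c in self.compounds if c.category in cats}

    def features_of(self, compound_id: str) -> tuple[str, ...]:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c.feature_ids
        raise KeyError(compound_id)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        rows = [
            {
                "compound_id": c.compound_id,
                "category": c.category,
                "target_class": c.target_class or "",
                "fraction": c.fraction,
                "feature_ids": ",".join(c.feature_ids),
                "response_factors": ",".join(repr(r) for r in c.response_factors),
                "retention": c.retention,
                "class_means": ";".join(f"{k}={v!r}" for k, v in c.class_means),
                "heat_labile": c.heat_labile,
                "processing_product": c.processing_product,
            }
            for c in self.compounds
        ]
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_RET_RANGE = {"VOC": (5.0, 25.0), "POL": (1000.0, 3500.0), "SOL": (1000.0, 3500.0)}


def _draw_features(
    rng: np.random.Generator,
    fraction: str,
    n_features: int,
    used_ids: set[str],
    sigma_feature_jitter: float = 0.05,
) -> tuple[float, list[str], list[float]]:
    """Retention, co-eluting feature ids and response factors for a compound.

    The first feature carries response factor 1.0 (the quantifier ion); the
    rest are fragment ions with smaller response.  Retentions of one
    compound's features sit within 0.1 RI/RT units of each other.
    """
    lo, hi = _RET_RANGE[fraction]
    for _ in range(1000):
        retention = round(float(rng.uniform(lo, hi)), 2)
        mzs = rng.choice(np.arange(70, 350), size=n_features, replace=False)
        fids = [
            make_feature_id(fraction, retention + 0.05 * j, int(mz))
            for j, mz in enumerate(mzs)
        ]
        if not any(f in used_ids for f in fids):
            used_ids.update(fids)
            responses = [1.0] + [float(rng.uniform(0.3, 0.9)) for _ in range(n_features - 1)]
            return retention, fids, responses
    raise RuntimeError("could not draw unique feature ids")  # pragma: no cover


def _lognoise(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def _render_matrix(
    rng: np.random.Generator,
    compounds: Sequence[CompoundTruth],
    samples: Sequence[SampleMeta],
    limits: Mapping[str, float],
    sigma_batch: float,
    sigma_replicate: float,
    sigma_feature: float,
) -> FeatureMatrix:
    """Draw abundances compound-by-compound and censor below the limits."""
    features: list[MassFeature] = []
    rows: list[np.ndarray] = []
    batch_of = [s.batch_id for s in samples]
    batches = list(dict.fromkeys(batch_of))
    class_of = {s.sample_id: s.class_label for s in samples}

    for comp in compounds:
        limit = limits[comp.fraction]
        batch_factor = {b: _lognoise(rng, sigma_batch) for b in batches}
        signal = np.empty(len(samples))
        for j, s in enumerate(samples):
            mean = comp.class_mean(class_of[s.sample_id])
            signal[j] = mean * batch_factor[s.batch_id] * _lognoise(rng, sigma_replicate)
        for fid, resp in zip(comp.feature_ids, comp.response_factors):
            vals = np.array([resp * v * _lognoise(rng, sigma_feature) for v in signal])
            rows.append(vals)
            features.append(
                MassFeature.from_id(fid, compound_group=comp.compound_id)
            )

    values = np.vstack(rows) if rows else np.empty((0, len(samples)))
    limit_per_feature = np.array([limits[f.fraction] for f in features])[:, None] \
        if features else np.empty((0, 1))
    missing = values < limit_per_feature
    values = np.where(missing, np.nan, values)
    return FeatureMatrix.from_arrays(values, missing, features, list(samples))


# ---------------------------------------------------------------------------
# raw-seed scenario
# ---------------------------------------------------------------------------

def generate_seed_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Generate a raw-seed feature matrix plus its ground-truth ledger.

    Deterministic for a fixed ``config.seed``.  With all sigmas at zero the
    abundances are exact products of class mean and response factor, which
    gives closed-form Min/Max ratios for the planted markers.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    limits = dict(cfg.detection_limit)
    frac_names = [f for f, _ in cfg.fraction_probs]
    frac_p = np.array([p for _, p in cfg.fraction_probs], dtype=float)
    frac_p = frac_p / frac_p.sum()

    used_ids: set[str] = set()
    compounds: list[CompoundTruth] = []
    counter = 0

    def new_compound(category: str, target: str | None, class_means: dict[str, float],
                     fraction: str, heat_labile: bool = False) -> None:
        nonlocal counter
        counter += 1
        retention, fids, resp = _draw_features(
            rng, fraction, cfg.redundant_features_per_compound, used_ids
        )
        compounds.append(
            CompoundTruth(
                compound_id=f"C{counter:03d}",
                category=category,
                target_class=target,
                fraction=fraction,
                feature_ids=tuple(fids),
                response_factors=tuple(resp),
                retention=retention,
                class_means=tuple(class_means.items()),
                heat_labile=heat_labile,
            )
        )

    for ci, cls in enumerate(cfg.class_names):
        for k in range(cfg.n_unique_per_class):
            frac = str(rng.choice(frac_names, p=frac_p))
            mean = cfg.marker_multiple * limits[frac]
            means = {c: (mean if c == cls else 0.0) for c in cfg.class_names}
            new_compound("unique", cls, means, frac,
                         heat_labile=k < cfg.heat_labile_per_class)
        for _ in range(cfg.n_enriched_per_class):
            frac = str(rng.choice(frac_names, p=frac_p))
            mean = cfg.marker_multiple * limits[frac]
            means = {c: (mean if c == cls else mean / cfg.enriched_fold)
                     for c in cfg.class_names}
            new_compound("enriched", cls, means, frac)
    lo, hi = cfg.background_mean_range
    for _ in range(cfg.n_shared_background):
        frac = str(rng.choice(frac_names, p=frac_p))
        mean = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) * limits[frac]
        new_compound("shared", None, {c: mean for c in cfg.class_names}, frac)
    nlo, nhi = cfg.noise_mean_range
    for _ in range(cfg.n_noise):
        frac = str(rng.choice(frac_names, p=frac_p))
        # near-limit cloud: real matrices crowd the detection limit, which is
        # what makes the minimal observed abundance a good limit estimate
        mean = float(np.exp(rng.uniform(np.log(nlo), np.log(nhi)))) * limits[frac]
        new_compound("noise", None, {c: mean for c in cfg.class_names}, frac)

    samples: list[SampleMeta] = []
    batch_counter = 0
    for cls, n_batches in zip(cfg.class_names, cfg.batches_per_class):
        for _ in range(n_batches):
            batch_counter += 1
            batch = f"S_{batch_counter:02d}"
            for t in range(1, cfg.replicates_per_batch + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{batch}_r{t}",
                        class_label=cls,
                        batch_id=batch,
                        replicate_index=t,
                        sample_amount=1.0,
                        istd_abundance=1.0,
                    )
                )

    matrix = _render_matrix(
        rng, compounds, samples, limits,
        cfg.sigma_batch, cfg.sigma_replicate, cfg.sigma_feature,
    )
    return matrix, SyntheticTruth(compounds=compounds, detection_limits=limits)


# ---------------------------------------------------------------------------
# processed-food (cookie) scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CookieProduct:
    """One bakery product: class label, % added seed material, form."""

    class_label: str  # "control" or a seed class
    percent: float
    form: str = "flour"  # flour | whole
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.percent <= 100:
            raise ValueError("percent must be in [0, 100]")


@dataclass(frozen=True)
class CookieBackgroundConfig:
    """Background matrix and processing-product design of the cookie scenario.

    Each bakery product is ground and pooled before analysis, so the
    analytical replicates of one product share one homogenate: replicate
    (aliquot) noise dominates and the per-product batch factor is small.
    """

    n_background_compounds: int = 40
    background_mean_range: tuple[float, float] = (5.0, 100.0)
    n_processing_per_class: int = 1
    processing_mean: float = 100.0  # × POL limit at 100 % addition
    redundant_features_per_compound: int = 2
    sigma_batch: float = 0.05
    sigma_replicate: float = 0.15
    sigma_feature: float = 0.05
    detection_limit_pol: float | None = None


def default_cookie_seed_config(seed: int = 0) -> SyntheticConfig:
    """Seed-compound design underlying the cookie scenario.

    The processed-food iteration profiles only the POL fraction, so every
    seed compound is assigned to POL; one unique marker per class is flagged
    heat-labile — in baked material most unique raw-seed markers are diluted
    or destroyed, which is exactly why processing-dependent markers matter.
    """
    return SyntheticConfig(
        seed=seed, fraction_probs=(("POL", 1.0),), heat_labile_per_class=1
    )


def default_cookie_products(
    class_names: Sequence[str] = ("chia", "linseed", "sesame"),
) -> list[CookieProduct]:
    """93-profile design: control n=5, then 28/30/30 per seed class.

    Per class: defatted seed flour at 5/10/15/20 % (5 replicates each) plus
    whole seeds at 10 and 20 % (5 replicates each); the first class uses 4
    whole-seed replicates, yielding class sizes 28/30/30.
    """
    products = [CookieProduct("control", 0.0, "flour", 5)]
    for i, cls in enumerate(class_names):
        for p in (5.0, 10.0, 15.0, 20.0):
            products.append(CookieProduct(cls, p, "flour", 5))
        whole_reps = 4 if i == 0 else 5
        for p in (10.0, 20.0):
            products.append(CookieProduct(cls, p, "whole", whole_reps))
    return products


def generate_cookie_dataset(
    seed_truth: SyntheticTruth,
    additions: Sequence[CookieProduct] | None = None,
    background: CookieBackgroundConfig | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Generate processed-food profiles mixing a background with seed signals.

    Each cookie profile is the background matrix plus, for a product with
    seed class *c* at *p* % addition, every POL-fraction seed compound at
    ``(p/100) ×`` its abundance in seed class *c* — except heat-labile
    compounds, which are lost in baking — plus processing-generated
    compounds whose abundance is proportional to *p*.  Only the POL fraction
    is profiled, matching the processed-food analysis design.
    """
    bg = background or CookieBackgroundConfig()
    products = list(additions) if additions is not None else default_cookie_products()
    seed_classes = {c.target_class for c in seed_truth.compounds if c.target_class}
    known = seed_classes | {cls for c in seed_truth.compounds for cls, _ in c.class_means}
    for prod in products:
        if prod.class_label != "control" and prod.class_label not in known:
            raise ValueError(f"unknown seed class in additions: {prod.class_label!r}")

    rng = np.random.default_rng(seed)
    limit = bg.detection_limit_pol
    if limit is None:
        limit = seed_truth.detection_limits.get("POL", 1.0)
    limits = {"POL": float(limit)}

    # class labels of the cookie samples
    cookie_classes = ["control"] + sorted(
        {p.class_label for p in products if p.class_label != "control"}
    )

    used_ids: set[str] = set()
    compounds: list[CompoundTruth] = []

    # seed-derived compounds survive with their original POL feature ids
    for comp in seed_truth.compounds:
        if comp.fraction != "POL":
            continue
        used_ids.update(comp.feature_ids)
        means = {"control": 0.0}
        for cls in cookie_classes[1:]:
            means[cls] = 0.0 if comp.heat_labile else comp.class_mean(cls)
        compounds.append(
            CompoundTruth(
                compound_id=comp.compound_id,
                category=comp.category,
                target_class=comp.target_class,
                fraction="POL",
                feature_ids=comp.feature_ids,
                response_factors=comp.response_factors,
                retention=comp.retention,
                class_means=tuple(means.items()),
                heat_labile=comp.heat_labile,
            )
        )

    counter = 0

    def new_compound(category: str, target: str | None, means: dict[str, float],
                     processing: bool = False) -> None:
        nonlocal counter
        counter += 1
        retention, fids, resp = _draw_features(
            rng, "POL", bg.redundant_features_per_compound, used_ids
        )
        compounds.append(
            CompoundTruth(
                compound_id=f"B{counter:03d}" if not processing else f"P{counter:03d}",
                category=category,
                target_class=target,
                fraction="POL",
                feature_ids=tuple(fids),
                response_factors=tuple(resp),
                retention=retention,
                class_means=tuple(means.items()),
                processing_product=processing,
            )
        )

    lo, hi = bg.background_mean_range
    for _ in range(bg.n_background_compounds):
        mean = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) * limits["POL"]
        new_compound("background", None, {c: mean for c in cookie_classes})
    for cls in cookie_classes[1:]:
        for _ in range(bg.n_processing_per_class):
            means = {c: (bg.processing_mean * limits["POL"] if c == cls else 0.0)
                     for c in cookie_classes}
            new_compound("processing", cls, means, processing=True)

    # the per-sample mean depends on the product's percent, so render with a
    # percent-scaled copy of the compound list per product batch
    samples: list[SampleMeta] = []
    for i, prod in enumerate(products, start=1):
        batch = f"K_{i:02d}"
        for t in range(1, prod.n_replicates + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{batch}_r{t}",
                    class_label=prod.class_label,
                    batch_id=batch,
                    replicate_index=t,
                    sample_amount=1.0,
                    istd_abundance=1.0,
                    addition_percent=prod.percent,
                )
            )

    percent_of_batch = {f"K_{i:02d}": p.percent for i, p in enumerate(products, start=1)}
    batch_of = [s.batch_id for s in samples]
    batches = list(dict.fromkeys(batch_of))
    class_of = {s.sample_id: s.class_label for s in samples}

    features: list[MassFeature] = []
    rows: list[np.ndarray] = []
    for comp in compounds:
        batch_factor = {b: _lognoise(rng, bg.sigma_batch) for b in batches}
        signal = np.empty(len(samples))
        for j, s in enumerate(samples):
            mean = comp.class_mean(class_of[s.sample_id])
            if comp.category != "background":
                mean *= percent_of_batch[s.batch_id] / 100.0
            signal[j] = mean * batch_factor[s.batch_id] * _lognoise(rng, bg.sigma_replicate)
        for fid, resp in zip(comp.feature_ids, comp.response_factors):
            vals = np.array([resp * v * _lognoise(rng, bg.sigma_feature) for v in signal])
            rows.append(vals)
            features.append(MassFeature.from_id(fid, compound_group=comp.compound_id))

    values = np.vstack(rows)
    missing = values < limits["POL"]
    values = np.where(missing, np.nan, values)
    matrix = FeatureMatrix.from_arrays(values, missing, features, samples)
    return matrix, SyntheticTruth(compounds=compounds, detection_limits=limits)
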