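import numpy as np
import pytest

from markerforest.feature_matrix import (
    FeatureMatrix,
    MassFeature,
    SampleMeta,
    make_feature_id,
)


def build_matrix(
    values,
    mask=None,
    classes=None,
    batches=None,
    replicates=None,
    fractions=None,
    retentions=None,
    amounts=None,
    istd=None,
    addition=None,
):
    """Construct a FeatureMatrix from plain arrays with sensible defaults."""
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    if mask is None:
        mask = np.isnan(values)
    mask = np.asarray(mask, dtype=bool)
    fractions = list(fractions) if fractions is not None else ["POL"] * nf
    retentions = (
        list(retentions) if retentions is not None else [1000.0 + 10.0 * i for i in range(nf)]
    )
    feats = [
        MassFeature(
            make_feature_id(fractions[i], retentions[i], 100 + i),
            fractions[i],
            round(retentions[i], 2),
            100 + i,
        )
        for i in range(nf)
    ]
    classes = list(classes) if classes is not None else ["A"] * ns
    batches = list(batches) if batches is not None else [f"b{j:02d}" for j in range(ns)]
    replicates = list(replicates) if replicates is not None else [1] * ns
    amounts = list(amounts) if amounts is not None else [1.0] * ns
    istd = list(istd) if istd is not None else [1.0] * ns
    addition = list(addition) if addition is not None else [np.nan] * ns
    samples = [
        SampleMeta(
            sample_id=f"s{j:02d}",
            class_label=classes[j],
            batch_id=batches[j],
            replicate_index=replicates[j],
            sample_amount=amounts[j],
            istd_abundance=istd[j],
            addition_percent=addition[j],
        )
        for j in range(ns)
    ]
    return FeatureMatrix.from_arrays(values, mask, feats, samples)


def random_matrix(rng, nf=6, ns=8, missing_rate=0.2, n_classes=2, fractions=("VOC", "POL")):
    """Random small matrix with a missing mask, for property tests."""
    values = rng.uniform(1.0, 50.0, size=(nf, ns))
    mask = rng.random((nf, ns)) < missing_rate
    # keep at least one observed value per fraction
    for i in range(nf):
        if mask[i].all():
            mask[i, rng.integers(ns)] = False
    values = np.where(mask, np.nan, values)
    classes = [f"c{j % n_classes}" for j in range(ns)]
    fracs = [fractions[i % len(fractions)] for i in range(nf)]
    return build_matrix(values, mask, classes=classes, fractions=fracs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
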