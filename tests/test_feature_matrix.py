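import numpy as np
import pandas as pd
import pytest

from markerforest.feature_matrix import (
    DetectionLimits,
    average_replicates,
    combine_fractions,
    estimate_detection_limits,
    impute_detection_limit,
    make_feature_id,
    normalize,
    parse_feature_id,
    read_matrix,
    split_by_fraction,
    write_matrix,
)

from conftest import build_matrix, random_matrix


class TestFeatureIds:
    def test_parse_convention(self):
        assert parse_feature_id("POL_3402.72_191") == ("POL", 3402.72, 191)

    def test_make_parse_round_trip(self):
        fid = make_feature_id("SOL", 1682.24, 103)
        assert parse_feature_id(fid) == ("SOL", 1682.24, 103)

    @pytest.mark.parametrize("bad", ["POL-12-34", "POL_x_191", "3402.72_191", ""])
    def test_malformed_ids_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_feature_id(bad)

    def test_nonpositive_fields_rejected(self):
        with pytest.raises(ValueError):
            make_feature_id("POL", -1.0, 191)
        with pytest.raises(ValueError):
            make_feature_id("POL", 12.0, 0)


class TestReadWrite:
    def test_na_cell_becomes_missing(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "feature_id\ts1\ts2\ts3\nPOL_100.00_70\t1.5\tNA\t2.5\nPOL_200.00_71\t3\t4\t5\n"
        )
        (tmp_path / "meta.tsv").write_text(
            "sample_id\tclass_label\tbatch_id\ns1\tA\tb1\ns2\tA\tb1\ns3\tB\tb2\n"
        )
        m = read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert m.missing.to_numpy().sum() == 1
        assert bool(m.missing.loc["POL_100.00_70", "s2"])

    def test_zero_is_missing_dialect(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "feature_id\ts1\ts2\nPOL_100.00_70\t0\t2.5\n"
        )
        (tmp_path / "meta.tsv").write_text(
            "sample_id\tclass_label\tbatch_id\ns1\tA\tb1\ns2\tA\tb1\n"
        )
        m = read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert bool(m.missing.loc["POL_100.00_70", "s1"])
        m2 = read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv", zero_is_missing=False)
        assert not bool(m2.missing.loc["POL_100.00_70", "s1"])
        assert m2.values.loc["POL_100.00_70", "s1"] == 0.0

    def test_round_trip_bit_exact(self, tmp_path, rng):
        m = random_matrix(rng, nf=50, ns=20, missing_rate=0.25)
        write_matrix(m, tmp_path / "m.tsv", tmp_path / "meta.tsv",
                     header_comment="round trip")
        back = read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert list(back.values.index) == list(m.values.index)
        assert (back.missing.to_numpy() == m.missing.to_numpy()).all()
        a, b = m.values.to_numpy(), back.values.to_numpy()
        obs = ~m.missing.to_numpy()
        assert (a[obs] == b[obs]).all()  # bit-exact, not approx

    def test_duplicate_feature_id_is_hard_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "feature_id\ts1\nPOL_100.00_70\t1\nPOL_100.00_70\t2\n"
        )
        (tmp_path / "meta.tsv").write_text("sample_id\tclass_label\tbatch_id\ns1\tA\tb1\n")
        with pytest.raises(ValueError, match="POL_100.00_70"):
            read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_metadata_sample_absent_from_matrix(self, tmp_path):
        (tmp_path / "m.tsv").write_text("feature_id\ts1\nPOL_100.00_70\t1\n")
        (tmp_path / "meta.tsv").write_text(
            "sample_id\tclass_label\tbatch_id\ns1\tA\tb1\nsX\tA\tb1\n"
        )
        with pytest.raises(ValueError, match="sX"):
            read_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")


class TestNormalize:
    def test_direct_arithmetic(self):
        m = build_matrix([[1000.0], [1000.0]], amounts=[1.0], istd=[1.0])
        assert normalize(m).values.iloc[0, 0] == 1000.0
        m2 = build_matrix([[1000.0]], amounts=[100.0], istd=[5000.0])
        assert normalize(m2).values.iloc[0, 0] == pytest.approx(0.002)

    def test_mask_preserved_for_all_missing_feature(self):
        vals = np.array([[np.nan, np.nan], [2.0, 3.0]])
        m = build_matrix(vals, amounts=[2.0, 2.0], istd=[10.0, 10.0])
        out = normalize(m)
        assert out.missing.iloc[0].all()
        assert not out.missing.iloc[1].any()

    def test_multiplicative_in_matrix_scale(self, rng):
        m = random_matrix(rng, nf=5, ns=4, missing_rate=0.1)
        c = 3.5
        scaled = m.copy()
        scaled.values = scaled.values * c
        a = normalize(scaled).values.to_numpy()
        b = normalize(m).values.to_numpy() * c
        obs = ~m.missing.to_numpy()
        np.testing.assert_allclose(a[obs], b[obs])

    def test_nonpositive_weight_rejected(self):
        m = build_matrix([[1.0]], amounts=[0.0], istd=[1.0])
        with pytest.raises(ValueError, match="s00"):
            normalize(m)


class TestAverageReplicates:
    def test_mean_of_fully_observed(self):
        m = build_matrix([[4.0, 6.0]], batches=["b1", "b1"], replicates=[1, 2])
        out = average_replicates(m)
        assert out.n_samples == 1
        assert out.values.iloc[0, 0] == 5.0
        assert not out.missing.iloc[0, 0]

    def test_hundred_percent_rule(self):
        vals = np.array([[5.0, 6.0, np.nan]])
        m = build_matrix(vals, batches=["b1"] * 3, replicates=[1, 2, 3])
        out = average_replicates(m)
        assert bool(out.missing.iloc[0, 0])

    def test_single_replicate_identity(self):
        m = build_matrix([[7.0]], batches=["b1"])
        out = average_replicates(m)
        assert out.values.iloc[0, 0] == 7.0
        assert not out.missing.iloc[0, 0]

    def test_unknown_batch_key(self):
        m = build_matrix([[1.0]])
        with pytest.raises(KeyError, match="not_a_key"):
            average_replicates(m, group_by="not_a_key")

    def test_never_observed_where_any_replicate_missing(self, rng):
        """Brute-force per-cell check on random small matrices."""
        for _ in range(10):
            nf, nb, nr = 4, 3, 3
            vals = rng.uniform(1, 10, size=(nf, nb * nr))
            mask = rng.random((nf, nb * nr)) < 0.35
            vals = np.where(mask, np.nan, vals)
            batches = [f"b{j // nr}" for j in range(nb * nr)]
            m = build_matrix(vals, mask, batches=batches,
                             replicates=[j % nr + 1 for j in range(nb * nr)])
            out = average_replicates(m)
            for i in range(nf):
                for bi in range(nb):
                    cols = slice(bi * nr, (bi + 1) * nr)
                    expect_missing = mask[i, cols].any()
                    assert bool(out.missing.iloc[i, bi]) == expect_missing
                    if not expect_missing:
                        assert out.values.iloc[i, bi] == pytest.approx(
                            vals[i, cols].mean()
                        )


class TestDetectionLimits:
    def test_per_fraction_minimum(self):
        vals = np.array([[2.0, 5.0, 9.0], [0.1, 3.0, 4.0]])
        m = build_matrix(vals, fractions=["POL", "VOC"])
        lim = estimate_detection_limits(m)
        assert lim["POL"] == 2.0
        assert lim["VOC"] == 0.1

    def test_scaling_property(self, rng):
        m = random_matrix(rng, nf=8, ns=6, missing_rate=0.2)
        lim = estimate_detection_limits(m)
        c = 7.25
        scaled = m.copy()
        scaled.values = scaled.values * c
        lim_scaled = estimate_detection_limits(scaled)
        for frac in lim:
            assert lim_scaled[frac] == pytest.approx(c * lim[frac])

    def test_fully_missing_fraction_is_error(self):
        vals = np.array([[np.nan, np.nan], [1.0, 2.0]])
        m = build_matrix(vals, fractions=["VOC", "POL"])
        with pytest.raises(ValueError, match="VOC"):
            estimate_detection_limits(m)


class TestImputation:
    def test_substitution_and_idempotence(self):
        vals = np.array([[np.nan, 5.0], [1.0, 2.0]])
        m = build_matrix(vals, fractions=["POL", "POL"])
        lim = DetectionLimits({"POL": 3.0})
        once = impute_detection_limit(m, lim)
        assert once.values.iloc[0, 0] == 3.0
        assert bool(once.missing.iloc[0, 0])  # provenance mask retained
        twice = impute_detection_limit(once, lim)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_frame_equal(once.missing, twice.missing)

    def test_fully_observed_noop(self, rng):
        m = random_matrix(rng, nf=4, ns=4, missing_rate=0.0)
        lim = estimate_detection_limits(m)
        out = impute_detection_limit(m, lim)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_uncovered_fraction_rejected(self):
        m = build_matrix([[np.nan, 1.0]], fractions=["SOL"])
        with pytest.raises(ValueError, match="SOL"):
            impute_detection_limit(m, DetectionLimits({"POL": 1.0}))


class TestCombineFractions:
    def _per_fraction(self, rng):
        out = []
        for frac, nf in (("VOC", 10), ("POL", 20), ("SOL", 30)):
            m = random_matrix(rng, nf=nf, ns=28, missing_rate=0.1,
                              fractions=(frac,))
            out.append(m)
        return out

    def test_concatenation_shape(self, rng):
        combined = combine_fractions(self._per_fraction(rng))
        assert combined.n_features == 60
        assert combined.n_samples == 28

    def test_self_combination_rejected(self, rng):
        m = random_matrix(rng, nf=4, ns=4)
        with pytest.raises(ValueError, match="duplicate feature_id"):
            combine_fractions([m, m])

    def test_split_round_trip(self, rng):
        mats = self._per_fraction(rng)
        combined = combine_fractions(mats)
        split = split_by_fraction(combined)
        assert set(split) == {"VOC", "POL", "SOL"}
        for m in mats:
            frac = m.fractions[0]
            pd.testing.assert_frame_equal(split[frac].values, m.values)
            pd.testing.assert_frame_equal(split[frac].missing, m.missing)

    def test_sample_mismatch_lists_difference(self, rng):
        a = random_matrix(rng, nf=3, ns=4)
        b = random_matrix(rng, nf=3, ns=5)
        with pytest.raises(ValueError, match="s04"):
            combine_fractions([a, b])
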