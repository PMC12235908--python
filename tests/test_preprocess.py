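"""Readers and quality-control operators: imputation, filtering,
normalization, FSQN, and segment-to-gene projection."""

import numpy as np
import pandas as pd
import pytest

from wmrca import (
    FeatureMatrix,
    GeneModel,
    SegmentTable,
    cnv_segments_to_matrix,
    filter_by_missingness,
    fsqn_normalize,
    impute_missing,
    normalize_features,
    read_feature_matrix,
    read_gene_model,
    read_gtf_gene_model,
    read_segments,
    write_feature_matrix,
)


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadFeatureMatrix:
    def test_parses_na_as_missing(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv",
                      "id\tS1\tS2\nG1\t1\t2\nG2\tNA\t4\nG3\t5\t6\n")
        m = read_feature_matrix(p, "mrna")
        assert m.values.shape == (3, 2)
        assert m.n_missing == 1
        assert np.isnan(m.values[1, 0])
        assert m.layer_name == "mrna"

    def test_duplicate_ids_collapsed_by_mean(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv",
                      "id\tS1\nG1\t1\nG1\t3\nG2\t7\n")
        m = read_feature_matrix(p)
        assert m.feature_ids == ["G1", "G2"]
        assert m.values[0, 0] == 2.0

    def test_empty_file_errors(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "")
        with pytest.raises(ValueError, match="empty"):
            read_feature_matrix(p)

    def test_non_numeric_cell_errors(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "id\tS1\nG1\tbogus\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_feature_matrix(p)

    def test_zero_samples_errors(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "id\nG1\n")
        with pytest.raises(ValueError):
            read_feature_matrix(p)

    def test_round_trip(self, tmp_path, small_matrix):
        write_feature_matrix(small_matrix, tmp_path / "m.tsv")
        back = read_feature_matrix(tmp_path / "m.tsv", small_matrix.layer_name)
        np.testing.assert_array_equal(back.values, small_matrix.values)
        assert back.feature_ids == small_matrix.feature_ids
        assert back.sample_ids == small_matrix.sample_ids


class TestFeatureMatrixInvariants:
    def test_duplicate_feature_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(np.zeros((2, 1)), ["a", "a"], ["s"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros((2, 2)), ["a"], ["s1", "s2"])

    def test_infinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureMatrix(np.array([[np.inf]]), ["a"], ["s"])


class TestImputation:
    def test_median_fill(self):
        m = FeatureMatrix(np.array([[1.0, 3.0, np.nan]]), ["g"], ["a", "b", "c"])
        out = impute_missing(m, "median", k=1)
        assert out.values[0, 2] == 2.0

    def test_no_missing_is_identity(self, small_matrix):
        for method in ("median", "mean", "knn"):
            out = impute_missing(small_matrix, method, k=2)
            np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_knn_matches_brute_force_nearest_neighbor(self):
        # 4 features x 3 samples with one missing entry; k=1 must copy the
        # value of the single nearest sample by Euclidean distance over
        # features observed in both samples.
        vals = np.array([
            [1.0, 1.1, 9.0],
            [2.0, 2.2, 8.0],
            [3.0, 2.9, 7.0],
            [np.nan, 5.0, 6.0],
        ])
        m = FeatureMatrix(vals, ["g1", "g2", "g3", "g4"], ["a", "b", "c"])
        out = impute_missing(m, "knn", k=1)
        # brute force: distance a-b and a-c over rows 0..2 (co-observed)
        d_ab = np.sqrt(((vals[:3, 0] - vals[:3, 1]) ** 2).sum())
        d_ac = np.sqrt(((vals[:3, 0] - vals[:3, 2]) ** 2).sum())
        nearest_value = vals[3, 1] if d_ab < d_ac else vals[3, 2]
        assert out.values[3, 0] == nearest_value

    def test_knn_mean_of_k_donors(self):
        vals = np.array([
            [0.0, 0.1, 0.2, 9.0],
            [0.0, 0.1, 0.2, 9.0],
            [np.nan, 4.0, 6.0, 100.0],
        ])
        m = FeatureMatrix(vals, ["g1", "g2", "g3"], list("abcd"))
        out = impute_missing(m, "knn", k=2)
        assert out.values[2, 0] == pytest.approx((4.0 + 6.0) / 2)

    def test_observed_entries_never_altered(self, rng):
        vals = rng.normal(size=(10, 6))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        vals[:, 0] = 1.0  # keep every feature observed somewhere
        m = FeatureMatrix(vals, [f"g{i}" for i in range(10)], list("abcdef"))
        for method in ("median", "mean", "knn"):
            out = impute_missing(m, method, k=2)
            obs = ~np.isnan(vals)
            assert not np.isnan(out.values).any()
            np.testing.assert_array_equal(out.values[obs], vals[obs])

    def test_fully_missing_feature_errors(self):
        m = FeatureMatrix(np.array([[np.nan, np.nan], [1.0, 2.0]]), ["g1", "g2"], ["a", "b"])
        with pytest.raises(ValueError, match="filter"):
            impute_missing(m, "median")

    def test_bad_k_errors(self, small_matrix):
        m = FeatureMatrix(np.array([[1.0, np.nan], [0.0, 1.0]]), ["g1", "g2"], ["a", "b"])
        with pytest.raises(ValueError):
            impute_missing(m, "knn", k=0)
        with pytest.raises(ValueError):
            impute_missing(m, "knn", k=2)


class TestMissingnessFilter:
    def test_fraction_thresholding(self):
        # missing fractions 0, 0.2, 0.5, 0.8, 1.0 over 10 samples
        vals = np.ones((5, 10))
        for i, n_miss in enumerate([0, 2, 5, 8, 10]):
            vals[i, :n_miss] = np.nan
        m = FeatureMatrix(vals, [f"g{i}" for i in range(5)], [f"s{j}" for j in range(10)])
        out = filter_by_missingness(m, 0.8)
        assert out.feature_ids == ["g0", "g1", "g2", "g3"]  # 0.8 tolerated, 1.0 dropped

    def test_feature_missing_in_9_of_10_removed(self):
        vals = np.ones((2, 10))
        vals[0, :9] = np.nan
        m = FeatureMatrix(vals, ["bad", "good"], [f"s{j}" for j in range(10)])
        out = filter_by_missingness(m, 0.8)
        assert out.feature_ids == ["good"]

    def test_no_missing_is_identity(self, small_matrix):
        out = filter_by_missingness(small_matrix, 0.0)
        np.testing.assert_array_equal(out.values, small_matrix.values)

    def test_min_observed_mode(self):
        vals = np.ones((2, 10))
        vals[0, :3] = np.nan  # 70% observed
        m = FeatureMatrix(vals, ["g0", "g1"], [f"s{j}" for j in range(10)])
        assert filter_by_missingness(m, 0.8, mode="min_observed").feature_ids == ["g1"]
        assert filter_by_missingness(m, 0.8, mode="max_missing").feature_ids == ["g0", "g1"]

    def test_threshold_out_of_range_errors(self, small_matrix):
        with pytest.raises(ValueError):
            filter_by_missingness(small_matrix, 1.2)

    def test_filter_then_impute_leaves_no_missing(self, rng):
        vals = rng.normal(size=(20, 8))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = FeatureMatrix(vals, [f"g{i}" for i in range(20)], [f"s{j}" for j in range(8)])
        out = impute_missing(filter_by_missingness(m, 0.8), "knn", k=3)
        assert not np.isnan(out.values).any()
        assert out.sample_ids == m.sample_ids


class TestNormalization:
    def test_median_centering(self):
        m = FeatureMatrix(np.array([[1.0, 2.0, 4.0]]), ["g"], ["a", "b", "c"])
        out = normalize_features(m, "median")
        np.testing.assert_array_equal(out.values, [[-1.0, 0.0, 2.0]])

    def test_log2_with_pseudocount(self):
        m = FeatureMatrix(np.array([[0.0, 1.0, 3.0]]), ["g"], ["a", "b", "c"])
        out = normalize_features(m, "mean", log2_transform=True, pseudocount=1.0)
        logged = np.log2([1.0, 2.0, 4.0])
        np.testing.assert_allclose(out.values[0], logged - logged.mean())

    def test_zscore_moments(self, rng):
        m = FeatureMatrix(rng.normal(2, 5, size=(20, 10)),
                          [f"g{i}" for i in range(20)], [f"s{j}" for j in range(10)])
        out = normalize_features(m, "zscore")
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_zero_variance_feature_left_centered(self):
        m = FeatureMatrix(np.array([[3.0, 3.0, 3.0]]), ["g"], ["a", "b", "c"])
        out = normalize_features(m, "zscore")
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])

    def test_log_of_non_positive_errors(self):
        m = FeatureMatrix(np.array([[-2.0, 1.0]]), ["g"], ["a", "b"])
        with pytest.raises(ValueError, match="log2"):
            normalize_features(m, "median", log2_transform=True, pseudocount=1.0)


class TestFsqn:
    def test_reference_equals_target_is_identity(self, small_matrix):
        out = fsqn_normalize(small_matrix, small_matrix)
        np.testing.assert_allclose(out.values, small_matrix.values, atol=1e-12)

    def test_sorted_values_equal_reference_for_equal_n(self, rng):
        t = FeatureMatrix(rng.normal(size=(6, 8)), [f"g{i}" for i in range(6)],
                          [f"t{j}" for j in range(8)])
        r = FeatureMatrix(rng.normal(5, 2, size=(6, 8)), list(t.feature_ids),
                          [f"r{j}" for j in range(8)])
        out = fsqn_normalize(t, r)
        for i in range(6):
            np.testing.assert_allclose(np.sort(out.values[i]), np.sort(r.values[i]))

    def test_rank_mapping_by_hand(self):
        t = FeatureMatrix(np.array([[10.0, 0.0, 5.0]]), ["g"], ["a", "b", "c"])
        r = FeatureMatrix(np.array([[2.0, 4.0, 6.0]]), ["g"], ["x", "y", "z"])
        out = fsqn_normalize(t, r)
        np.testing.assert_allclose(out.values[0], [6.0, 2.0, 4.0])

    def test_idempotent(self, rng):
        t = FeatureMatrix(rng.normal(size=(5, 7)), [f"g{i}" for i in range(5)],
                          [f"t{j}" for j in range(7)])
        r = FeatureMatrix(rng.normal(size=(5, 9)), list(t.feature_ids),
                          [f"r{j}" for j in range(9)])
        once = fsqn_normalize(t, r)
        twice = fsqn_normalize(once, r)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_feature_mismatch_errors(self, small_matrix):
        other = FeatureMatrix(np.zeros((1, 3)), ["other"], small_matrix.sample_ids)
        with pytest.raises(ValueError, match="feature"):
            fsqn_normalize(small_matrix, other)

    def test_missing_values_error(self, small_matrix):
        t = FeatureMatrix(np.array([[1.0, np.nan, 2.0]]), ["g"], ["a", "b", "c"])
        r = FeatureMatrix(np.array([[1.0, 2.0, 3.0]]), ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="complete"):
            fsqn_normalize(t, r)


def seg_table(rows):
    return SegmentTable(pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"]))


class TestCnvToMatrix:
    def test_gene_fully_contained_in_one_segment(self):
        seg = seg_table([("s1", "chr1", 1, 10_000, 0.35)])
        genes = GeneModel({"g1": ("chr1", 100, 200)})
        out = cnv_segments_to_matrix(seg, genes)
        assert out.values[0, 0] == pytest.approx(0.35)

    def test_equal_overlaps_weighted_mean(self):
        # gene [101, 300]: 100 bases in each of two segments
        seg = seg_table([("s1", "chr1", 1, 200, 0.2), ("s1", "chr1", 201, 400, 0.4)])
        genes = GeneModel({"g1": ("chr1", 101, 300)})
        out = cnv_segments_to_matrix(seg, genes)
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_unequal_overlaps_weighted(self):
        # 150 bases at 0.2, 50 bases at 0.6
        seg = seg_table([("s1", "chr1", 1, 200, 0.2), ("s1", "chr1", 201, 400, 0.6)])
        genes = GeneModel({"g1": ("chr1", 51, 250)})
        out = cnv_segments_to_matrix(seg, genes)
        assert out.values[0, 0] == pytest.approx((150 * 0.2 + 50 * 0.6) / 200)

    def test_absent_chromosome_gives_missing(self):
        seg = seg_table([("s1", "chr1", 1, 100, 0.1), ("s2", "chr2", 1, 100, 0.1)])
        genes = GeneModel({"g1": ("chr2", 10, 20)})
        out = cnv_segments_to_matrix(seg, genes)
        assert np.isnan(out.values[0, out.sample_ids.index("s1")])
        assert out.values[0, out.sample_ids.index("s2")] == pytest.approx(0.1)

    def test_max_abs_aggregation(self):
        seg = seg_table([("s1", "chr1", 1, 200, 0.2), ("s1", "chr1", 201, 400, -0.9)])
        genes = GeneModel({"g1": ("chr1", 101, 300)})
        out = cnv_segments_to_matrix(seg, genes, aggregation="max_abs")
        assert out.values[0, 0] == pytest.approx(-0.9)

    def test_values_within_segment_value_range(self, rng):
        rows = []
        for s in ("s1", "s2"):
            pos = 1
            for _ in range(6):
                end = pos + int(rng.integers(50, 300))
                rows.append((s, "chr1", pos, end, float(rng.normal())))
                pos = end + 1
        seg = seg_table(rows)
        genes = GeneModel({f"g{i}": ("chr1", 1 + 137 * i, 137 * i + 200) for i in range(5)})
        out = cnv_segments_to_matrix(seg, genes)
        df = seg.records
        for gi, gid in enumerate(out.feature_ids):
            chrom, gs, ge = genes.genes[gid]
            for sj, s in enumerate(out.sample_ids):
                sub = df[(df["sample"] == s) & (df["chrom"] == chrom)
                         & (df["start"] <= ge) & (df["end"] >= gs)]
                if len(sub):
                    assert sub["value"].min() - 1e-12 <= out.values[gi, sj] <= sub["value"].max() + 1e-12

    def test_empty_inputs_error(self):
        genes = GeneModel({"g1": ("chr1", 1, 10)})
        seg = seg_table([("s1", "chr1", 1, 100, 0.0)])
        with pytest.raises(ValueError, match="empty segment"):
            cnv_segments_to_matrix(seg_table([]), genes)
        with pytest.raises(ValueError, match="empty gene"):
            cnv_segments_to_matrix(seg, GeneModel({}))


class TestGenomicReaders:
    def test_segments_round_trip_with_header(self, tmp_path):
        p = tmp_path / "s.seg"
        p.write_text("sample\tchrom\tstart\tend\tvalue\nA\tchr1\t1\t100\t0.5\n")
        seg = read_segments(p)
        assert len(seg) == 1
        assert seg.records.loc[0, "value"] == 0.5

    def test_gene_model_reader(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tchrom\tstart\tend\ng1\tchr1\t10\t99\n")
        gm = read_gene_model(p)
        assert gm.genes["g1"] == ("chr1", 10, 99)

    def test_gtf_gene_extraction(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            "#comment\n"
            'chr1\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "G1"; gene_name "X";\n'
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1";\n'
            'chr2\tsrc\tgene\t10\t90\t.\t-\t.\tgene_id "G2";\n'
        )
        gm = read_gtf_gene_model(p)
        assert gm.genes == {"G1": ("chr1", 100, 500), "G2": ("chr2", 10, 90)}

    def test_invalid_segment_coordinates_rejected(self):
        with pytest.raises(ValueError, match="start"):
            seg_table([("s1", "chr1", 100, 50, 0.0)])
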