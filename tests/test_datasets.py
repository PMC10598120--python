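import numpy as np
import pytest

import tripletgene as tg
from tripletgene.datasets import ClinicalTable, FeatureScaler, load_gene_groups


def _write(tmp_path, text, name="expr.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpression:
    def test_parses_numeric_table_with_header(self, tmp_path):
        p = _write(
            tmp_path,
            "sample_id\tgA\tgB\tgC\tgD\n"
            "s1\t1\t2\t3\t4\n"
            "s2\t5\t6\t7\t8\n"
            "s3\t9\t10\t11\t12\n",
        )
        ds = tg.load_expression(p)
        assert ds.n_samples == 3 and ds.n_genes == 4
        assert ds.gene_ids == ["gA", "gB", "gC", "gD"]
        assert ds.labels is None and ds.n_clinical == 0
        assert ds.values[1, 2] == 7.0

    def test_empty_file_is_a_parse_error(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            tg.load_expression(_write(tmp_path, ""))

    def test_non_numeric_cell_error_names_location(self, tmp_path):
        p = _write(tmp_path, "id\tgA\tgB\ns1\t1\t2\ns2\toops\t4\n")
        with pytest.raises(ValueError, match="s2.*gA|gA.*s2"):
            tg.load_expression(p)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "id\tgA\ns1\t1\ns1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            tg.load_expression(p)

    def test_round_trips_synthetic_output(self, tmp_path, small_dataset):
        small_dataset.to_tsv(tmp_path / "out.tsv")
        back = tg.load_expression(tmp_path / "out.tsv")
        np.testing.assert_allclose(back.values, small_dataset.values)
        assert back.gene_ids == small_dataset.gene_ids
        assert back.sample_ids == small_dataset.sample_ids


class TestCollapseDuplicateGenes:
    def _ds(self, ids, rows):
        return tg.ExpressionDataset(
            np.array(rows, dtype=float), ids,
            [f"s{i}" for i in range(len(rows))],
        )

    def test_mean_of_two_copies(self):
        out = tg.collapse_duplicate_genes(self._ds(["gA", "gB", "gA"], [[1, 2, 3]]))
        assert out.gene_ids == ["gA", "gB"]
        np.testing.assert_allclose(out.values, [[2.0, 2.0]])

    def test_mean_of_three_copies(self):
        out = tg.collapse_duplicate_genes(self._ds(["gA"] * 3, [[1, 2, 6]]))
        np.testing.assert_allclose(out.values, [[3.0]])

    def test_no_duplicates_is_identity(self, small_dataset):
        out = tg.collapse_duplicate_genes(small_dataset)
        assert out.gene_ids == small_dataset.gene_ids
        np.testing.assert_array_equal(out.values, small_dataset.values)

    def test_idempotent(self):
        ds = self._ds(["a", "b", "a", "c", "b"], [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        once = tg.collapse_duplicate_genes(ds)
        twice = tg.collapse_duplicate_genes(once)
        assert once.gene_ids == twice.gene_ids
        np.testing.assert_array_equal(once.values, twice.values)


class TestNormalizeFeatures:
    def test_two_point_column_maps_to_plus_minus_one(self):
        ds = tg.ExpressionDataset(np.array([[1.0], [3.0]]), ["g"], ["a", "b"])
        np.testing.assert_allclose(
            tg.normalize_features(ds).values, [[-1.0], [1.0]]
        )

    def test_constant_column_becomes_zero(self):
        ds = tg.ExpressionDataset(np.array([[5.0], [5.0], [5.0]]), ["g"], list("abc"))
        np.testing.assert_array_equal(tg.normalize_features(ds).values, np.zeros((3, 1)))

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.standard_normal((40, 6))
        once = tg.normalize_features(
            tg.ExpressionDataset(x, [f"g{i}" for i in range(6)],
                                 [f"s{i}" for i in range(40)])
        )
        again = tg.normalize_features(once)
        np.testing.assert_allclose(again.values, once.values, atol=1e-9)

    def test_columns_have_zero_mean_unit_population_sd(self, rng):
        x = rng.standard_normal((30, 8)) * rng.uniform(0.5, 9, 8) + rng.uniform(-5, 5, 8)
        out = tg.normalize_features(
            tg.ExpressionDataset(x, [f"g{i}" for i in range(8)],
                                 [f"s{i}" for i in range(30)])
        )
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(out.values.std(axis=0) - 1) < 1e-9)

    def test_scaler_fits_on_train_applies_elsewhere(self, rng):
        train = rng.standard_normal((20, 3)) + 10
        test = rng.standard_normal((5, 3))
        scaler = FeatureScaler().fit(train)
        out = scaler.transform(test)
        # test statistics are NOT zero-mean: train statistics were used
        assert np.all(out.mean(axis=0) < -5)


class TestEncodeClinical:
    def test_marital_unknown_maps_to_zero(self):
        table = ClinicalTable(["s1", "s2"], {"marital": ["unknown", "married"]})
        mat, names = tg.encode_clinical(table)
        assert names == ["marital"]
        np.testing.assert_array_equal(mat[:, 0], [0.0, 2.0])

    def test_custom_mapping_applies(self):
        table = ClinicalTable(["s1"], {"marital": ["married"]})
        mat, _ = tg.encode_clinical(table, mapping={"married": 2})
        assert mat[0, 0] == 2.0

    def test_unlisted_marital_category_falls_back_to_zero(self):
        table = ClinicalTable(["s1"], {"marital": ["separated"]})
        mat, _ = tg.encode_clinical(table)
        assert mat[0, 0] == 0.0

    def test_sex_binary_and_three_values_rejected(self):
        ok = ClinicalTable(["s1", "s2"], {"sex": ["M", "F"]})
        mat, _ = tg.encode_clinical(ok)
        assert set(mat[:, 0]) == {0.0, 1.0}
        bad = ClinicalTable(["a", "b", "c"], {"sex": ["M", "F", "X"]})
        with pytest.raises(ValueError, match="sex"):
            tg.encode_clinical(bad)

    def test_age_education_pass_through_and_order_follows_sample_ids(self):
        table = ClinicalTable(
            ["s1", "s2"], {"age": ["70.5", "62"], "education": ["12", "16"]}
        )
        mat, names = tg.encode_clinical(table)
        assert names == ["age", "education"]
        np.testing.assert_allclose(mat, [[70.5, 12.0], [62.0, 16.0]])


class TestAttachClinical:
    def test_appends_columns_and_sets_n_clinical(self, small_dataset):
        clin = np.column_stack(
            [np.arange(small_dataset.n_samples), np.ones(small_dataset.n_samples)]
        ).astype(float)
        out = tg.attach_clinical(small_dataset, clin, feature_names=["age", "sex"])
        assert out.n_features == small_dataset.n_features + 2
        assert out.n_clinical == 2
        assert out.gene_ids[-2:] == ["age", "sex"]
        # appended columns are standardized
        assert abs(out.values[:, -2].mean()) < 1e-9

    def test_sample_id_mismatch_rejected(self, small_dataset):
        clin = np.zeros((small_dataset.n_samples, 1))
        wrong = list(reversed(small_dataset.sample_ids))
        with pytest.raises(ValueError, match="sample ID"):
            tg.attach_clinical(small_dataset, clin, sample_ids=wrong)

    def test_empty_clinical_is_identity(self, small_dataset):
        out = tg.attach_clinical(small_dataset, np.zeros((small_dataset.n_samples, 0)))
        assert out is small_dataset


class TestLabelStage:
    @pytest.mark.parametrize(
        "stage,expected",
        [
            ("Stage I", 0), ("stage ia", 0), ("STAGE IB", 0), ("I", 0),
            ("Stage II", 1), ("Stage IIIB", 1), ("stage iv", 1), ("IIA", 1),
        ],
    )
    def test_stage_i_is_early_everything_else_late(self, stage, expected):
        assert tg.label_stage(stage) == expected

    @pytest.mark.parametrize("bad", ["", "unknown", "not reported", None, "stage x0"])
    def test_missing_or_unknown_stage_raises(self, bad):
        with pytest.raises(ValueError):
            tg.label_stage(bad)


class TestOrderGenesByGroups:
    def test_groups_become_contiguous_in_iteration_order(self):
        perm = tg.order_genes_by_groups(
            ["a", "b", "c", "d"], {"G1": ["c", "a"], "G2": ["d"]}
        )
        np.testing.assert_array_equal(perm, [2, 0, 3, 1])

    def test_empty_grouping_is_identity(self):
        perm = tg.order_genes_by_groups(["a", "b", "c"], {})
        np.testing.assert_array_equal(perm, [0, 1, 2])

    def test_gene_in_two_groups_placed_once_at_first(self):
        perm = tg.order_genes_by_groups(
            ["a", "b", "c"], {"G1": ["b"], "G2": ["b", "a"]}
        )
        np.testing.assert_array_equal(perm, [1, 0, 2])

    def test_always_a_permutation(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(25):
            k = rng.integers(0, 4)
            grouping = {
                f"G{j}": list(rng.choice(genes, size=rng.integers(1, 10), replace=True))
                for j in range(k)
            }
            perm = tg.order_genes_by_groups(genes, grouping)
            assert sorted(perm.tolist()) == list(range(30))

    def test_gene_group_tsv_loader(self, tmp_path):
        p = tmp_path / "groups.tsv"
        p.write_text("gene_id\tgroup\nc\tG1\na\tG1\nd\tG2\n")
        grouping = load_gene_groups(p)
        assert grouping == {"G1": ["c", "a"], "G2": ["d"]}
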