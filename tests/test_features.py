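"""MAD/RF selection, splits, folds, SMOTE, and gene-level collapsing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestNeighbors

from methsubtype.features import (
    SmoteParams,
    SplitSpec,
    annotate_collapse,
    balance_classes,
    mad_select,
    make_folds,
    rf_importance_select,
    smote,
    split_data,
)


def _beta(values, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:03d}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=probes,
                        columns=[f"S{j}" for j in range(values.shape[1])])


class TestMadSelect:
    def test_variable_probe_beats_constant(self):
        beta = _beta([[1, 2, 3, 4, 5], [3, 3, 3, 3, 3]], probes=["var", "flat"])
        assert mad_select(beta, 1) == ["var"]

    def test_full_selection_returns_all_ordered(self):
        beta = _beta([[1, 2, 3], [0, 0, 0], [1, 5, 9]], probes=["a", "b", "c"])
        assert mad_select(beta, 3) == ["c", "a", "b"]

    def test_ranking_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(10, 15))
        beta = _beta(values)
        # independent oracle: unscaled MAD definition + stable sort
        mads = {
            beta.index[i]: np.median(np.abs(values[i] - np.median(values[i])))
            for i in range(10)
        }
        expected = sorted(beta.index, key=lambda p: (-mads[p], p))
        assert mad_select(beta, 10) == expected

    def test_scaling_constant_never_changes_ranks(self, rng):
        beta = _beta(rng.normal(size=(8, 12)))
        assert mad_select(beta, 8) == mad_select(beta * 1.4826, 8)

    def test_constant_matrix_tie_broken_lexicographically(self):
        beta = _beta(np.ones((4, 5)), probes=["d", "b", "a", "c"])
        assert mad_select(beta, 2) == ["a", "b"]

    def test_n_top_too_large_rejected(self):
        with pytest.raises(ValueError):
            mad_select(_beta(np.ones((3, 2))), 4)


class TestRfImportanceSelect:
    def test_informative_probes_recovered(self, four_group_omics):
        omics = four_group_omics
        n_info = len(omics.informative_probes)
        panel = rf_importance_select(
            omics.beta, omics.labels.to_numpy(), n_select=n_info, seed=0
        )
        recovered = len(set(panel) & set(omics.informative_probes))
        assert recovered >= int(0.9 * n_info)

    def test_select_all_returns_everything(self, four_group_omics):
        omics = four_group_omics
        panel = rf_importance_select(
            omics.beta, omics.labels.to_numpy(),
            n_trees=50, n_select=omics.beta.shape[0], seed=0,
        )
        assert sorted(panel) == sorted(omics.beta.index)

    def test_deterministic_given_seed(self, four_group_omics):
        omics = four_group_omics
        a = rf_importance_select(omics.beta, omics.labels.to_numpy(),
                                 n_trees=50, n_select=20, seed=3)
        b = rf_importance_select(omics.beta, omics.labels.to_numpy(),
                                 n_trees=50, n_select=20, seed=3)
        assert a == b

    def test_gini_fallback_also_recovers_signal(self, four_group_omics):
        omics = four_group_omics
        n_info = len(omics.informative_probes)
        panel = rf_importance_select(
            omics.beta, omics.labels.to_numpy(), n_select=n_info,
            seed=0, method="gini",
        )
        assert len(set(panel) & set(omics.informative_probes)) >= int(0.9 * n_info)

    def test_single_class_rejected(self, four_group_omics):
        beta = four_group_omics.beta
        with pytest.raises(ValueError):
            rf_importance_select(beta, ["X"] * beta.shape[1], n_select=5)


class TestSplitData:
    def test_eighty_twenty_exact(self, rng):
        y = np.repeat(["A", "B"], 50)
        x = rng.normal(size=(100, 3))
        parts = split_data(x, y, SplitSpec(train_frac=0.8, seed=0))
        assert len(parts["train"]) == 80 and len(parts["test"]) == 20

    def test_partition_property(self, rng):
        y = np.repeat(["A", "B", "C"], 20)
        parts = split_data(rng.normal(size=(60, 2)), y, SplitSpec(seed=1))
        joined = np.sort(np.concatenate(list(parts.values())))
        np.testing.assert_array_equal(joined, np.arange(60))

    def test_three_way_sixty_twenty_twenty(self, rng):
        y = np.repeat(["A", "B"], 50)
        parts = split_data(
            rng.normal(size=(100, 2)), y,
            SplitSpec(train_frac=0.6, val_frac=0.2, seed=2),
        )
        sizes = {k: len(v) for k, v in parts.items()}
        assert sizes == {"train": 60, "val": 20, "test": 20}

    def test_stratification_preserves_proportions(self, rng):
        y = np.repeat(["A", "B", "C", "D"], [40, 20, 20, 20])
        parts = split_data(rng.normal(size=(100, 2)), y, SplitSpec(seed=3))
        test_counts = pd.Series(y[parts["test"]]).value_counts()
        assert test_counts.to_dict() == {"A": 8, "B": 4, "C": 4, "D": 4}

    def test_tiny_class_under_stratification_rejected(self, rng):
        y = np.array(["A"] * 9 + ["B"])
        with pytest.raises(ValueError):
            split_data(rng.normal(size=(10, 2)), y, SplitSpec())


class TestMakeFolds:
    def test_ten_folds_of_ten(self):
        folds = make_folds(np.repeat(["A", "B"], 50), k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 10 for f in folds)

    def test_every_index_exactly_once(self):
        y = np.repeat(["A", "B", "C"], 11)
        folds = make_folds(y, k=5, seed=1)
        joined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(joined, np.arange(33))

    def test_uneven_sizes_pigeonhole(self):
        folds = make_folds(np.repeat(["A", "B"], [12, 11]), k=10, seed=2)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {2, 3} and sum(sizes) == 23

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array(["A", "B", "A"]), k=4)


class TestSmote:
    def test_seventy_to_two_hundred_ten(self, rng):
        x = rng.uniform(size=(70, 10))
        synth = smote(x, SmoteParams(perc_over=200, seed=0))
        assert synth.shape == (140, 10)
        assert len(x) + len(synth) == 210

    def test_synthetic_points_on_parent_segments(self, rng):
        """With k=1 each sample's only possible partner is its nearest
        neighbour, so the parent pair is known exactly."""
        x = rng.uniform(size=(3, 4))
        nn = NearestNeighbors(n_neighbors=2).fit(x)
        _, idx = nn.kneighbors(x)
        synth = smote(x, SmoteParams(k_neighbors=1, perc_over=100, seed=1))
        assert synth.shape == (3, 4)
        for i in range(3):
            a, b = x[i], x[idx[i, 1]]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            assert ((synth[i] >= lo - 1e-12) & (synth[i] <= hi + 1e-12)).all()

    def test_convex_hull_coordinatewise(self, rng):
        x = rng.uniform(size=(20, 5))
        synth = smote(x, SmoteParams(perc_over=300, seed=2))
        assert (synth >= x.min(axis=0) - 1e-12).all()
        assert (synth <= x.max(axis=0) + 1e-12).all()

    def test_degenerate_identical_points(self):
        x = np.ones((6, 3))
        synth = smote(x, SmoteParams(k_neighbors=2, perc_over=100, seed=3))
        np.testing.assert_allclose(synth, 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            smote(np.ones((5, 2)), SmoteParams(k_neighbors=5))

    @pytest.mark.parametrize("perc", [0, 150, -100])
    def test_invalid_percentage_rejected(self, perc):
        with pytest.raises(ValueError):
            SmoteParams(perc_over=perc)


class TestBalanceClasses:
    def test_named_minority_oversampled(self, rng):
        x = rng.uniform(size=(100, 4))
        y = np.repeat(["maj", "min"], [70, 30])
        xb, yb = balance_classes(x, y, SmoteParams(perc_over=200, seed=0),
                                 minority="min")
        assert np.sum(yb == "min") == 90
        assert np.sum(yb == "maj") == 70

    def test_automatic_balancing_tops_up_all(self, rng):
        x = rng.uniform(size=(90, 4))
        y = np.repeat(["a", "b", "c"], [60, 20, 10])
        xb, yb = balance_classes(x, y, SmoteParams(seed=1))
        counts = pd.Series(yb).value_counts()
        assert counts["a"] == 60 and counts["b"] == 60 and counts["c"] == 60


class TestAnnotateCollapse:
    def _ann(self, genes):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(genes))],
                "chr": ["1"] * len(genes),
                "gene": genes,
                "snp_flag": [False] * len(genes),
            }
        )

    def test_median_of_duplicated_gene(self):
        values = _beta([[0.2], [0.4], [0.9]], probes=["cg0", "cg1", "cg2"])
        out = annotate_collapse(["cg0", "cg1", "cg2"], values,
                                self._ann(["G1", "G1", "G1"]))
        assert out.loc["G1"].iloc[0] == pytest.approx(0.4)

    def test_unannotated_probe_dropped(self):
        values = _beta([[0.2], [0.8]], probes=["cg0", "cg1"])
        out = annotate_collapse(["cg0", "cg1"], values, self._ann(["G1", ""]))
        assert list(out.index) == ["G1"]

    def test_one_probe_per_gene_is_identity(self):
        values = _beta([[0.1, 0.2], [0.6, 0.7]], probes=["cg0", "cg1"])
        out = annotate_collapse(["cg0", "cg1"], values, self._ann(["G1", "G2"]))
        np.testing.assert_allclose(out.loc["G1"], values.loc["cg0"])
        np.testing.assert_allclose(out.loc["G2"], values.loc["cg1"])

    def test_all_unannotated_warns_and_empty(self):
        values = _beta([[0.5]], probes=["cg0"])
        with pytest.warns(UserWarning):
            out = annotate_collapse(["cg0"], values, self._ann([""]))
        assert out.empty
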