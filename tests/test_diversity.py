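"""Descriptor-space PCA: standardization, eigenstructure, overlays."""

import numpy as np
import pandas as pd
import pytest

from chemprof.chemio import Library, MoleculeRecord
from chemprof.diversity import (
    DescriptorMatrix, build_matrix, overlay_scores, pca, standardize,
    variance_explained,
)
from chemprof.synthdata import two_population_library
from chemprof.chemio import DEFAULT_TAG_SCHEMA, extract_descriptors
from chemprof.vector import DescriptorVector


def toy_library(values_per_record, panel):
    records, desc = [], {}
    for i, vals in enumerate(values_per_record):
        rid = f"m{i}"
        records.append(MoleculeRecord(record_id=rid))
        desc[rid] = DescriptorVector.from_dict(dict(zip(panel, vals)))
    return Library(records=records, name="toy"), desc


PANEL2 = ("MW", "logP")


class TestBuildMatrix:
    def test_full_panel_shape(self):
        lib, desc = toy_library([(300, 2), (400, 3), (500, 4), (350, 1),
                                 (420, 2.5)], PANEL2)
        m = build_matrix(lib, desc, PANEL2)
        assert m.data.shape == (5, 2)
        assert list(m.data.index) == [f"m{i}" for i in range(5)]

    def test_drop_record_policy(self):
        lib, desc = toy_library([(300, 2), (400, 3), (500, 4), (350, 1),
                                 (420, 2.5)], PANEL2)
        del desc["m2"].values["logP"]
        m = build_matrix(lib, desc, PANEL2, completion="drop_record")
        assert m.data.shape == (4, 2)

    def test_impute_mean_policy(self):
        lib, desc = toy_library([(300, 2), (400, 3), (500, 4), (350, 1),
                                 (450, 5)], PANEL2)
        del desc["m2"].values["logP"]
        m = build_matrix(lib, desc, PANEL2, completion="impute_mean")
        assert m.data.shape == (5, 2)
        assert m.data.loc["m2", "logP"] == pytest.approx((2 + 3 + 1 + 5) / 4)

    def test_too_few_records_fatal(self):
        lib, desc = toy_library([(300, 2), (400, 3)], PANEL2)
        with pytest.raises(ValueError, match="at least 3"):
            build_matrix(lib, desc, PANEL2)


class TestStandardize:
    def test_hand_example(self):
        m = DescriptorMatrix(
            data=pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 9.0]})
        )
        out = standardize(m)
        # column (1,2,3): mean 2, sample sd exactly 1
        assert np.allclose(out.data["x"], [-1.0, 0.0, 1.0])

    def test_moments_within_tolerance(self):
        rng = np.random.default_rng(5)
        m = DescriptorMatrix(data=pd.DataFrame(rng.normal(5, 3, (40, 4))))
        out = standardize(m)
        assert np.all(np.abs(out.data.mean()) < 1e-10)
        assert np.all(np.abs(out.data.std(ddof=1) - 1) < 1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = DescriptorMatrix(data=pd.DataFrame(rng.normal(size=(30, 3))))
        once = standardize(m)
        twice = standardize(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_column_dropped(self, caplog):
        m = DescriptorMatrix(
            data=pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [7.0, 7.0, 7.0]})
        )
        with caplog.at_level("WARNING"):
            out = standardize(m)
        assert list(out.data.columns) == ["x"]

    def test_all_constant_fatal(self):
        m = DescriptorMatrix(data=pd.DataFrame({"c": [1.0, 1.0, 1.0]}))
        with pytest.raises(ValueError):
            standardize(m)


def correlated_pair(rho, n=4000, seed=13):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return DescriptorMatrix(data=pd.DataFrame({"x": x, "y": y}))


class TestPCA:
    def test_perfectly_correlated_columns_rank_one(self):
        x = np.arange(10.0)
        m = standardize(
            DescriptorMatrix(data=pd.DataFrame({"a": x, "b": 3 * x + 1}))
        )
        res = pca(m)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_shares_for_rho_half(self):
        # correlation-matrix eigenvalues are 1 +- rho
        res = pca(standardize(correlated_pair(0.5)))
        assert res.variance_fractions[0] == pytest.approx(0.75, abs=0.02)
        assert res.variance_fractions[1] == pytest.approx(0.25, abs=0.02)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        m = standardize(DescriptorMatrix(data=pd.DataFrame(
            rng.normal(size=(50, 5)))))
        res = pca(m)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(8)
        m = standardize(DescriptorMatrix(data=pd.DataFrame(
            rng.normal(size=(40, 6)))))
        res = pca(m)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.linalg.norm(recon - m.data.to_numpy()) < 1e-8

    def test_loadings_orthonormal_and_scores_centered(self):
        rng = np.random.default_rng(9)
        m = standardize(DescriptorMatrix(data=pd.DataFrame(
            rng.normal(size=(60, 4)))))
        res = pca(m)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert np.all(np.abs(res.scores.mean()) < 1e-10)

    def test_sign_convention_deterministic(self):
        res1 = pca(standardize(correlated_pair(0.5)))
        res2 = pca(standardize(correlated_pair(0.5)))
        assert np.array_equal(res1.loadings, res2.loadings)
        for j in range(res1.loadings.shape[1]):
            col = res1.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_row_permutation_leaves_fractions_unchanged(self):
        m = correlated_pair(0.6, n=500)
        res = pca(standardize(m))
        shuffled = DescriptorMatrix(
            data=m.data.sample(frac=1.0, random_state=3)
        )
        res2 = pca(standardize(shuffled))
        assert np.allclose(res.variance_fractions, res2.variance_fractions)

    def test_unstandardized_input_rejected(self):
        with pytest.raises(ValueError, match="standardize"):
            pca(correlated_pair(0.5))

    def test_k_exceeding_columns_fatal(self):
        with pytest.raises(ValueError):
            pca(standardize(correlated_pair(0.5)), k=5)


class TestVarianceExplained:
    def test_all_components_give_one(self):
        res = pca(standardize(correlated_pair(0.3)))
        assert variance_explained(res, 2) == pytest.approx(1.0, abs=1e-12)

    def test_first_component_of_toy(self):
        res = pca(standardize(correlated_pair(0.5)))
        assert variance_explained(res, 1) == pytest.approx(0.75, abs=0.02)

    def test_monotone_in_k(self):
        res = pca(standardize(correlated_pair(0.4)))
        assert variance_explained(res, 1) <= variance_explained(res, 2)

    def test_k_beyond_retained_fatal(self):
        res = pca(standardize(correlated_pair(0.4)), k=1)
        with pytest.raises(ValueError):
            variance_explained(res, 2)


def descriptors_for(lib):
    return {
        rec.record_id: extract_descriptors(rec, DEFAULT_TAG_SCHEMA)
        for rec in lib.records
    }


class TestOverlay:
    def test_identical_libraries_indistinguishable(self):
        a, _ = two_population_library(60, 60, {}, seed=21)
        desc = descriptors_for(a)
        ov = overlay_scores(a, a, desc, desc, k=3)
        s = ov["scores"]
        la, lb = ov["labels"]
        mean_a = s[s["library"] == la][["PC1", "PC2", "PC3"]].mean()
        mean_b = s[s["library"] == lb][["PC1", "PC2", "PC3"]].mean()
        assert np.allclose(mean_a, mean_b, atol=1e-10)

    def test_mw_shift_separates_along_mw_component(self):
        a, b = two_population_library(150, 150, {"MW": 600.0}, seed=22)
        ov = overlay_scores(a, b, descriptors_for(a), descriptors_for(b), k=3)
        s = ov["scores"]
        # find the component with the largest |MW| loading
        mw_pc = ov["loadings"].loc["MW"].abs().idxmax()
        la, lb = ov["labels"]
        gap = abs(
            s[s["library"] == la][mw_pc].mean()
            - s[s["library"] == lb][mw_pc].mean()
        )
        assert gap > 1.0  # far beyond sampling noise on standardized scores

    def test_outliers_zero_at_infinite_radius(self):
        a, b = two_population_library(30, 30, {}, seed=23)
        ov = overlay_scores(a, b, descriptors_for(a), descriptors_for(b),
                            mahalanobis_radius=np.inf)
        assert set(ov["outliers"].values()) == {0}

    def test_finite_radius_flags_some(self):
        a, b = two_population_library(100, 100, {}, seed=24)
        ov = overlay_scores(a, b, descriptors_for(a), descriptors_for(b),
                            mahalanobis_radius=1.0)
        assert sum(ov["outliers"].values()) > 0
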