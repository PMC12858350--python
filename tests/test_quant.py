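import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from membranebench.annotation import classify_proteins
from membranebench.io import QuantMatrix, SampleDesign, Sample
from membranebench.quant import (
    best_replicate,
    exclusive_set_overlaps,
    heatmap_matrix,
    log2_matrix,
    mass_bin_ratio,
    pca_profiles,
    pearson_matrix,
    quartile_composition,
    top_n_composition,
)

from conftest import make_annotation


def qm(arr, columns=None, index=None, scale="linear"):
    arr = np.asarray(arr, dtype=float)
    columns = columns or [f"s{i}" for i in range(arr.shape[1])]
    index = index or [f"P{i}" for i in range(arr.shape[0])]
    return QuantMatrix(pd.DataFrame(arr, index=index, columns=columns), scale=scale)


class TestLog2Matrix:
    def test_values_and_missing(self):
        q = qm([[8.0, np.nan]])
        out = log2_matrix(q)
        assert out.scale == "log2"
        assert out.data.iloc[0, 0] == 3.0
        assert np.isnan(out.data.iloc[0, 1])

    def test_double_transform_is_error(self):
        q = log2_matrix(qm([[8.0, 4.0]]))
        with pytest.raises(ValueError, match="already"):
            log2_matrix(q)


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        q = qm(np.random.default_rng(0).normal(20, 2, (10, 3)), scale="log2")
        r = pearson_matrix(q)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert (r.to_numpy() <= 1 + 1e-12).all() and (r.to_numpy() >= -1 - 1e-12).all()

    def test_pairwise_complete_collinear(self):
        q = qm([[1, 2], [2, 4], [3, 6], [np.nan, 5]], scale="log2")
        r = pearson_matrix(q)
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_anti_ordered_pair(self):
        q = qm([[1, 3], [2, 2], [3, 1]], scale="log2")
        assert pearson_matrix(q).iloc[0, 1] == pytest.approx(-1.0)

    def test_insufficient_shared_proteins_undefined(self):
        q = qm([[1, 1], [2, 2], [np.nan, 3], [np.nan, 4]], scale="log2")
        assert np.isnan(pearson_matrix(q, min_shared=3).iloc[0, 1])

    def test_requires_log2(self):
        with pytest.raises(ValueError, match="log2"):
            pearson_matrix(qm([[1.0, 2.0]]))


class TestBestReplicate:
    def test_highest_identification_replicate_wins(self, design3):
        data = pd.DataFrame(1.0, index=["P1", "P2", "P3"], columns=design3.sample_ids)
        data.loc[["P2", "P3"], "W_LFD_1"] = np.nan
        data.loc["P3", "W_LFD_3"] = np.nan
        q = QuantMatrix(data)
        assert best_replicate(q, design3, "W", "LFD") == "W_LFD_2"

    def test_tie_breaks_to_lowest_replicate_index(self, design3):
        data = pd.DataFrame(1.0, index=["P1"], columns=design3.sample_ids)
        q = QuantMatrix(data)
        assert best_replicate(q, design3, "W", "HFD") == "W_HFD_1"


class TestPcaProfiles:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 3, 30)
        data = np.column_stack([base, base, base + rng.normal(0, 4, 30)])
        out = pca_profiles(qm(data, scale="log2"))
        c = out.coordinates
        assert np.allclose(c.iloc[0], c.iloc[1], atol=1e-8)
        assert out.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.normal(20, 2, (10, 4))
        q = qm(data, scale="log2")
        out = pca_profiles(q)
        # oracle: eigen-decomposition of the sample covariance of the
        # centered/scaled protein profiles
        X = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, ddof=1, keepdims=True)
        Xs = X.T - X.T.mean(axis=0, keepdims=True)
        cov = Xs.T @ Xs / (Xs.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(2):
            vec = v[:, i]
            nz = np.flatnonzero(vec)
            if vec[nz[0]] < 0:
                vec = -vec
            assert np.allclose(out.coordinates.iloc[:, i], Xs @ vec, atol=1e-8)
        assert np.allclose(out.explained_variance_ratio, (w / w.sum())[:2], atol=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(20, 2, (12, 4)),
                            index=[f"P{i}" for i in range(12)],
                            columns=list("abcd"))
        q1 = QuantMatrix(data, scale="log2")
        perm = data.sample(frac=1, random_state=1)
        q2 = QuantMatrix(perm, scale="log2")
        c1 = pca_profiles(q1).coordinates
        c2 = pca_profiles(q2).coordinates
        # same subspace and, with the first-nonzero-loading sign rule applied
        # to different first proteins, coordinates agree up to sign per axis
        for i in range(2):
            assert (np.allclose(c1.iloc[:, i], c2.iloc[:, i], atol=1e-8)
                    or np.allclose(c1.iloc[:, i], -c2.iloc[:, i], atol=1e-8))

    def test_too_few_complete_proteins_is_error(self):
        data = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0], [1.0, np.nan, 2.0]])
        with pytest.raises(ValueError, match="complete-case"):
            pca_profiles(qm(data, scale="log2"))


@pytest.fixture
def rank_fixture():
    anns = {
        "A": make_annotation("A", keywords="plasma membrane", tm=2),
        "B": make_annotation("B", keywords="cytosol", tm=0),
        "C": make_annotation("C", keywords="plasma membrane", tm=1),
        "D": make_annotation("D", keywords="cytosol", tm=0),
    }
    calls = classify_proteins(anns)
    q = qm([[10.0], [9.0], [8.0], [7.0]], columns=["s0"], index=list("ABCD"))
    return q, calls


class TestTopNComposition:
    def test_rank_walk(self, rank_fixture):
        q, calls = rank_fixture
        out = top_n_composition(q, calls, "s0", n=2)
        assert out.iloc[0]["pIMP"] == 1 and out.iloc[0]["SP"] == 1

    def test_all_soluble(self):
        anns = {f"P{i}": make_annotation(f"P{i}", keywords="cytosol") for i in range(5)}
        calls = classify_proteins(anns)
        q = qm(np.arange(1, 6).reshape(-1, 1), columns=["s0"], index=list(anns))
        out = top_n_composition(q, calls, "s0", n=3)
        assert out.iloc[0]["SP"] == 3 and out.iloc[0]["IMP"] == 0

    def test_tie_determinism(self, rank_fixture):
        q, calls = rank_fixture
        q.data.loc[:, "s0"] = 5.0  # full tie: lexicographic accession order
        out1 = top_n_composition(q, calls, "s0", n=2)
        out2 = top_n_composition(q, calls, "s0", n=2)
        pd.testing.assert_frame_equal(out1, out2)
        assert out1.iloc[0]["pIMP"] == 1 and out1.iloc[0]["SP"] == 1  # A, B

    def test_fewer_than_n_warns(self, rank_fixture):
        q, calls = rank_fixture
        with pytest.warns(UserWarning, match="present proteins"):
            out = top_n_composition(q, calls, "s0", n=10)
        assert out.iloc[0]["n"] == 4


class TestQuartileComposition:
    def test_direct_count(self):
        anns = {}
        for i in range(8):
            kw = "plasma membrane" if i < 4 else "cytosol"
            anns[f"P{i}"] = make_annotation(f"P{i}", keywords=kw, tm=2 if i < 4 else 0)
        calls = classify_proteins(anns)
        q = qm(np.arange(8, 0, -1).reshape(-1, 1), columns=["s0"], index=list(anns))
        out = quartile_composition(q, calls, "s0")
        assert out.loc["Q1", "IMP %"] == 100.0
        assert out.loc["Q4", "IMP %"] == 0.0

    def test_boundary_assignment_for_five_proteins(self):
        anns = {f"P{i}": make_annotation(f"P{i}", keywords="cytosol") for i in range(5)}
        calls = classify_proteins(anns)
        q = qm(np.arange(5, 0, -1).reshape(-1, 1), columns=["s0"], index=list(anns))
        out = quartile_composition(q, calls, "s0")
        assert list(out["n"]) == [2, 1, 1, 1]

    def test_uniform_mixture_gives_equal_percentages(self):
        anns = {}
        for i in range(8):
            kw = "plasma membrane" if i % 2 == 0 else "cytosol"
            anns[f"P{i}"] = make_annotation(f"P{i}", keywords=kw, tm=1 if i % 2 == 0 else 0)
        calls = classify_proteins(anns)
        q = qm(np.arange(8, 0, -1).reshape(-1, 1), columns=["s0"], index=list(anns))
        out = quartile_composition(q, calls, "s0")
        assert (out["IMP %"] == 50.0).all()


class TestMassBinRatio:
    def _fixture(self, n_imp_a, n_imp_b, mw=30.0):
        anns, rows_a, rows_b = {}, {}, {}
        for i in range(max(n_imp_a, n_imp_b)):
            pid = f"P{i}"
            anns[pid] = make_annotation(pid, keywords="plasma membrane", tm=2, mw=mw)
            rows_a[pid] = 1.0 if i < n_imp_a else np.nan
            rows_b[pid] = 1.0 if i < n_imp_b else np.nan
        qa = QuantMatrix(pd.DataFrame({"a1": rows_a}))
        qb = QuantMatrix(pd.DataFrame({"b1": rows_b}))
        return qa, qb, classify_proteins(anns), anns

    def test_simple_division(self):
        qa, qb, calls, anns = self._fixture(51, 100)
        out = mass_bin_ratio(qa, qb, calls, anns)
        assert out.loc["0–40 kDa", "ratio %"] == pytest.approx(51.0)

    def test_identical_matrices_give_100(self):
        qa, qb, calls, anns = self._fixture(10, 10, mw=120.0)
        out = mass_bin_ratio(qa, qa, calls, anns)
        assert out.loc[">100 kDa", "ratio %"] == pytest.approx(100.0)

    def test_empty_denominator_undefined(self):
        qa, qb, calls, anns = self._fixture(5, 5, mw=30.0)
        out = mass_bin_ratio(qa, qb, calls, anns)
        assert np.isnan(out.loc[">100 kDa", "ratio %"])


class TestExclusiveSetOverlaps:
    def test_simple_overlap(self):
        out = exclusive_set_overlaps({"A": {"p1", "p2"}, "B": {"p2", "p3"}})
        sizes = dict(zip(out["pattern"], out["size"]))
        assert sizes == {"A": 1, "B": 1, "A&B": 1}

    def test_identical_sets_single_pattern(self):
        out = exclusive_set_overlaps({"A": {"x", "y"}, "B": {"x", "y"}})
        assert len(out) == 1
        assert out.iloc[0]["pattern"] == "A&B" and out.iloc[0]["size"] == 2

    @given(
        st.lists(
            st.sets(st.integers(min_value=0, max_value=30), max_size=15),
            min_size=2, max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_property(self, families):
        sets = {f"S{i}": s for i, s in enumerate(families)}
        union = set().union(*sets.values())
        if not union:
            return
        out = exclusive_set_overlaps(sets)
        assert out["size"].sum() == len(union)


class TestHeatmapMatrix:
    def test_all_missing_row_becomes_zero(self):
        q = qm([[np.nan, np.nan, np.nan]], scale="log2")
        out = heatmap_matrix(q)
        assert (out.iloc[0] == 0).all()

    def test_two_value_row_hand_computed(self):
        q = qm([[2.0, 4.0]], scale="log2")
        out = heatmap_matrix(q)
        assert out.iloc[0, 0] == pytest.approx(-1 / np.sqrt(2))
        assert out.iloc[0, 1] == pytest.approx(+1 / np.sqrt(2))

    def test_rows_standardized(self):
        rng = np.random.default_rng(8)
        data = rng.normal(20, 3, (20, 6))
        data[data < 17] = np.nan
        out = heatmap_matrix(qm(data, scale="log2"))
        means = out.mean(axis=1)
        sds = out.std(axis=1, ddof=1)
        assert np.allclose(means, 0, atol=1e-10)
        assert all(np.isclose(s, 1.0) or np.isclose(s, 0.0) for s in sds)
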