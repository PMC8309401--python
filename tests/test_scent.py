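"""Volatile composition tables, the floral filter, and similarities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from floracues.scent import (
    CompoundTable,
    SimilarityMatrix,
    binarise,
    bray_curtis_similarity,
    floral_filter,
    fourth_root,
    relative_amounts,
    similarity_matrix,
    sorensen_similarity,
    top_k_share,
)


def table(values, species, columns=None, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    columns = columns or [f"c{i}" for i in range(values.shape[1])]
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return CompoundTable(
        values=pd.DataFrame(values, index=samples, columns=columns),
        species=pd.Series(species, index=samples),
    )


class TestFloralFilter:
    def make_pair(self, floral_mean, veg_mean):
        # c2 is a leaf volatile so the control sample is never empty
        flo = table([[floral_mean, 500.0, 0.0]], ["A"])
        veg = table([[veg_mean, 0.0, 30.0]], ["A"], samples=["v0"])
        return flo, veg

    def test_twenty_fold_kept(self):
        flo, veg = self.make_pair(1000.0, 50.0)
        out, _ = floral_filter(flo, veg)
        assert "c0" in out.compounds

    def test_five_fold_removed(self):
        flo, veg = self.make_pair(1000.0, 200.0)
        out, log = floral_filter(flo, veg)
        assert "c0" not in out.compounds
        assert log["removed"]["A"] == ["c0"]

    def test_exclusively_floral_kept(self):
        flo, veg = self.make_pair(3.0, 0.0)
        out, _ = floral_filter(flo, veg)
        assert set(out.compounds) == {"c0", "c1"}

    def test_boundary_exact_tenfold_kept(self):
        flo, veg = self.make_pair(1000.0, 100.0)
        out, _ = floral_filter(flo, veg)
        assert "c0" in out.compounds

    def test_per_species_decision(self):
        # compound is floral for A (clean) but vegetative for B (2-fold)
        flo = table([[100.0, 10.0], [100.0, 10.0]], ["A", "B"])
        veg = table([[0.0, 1.0], [50.0, 1.0]], ["A", "B"],
                    samples=["vA", "vB"])
        out, _ = floral_filter(flo, veg)
        assert out.values.loc["s0", "c0"] == 100.0
        assert out.values.loc["s1", "c0"] == 0.0

    def test_missing_controls_warns_and_keeps(self):
        flo = table([[100.0, 10.0]], ["A"])
        veg = table([[50.0, 0.0]], ["B"], samples=["vB"])
        with pytest.warns(UserWarning, match="no vegetative controls"):
            out, log = floral_filter(flo, veg)
        assert log["no_controls"] == ["A"]
        assert out.compounds == ["c0", "c1"]

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(3)
        flo = table(rng.uniform(0, 100, size=(6, 8)),
                    ["A"] * 3 + ["B"] * 3)
        veg = table(rng.uniform(0, 3, size=(4, 8)),
                    ["A"] * 2 + ["B"] * 2,
                    samples=[f"v{i}" for i in range(4)])
        once, _ = floral_filter(flo, veg)
        twice, _ = floral_filter(once, veg)
        assert once.compounds == twice.compounds
        np.testing.assert_allclose(once.values, twice.values[once.compounds])


class TestTransforms:
    def test_relative_amounts(self):
        t = relative_amounts(table([[2.0, 2.0, 4.0]], ["A"]))
        np.testing.assert_allclose(t.values.iloc[0], [25, 25, 50])

    def test_relative_amounts_idempotent(self):
        t = relative_amounts(table([[30.0, 70.0]], ["A"]))
        t2 = relative_amounts(t)
        np.testing.assert_allclose(t.values, t2.values)

    def test_zero_sample_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no positive entry"):
            table([[0.0, 0.0, 0.0]], ["A"])

    @pytest.mark.parametrize("x,root", [(16.0, 2.0), (0.0, 0.0), (81.0, 3.0)])
    def test_fourth_root_values(self, x, root):
        t = fourth_root(table([[x, 1.0]], ["A"]))
        assert t.values.iloc[0, 0] == pytest.approx(root)

    def test_fourth_root_preserves_within_sample_ranking(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 100, size=12)
        t = fourth_root(table([v], ["A"]))
        assert list(np.argsort(v)) == list(np.argsort(t.values.iloc[0]))


class TestSimilarities:
    def test_identical_vectors_are_100(self):
        v = np.array([3.0, 1.0, 0.0])
        assert bray_curtis_similarity(v, v) == pytest.approx(100.0)
        assert sorensen_similarity(v, v) == pytest.approx(100.0)

    def test_disjoint_supports_are_0(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        assert bray_curtis_similarity(a, b) == 0.0
        assert sorensen_similarity(a, b) == 0.0

    def test_bray_curtis_hand_value(self):
        a, b = np.array([75.0, 25.0, 0.0]), np.array([0.0, 25.0, 75.0])
        assert bray_curtis_similarity(a, b) == pytest.approx(25.0)

    def test_sorensen_hand_value(self):
        a = np.array([1.0, 1.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 1.0])
        assert sorensen_similarity(a, b) == pytest.approx(100 * 2 * 2 / 6)

    def test_sorensen_equals_bray_curtis_on_binary_data(self, rng):
        for _ in range(20):
            a = (rng.random(10) < 0.5).astype(float)
            b = (rng.random(10) < 0.5).astype(float)
            if a.sum() + b.sum() == 0:
                continue
            assert sorensen_similarity(a, b) == pytest.approx(
                bray_curtis_similarity(a, b)
            )

    def test_both_empty_rejected(self):
        z = np.zeros(3)
        with pytest.raises(ValueError):
            bray_curtis_similarity(z, z)
        with pytest.raises(ValueError):
            sorensen_similarity(z, z)

    def test_matrix_is_valid_similarity(self, rng):
        t = table(rng.uniform(0, 50, size=(5, 7)), list("AABBC"))
        sim = similarity_matrix(t, "bray-curtis")
        assert isinstance(sim, SimilarityMatrix)
        v = sim.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 100.0)
        assert v.min() >= 0 and v.max() <= 100 + 1e-9

    def test_cross_check_against_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.diversity")
        from skbio.diversity import beta_diversity

        V = rng.uniform(0, 50, size=(6, 9))
        t = table(V, list("AABBCC"))
        sim = similarity_matrix(t, "bray-curtis")
        ref = beta_diversity("braycurtis", V).data * 100.0
        np.testing.assert_allclose(
            100.0 - sim.values.to_numpy(), ref, atol=1e-8
        )


abundance_pairs = st.integers(2, 12).flatmap(
    lambda n: st.tuples(
        hnp.arrays(float, n, elements=st.floats(0, 1e4)),
        hnp.arrays(float, n, elements=st.floats(0, 1e4)),
    )
)


class TestSimilarityProperties:
    @settings(max_examples=100, derandomize=True)
    @given(abundance_pairs)
    def test_bounded_symmetric_and_binarisation_consistent(self, pair):
        a, b = pair
        if a.sum() + b.sum() == 0:
            return
        s = bray_curtis_similarity(a, b)
        assert 0.0 <= s <= 100.0
        assert s == pytest.approx(bray_curtis_similarity(b, a))
        # Sorensen is Bray-Curtis on the binarised vectors
        assert sorensen_similarity(a, b) == pytest.approx(
            bray_curtis_similarity((a > 0).astype(float),
                                   (b > 0).astype(float))
        )

    @settings(max_examples=50, derandomize=True)
    @given(hnp.arrays(float, 8, elements=st.floats(0.01, 1e3)))
    def test_fourth_root_then_normalise_keeps_rank_order(self, v):
        t = fourth_root(
            relative_amounts(
                CompoundTable(
                    values=pd.DataFrame([v]),
                    species=pd.Series(["A"], index=[0]),
                )
            )
        )
        assert list(np.argsort(v, kind="stable")) == list(
            np.argsort(t.values.iloc[0].to_numpy(), kind="stable")
        )


class TestTopKShare:
    def test_single_sample(self):
        t = table([[50, 30, 10, 5, 3, 2]], ["A"])
        assert top_k_share(relative_amounts(t), "A", k=5) == pytest.approx(98.0)

    def test_k_at_least_p_gives_100(self):
        t = relative_amounts(table([[40, 40, 20]], ["A"]))
        assert top_k_share(t, "A", k=10) == pytest.approx(100.0)

    def test_species_mean_ranking_across_samples(self):
        t = relative_amounts(
            table([[60, 40, 0], [40, 40, 20]], ["A", "A"])
        )
        assert top_k_share(t, "A", k=1) == pytest.approx(50.0)
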