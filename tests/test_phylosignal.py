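"""Phylogenetic-signal statistics: Cmean, Blomberg K, Kmult, Pagel lambda."""

import subprocess

import numpy as np
import pytest

from floracues.phylo import PhyloTree
from floracues.phylosignal import (
    blomberg_k,
    cmean_test,
    kmult,
    morans_i,
    pagel_lambda_fit,
)
from floracues.synth import gen_yule_tree, sim_traits


class TestMoransI:
    def test_matches_hand_arithmetic_on_balanced_four(self, balanced_four):
        W, labels = balanced_four.abouheif_proximity("row")
        x = np.array([1.0, 1.0, -1.0, -1.0])  # (A,B) vs (C,D)
        z = x - x.mean()
        expected = z @ W @ z / (z @ z)
        assert morans_i(x, W) == pytest.approx(expected)
        # hand value: rows are (2/3) to the cherry mate, (1/6) across,
        # so each term contributes 2/3 - 2*(1/6) = 1/3
        assert morans_i(x, W) == pytest.approx(1 / 3)

    def test_null_expectation_minus_one_over_n_minus_1(self, yule14, rng):
        W, _ = yule14.abouheif_proximity("row")
        n = 14
        x = rng.normal(size=n)
        vals = [
            morans_i(x[rng.permutation(n)], W) for _ in range(4000)
        ]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.01)

    def test_constant_trait_rejected(self, yule14):
        W, _ = yule14.abouheif_proximity("row")
        with pytest.raises(ValueError):
            morans_i(np.ones(14), W)


class TestCmean:
    def test_permutation_granularity(self, yule14, rng):
        x = rng.normal(size=14)
        res = cmean_test(x, yule14, n_perm=999, seed=0)
        assert res.p * 1000 == pytest.approx(round(res.p * 1000))
        assert 1 / 1000 <= res.p <= 1.0

    def test_detects_strong_clade_structure(self):
        tree = gen_yule_tree(16, seed=11)
        hits = 0
        for rep in range(40):
            x = sim_traits(tree, p=1, lam=1.0, sigma2=4.0,
                           seed=100 + rep).to_numpy().ravel()
            res = cmean_test(x, tree, n_perm=199, seed=rep)
            hits += res.p <= 0.05
        assert hits >= 0.65 * 40  # BM on a 16-tip tree is usually detected

    def test_reproducible_given_seed(self, yule14, rng):
        x = rng.normal(size=14)
        a = cmean_test(x, yule14, n_perm=499, seed=9)
        b = cmean_test(x, yule14, n_perm=499, seed=9)
        assert (a.value, a.p) == (b.value, b.p)


class TestBlombergK:
    def test_star_tree_K_is_exactly_one(self, rng):
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        for _ in range(5):
            assert blomberg_k(rng.normal(size=5), star) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_bm_simulations_centre_on_one(self):
        tree = gen_yule_tree(20, seed=2)
        C, _ = tree.bm_covariance()
        vals = [
            blomberg_k(
                sim_traits(tree, p=1, seed=s).to_numpy().ravel(), C=C
            )
            for s in range(300)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_matches_phytools_reference(self):
        """Independent oracle: phytools::phylosig K on the same data."""
        tree = gen_yule_tree(12, seed=4)
        x = sim_traits(tree, p=1, lam=0.6, seed=8).to_numpy().ravel()
        k_py = blomberg_k(x, tree)
        labels = tree.tip_labels
        r_code = (
            "suppressMessages(library(phytools));"
            f"tr <- read.tree(text='{tree.to_newick()}');"
            f"x <- c({','.join(f'{v:.15g}' for v in x)});"
            f"names(x) <- c({','.join(repr(l) for l in labels)});"
            'cat(sprintf("%.10f", phylosig(tr, x, method="K")))'
        )
        out = subprocess.run(["Rscript", "-e", r_code],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert k_py == pytest.approx(float(out.stdout), rel=1e-6)


class TestKmult:
    def test_reduces_to_blomberg_k_for_single_trait(self):
        tree = gen_yule_tree(10, seed=3)
        for s in range(20):
            x = sim_traits(tree, p=1, seed=s).to_numpy()
            km = kmult(x, tree, n_perm=9, seed=0).value
            assert km == pytest.approx(blomberg_k(x.ravel(), tree),
                                       abs=1e-10)

    def test_invariant_to_column_shifts_and_global_scaling(self, yule14, rng):
        X = sim_traits(yule14, p=4, seed=5).to_numpy()
        base = kmult(X, yule14, n_perm=9, seed=0).value
        shifted = X + rng.normal(size=(1, 4))
        scaled = 3.7 * X
        assert kmult(shifted, yule14, n_perm=9, seed=0).value == pytest.approx(
            base, rel=1e-10
        )
        assert kmult(scaled, yule14, n_perm=9, seed=0).value == pytest.approx(
            base, rel=1e-10
        )

    def test_null_rows_give_uniform_p_on_average(self, yule14, rng):
        # traits unrelated to the tree: the observed K is a typical
        # member of its own permutation distribution
        ps = []
        for i in range(30):
            X = rng.normal(size=(14, 5))
            ps.append(kmult(X, yule14, n_perm=199, seed=i).p)
        assert 0.3 < float(np.mean(ps)) < 0.7


class TestPagelLambda:
    def test_loglik_at_optimum_dominates_zero(self, yule14):
        for s in range(5):
            x = sim_traits(yule14, p=1, lam=0.8, seed=40 + s)
            res = pagel_lambda_fit(x.to_numpy().ravel(), yule14)
            assert res.nuisance["lnL_hat"] >= res.nuisance["lnL_0"] - 1e-9

    def test_iid_data_fits_lambda_zero_with_p_one(self, yule14, rng):
        zero_hits = 0
        for _ in range(20):
            x = rng.normal(size=14)
            res = pagel_lambda_fit(x, yule14)
            if res.value == 0.0:
                zero_hits += 1
                assert res.p == 1.0
        assert zero_hits >= 10

    def test_non_ultrametric_rejected(self):
        t = PhyloTree.from_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            pagel_lambda_fit(np.array([1.0, 2.0, 3.0]), t)

    def test_matches_phytools_reference(self):
        """Independent oracle: phytools::phylosig lambda fit."""
        tree = gen_yule_tree(14, seed=1)
        x = sim_traits(tree, p=1, lam=0.7, seed=42).to_numpy().ravel()
        res = pagel_lambda_fit(x, tree)
        labels = tree.tip_labels
        r_code = (
            "suppressMessages(library(phytools));"
            f"tr <- read.tree(text='{tree.to_newick()}');"
            f"x <- c({','.join(f'{v:.15g}' for v in x)});"
            f"names(x) <- c({','.join(repr(l) for l in labels)});"
            'f <- phylosig(tr, x, method="lambda");'
            'cat(sprintf("%.8f %.8f", f$lambda, f$logL))'
        )
        out = subprocess.run(["Rscript", "-e", r_code],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        lam_r, lnl_r = map(float, out.stdout.split())
        assert res.value == pytest.approx(lam_r, abs=1e-4)
        assert res.nuisance["lnL_hat"] == pytest.approx(lnl_r, abs=1e-4)
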