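import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from colonscape.diversity import bray_curtis
from colonscape.ordination import (
    dbrda,
    design_matrices,
    pcoa,
    permanova,
    variation_partition,
)


def euclidean_frame(x):
    d = squareform(pdist(np.asarray(x, float)))
    ids = [f"s{i}" for i in range(d.shape[0])]
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_two_points(self):
        d = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        np.testing.assert_allclose(
            np.abs(res.coordinates.iloc[:, 0].to_numpy()), [1.0, 1.0], atol=1e-12
        )

    def test_three_equidistant_points(self):
        ids = list("abc")
        d = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-9)

    def test_euclidean_input_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 4))
        d = euclidean_frame(x)
        res = pcoa(d)
        assert not res.correction_applied
        recon = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-9)

    def test_lingoes_correction_on_bray_curtis(self, random_tables):
        d = bray_curtis(random_tables[0])
        res = pcoa(d)
        assert res.correction_applied
        assert res.lingoes_constant > 0
        assert res.eigenvalues.min() >= -1e-8 * res.eigenvalues.max()

    def test_single_sample_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            pcoa(d)


# ---------------------------------------------------------------------------
# perMANOVA
# ---------------------------------------------------------------------------

def permanova_ss_oracle(d, labels):
    """Naive triple-loop partition of squared dissimilarities."""
    d = np.asarray(d, float)
    n = d.shape[0]
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_g = sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        )
        ss_within += ss_g / len(idx)
    return ss_total, ss_within


class TestPermanova:
    def test_ss_partition_matches_oracle(self, random_tables):
        labels = list("aaaabbbbcccc")
        for table in random_tables[:5]:
            d = bray_curtis(table)
            res = permanova(d, labels, n_perm=9, seed=0)
            ss_total, ss_within = permanova_ss_oracle(d.to_numpy(), labels)
            assert res.ss_total == pytest.approx(ss_total, abs=1e-12)
            assert res.ss_within == pytest.approx(ss_within, abs=1e-12)
            assert res.ss_between + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        d = euclidean_frame(rng.normal(size=(6, 3)))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(d, labels, n_perm=10_000, seed=1)
        # exhaustive: all distinct relabelings of 3 vs 3
        f_obs = res.statistic
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            fs.append(permanova(d, lab, n_perm=0, seed=0).statistic)
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.pvalue == pytest.approx(exact_p, abs=0.02)

    def test_separated_clusters_reach_minimal_p(self):
        # groups large enough that no sampled relabeling recreates the
        # partition (which would tie the observed, maximal F)
        x = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
        x += np.random.default_rng(0).normal(0, 0.005, x.shape)
        d = euclidean_frame(x)
        labels = ["a"] * 10 + ["b"] * 10
        res = permanova(d, labels, n_perm=199, seed=3)
        assert res.pvalue == pytest.approx(1.0 / 200.0)

    def test_f_invariant_to_distance_scaling(self, random_tables):
        d = bray_curtis(random_tables[1])
        labels = list("aaaabbbbcccc")
        f1 = permanova(d, labels, n_perm=9, seed=0).statistic
        f2 = permanova(d * 3.0, labels, n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_scikit_bio(self, random_tables):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d = bray_curtis(random_tables[2])
        labels = list("aaaabbbbcccc")
        ours = permanova(d, labels, n_perm=99, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=labels, permutations=99,
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_degenerate_grouping_rejected(self):
        d = euclidean_frame(np.eye(4))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# db-RDA and variation partitioning
# ---------------------------------------------------------------------------

class TestDbrda:
    def test_perfect_linear_response(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 2))
        y = x @ rng.normal(size=(2, 3))
        res = dbrda(euclidean_frame(y), x)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_ezekiel_adjustment_formula(self):
        # construct a fit with known R2 = 0.5 at n = 11, m = 1 and check
        # the closed-form adjustment on the result object's inputs
        from colonscape.ordination import _adjust

        assert _adjust(0.5, 11, 1) == pytest.approx(0.444444444, abs=1e-9)

    def test_noise_predictors_give_unbiased_adjusted_r2(self):
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(200):
            y = rng.normal(size=(50, 4))
            x = rng.normal(size=(50, 3))
            vals.append(dbrda(euclidean_frame(y), x).adj_r2)
        assert abs(np.mean(vals)) < 0.02

    def test_conditioning_removes_shared_signal(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(30, 1))
        y = z @ np.ones((1, 2)) + rng.normal(0, 0.01, size=(30, 2))
        res = dbrda(euclidean_frame(y), z, condition=z)
        assert res.r2 == pytest.approx(0.0, abs=1e-6)

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            dbrda(euclidean_frame(y), rng.normal(size=(5, 5)))


class TestVariationPartition:
    def test_noise_free_signal_attributed_to_its_block(self):
        rng = np.random.default_rng(8)
        x1 = rng.normal(size=(40, 2))
        x2 = rng.normal(size=(40, 2))
        y = x1 @ rng.normal(size=(2, 3))
        part = variation_partition(euclidean_frame(y), {"x1": x1, "x2": x2})
        assert part.unique["x1"] > 0.9
        assert abs(part.unique["x2"]) < 0.05

    def test_order_invariance(self, random_tables):
        d = bray_curtis(random_tables[3])
        rng = np.random.default_rng(9)
        blocks = {"a": rng.normal(size=(12, 2)), "b": rng.normal(size=(12, 1)),
                  "c": rng.normal(size=(12, 1))}
        p1 = variation_partition(d, blocks)
        p2 = variation_partition(d, dict(reversed(list(blocks.items()))))
        for key, val in p1.fractions.items():
            assert p2.fractions[key] == pytest.approx(val, abs=1e-12)

    def test_fractions_sum_to_total(self, random_tables):
        d = bray_curtis(random_tables[4])
        rng = np.random.default_rng(10)
        blocks = {"a": rng.normal(size=(12, 2)), "b": rng.normal(size=(12, 2))}
        part = variation_partition(d, blocks)
        assert sum(part.fractions.values()) == pytest.approx(part.total_adj_r2, abs=1e-9)
        assert part.residual == pytest.approx(1.0 - part.total_adj_r2, abs=1e-12)

    def test_matches_vegan_varpart(self, tmp_path):
        """Independent oracle: vegan's varpart on the same Euclidean data.

        RDA of Y equals db-RDA of the Euclidean distances of Y, so the
        adjusted fractions must agree.
        """
        rng = np.random.default_rng(12)
        y = rng.normal(size=(24, 5))
        x1 = rng.normal(size=(24, 2))
        x2 = rng.normal(size=(24, 2))
        y[:, 0] += x1[:, 0]
        y[:, 1] += 0.5 * x2[:, 1]
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "x1.csv", x1, delimiter=",")
        np.savetxt(tmp_path / "x2.csv", x2, delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            y <- as.matrix(read.csv("y.csv", header = FALSE))
            x1 <- as.matrix(read.csv("x1.csv", header = FALSE))
            x2 <- as.matrix(read.csv("x2.csv", header = FALSE))
            vp <- varpart(y, x1, x2)
            f <- vp$part$indfract$Adj.R.square
            cat(sprintf("%.10f %.10f %.10f\\n", f[1], f[2], f[3]))
        """)
        (tmp_path / "vp.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "vp.R"], cwd=tmp_path, capture_output=True, text=True,
            check=True,
        )
        # vegan's indfract rows: [a] = X1|X2, [b] = X2|X1, [c] = shared
        a, b, c = (float(v) for v in out.stdout.split())
        part = variation_partition(euclidean_frame(y), {"x1": x1, "x2": x2})
        assert part.fractions[frozenset(["x1"])] == pytest.approx(a, abs=1e-6)
        assert part.fractions[frozenset(["x2"])] == pytest.approx(b, abs=1e-6)
        assert part.fractions[frozenset(["x1", "x2"])] == pytest.approx(c, abs=1e-6)

    def test_wrong_block_count_rejected(self, random_tables):
        d = bray_curtis(random_tables[0])
        with pytest.raises(ValueError):
            variation_partition(d, {"only": np.ones((12, 1))})


class TestDesignMatrices:
    def test_blocks_present_and_shaped(self):
        md = pd.DataFrame(
            {"block": [1, 2, 3, 4], "compartment": ["mucus", "lumen"] * 2,
             "diet": ["CON", "CON", "FD", "FD"]}
        )
        mats = design_matrices(md)
        assert set(mats) == {"longitudinal", "lateral", "diet"}
        assert mats["longitudinal"].shape == (4, 2)
        np.testing.assert_allclose(mats["lateral"][:, 0], [1, 0, 1, 0])

    def test_orthogonal_polynomials_are_orthogonal(self):
        md = pd.DataFrame({"block": np.tile(np.arange(1, 8), 4)})
        poly = design_matrices(md)["longitudinal"]
        gram = poly.T @ poly
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-10)
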