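import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import pearsonr, spearmanr

from apucnet import (
    alan_matrix,
    alan_profile,
    cluster_hierarchical,
    coalescence_score,
    embed_profiles,
    first_order_correlation,
    generate_expression,
)

from conftest import make_expr


def two_loop_alan_oracle(values: np.ndarray) -> np.ndarray:
    """Explicit reference: ranks -> Spearman matrix -> profile Pearson with
    self-columns removed, one pair at a time."""
    n = values.shape[0]
    c = spearmanr(values, axis=1).statistic
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k not in (i, j)]
            r = pearsonr(c[i, keep], c[j, keep]).statistic
            out[i, j] = out[j, i] = r
    return out


class TestFirstOrder:
    def test_duplicated_gene_correlates_perfectly(self, rng):
        x = rng.normal(size=8)
        m = make_expr([x, x, rng.normal(size=8)], unit="logTPM")
        c = first_order_correlation(m)
        assert c.loc["g0", "g1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_negation_gives_minus_one(self, rng, method):
        x = rng.normal(size=10)
        m = make_expr([x, -x], unit="logTPM")
        c = first_order_correlation(m, method=method)
        assert c.loc["g0", "g1"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_matches_per_pair_scalar_oracle(self, rng, method):
        m = make_expr(rng.lognormal(size=(4, 8)))
        c = first_order_correlation(m, method=method)
        fn = spearmanr if method == "spearman" else pearsonr
        for i in range(4):
            for j in range(4):
                ref = 1.0 if i == j else fn(m.values.iloc[i], m.values.iloc[j]).statistic
                assert c.iloc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            first_order_correlation(make_expr([[1, 2], [3, 4]]))

    def test_constant_gene_flagged_missing(self, rng):
        m = make_expr([np.ones(6), rng.normal(size=6), rng.normal(size=6)], unit="logTPM")
        c = first_order_correlation(m)
        assert c.loc["g0", "g1"] != c.loc["g0", "g1"]  # NaN
        assert c.loc["g0", "g0"] == 1.0


class TestAlanMatrix:
    def test_duplicated_genes_have_association_one(self, rng):
        x = rng.normal(size=10)
        rows = [x, x] + [rng.normal(size=10) for _ in range(4)]
        a = alan_matrix(make_expr(rows, unit="logTPM"))
        assert a.values.loc["g0", "g1"] == pytest.approx(1.0, abs=1e-10)

    def test_unit_diagonal(self, random_tpm):
        a = alan_matrix(random_tpm)
        assert (np.diag(a.values.to_numpy()) == 1.0).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_two_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(5, 13))
        n_samples = int(rng.integers(6, 16))
        m = make_expr(rng.lognormal(1.0, 1.0, size=(n_genes, n_samples)))
        a = alan_matrix(m).values.to_numpy()
        ref = two_loop_alan_oracle(m.values.to_numpy())
        assert np.abs(a - ref).max() < 1e-10

    def test_constant_gene_is_error_listing_gene(self, rng):
        rows = [rng.normal(size=8) for _ in range(5)] + [np.full(8, 3.0)]
        with pytest.raises(ValueError, match="g5"):
            alan_matrix(make_expr(rows, unit="logTPM"))

    def test_permutation_equivariance(self, rng, random_tpm):
        a = alan_matrix(random_tpm)
        perm = rng.permutation(random_tpm.gene_ids)
        m2 = make_expr(
            random_tpm.values.loc[perm].to_numpy(),
            genes=list(perm),
            samples=random_tpm.sample_ids,
        )
        a2 = alan_matrix(m2)
        pd.testing.assert_frame_equal(
            a2.values, a.values.loc[perm, perm], atol=1e-12, rtol=0
        )

    def test_sample_order_invariance(self, rng, random_tpm):
        a = alan_matrix(random_tpm).values.to_numpy()
        cols = rng.permutation(random_tpm.sample_ids)
        m2 = make_expr(
            random_tpm.values[cols].to_numpy(),
            genes=random_tpm.gene_ids,
            samples=list(cols),
        )
        assert np.allclose(alan_matrix(m2).values.to_numpy(), a, atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_symmetry_and_range_on_random_input(self, seed):
        rng = np.random.default_rng(seed)
        m = make_expr(rng.lognormal(size=(6, 9)))
        a = alan_matrix(m).values.to_numpy()
        assert np.allclose(a, a.T, atol=1e-10)
        assert np.abs(a).max() <= 1.0


class TestProfilesAndScore:
    def test_profile_length_and_range(self, random_tpm):
        a = alan_matrix(random_tpm)
        prof = alan_profile(a, "g3")
        assert len(prof) == len(random_tpm.gene_ids) - 1
        assert "g3" not in prof.index
        assert prof.abs().max() <= 1.0

    def test_unknown_gene_is_error(self, random_tpm):
        with pytest.raises(KeyError):
            alan_profile(alan_matrix(random_tpm), "nope")

    def test_duplicated_genes_have_identical_profiles(self, rng):
        x = rng.normal(size=12)
        rows = [x, x] + [rng.normal(size=12) for _ in range(5)]
        a = alan_matrix(make_expr(rows, unit="logTPM"))
        p0 = alan_profile(a, "g0").drop("g1")
        p1 = alan_profile(a, "g1").drop("g0")
        assert np.allclose(p0.to_numpy(), p1.to_numpy(), atol=1e-10)

    def test_duplicate_set_scores_one(self, rng):
        x = rng.normal(size=10)
        rows = [x, x, x] + [rng.normal(size=10) for _ in range(4)]
        a = alan_matrix(make_expr(rows, unit="logTPM"))
        assert coalescence_score(a, ["g0", "g1", "g2"]) == pytest.approx(1.0, abs=1e-10)

    def test_null_noise_score_near_zero(self):
        rng = np.random.default_rng(3)
        m = make_expr(rng.lognormal(size=(20, 200)))
        a = alan_matrix(m)
        assert abs(coalescence_score(a, [f"g{i}" for i in range(6)])) < 0.1

    def test_fewer_than_two_found_is_error(self, random_tpm):
        a = alan_matrix(random_tpm)
        with pytest.raises(ValueError, match=">= 2"):
            coalescence_score(a, ["g0", "absent"])


class TestClustering:
    def test_two_perfect_blocks_split_at_k2(self):
        sim = np.zeros((6, 6))
        sim[:3, :3] = 1.0
        sim[3:, 3:] = 1.0
        np.fill_diagonal(sim, 1.0)
        ids = list("abcdef")
        res = cluster_hierarchical(pd.DataFrame(sim, index=ids, columns=ids))
        labels = res.cut(2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels["a"] != labels["f"]

    def test_single_gene_is_single_leaf(self):
        res = cluster_hierarchical(pd.DataFrame([[1.0]], index=["a"], columns=["a"]))
        assert res.leaf_order == ["a"]
        assert list(res.cut(1)) == [1]

    def test_asymmetric_input_is_error(self):
        d = pd.DataFrame([[1.0, 0.5], [0.1, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            cluster_hierarchical(d)

    def test_samples_mode_groups_shifted_columns(self, rng):
        left = rng.normal(0, 1, size=(10, 4))
        right = rng.normal(8, 1, size=(10, 4))
        df = pd.DataFrame(
            np.hstack([left, right]), columns=[f"s{i}" for i in range(8)]
        )
        labels = cluster_hierarchical(df, on="samples").cut(2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels["s0"] != labels["s7"]

    def test_planted_module_isolated_at_k2(self, staged_config):
        from sklearn.metrics import adjusted_rand_score

        m = generate_expression(staged_config, "metastatic")
        a = alan_matrix(m)
        labels = cluster_hierarchical(a.values).cut(2)
        truth = [1 if g in staged_config.module_genes else 0 for g in labels.index]
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0


class TestEmbedding:
    def test_shape_seed_determinism_and_duplicate_neighbourhood(self, rng):
        x = rng.normal(size=25)
        rows = [x, x] + [rng.normal(size=25) for _ in range(38)]
        a = alan_matrix(make_expr(rows, unit="logTPM"))
        coords = embed_profiles(a, seed=11)
        assert coords.shape == (40, 2)
        again = embed_profiles(a, seed=11)
        assert np.allclose(coords.to_numpy(), again.to_numpy())
        d = np.linalg.norm(
            coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :], axis=-1
        )
        dup = d[0, 1]
        all_pairs = d[np.triu_indices(40, 1)]
        assert dup < np.percentile(all_pairs, 5)

    def test_too_few_genes_is_error(self, rng):
        a = alan_matrix(make_expr(rng.lognormal(size=(6, 12))))
        with pytest.raises(ValueError, match=">= 10"):
            embed_profiles(a, seed=0)

    def test_planted_module_compact_in_embedding(self, staged_config):
        m = generate_expression(staged_config, "metastatic")
        a = alan_matrix(m)
        coords = embed_profiles(a, seed=3).to_numpy()
        is_mod = np.array([g in staged_config.module_genes for g in a.gene_ids])
        mod = coords[is_mod]
        bg = coords[~is_mod]
        intra = np.mean(
            [np.linalg.norm(p - q) for i, p in enumerate(mod) for q in mod[i + 1 :]]
        )
        cross = np.mean([np.linalg.norm(p - q) for p in mod for q in bg])
        assert intra < cross
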