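"""Tests for the feature-selection suite, including brute-force oracle
equivalence for the greedy cosine filter, ReliefF and CMIM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpdeep.data import CASE, CONTROL, EncodedMatrix, GenotypeMatrix
from snpdeep.errors import ValidationError
from snpdeep.select import (
    FS_METHODS,
    FeatureRanking,
    amgm_ratio,
    autoencoder_l1_ranking,
    cmim_select,
    cosine_redundancy_filter,
    cosine_similarity,
    hybrid_cmim_svmrfe,
    rank_by_amgm,
    relieff_weights,
    select_features,
    svm_rfe_select,
    univariate_ranking,
)

from conftest import make_matrix


def encoded_from_array(X: np.ndarray, y: np.ndarray | None = None) -> EncodedMatrix:
    n, d = X.shape
    if y is None:
        y = np.tile([1, 0], n)[:n]
    values = pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=[f"rs{j:03d}" for j in range(d)])
    labels = pd.Series(np.where(y == 1, CASE, CONTROL), index=values.index)
    return EncodedMatrix(values, labels)


# ---------------------------------------------------------------------------
# AMGM
# ---------------------------------------------------------------------------


class TestAmgm:
    def test_constant_vector_is_one(self):
        assert amgm_ratio(np.full(7, 0.37)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_example(self):
        assert amgm_ratio(np.array([1.0, 2.0, 4.0])) == pytest.approx(7 / 6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            amgm_ratio(np.array([0.5, 0.0, 1.0]))

    @given(st.lists(st.floats(1e-4, 1e4), min_size=1, max_size=40))
    def test_am_gm_inequality(self, values):
        v = np.array(values)
        r = amgm_ratio(v)
        assert r >= 1 - 1e-9
        if np.ptp(v) > 1e-6 * v.max():
            assert r > 1
        if np.ptp(v) == 0:
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_constant_snp_ranked_last_variable_first(self):
        X = encoded_from_array(
            np.column_stack([np.full(8, 0.5), np.tile([0.2, 0.8], 4)])
        )
        ranking = rank_by_amgm(X)
        assert ranking.snp_ids == ["rs001", "rs000"]
        assert ranking.scores[-1] == pytest.approx(1.0, abs=1e-6)


class TestCosine:
    def test_identity(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert cosine_similarity([1.0, 1.0], [1.0, 0.0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


def brute_force_greedy_cosine(X, order, n_final, tau):
    """Independent restatement of the greedy rule, O(kept * candidates)."""
    kept, skipped = [], []
    for snp in order:
        if len(kept) >= n_final:
            break
        v = X[snp].to_numpy()
        if all(
            cosine_similarity(v, X[k].to_numpy()) < tau for k in kept
        ):
            kept.append(snp)
        else:
            skipped.append(snp)
    return kept + skipped[: n_final - len(kept)]


class TestCosineRedundancyFilter:
    def _ranked(self, X):
        return rank_by_amgm(X)

    def test_duplicate_skipped(self):
        rng = np.random.default_rng(0)
        base = rng.random(10) * 0.8 + 0.1
        X = encoded_from_array(np.column_stack([base, base, rng.random(10)]))
        ranking = FeatureRanking("manual", ["rs000", "rs001", "rs002"], np.array([3.0, 2.0, 1.0]))
        res = cosine_redundancy_filter(X, ranking, n_final=2)
        assert res.snp_ids == ["rs000", "rs002"]

    def test_orthogonal_features_keep_rank_order(self):
        X = encoded_from_array(np.eye(6))
        ranking = FeatureRanking("manual", [f"rs{j:03d}" for j in range(6)], np.arange(6, 0, -1.0))
        res = cosine_redundancy_filter(X, ranking, n_final=4, tau=0.95)
        assert res.snp_ids == [f"rs{j:03d}" for j in range(4)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((12, 10))
        X[:, 7] = X[:, 2] * 0.9 + 0.01  # planted near-duplicate pair
        em = encoded_from_array(X)
        ranking = rank_by_amgm(em)
        res = cosine_redundancy_filter(em, ranking, n_final=6, tau=0.9)
        expected = brute_force_greedy_cosine(em.values, ranking.snp_ids, 6, 0.9)
        assert res.snp_ids == expected

    def test_invalid_n_final(self):
        em = encoded_from_array(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValidationError):
            cosine_redundancy_filter(em, rank_by_amgm(em), n_final=0)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def brute_force_relieff(X, y, k):
    """Literal ReliefF restatement: explicit loops, no vectorization."""
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    W = np.zeros(d)
    for i in range(n):
        dists = []
        for j in range(n):
            dists.append(sum(abs(X[i, f] - X[j, f]) / span[f] for f in range(d)))
        dists = np.array(dists)
        dists[i] = np.inf
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        hits = sorted(same, key=lambda j: (dists[j], j))[:k]
        for f in range(d):
            W[f] -= np.mean([abs(X[i, f] - X[h, f]) / span[f] for h in hits]) / n
        for c in classes:
            if c == y[i]:
                continue
            others = [j for j in range(n) if y[j] == c]
            misses = sorted(others, key=lambda j: (dists[j], j))[:k]
            w_c = priors[c] / (1 - priors[y[i]])
            for f in range(d):
                W[f] += w_c * np.mean([abs(X[i, f] - X[m, f]) / span[f] for m in misses]) / n
    return W


class TestReliefF:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        X[:, 2] = 0.5
        y = np.tile([0, 1], 10)
        r = relieff_weights(X, y, k_neighbors=3)
        idx = r.snp_ids.index("f2")
        assert r.scores[idx] == pytest.approx(0.0, abs=1e-12)

    def test_separating_feature_gets_max_weight(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 6 + [1] * 6)
        X = rng.random((12, 5)) * 0.2 + 0.4
        X[:, 3] = np.where(y == 1, 0.9, 0.1) + rng.normal(0, 0.01, 12)
        r = relieff_weights(X, y, k_neighbors=3)
        assert r.snp_ids[0] == "f3"

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.random((16, 6))
        y = np.tile([0, 1], 8)
        w1 = relieff_weights(X, y, k_neighbors=3)
        X2 = X.copy()
        X2[:, 4] *= 10
        w2 = relieff_weights(X2, y, k_neighbors=3)
        s1 = dict(zip(w1.snp_ids, w1.scores))
        s2 = dict(zip(w2.snp_ids, w2.scores))
        for f in s1:
            assert s1[f] == pytest.approx(s2[f], abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((12, 5))
        y = np.tile([0, 1], 6)
        expected = brute_force_relieff(X, y, k=3)
        r = relieff_weights(X, y, k_neighbors=3)
        got = dict(zip(r.snp_ids, r.scores))
        for f in range(5):
            assert got[f"f{f}"] == pytest.approx(expected[f], abs=1e-9)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((8, 3))
        with pytest.raises(ValidationError):
            relieff_weights(X, np.zeros(8), k_neighbors=2)


# ---------------------------------------------------------------------------
# autoencoder + L1
# ---------------------------------------------------------------------------


class TestAutoencoderL1:
    def test_constant_feature_at_bottom(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 8))
        X[:, 5] = 0.5
        r = autoencoder_l1_ranking(X, bottleneck=3, epochs=30, seed=0)
        assert r.snp_ids[-1] == "f5"

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 10))
        a = autoencoder_l1_ranking(X, bottleneck=3, epochs=20, seed=5)
        b = autoencoder_l1_ranking(X, bottleneck=3, epochs=20, seed=5)
        assert a.snp_ids == b.snp_ids
        assert np.array_equal(a.scores, b.scores)

    def test_latent_factor_features_rank_high(self):
        """5 features carry 2 latent factors, 15 are small noise; factor-linked
        features should dominate the top-5 in >= 8/10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 60
            factors = rng.normal(0, 1.0, (n, 2))
            X = rng.normal(0, 0.3, (n, 20))
            loadings = [(0, 0), (1, 0), (2, 1), (3, 1), (4, 0)]
            for col, fac in loadings:
                X[:, col] = factors[:, fac] + rng.normal(0, 0.1, n)
            r = autoencoder_l1_ranking(X, bottleneck=2, seed=seed)
            top5 = set(r.snp_ids[:5])
            if len(top5 & {"f0", "f1", "f2", "f3", "f4"}) >= 4:
                wins += 1
        assert wins >= 8


# ---------------------------------------------------------------------------
# CMIM / univariate (categorical)
# ---------------------------------------------------------------------------


def _entropy(counts):
    p = np.array([c for c in counts if c > 0], dtype=float)
    p /= p.sum()
    return -(p * np.log2(p)).sum()


def brute_force_mi(f, y):
    n = len(f)
    joint = [np.sum((f == a) & (y == b)) for a in range(3) for b in range(2)]
    hf = _entropy([np.sum(f == a) for a in range(3)])
    hy = _entropy([np.sum(y == b) for b in range(2)])
    return hf + hy - _entropy(joint)


def brute_force_cmim(codes, y, n_select):
    """Exhaustive evaluation of the CMIM criterion at every step."""
    p = codes.shape[0]
    selected = []
    remaining = list(range(p))
    while len(selected) < n_select:
        best, best_v = None, -np.inf
        for f in remaining:
            if not selected:
                v = brute_force_mi(codes[f], y)
            else:
                v = min(
                    sum(
                        (np.sum(codes[s] == sv) / len(y)) * brute_force_mi(
                            codes[f][codes[s] == sv], y[codes[s] == sv]
                        )
                        for sv in range(3)
                        if np.sum(codes[s] == sv) > 0
                    )
                    for s in selected
                )
            if v > best_v + 1e-15:
                best, best_v = f, v
        selected.append(best)
        remaining.remove(best)
    return selected


def genotype_matrix_from_codes(codes: np.ndarray, y: np.ndarray) -> GenotypeMatrix:
    from snpdeep.data import GENOTYPES

    rows = {f"rs{i:02d}": [GENOTYPES[c] for c in codes[i]] for i in range(codes.shape[0])}
    return make_matrix(rows, labels=[CASE if b else CONTROL for b in y])


class TestCmim:
    def test_duplicate_feature_never_selected_early(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        informative = (y + rng.integers(0, 2, 40)).clip(0, 2)
        other = rng.integers(0, 3, 40)
        codes = np.stack([informative, informative.copy(), other])
        G = genotype_matrix_from_codes(codes, y)
        res = cmim_select(G, n_select=2)
        # the duplicate of the first pick scores I(F;Y|F)=0; the alternative wins
        assert set(res.snp_ids) == {"rs00", "rs02"} or set(res.snp_ids) == {"rs01", "rs02"}

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 30)
        codes = rng.integers(0, 3, (6, 30))
        codes[0] = (y * 2 + rng.integers(0, 2, 30)).clip(0, 2)
        G = genotype_matrix_from_codes(codes, y)
        res = cmim_select(G, n_select=4)
        expected = brute_force_cmim(codes, y, 4)
        # oracle ties broken by index order == id order here
        assert res.snp_ids == [f"rs{i:02d}" for i in expected]

    def test_null_first_pick_mi_below_permutation_quantile(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        codes = rng.integers(0, 3, (10, 200))
        G = genotype_matrix_from_codes(codes, y)
        res = cmim_select(G, n_select=1)
        first_mi = res.provenance["first_pick_mi_bits"]
        # permutation distribution of max-MI over 10 null features
        perm_max = []
        for _ in range(50):
            yp = rng.permutation(y)
            perm_max.append(max(brute_force_mi(codes[i], yp) for i in range(10)))
        assert first_mi <= np.quantile(perm_max, 0.99) + 1e-9


class TestUnivariate:
    def test_null_chi2_near_df(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000)
        codes = rng.integers(0, 3, (8, 2000))
        G = genotype_matrix_from_codes(codes, y)
        r = univariate_ranking(G, "chi_squared")
        # under independence each statistic ~ chi2(df=2); mean over 8 SNPs near 2
        assert np.mean(r.scores) < 8.0

    def test_perfectly_determined_feature_mi_equals_entropy(self):
        y = np.tile([0, 1], 15)
        codes = np.stack([y * 2, np.random.default_rng(0).integers(0, 3, 30)])
        G = genotype_matrix_from_codes(codes, y)
        r = univariate_ranking(G, "mutual_information")
        assert r.snp_ids[0] == "rs00"
        assert r.scores[0] == pytest.approx(1.0)  # H(Y) for balanced y

    def test_hand_computed_chi_squared(self):
        """3x2 table ((10,0),(0,10),(5,5)) has chi-squared exactly 20."""
        codes = np.array([[0] * 10 + [1] * 10 + [2] * 10])
        y = np.array([0] * 10 + [1] * 10 + [0] * 5 + [1] * 5)
        G = genotype_matrix_from_codes(codes, y)
        r = univariate_ranking(G, "chi_squared")
        assert r.scores[0] == pytest.approx(20.0)

    def test_unknown_method_rejected(self, toy_labeled):
        with pytest.raises(ValidationError):
            univariate_ranking(toy_labeled, "anova")


# ---------------------------------------------------------------------------
# SVM-RFE and the hybrid
# ---------------------------------------------------------------------------


class TestSvmRfe:
    def test_separating_feature_survives(self):
        rng = np.random.default_rng(0)
        n = 50
        y = np.tile([0, 1], 25)
        X = rng.random((n, 20))
        X[:, 11] = y * 0.8 + 0.1 + rng.normal(0, 0.02, n)
        res = svm_rfe_select(X, y, n_select=3)
        assert "f11" in res.snp_ids

    def test_no_elimination_when_n_select_equals_pool(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 6))
        y = np.tile([0, 1], 10)
        res = svm_rfe_select(X, y, n_select=6)
        assert sorted(res.snp_ids) == [f"f{i}" for i in range(6)]
        assert res.provenance["elimination_order"] == []

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 10))
        y = np.tile([0, 1], 15)
        a = svm_rfe_select(X, y, n_select=4)
        b = svm_rfe_select(X, y, n_select=4)
        assert a.snp_ids == b.snp_ids


class TestHybrid:
    def _data(self, seed=0, n=40, p=8):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        codes = rng.integers(0, 3, (p, n))
        codes[2] = (y * 2 + rng.integers(0, 2, n)).clip(0, 2)
        G = genotype_matrix_from_codes(codes, y)
        from snpdeep.preprocess import encode

        X, _ = encode(G)
        return G, X, y

    def test_full_intermediate_equals_plain_svmrfe(self):
        G, X, y = self._data()
        hybrid = hybrid_cmim_svmrfe(G, X, n_intermediate=8, n_select=3)
        plain = svm_rfe_select(X, n_select=3)
        assert hybrid.snp_ids == plain.snp_ids

    def test_n_select_equals_intermediate_is_plain_cmim(self):
        G, X, y = self._data()
        hybrid = hybrid_cmim_svmrfe(G, X, n_intermediate=4, n_select=4)
        plain = cmim_select(G, n_select=4)
        assert set(hybrid.snp_ids) == set(plain.snp_ids)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


class TestSelectFeaturesDispatcher:
    def test_unknown_method_lists_options(self, strong_signal_dataset):
        G, _ = strong_signal_dataset
        from snpdeep.preprocess import encode

        X, _ = encode(G)
        with pytest.raises(ValidationError, match="amgm_cosine"):
            select_features(G, X, "pca")

    def test_oversized_request_returns_pool(self, strong_signal_dataset, caplog):
        G, _ = strong_signal_dataset
        from snpdeep.preprocess import encode

        X, _ = encode(G)
        with caplog.at_level("WARNING"):
            res = select_features(G, X, "chi_squared", n_select=10_000)
        assert len(res) == G.n_snps

    @pytest.mark.parametrize("method", ["amgm_cosine", "chi_squared", "relieff"])
    def test_deterministic(self, strong_signal_dataset, method):
        G, _ = strong_signal_dataset
        from snpdeep.preprocess import encode

        X, _ = encode(G)
        a = select_features(G, X, method, n_select=10, n_intermediate=30, seed=3)
        b = select_features(G, X, method, n_select=10, n_intermediate=30, seed=3)
        assert a.snp_ids == b.snp_ids

    @pytest.mark.parametrize("method", ["chi_squared", "mutual_information", "relieff"])
    def test_permutation_equivariance(self, method):
        """Permuting SNP order does not change which SNPs are selected."""
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        codes = rng.integers(0, 3, (9, 40))
        codes[4] = (y * 2 + rng.integers(0, 2, 40)).clip(0, 2)
        G = genotype_matrix_from_codes(codes, y)
        from snpdeep.preprocess import encode

        X, _ = encode(G)
        sel = select_features(G, X, method, n_select=3)

        perm = rng.permutation(G.n_snps)
        Gp = G.subset_snps([G.snp_ids[i] for i in perm])
        Xp, _ = encode(Gp)
        sel_p = select_features(Gp, Xp, method, n_select=3)
        assert sel.snp_ids == sel_p.snp_ids
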