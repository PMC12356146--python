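"""Feature-selection suite for SNP panels.

Six strategies behind one dispatcher (:func:`select_features`):

``amgm_cosine``
    The two-step filter: rank SNPs by the arithmetic-mean / geometric-mean
    (AMGM) ratio of their encoded values (higher = more variable = more
    relevant), keep the top ``n_intermediate`` (1000 by default), then run a
    greedy cosine-redundancy pass that keeps a SNP only if its maximum
    cosine similarity to already-kept SNPs is below a threshold, stopping at
    ``n_final`` (100 by default).
``ae_l1``
    Autoencoder with an L1 penalty on first-layer weights; a feature's score
    is the total absolute weight it feeds into the bottleneck.
``relieff``
    ReliefF instance-based weights (nearest hits vs. nearest misses).
``cmim_svmrfe``
    Conditional Mutual Information Maximization down to an intermediate
    pool, then SVM recursive feature elimination to the final size.
``chi_squared`` / ``mutual_information``
    Univariate rankings on the genotype-by-class contingency tables.

Information-theoretic selectors (CMIM, chi-squared, MI) run on the raw
genotype categories; ReliefF, SVM-RFE and the AMGM/cosine/autoencoder steps
need numeric inputs and run on the mean encodings.  All selectors break
score ties by SNP id, so permuting the input SNP order permutes nothing but
the bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

from .data import GENOTYPES, EncodedMatrix, GenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Shift applied before the AMGM ratio: mean encodings can be exactly 0,
#: which degenerates the geometric mean.
AMGM_EPSILON = 1e-6

#: Default cosine-similarity threshold above which two SNPs are redundant.
COSINE_TAU = 0.95


@dataclass
class FeatureRanking:
    """SNP ids ordered by non-increasing relevance score."""

    method: str
    snp_ids: list[str]
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.snp_ids) != len(self.scores):
            raise ValidationError("ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("ranking scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.snp_ids[:k]


@dataclass
class SelectionResult:
    """An ordered selected subset plus the provenance that produced it."""

    snp_ids: list[str]
    method: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"rank": np.arange(1, len(self.snp_ids) + 1), "SNP_ID": self.snp_ids})


def _make_ranking(method: str, ids: list[str], scores: np.ndarray, **params) -> FeatureRanking:
    """Sort descending by score, ties broken by SNP id."""
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return FeatureRanking(method, [ids[i] for i in order], scores[list(order)], params)


# ---------------------------------------------------------------------------
# AMGM + cosine
# ---------------------------------------------------------------------------


def amgm_ratio(values: np.ndarray) -> float:
    """Arithmetic mean over geometric mean of a strictly positive vector.

    By the AM-GM inequality the ratio is >= 1, with equality exactly for
    constant vectors; it grows with the spread of the values.  The geometric
    mean is computed in log space.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("empty feature vector")
    if np.any(v <= 0):
        raise ValidationError("AMGM requires strictly positive values (apply the epsilon shift)")
    return float(v.mean() / np.exp(np.mean(np.log(v))))


def rank_by_amgm(X: EncodedMatrix, epsilon: float = AMGM_EPSILON) -> FeatureRanking:
    """Score every SNP by the AMGM ratio of its (epsilon-shifted) encodings."""
    data = X.X() + epsilon
    am = data.mean(axis=0)
    gm = np.exp(np.mean(np.log(data), axis=0))
    scores = am / gm
    return _make_ranking("amgm", X.snp_ids, scores, epsilon=epsilon)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


def cosine_redundancy_filter(
    X: EncodedMatrix,
    ranking: FeatureRanking,
    n_final: int,
    tau: float = COSINE_TAU,
) -> SelectionResult:
    """Greedy redundancy pass in rank order.

    A SNP is kept iff its maximum cosine similarity to every already-kept
    SNP is strictly below ``tau``; the pass stops once ``n_final`` SNPs are
    kept.  If the pool is exhausted first, the remaining slots are filled
    from the skipped SNPs in rank order (most relevant first) with a logged
    warning, so the requested size is always honored when the pool allows.
    """
    if n_final <= 0:
        raise ValidationError("n_final must be positive")
    missing = set(ranking.snp_ids) - set(X.snp_ids)
    if missing:
        raise ValidationError(f"ranking refers to SNPs absent from X, e.g. {next(iter(missing))!r}")

    cols = X.values
    kept: list[str] = []
    kept_units: list[np.ndarray] = []
    skipped: list[str] = []
    for snp in ranking.snp_ids:
        if len(kept) >= n_final:
            break
        v = cols[snp].to_numpy(dtype=np.float64)
        norm = np.linalg.norm(v)
        if norm == 0:
            skipped.append(snp)
            continue
        unit = v / norm
        if kept_units and np.max(np.stack(kept_units) @ unit) >= tau:
            skipped.append(snp)
            continue
        kept.append(snp)
        kept_units.append(unit)

    if len(kept) < n_final:
        fill = skipped[: n_final - len(kept)]
        if fill:
            logger.warning(
                "cosine filter kept only %d/%d SNPs below tau=%.2f; filling %d slot(s) by rank",
                len(kept), n_final, tau, len(fill),
            )
        kept = kept + fill
    return SelectionResult(
        kept,
        method="amgm_cosine" if ranking.method == "amgm" else f"{ranking.method}_cosine",
        provenance={"tau": tau, "n_final": n_final, "ranking_method": ranking.method,
                    "pool_size": len(ranking.snp_ids)},
    )


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def relieff_weights(
    X: EncodedMatrix | np.ndarray,
    y: np.ndarray | None = None,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    snp_ids: list[str] | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """ReliefF feature weights for a binary target.

    For each probe sample the k nearest same-class neighbors (hits) and the
    k nearest other-class neighbors (misses, weighted by the other class's
    prior over 1 - prior of the probe's class) update each feature weight by
    mean miss-difference minus mean hit-difference.  Value differences are
    range-normalized, making the weights invariant to positive rescaling of
    any feature; distances are the sum of those normalized differences.
    ``n_iterations=None`` probes every sample (deterministic); a smaller
    count probes a seeded random subset.
    """
    if isinstance(X, EncodedMatrix):
        ids = X.snp_ids
        y = X.y() if y is None else np.asarray(y)
        Xd = X.X()
    else:
        Xd = np.asarray(X, dtype=np.float64)
        ids = snp_ids if snp_ids is not None else [f"f{i}" for i in range(Xd.shape[1])]
        y = np.asarray(y)
    n, d = Xd.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("ReliefF requires both classes")
    if any(c <= k_neighbors for c in counts):
        raise ValidationError("k_neighbors must be smaller than every class size")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    span = Xd.max(axis=0) - Xd.min(axis=0)
    span[span == 0] = 1.0  # constant features contribute zero difference anyway
    Xn = Xd / span

    if n_iterations is None or n_iterations >= n:
        probes = np.arange(n)
    else:
        probes = np.random.default_rng(seed).choice(n, size=n_iterations, replace=False)
    m = len(probes)

    W = np.zeros(d)
    for i in probes:
        diffs = np.abs(Xn - Xn[i])  # (n, d) range-normalized differences
        dist = diffs.sum(axis=1)
        dist[i] = np.inf
        same = y == y[i]
        hit_idx = np.where(same)[0]
        hit_idx = hit_idx[hit_idx != i]
        hits = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:k_neighbors]]
        W -= diffs[hits].mean(axis=0) / m
        for c in classes:
            if c == y[i]:
                continue
            miss_idx = np.where(y == c)[0]
            misses = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:k_neighbors]]
            w_c = priors[c] / (1.0 - priors[y[i]])
            W += w_c * diffs[misses].mean(axis=0) / m
    return _make_ranking("relieff", ids, W, k_neighbors=k_neighbors, n_iterations=m)


# ---------------------------------------------------------------------------
# autoencoder + L1
# ---------------------------------------------------------------------------


def autoencoder_l1_ranking(
    X: EncodedMatrix | np.ndarray,
    bottleneck: int | None = None,
    l1_lambda: float = 1e-3,
    epochs: int = 150,
    seed: int = 0,
    snp_ids: list[str] | None = None,
    learning_rate: float = 1e-2,
    batch_size: int = 32,
) -> FeatureRanking:
    """Rank features by their total absolute first-layer weight in an
    L1-regularized autoencoder.

    Columns are mean-centered but deliberately *not* variance-scaled: for
    mean-encoded SNPs the association signal lives in the spread of the
    per-genotype encodings, and a narrow bottleneck plus the L1 penalty on
    encoder weights then concentrates weight on the high-variance,
    reconstructable features while near-constant columns shrink to zero.
    The default bottleneck is ceil(n_features / 16), at least 2.
    """
    from .nn import Adam, Dense, Tensor

    if isinstance(X, EncodedMatrix):
        ids = X.snp_ids
        Xd = X.X()
    else:
        Xd = np.asarray(X, dtype=np.float64)
        ids = snp_ids if snp_ids is not None else [f"f{i}" for i in range(Xd.shape[1])]
    n, d = Xd.shape
    Z = Xd - Xd.mean(axis=0)

    width = bottleneck if bottleneck is not None else max(2, int(np.ceil(d / 16)))
    if width >= d and d > 1:
        raise ValidationError("bottleneck must be smaller than the number of features")
    rng = np.random.default_rng(seed)
    enc = Dense(d, width, rng)
    dec = Dense(width, d, rng)
    opt = Adam(enc.parameters() + dec.parameters(), lr=learning_rate)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = Tensor(Z[idx])
            codes = enc(xb).tanh()
            loss = (dec(codes) - xb).square().mean() + enc.W.abs().mean() * l1_lambda
            opt.zero_grad()
            loss.backward()
            opt.step()
    scores = np.abs(enc.W.data).sum(axis=1)
    return _make_ranking("ae_l1", ids, scores, bottleneck=width, l1_lambda=l1_lambda,
                         epochs=epochs, seed=seed)


# ---------------------------------------------------------------------------
# information-theoretic selectors (on raw genotype categories)
# ---------------------------------------------------------------------------


def _genotype_codes(G: GenotypeMatrix) -> np.ndarray:
    """(n_snps, n_samples) integer codes AA=0, AB=1, BB=2."""
    cells = G.calls.to_numpy(dtype=object)
    codes = np.empty(cells.shape, dtype=np.int64)
    for code, g in enumerate(GENOTYPES):
        codes[cells == g] = code
    if not set(np.unique(cells)) <= set(GENOTYPES):
        raise ValidationError("matrix must be NC-free for categorical selectors")
    return codes


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mi_bits(f: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information I(F; Y) in bits from empirical counts."""
    table = np.zeros((3, 2))
    for a in range(3):
        for b in range(2):
            table[a, b] = np.sum((f == a) & (y == b))
    n = table.sum()
    hf = _entropy_bits(table.sum(axis=1))
    hy = _entropy_bits(table.sum(axis=0))
    hfy = _entropy_bits(table.ravel())
    return hf + hy - hfy


def _cond_mi_bits(f: np.ndarray, y: np.ndarray, s: np.ndarray) -> float:
    """I(F; Y | S) = sum_s P(S=s) I(F; Y | S=s), plug-in, in bits."""
    total = 0.0
    n = len(s)
    for val in range(3):
        mask = s == val
        m = int(mask.sum())
        if m == 0:
            continue
        total += (m / n) * _mi_bits(f[mask], y[mask])
    return total


def cmim_select(G: GenotypeMatrix, n_select: int) -> SelectionResult:
    """Conditional Mutual Information Maximization on genotype categories.

    First pick argmax I(F; Y); then repeatedly pick
    argmax_F min_{S in selected} I(F; Y | S) — a candidate that is redundant
    given any already-selected SNP scores low.  Plug-in (empirical)
    entropies in bits; ties broken by SNP id.
    """
    if G.labels is None:
        raise ValidationError("CMIM requires a labeled matrix")
    codes = _genotype_codes(G)
    y = G.y()
    ids = G.snp_ids
    pool = len(ids)
    if n_select > pool:
        logger.warning("n_select=%d exceeds pool of %d; returning the full pool", n_select, pool)
        n_select = pool

    order = sorted(range(pool), key=lambda i: ids[i])  # id order for tie-breaks
    mi = np.array([_mi_bits(codes[i], y) for i in range(pool)])

    selected: list[int] = []
    # running CMIM score: min over selected of I(F; Y | S); starts at I(F; Y)
    score = mi.copy()
    remaining = set(range(pool))
    while len(selected) < n_select:
        best_i, best_v = None, -np.inf
        for i in order:
            if i not in remaining:
                continue
            if score[i] > best_v + 1e-15:
                best_i, best_v = i, score[i]
        selected.append(best_i)
        remaining.discard(best_i)
        for i in remaining:
            score[i] = min(score[i], _cond_mi_bits(codes[i], y, codes[best_i]))
    return SelectionResult(
        [ids[i] for i in selected],
        method="cmim",
        provenance={"n_select": n_select, "first_pick_mi_bits": float(mi[selected[0]])},
    )


def univariate_ranking(G: GenotypeMatrix, method: str) -> FeatureRanking:
    """Per-SNP chi-squared statistic or mutual information vs. the labels."""
    if method not in ("chi_squared", "mutual_information"):
        raise ValidationError("method must be 'chi_squared' or 'mutual_information'")
    if G.labels is None:
        raise ValidationError("univariate ranking requires labels")
    codes = _genotype_codes(G)
    y = G.y()
    scores = np.empty(G.n_snps)
    for i in range(G.n_snps):
        if method == "mutual_information":
            scores[i] = _mi_bits(codes[i], y)
        else:
            table = np.array([[np.sum((codes[i] == a) & (y == b)) for b in (0, 1)] for a in range(3)])
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                scores[i] = 0.0
            else:
                scores[i] = float(chi2_contingency(table, correction=False)[0])
    return _make_ranking(method, G.snp_ids, scores)


# ---------------------------------------------------------------------------
# SVM-RFE and the hybrid
# ---------------------------------------------------------------------------


def svm_rfe_select(
    X: EncodedMatrix | np.ndarray,
    y: np.ndarray | None = None,
    n_select: int = 100,
    drop_fraction: float = 0.1,
    snp_ids: list[str] | None = None,
) -> SelectionResult:
    """Recursive feature elimination with a linear soft-margin SVM (C=1).

    Each round fits the SVM on the surviving features and removes the
    ceil(drop_fraction * surviving) features with the smallest absolute
    weights (never dropping below ``n_select``).  The final survivors are
    ordered by decreasing absolute weight of the last fit; the full
    elimination order is recorded in the provenance.
    """
    from sklearn.svm import SVC

    if isinstance(X, EncodedMatrix):
        ids = X.snp_ids
        y = X.y() if y is None else np.asarray(y)
        Xd = X.X()
    else:
        Xd = np.asarray(X, dtype=np.float64)
        ids = snp_ids if snp_ids is not None else [f"f{i}" for i in range(Xd.shape[1])]
        y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("SVM-RFE requires both classes")
    if not 0 < drop_fraction < 1:
        raise ValidationError("drop_fraction must be in (0, 1)")
    pool = len(ids)
    if n_select > pool:
        logger.warning("n_select=%d exceeds pool of %d; returning the full pool", n_select, pool)
        n_select = pool

    surviving = list(range(pool))
    eliminated: list[str] = []
    w = np.zeros(pool)
    while len(surviving) > n_select:
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(Xd[:, surviving], y)
        w_abs = np.abs(svm.coef_[0])
        n_drop = min(int(np.ceil(drop_fraction * len(surviving))), len(surviving) - n_select)
        # drop smallest |w|; ties broken by SNP id (later id dropped first
        # would be arbitrary — use ascending id among ties for determinism)
        order = sorted(range(len(surviving)), key=lambda j: (w_abs[j], ids[surviving[j]]))
        drop = sorted(order[:n_drop], reverse=True)
        for j in drop:
            eliminated.append(ids[surviving[j]])
            del surviving[j]
    svm = SVC(kernel="linear", C=1.0)
    svm.fit(Xd[:, surviving], y)
    w_abs = np.abs(svm.coef_[0])
    final_order = sorted(range(len(surviving)), key=lambda j: (-w_abs[j], ids[surviving[j]]))
    return SelectionResult(
        [ids[surviving[j]] for j in final_order],
        method="svm_rfe",
        provenance={"n_select": n_select, "drop_fraction": drop_fraction,
                    "elimination_order": eliminated},
    )


def hybrid_cmim_svmrfe(
    G: GenotypeMatrix,
    X: EncodedMatrix,
    n_intermediate: int,
    n_select: int,
) -> SelectionResult:
    """CMIM down to ``n_intermediate`` SNPs, then SVM-RFE down to ``n_select``."""
    stage1 = cmim_select(G, n_intermediate)
    X_sub = X.subset_snps(stage1.snp_ids)
    stage2 = svm_rfe_select(X_sub, n_select=n_select)
    return SelectionResult(
        stage2.snp_ids,
        method="cmim_svmrfe",
        provenance={"n_intermediate": len(stage1), "n_select": n_select,
                    "cmim": stage1.provenance, "svm_rfe": {k: v for k, v in stage2.provenance.items()
                                                           if k != "elimination_order"}},
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

FS_METHODS = ("amgm_cosine", "ae_l1", "relieff", "cmim_svmrfe", "chi_squared", "mutual_information")


def select_features(
    G: GenotypeMatrix,
    X: EncodedMatrix,
    method: str,
    n_select: int = 100,
    n_intermediate: int = 1000,
    tau: float = COSINE_TAU,
    seed: int = 0,
    **params,
) -> SelectionResult:
    """Run one feature-selection method with its standard staging.

    ``G`` is the cleaned categorical matrix (used by CMIM / chi-squared /
    mutual information); ``X`` its mean-encoded counterpart (used by the
    numeric selectors).  ``amgm_cosine`` keeps the top ``n_intermediate``
    SNPs by AMGM ratio and then cosine-filters down to ``n_select``;
    ``cmim_svmrfe`` stages through ``min(n_intermediate, pool)`` as well.
    A request exceeding the pool returns the full pool with a warning.
    """
    if method not in FS_METHODS:
        raise ValidationError(f"unknown FS method {method!r}; choose from {list(FS_METHODS)}")
    pool = X.values.shape[1]
    if n_select > pool:
        logger.warning("n_select=%d exceeds pool of %d; returning the full pool", n_select, pool)
        n_select = pool

    if method == "amgm_cosine":
        ranking = rank_by_amgm(X, epsilon=params.get("epsilon", AMGM_EPSILON))
        n_mid = min(n_intermediate, pool)
        mid_ids = ranking.top(n_mid)
        mid_ranking = FeatureRanking(ranking.method, mid_ids, ranking.scores[:n_mid], ranking.params)
        result = cosine_redundancy_filter(X.subset_snps(mid_ids), mid_ranking, n_select, tau=tau)
        result.provenance["n_intermediate"] = n_mid
        return result
    if method == "ae_l1":
        ranking = autoencoder_l1_ranking(X, seed=seed, **params)
        return SelectionResult(ranking.top(n_select), method, {"n_select": n_select, **ranking.params})
    if method == "relieff":
        ranking = relieff_weights(X, seed=seed, **params)
        return SelectionResult(ranking.top(n_select), method, {"n_select": n_select, **ranking.params})
    if method == "cmim_svmrfe":
        return hybrid_cmim_svmrfe(G, X, min(n_intermediate, pool), n_select)
    ranking = univariate_ranking(G, method)
    return SelectionResult(ranking.top(n_select), method, {"n_select": n_select})
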