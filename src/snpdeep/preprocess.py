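"""Dataset cleaning and per-SNP mean (target) encoding.

Cleaning has a fixed order — drop invariant SNPs, drop SNPs with more than
10% No-Calls, mode-impute the remaining No-Calls — after which each
categorical genotype is replaced by its mean encoding

    E(G) = (# Case samples with genotype G) / (# samples with genotype G),

computed SNP by SNP.  Because E(G) is fitted from the labels, fitting it on
samples that later appear in a test fold leaks phenotype information into
the features.  The encoding therefore supports two modes:

* fold-safe (default) — :func:`fit_mean_encoding` is called on the training
  samples of each cross-validation fold only, and applied to the held-out
  samples with a fallback for genotypes unseen at fit time;
* global — fitted once on the full dataset, which mirrors a common but
  leakage-prone practice and measurably inflates null-data accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CASE, GENOTYPES, NO_CALL, EncodedMatrix, GenotypeMatrix
from .errors import EmptyDatasetError, ValidationError

logger = logging.getLogger(__name__)


def drop_invariant_snps(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove SNPs whose non-NC genotypes are all identical.

    Invariance is judged on called (non-NC) cells: a SNP that is all-AA apart
    from a few No-Calls carries no genotype signal either way.  A SNP with
    zero called cells is likewise removed.
    """
    if matrix.n_snps == 0:
        raise EmptyDatasetError("empty genotype matrix")
    cells = matrix.calls.to_numpy(dtype=object)
    keep = np.zeros(matrix.n_snps, dtype=bool)
    for i in range(matrix.n_snps):
        called = {c for c in cells[i] if c != NO_CALL}
        keep[i] = len(called) > 1
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d invariant SNP(s)", n_dropped)
    if not keep.any():
        raise EmptyDatasetError("all SNPs are invariant")
    return GenotypeMatrix(matrix.calls.loc[keep], matrix.labels)


def drop_high_nocall_snps(matrix: GenotypeMatrix, threshold: float = 0.10) -> GenotypeMatrix:
    """Remove SNPs whose No-Call fraction is strictly greater than ``threshold``.

    "More than 10%" is read as a strict inequality: a SNP at exactly the
    threshold is retained.
    """
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must be in [0, 1)")
    nc_frac = (matrix.calls == NO_CALL).mean(axis=1).to_numpy()
    keep = nc_frac <= threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d SNP(s) with NC fraction > %.0f%%", n_dropped, 100 * threshold)
    if not keep.any():
        raise EmptyDatasetError("all SNPs exceed the No-Call threshold")
    return GenotypeMatrix(matrix.calls.loc[keep], matrix.labels)


def impute_nocall_mode(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each NC by its SNP's most common called genotype.

    Ties are broken by the fixed order AA < AB < BB so imputation is
    deterministic.  A SNP with no called cells at all cannot be imputed (this
    cannot happen after :func:`drop_high_nocall_snps` with threshold < 1).
    """
    cells = matrix.calls.to_numpy(dtype=object, copy=True)
    nc_mask = cells == NO_CALL
    if not nc_mask.any():
        return GenotypeMatrix(matrix.calls.copy(), matrix.labels)
    for i in np.flatnonzero(nc_mask.any(axis=1)):
        row = cells[i]
        counts = {g: int((row == g).sum()) for g in GENOTYPES}
        if sum(counts.values()) == 0:
            raise ValidationError(f"SNP {matrix.snp_ids[i]!r} has no called genotypes to impute from")
        best = max(counts.values())
        # tie-break: first genotype in AA < AB < BB order wins
        mode = next(g for g in GENOTYPES if counts[g] == best)
        row[row == NO_CALL] = mode
    calls = pd.DataFrame(cells, index=matrix.calls.index, columns=matrix.calls.columns)
    return GenotypeMatrix(calls, matrix.labels)


@dataclass
class EncodingMap:
    """Fitted per-SNP genotype -> E(G) encodings plus an unseen-genotype fallback.

    ``fallback`` is the case prevalence of the fitting subset; it is used for
    any (SNP, genotype) pair not observed at fit time — the
    minimal-assumption prior for a genotype about which the training data
    says nothing.
    """

    per_snp: dict[str, dict[str, float]]
    fallback: float

    def __post_init__(self) -> None:
        if not 0 <= self.fallback <= 1:
            raise ValidationError("fallback must be in [0, 1]")
        for snp, enc in self.per_snp.items():
            for g, v in enc.items():
                if not 0 <= v <= 1:
                    raise ValidationError(f"E({g}) = {v} out of [0, 1] for SNP {snp!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table (snp_id, genotype, encoding)."""
        rows = [
            {"snp_id": s, "genotype": g, "encoding": v}
            for s, enc in self.per_snp.items()
            for g, v in sorted(enc.items())
        ]
        return pd.DataFrame(rows)


def fit_mean_encoding(matrix: GenotypeMatrix, sample_subset: list[str] | None = None) -> EncodingMap:
    """Fit E(G) for every SNP and every genotype observed in the fitting subset.

    ``sample_subset`` restricts fitting (e.g. to a training fold); it must
    contain both classes, otherwise every encoding would be the constant 0
    or 1 and the fit is refused.
    """
    if matrix.labels is None:
        raise ValidationError("mean encoding requires a labeled matrix")
    sub = matrix if sample_subset is None else matrix.subset_samples(sample_subset)
    if sub.n_samples == 0:
        raise ValidationError("empty fitting subset")
    y = sub.y()
    if y.min() == y.max():
        raise ValidationError("fitting subset contains a single class")
    cells = sub.calls.to_numpy(dtype=object)
    if (cells == NO_CALL).any():
        raise ValidationError("matrix must be NC-free before encoding (run impute_nocall_mode)")

    per_snp: dict[str, dict[str, float]] = {}
    for i, snp in enumerate(sub.snp_ids):
        row = cells[i]
        enc: dict[str, float] = {}
        for g in GENOTYPES:
            sel = row == g
            n_g = int(sel.sum())
            if n_g:
                enc[g] = float(y[sel].sum() / n_g)
        per_snp[snp] = enc
    return EncodingMap(per_snp, fallback=float(y.mean()))


def apply_mean_encoding(mapping: EncodingMap, matrix: GenotypeMatrix) -> EncodedMatrix:
    """Replace every genotype cell by its SNP's fitted E(G).

    Genotypes unseen during fitting receive the map's fallback value.  The
    result is samples-by-SNPs (the modeling orientation) with labels carried
    through.
    """
    if matrix.labels is None:
        raise ValidationError("matrix must be labeled")
    missing = [s for s in matrix.snp_ids if s not in mapping.per_snp]
    if missing:
        raise ValidationError(f"encoding map lacks {len(missing)} SNP(s), e.g. {missing[0]!r}")
    cells = matrix.calls.to_numpy(dtype=object)
    if (cells == NO_CALL).any():
        raise ValidationError("matrix must be NC-free before encoding")

    out = np.empty(cells.shape, dtype=np.float64)
    for i, snp in enumerate(matrix.snp_ids):
        enc = mapping.per_snp[snp]
        row = cells[i]
        vals = np.full(row.shape, mapping.fallback)
        for g, v in enc.items():
            vals[row == g] = v
        out[i] = vals
    values = pd.DataFrame(out.T, index=matrix.sample_ids, columns=matrix.snp_ids)
    return EncodedMatrix(values, matrix.labels.copy())


def clean(matrix: GenotypeMatrix, nc_threshold: float = 0.10) -> GenotypeMatrix:
    """The full cleaning pipeline: invariant filter -> NC filter -> mode imputation."""
    return impute_nocall_mode(drop_high_nocall_snps(drop_invariant_snps(matrix), nc_threshold))


def encode(matrix: GenotypeMatrix, sample_subset: list[str] | None = None) -> tuple[EncodedMatrix, EncodingMap]:
    """Fit the mean encoding (optionally on a subset) and apply it to ``matrix``."""
    mapping = fit_mean_encoding(matrix, sample_subset)
    return apply_mean_encoding(mapping, matrix), mapping
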