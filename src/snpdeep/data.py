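"""Core in-memory containers: genotype matrices and encoded matrices.

The GEO export convention is SNPs-as-rows / samples-as-columns, and that is
how :class:`GenotypeMatrix` stores its calls.  Modeling code wants
samples-as-rows; the transpose happens exactly once, in
:meth:`GenotypeMatrix.samples_by_snps` (and hence in everything downstream
of the case/control merge).  Keeping a single transposition site avoids
orientation bugs when the same identifiers appear on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Recognised genotype calls.  ``NC`` marks a genotyping failure (No Call).
GENOTYPES = ("AA", "AB", "BB")
NO_CALL = "NC"
CALL_VOCABULARY = frozenset(GENOTYPES) | {NO_CALL}

#: Case is the positive class everywhere (sensitivity == Case recall).
CASE, CONTROL = "Case", "Control"


@dataclass
class GenotypeMatrix:
    """Categorical genotype calls for a panel of SNPs over a set of samples.

    Parameters
    ----------
    calls
        DataFrame of shape (n_snps, n_samples); index = SNP ids, columns =
        sample ids, values in ``{"AA", "AB", "BB", "NC"}``.
    labels
        Optional per-sample phenotype, a Series indexed by sample id with
        values ``"Case"`` / ``"Control"``.
    """

    calls: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValidationError("duplicate SNP ids in genotype matrix")
        if self.calls.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in genotype matrix")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.calls.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()][:3].tolist()
                raise ValidationError(f"labels missing for samples {missing}")
            bad = set(self.labels.unique()) - {CASE, CONTROL}
            if bad:
                raise ValidationError(f"labels outside {{Case, Control}}: {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_snps(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def y(self) -> np.ndarray:
        """Binary target vector (Case=1, Control=0), sample order."""
        if self.labels is None:
            raise ValidationError("matrix is unlabeled")
        return (self.labels.to_numpy() == CASE).astype(np.int64)

    def samples_by_snps(self) -> pd.DataFrame:
        """The modeling orientation: one row per sample, one column per SNP."""
        return self.calls.T

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        sub = self.calls.loc[:, list(sample_ids)]
        lab = self.labels.loc[list(sample_ids)] if self.labels is not None else None
        return GenotypeMatrix(sub, lab)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(snp_ids)], self.labels)

    def equals(self, other: "GenotypeMatrix") -> bool:
        if not self.calls.equals(other.calls):
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        return self.labels is None or self.labels.equals(other.labels)


@dataclass
class EncodedMatrix:
    """Numeric (mean-encoded) feature matrix: samples x SNPs, values in [0, 1]."""

    values: pd.DataFrame  # index = sample ids, columns = SNP ids
    labels: pd.Series  # indexed like values.index

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValidationError("encoded matrix labels incomplete")
        v = self.values.to_numpy()
        if not np.isfinite(v).all():
            raise ValidationError("encoded matrix contains non-finite values")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValidationError("encoded values outside [0, 1]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)

    def y(self) -> np.ndarray:
        return (self.labels.to_numpy() == CASE).astype(np.int64)

    def subset_samples(self, sample_ids) -> "EncodedMatrix":
        ids = list(sample_ids)
        return EncodedMatrix(self.values.loc[ids], self.labels.loc[ids])

    def subset_snps(self, snp_ids) -> "EncodedMatrix":
        return EncodedMatrix(self.values.loc[:, list(snp_ids)], self.labels)


@dataclass
class PhenotypeTable:
    """Per-sample Case/Control status, as read from a GEO-style phenotype CSV."""

    sample_ids: list[str]
    status: pd.Series  # indexed by sample id, values Case/Control

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in phenotype table")
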