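"""Reading, merging, and writing GEO-style genotype/phenotype CSV pairs.

The input contract is the CSV dialect exported from GEO series matrices:

* genotype CSV — first column SNP ids, remaining columns one per sample,
  cells in ``{AA, AB, BB, NC}`` (case-insensitive; ``No Call`` and empty
  cells are treated as NC);
* phenotype CSV — one row per sample with a Case/Control status column.

Matching of sample identifiers is exact string equality after whitespace
trimming; silently fuzzy matches would be worse than dropped samples.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CALL_VOCABULARY, CASE, CONTROL, NO_CALL, GenotypeMatrix, PhenotypeTable
from .errors import FormatError, MergeError, ValidationError

logger = logging.getLogger(__name__)

_NC_ALIASES = {"NC", "NO CALL", "NOCALL", "NO_CALL", ""}


def _normalize_call(raw: object) -> str | None:
    """Map a raw cell to the call vocabulary; None if unrecognized."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return NO_CALL
    s = str(raw).strip().upper()
    if s in _NC_ALIASES or s == "NAN":
        return NO_CALL
    if s in CALL_VOCABULARY:
        return s
    return None


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a GEO-style genotype CSV into an (unlabeled) GenotypeMatrix.

    Raises
    ------
    FormatError
        On duplicate SNP ids or any cell outside the recognized vocabulary
        (the error names the offending SNP row and sample column).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected an id column plus sample columns")
    df.columns = [str(c).strip() for c in df.columns]
    snp_col = df.columns[0]
    snp_ids = df[snp_col].astype(str).str.strip()
    dup = snp_ids[snp_ids.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate SNP id {dup.iloc[0]!r}")

    calls = df.drop(columns=[snp_col])
    calls.index = snp_ids
    norm = calls.map(_normalize_call)
    bad = norm.isna()
    if bad.to_numpy().any():
        snp = norm.index[bad.any(axis=1)][0]
        col = norm.columns[bad.loc[snp].to_numpy()][0]
        raise FormatError(
            f"{path}: unrecognized genotype {calls.loc[snp, col]!r} at SNP {snp!r}, sample {col!r}"
        )
    return GenotypeMatrix(norm.astype(object))


_STATUS_COLUMN_HINTS = ("case_control", "case/control", "case or control", "status", "phenotype")


def read_phenotype_csv(path: str | Path, status_map: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a phenotype CSV; samples whose status is not Case/Control are dropped.

    ``status_map`` optionally maps raw status strings (case-insensitively) to
    ``"Case"``/``"Control"`` — e.g. ``{"AML": "Case", "MDS": "Control"}`` for
    series whose phenotype uses disease-specific terms.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a sample-id column plus a status column")

    status_col = None
    for col in df.columns[1:]:
        if col.strip().lower().replace(" ", "_") in {h.replace(" ", "_") for h in _STATUS_COLUMN_HINTS}:
            status_col = col
            break
    if status_col is None:
        # Fall back to any column whose values look like case/control statuses.
        mapping = _build_status_mapper(status_map)
        for col in df.columns[1:]:
            vals = {mapping(v) for v in df[col]}
            if vals and vals <= {CASE, CONTROL, None} and vals != {None}:
                status_col = col
                break
    if status_col is None:
        raise FormatError(f"{path}: no recognizable Case/Control status column")

    mapping = _build_status_mapper(status_map)
    sample_ids = df.iloc[:, 0].astype(str).str.strip()
    status = df[status_col].map(mapping)
    dropped = sample_ids[status.isna()]
    if len(dropped):
        logger.warning(
            "dropping %d sample(s) with unmapped status (e.g. %r)",
            len(dropped),
            df.loc[status.isna(), status_col].iloc[0],
        )
    keep = status.notna()
    kept_ids = sample_ids[keep].tolist()
    return PhenotypeTable(kept_ids, pd.Series(status[keep].to_numpy(), index=kept_ids, name="Case_Control"))


def _build_status_mapper(status_map: dict[str, str] | None):
    extra = {k.strip().lower(): v for k, v in (status_map or {}).items()}

    def mapping(raw: object) -> str | None:
        s = str(raw).strip().lower()
        if s in extra:
            target = extra[s].strip().capitalize()
            if target not in (CASE, CONTROL):
                raise ValidationError(f"status_map value {extra[s]!r} is not Case/Control")
            return target
        if s == "case":
            return CASE
        if s == "control":
            return CONTROL
        return None

    return mapping


def merge_case_control(geno: GenotypeMatrix, pheno: PhenotypeTable) -> GenotypeMatrix:
    """Attach Case/Control labels to the genotype matrix.

    The result is restricted to the intersection of sample ids, preserving
    the genotype file's sample order; counts of dropped samples are logged.
    Merging an already-labeled matrix with a consistent table is a no-op.
    """
    pheno_ids = set(pheno.sample_ids)
    shared = [s for s in geno.sample_ids if s in pheno_ids]
    if not shared:
        raise MergeError("no sample ids shared between genotype and phenotype files")
    n_geno_only = geno.n_samples - len(shared)
    n_pheno_only = len(pheno_ids) - len(shared)
    if n_geno_only or n_pheno_only:
        logger.info(
            "merge dropped %d genotype-only and %d phenotype-only sample(s)",
            n_geno_only,
            n_pheno_only,
        )
    calls = geno.calls.loc[:, shared]
    labels = pheno.status.loc[shared]
    return GenotypeMatrix(calls, labels)


def write_processed_csv(matrix, path: str | Path) -> Path:
    """Write a labeled matrix as samples-by-SNPs CSV with a final Case_Control column.

    Accepts either a labeled :class:`GenotypeMatrix` (categorical cells) or an
    :class:`EncodedMatrix` (numeric cells; serialized with 12 significant
    digits so the round-trip is lossless well past 1e-9).
    """
    path = Path(path)
    if hasattr(matrix, "calls"):  # GenotypeMatrix
        if matrix.labels is None:
            raise ValidationError("matrix must be labeled")
        wide = matrix.samples_by_snps().copy()
        labels = matrix.labels
        float_format = None
    else:  # EncodedMatrix
        wide = matrix.values.copy()
        labels = matrix.labels
        float_format = "%.12g"
    wide["Case_Control"] = labels.to_numpy()
    wide.index.name = "Sample_ID"
    wide.to_csv(path, float_format=float_format)
    return path


def read_processed_csv(path: str | Path):
    """Inverse of :func:`write_processed_csv`.

    Returns an :class:`EncodedMatrix` when the cells are numeric, otherwise a
    labeled :class:`GenotypeMatrix`.
    """
    from .data import EncodedMatrix

    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if "Case_Control" not in df.columns:
        raise FormatError(f"{path}: missing Case_Control column")
    labels = pd.Series(df["Case_Control"].to_numpy(), index=df.index, name="Case_Control")
    body = df.drop(columns=["Case_Control"])
    try:
        numeric = body.astype(np.float64)
    except ValueError:
        norm = body.map(_normalize_call)
        if norm.isna().to_numpy().any():
            raise FormatError(f"{path}: cells are neither numeric nor genotype calls")
        return GenotypeMatrix(norm.T.astype(object), labels)
    return EncodedMatrix(numeric, labels)
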