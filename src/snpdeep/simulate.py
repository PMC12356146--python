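"""Synthetic GEO-style genotype/phenotype data with planted case/control signal.

The generator emulates the case/control SNP-array datasets the pipeline is
built for: a panel of biallelic SNPs with genotypes drawn under
Hardy-Weinberg proportions, a binary phenotype generated by an additive
logistic liability model over a chosen set of causal SNPs, and an optional
per-cell No-Call (genotyping failure) rate.  Ground truth (which SNPs are
causal, each SNP's genotype frequencies, the effect sizes used) travels with
the matrix so downstream feature-selection and evaluation code can be tested
against a known answer.

Conventions
-----------
* The minor allele is always the "B" allele, and B is always the risk
  allele: a sample's risk dosage at a SNP is its count of B alleles
  (AA=0, AB=1, BB=2).
* The phenotype model is ``logit P(Case) = alpha + log(causal_effect) *
  sum(dosage over causal SNPs)``; ``alpha`` is calibrated by root-finding so
  the expected case fraction matches ``case_fraction``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import CASE, CONTROL, GENOTYPES, NO_CALL, GenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic case/control dataset.

    Attributes
    ----------
    n_samples, n_snps
        Panel dimensions.
    n_causal
        Number of SNPs given a real phenotype effect (0 => pure null data).
    causal_effect
        Odds multiplier per risk-allele copy (>= 1); 1 means no effect.
    maf_range
        Minor-allele frequencies are drawn uniformly from this interval,
        bounded within (0, 0.5].
    nc_rate
        Per-cell probability of a No-Call, applied after genotype sampling.
    case_fraction
        Target expected proportion of Case samples.
    seed
        RNG seed; identical configs produce byte-identical outputs.
    """

    n_samples: int = 400
    n_snps: int = 2000
    n_causal: int = 5
    causal_effect: float = 4.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    nc_rate: float = 0.02
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be a positive integer")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be a positive integer")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValidationError("n_causal must satisfy 0 <= n_causal <= n_snps")
        if self.causal_effect < 1:
            raise ValidationError("causal_effect must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5] with lo <= hi")
        if not 0 <= self.nc_rate < 1:
            raise ValidationError("nc_rate must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """What the simulator actually planted, for test oracles."""

    causal_snp_ids: list[str]
    per_snp_genotype_probs: dict[str, tuple[float, float, float]]  # P(AA), P(AB), P(BB)
    label_model_params: dict = field(default_factory=dict)


def _snp_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"SNP_{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"GSM{i:0{width}d}" for i in range(1, n + 1)]


def generate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw a labeled genotype matrix under the configured liability model.

    Genotypes are sampled per SNP under Hardy-Weinberg proportions
    ``((1-q)^2, 2q(1-q), q^2)`` for a minor-allele frequency ``q`` drawn
    uniformly from ``config.maf_range``.  Labels are Bernoulli draws from the
    additive logistic model described in the module docstring; with
    ``n_causal == 0`` (or ``causal_effect == 1``) labels are independent of
    every SNP by construction.

    Returns the matrix (no No-Calls; see :func:`inject_nocalls`) and the
    ground truth used to generate it.
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_ids(config.n_snps)
    samples = _sample_ids(config.n_samples)

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    probs = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], axis=1)
    # Dosage = count of B (minor, risk) alleles per cell.
    u = rng.random((config.n_snps, config.n_samples))
    cum = probs.cumsum(axis=1)
    dosage = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # values 0/1/2

    causal_idx = np.sort(rng.choice(config.n_snps, size=config.n_causal, replace=False))
    beta = float(np.log(config.causal_effect))
    linear = beta * dosage[causal_idx, :].sum(axis=0) if config.n_causal else np.zeros(config.n_samples)

    alpha = _calibrate_intercept(linear, config.case_fraction)
    p_case = expit(alpha + linear)
    is_case = rng.random(config.n_samples) < p_case

    cells = np.array(GENOTYPES, dtype=object)[dosage]
    calls = pd.DataFrame(cells, index=snps, columns=samples)
    labels = pd.Series(np.where(is_case, CASE, CONTROL), index=samples, name="Case_Control")

    truth = GroundTruth(
        causal_snp_ids=[snps[i] for i in causal_idx],
        per_snp_genotype_probs={s: tuple(probs[i]) for i, s in enumerate(snps)},
        label_model_params={
            "causal_effect": config.causal_effect,
            "beta_per_allele": beta,
            "intercept": alpha,
            "case_fraction": config.case_fraction,
        },
    )
    return GenotypeMatrix(calls, labels), truth


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + linear)) == target.

    The mean case probability is strictly increasing in alpha, so a sign
    change is guaranteed once the bracket is wide enough.
    """

    def gap(a: float) -> float:
        return float(expit(a + linear).mean() - target)

    lo, hi = -30.0, 30.0
    lo -= float(linear.max())
    hi += float(-linear.min())
    return float(brentq(gap, lo, hi, xtol=1e-10))


def inject_nocalls(matrix: GenotypeMatrix, nc_rate: float, seed: int) -> GenotypeMatrix:
    """Independently replace each genotype cell by NC with probability nc_rate."""
    if not 0 <= nc_rate < 1:
        raise ValidationError("nc_rate must be in [0, 1)")
    if nc_rate == 0:
        return GenotypeMatrix(matrix.calls.copy(), None if matrix.labels is None else matrix.labels.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.calls.shape) < nc_rate
    cells = matrix.calls.to_numpy(dtype=object, copy=True)
    cells[mask] = NO_CALL
    calls = pd.DataFrame(cells, index=matrix.calls.index, columns=matrix.calls.columns)
    return GenotypeMatrix(calls, None if matrix.labels is None else matrix.labels.copy())


def write_geo_style_csvs(
    matrix: GenotypeMatrix,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    prefix: str = "synthetic",
) -> tuple[Path, Path]:
    """Write the genotype/phenotype CSV pair in the dialect genotype_io reads.

    Genotype CSV: header ``SNP_ID,<sample ids...>``, one row per SNP.
    Phenotype CSV: header ``Sample_ID,Case_Control``.  If ``truth`` is given,
    a JSON sidecar ``<prefix>_truth.json`` records the planted causal SNPs
    and model parameters.
    """
    if matrix.labels is None:
        raise ValidationError("matrix must be labeled before writing the CSV pair")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geno_path = out / f"{prefix}_genotypes.csv"
    pheno_path = out / f"{prefix}_phenotypes.csv"

    geno = matrix.calls.copy()
    geno.index.name = "SNP_ID"
    geno.to_csv(geno_path)

    pheno = pd.DataFrame({"Sample_ID": matrix.sample_ids, "Case_Control": matrix.labels.to_numpy()})
    pheno.to_csv(pheno_path, index=False)

    if truth is not None:
        sidecar = {
            "causal_snp_ids": truth.causal_snp_ids,
            "label_model_params": truth.label_model_params,
        }
        (out / f"{prefix}_truth.json").write_text(json.dumps(sidecar, indent=2))
    logger.info("wrote %s and %s", geno_path, pheno_path)
    return geno_path, pheno_path


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Genotypes + labels with the configured No-Call rate already applied."""
    matrix, truth = generate_genotypes(config)
    if config.nc_rate > 0:
        labels = matrix.labels
        matrix = inject_nocalls(matrix, config.nc_rate, seed=config.seed + 1)
        matrix = GenotypeMatrix(matrix.calls, labels)
    return matrix, truth
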