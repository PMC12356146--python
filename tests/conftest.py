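import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from snpdeep.data import CASE, CONTROL, GenotypeMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(snp_rows: dict[str, list[str]], labels: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {snp_id: [call, ...]} plus optional labels."""
    n = len(next(iter(snp_rows.values())))
    samples = [f"S{i+1}" for i in range(n)]
    calls = pd.DataFrame.from_dict(snp_rows, orient="index", columns=samples).astype(object)
    lab = None
    if labels is not None:
        lab = pd.Series(labels, index=samples, name="Case_Control")
    return GenotypeMatrix(calls, lab)


@pytest.fixture
def toy_labeled():
    """A small labeled, NC-free matrix with a mix of informative and flat SNPs."""
    return make_matrix(
        {
            "rs1": ["AA", "AA", "AB", "AB", "BB", "BB"],
            "rs2": ["AA", "AB", "AA", "AB", "AA", "AB"],
            "rs3": ["BB", "BB", "AB", "AA", "AA", "AB"],
        },
        labels=[CASE, CASE, CASE, CONTROL, CONTROL, CONTROL],
    )


@pytest.fixture
def strong_signal_dataset():
    """Simulated 300x80 panel with 4 strong causal SNPs, cleaned and NC-free."""
    from snpdeep.preprocess import clean
    from snpdeep.simulate import SimulationConfig, generate_genotypes

    cfg = SimulationConfig(
        n_samples=300, n_snps=80, n_causal=4, causal_effect=6.0, nc_rate=0.0, seed=42
    )
    matrix, truth = generate_genotypes(cfg)
    return clean(matrix), truth
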