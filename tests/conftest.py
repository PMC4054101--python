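import numpy as np
import pandas as pd
import pytest

from phosresp import (
    IntensityMatrix,
    NormalizedMatrix,
    SynthConfig,
    default_viability_table,
    drug_response_config,
    full_normalize,
    generate_classification_dataset,
    generate_drug_response_dataset,
)


def make_matrix(values, peptides=None, samples=None) -> IntensityMatrix:
    values = np.asarray(values, dtype=float)
    peptides = peptides or [f"pep{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return IntensityMatrix(pd.DataFrame(values, index=peptides, columns=samples))


def make_normalized(values, peptides=None, samples=None, provenance=("row_mean",)) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    peptides = peptides or [f"pep{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(values, index=peptides, columns=samples), provenance=provenance
    )


@pytest.fixture(scope="session")
def small_classification():
    """Two diseases x two lines x 4 replicates, strong planted effects."""
    cfg = SynthConfig(
        n_peptides=300,
        diseases=(("AML", 2), ("lymphoma", 2)),
        replicates_per_line=4,
        disease_effect_fold=4.0,
        noise_cv=0.1,
        seed=11,
    )
    ds = generate_classification_dataset(cfg)
    return cfg, ds, full_normalize(ds.intensities)


@pytest.fixture(scope="session")
def small_drug():
    """Seven lines x 3 replicates with 3+3 planted markers, 250 peptides."""
    cfg = drug_response_config(
        n_peptides=250, marker_count_per_direction=3, assigned_motifs=(), seed=5
    )
    viab = default_viability_table([line for line, _ in cfg.cell_lines], seed=5)
    ds = generate_drug_response_dataset(cfg, viab)
    return cfg, ds, full_normalize(ds.intensities)
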