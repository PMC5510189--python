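import numpy as np
import pandas as pd
import pytest

from prostasig import ExpressionMatrix, PhenotypeTable, SimulationConfig, simulate_cohort


def make_expression(values, probe_ids=None, sample_ids=None, is_log2=True):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    return ExpressionMatrix(values=df, is_log2=is_log2)


def make_phenotype(sample_ids, outcomes, gleason=None, batch=None, replicate_of=None, age=None):
    n = len(sample_ids)
    return PhenotypeTable(
        table=pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "outcome": list(outcomes),
                "gleason": gleason or ["leq6"] * n,
                "stage": ["local"] * n,
                "psa_cat": ["lt4"] * n,
                "age": age if age is not None else [60.0] * n,
                "batch": batch or ["B1"] * n,
                "replicate_of": replicate_of or [None] * n,
            }
        )
    )


@pytest.fixture
def small_cohort():
    """Small seeded two-cohort pair with a few strong planted effects."""
    cfg = SimulationConfig(
        n_transcripts=120,
        n_planted=4,
        effect_range=(1.0, 1.2),
        n_nonrecurrent_discovery=80,
        n_metlethal_discovery=20,
        n_nonrecurrent_validation=46,
        n_metlethal_validation=32,
        seed=42,
    )
    return {
        "config": cfg,
        "discovery": simulate_cohort(cfg, "discovery"),
        "validation": simulate_cohort(cfg, "validation"),
    }
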