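"""Two-cohort synthetic expression data with planted prognostic effects.

Emulates the statistical structure of a discovery cohort (278 nonrecurrent vs 27
metastatic-lethal after radical prostatectomy) and an independent validation
cohort (46 vs 32) profiled on a ~26k-transcript expression array, with plate-style
batch offsets and outcome-dependent Gleason distributions.

Model: for transcript g and sample i,

    log2 expression  x_gi = mu_g + delta_g * case_i + b_batch(i) + eps_gi,
    eps_gi ~ Normal(0, sigma_g^2),

with mu_g uniform over ``baseline_mean_range``, sigma_g uniform over
``residual_sd_range``, and delta_g = 0 for null transcripts. Planted transcripts
get |delta_g| uniform over ``effect_range`` with sign + at rate
``frac_upregulated``. The validation cohort reuses the same truth vector (same
planted transcripts, same signed effects) but draws fresh samples — mirroring an
independent-cohort validation design. Gleason category is drawn per sample from
the outcome-specific probability vector, so Gleason is confounded with outcome
(as in real cohorts) but carries no information about any individual transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import (
    ExpressionMatrix,
    GLEASON_LEVELS,
    PSA_LEVELS,
    PhenotypeTable,
    STAGE_LEVELS,
    write_expression,
    write_phenotype,
)

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "write_fixture"]

# stage / PSA-category / age distributions by outcome, matching the discovery
# cohort's descriptive statistics (fractions over (local, regional, missing) and
# the five PSA categories; age as mean, SD in years)
_STAGE_P = {
    "nonrecurrent": (213 / 278, 65 / 278, 0.0),
    "metastatic_lethal": (13 / 27, 14 / 27, 0.0),
}
_PSA_P = {
    "nonrecurrent": (47 / 278, 174 / 278, 30 / 278, 11 / 278, 16 / 278),
    "metastatic_lethal": (2 / 27, 7 / 27, 6 / 27, 8 / 27, 4 / 27),
}
_AGE = {"nonrecurrent": (58.2, 6.9), "metastatic_lethal": (57.8, 6.7)}


@dataclass
class SimulationConfig:
    """Cohort sizes, effect structure and nuisance parameters for the generator.

    Defaults are the study conditions of the two-cohort design: discovery
    278/27, validation 46/32, 26 051 transcripts, 48 planted log2 effects with
    magnitudes 0.3-1.1 (about half up-regulated), residual SDs 0.6-1.1 (the
    range implied by per-transcript AUCs of 0.6-0.8 at those effect sizes),
    four plates with SD-0.2 offsets, and outcome-conditional Gleason
    probabilities matching the discovery cohort's observed distribution.
    """

    n_nonrecurrent_discovery: int = 278
    n_metlethal_discovery: int = 27
    n_nonrecurrent_validation: int = 46
    n_metlethal_validation: int = 32
    n_transcripts: int = 26_051
    n_planted: int = 48
    effect_range: tuple[float, float] = (0.3, 1.1)
    frac_upregulated: float = 25 / 48
    baseline_mean_range: tuple[float, float] = (7.0, 14.0)
    residual_sd_range: tuple[float, float] = (0.6, 1.1)
    n_batches: int = 4
    batch_sd: float = 0.2
    gleason_probs_nonrecurrent: tuple[float, ...] = (
        157 / 278,
        93 / 278,
        15 / 278,
        13 / 278,
    )
    gleason_probs_metlethal: tuple[float, ...] = (5 / 27, 11 / 27, 5 / 27, 6 / 27)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_nonrecurrent_discovery": self.n_nonrecurrent_discovery,
            "n_metlethal_discovery": self.n_metlethal_discovery,
            "n_nonrecurrent_validation": self.n_nonrecurrent_validation,
            "n_metlethal_validation": self.n_metlethal_validation,
            "n_transcripts": self.n_transcripts,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"invariant violated: {name} must be >= 1, got {v}")
        if not 0 <= self.n_planted <= self.n_transcripts:
            raise ValueError(
                "invariant violated: n_planted must be in [0, n_transcripts], "
                f"got {self.n_planted}"
            )
        lo, hi = self.effect_range
        if not (0 <= lo <= hi):
            raise ValueError(
                f"invariant violated: effect_range must satisfy 0 <= low <= high, got {self.effect_range}"
            )
        if not 0 <= self.frac_upregulated <= 1:
            raise ValueError(
                f"invariant violated: frac_upregulated must be in [0, 1], got {self.frac_upregulated}"
            )
        for name, probs in (
            ("gleason_probs_nonrecurrent", self.gleason_probs_nonrecurrent),
            ("gleason_probs_metlethal", self.gleason_probs_metlethal),
        ):
            if len(probs) != 4:
                raise ValueError(f"invariant violated: {name} must have 4 entries")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(
                    f"invariant violated: {name} must sum to 1 within 1e-9, got {sum(probs)}"
                )
        if self.seed < 0:
            raise ValueError(f"invariant violated: seed must be >= 0, got {self.seed}")


@dataclass
class SyntheticCohort:
    """Expression + phenotype for one cohort plus the planted-effect truth table."""

    expression: ExpressionMatrix
    phenotype: PhenotypeTable
    truth: pd.DataFrame = field(repr=False)  # columns: delta, planted; index: transcript_id


def _truth(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-transcript baseline means, residual SDs and planted effects (shared streams)."""
    rng = np.random.default_rng([config.seed, 11])
    g = config.n_transcripts
    mu = rng.uniform(*config.baseline_mean_range, size=g)
    sigma = rng.uniform(*config.residual_sd_range, size=g)
    delta = np.zeros(g)
    planted = np.zeros(g, dtype=bool)
    if config.n_planted > 0:
        idx = rng.choice(g, size=config.n_planted, replace=False)
        mag = rng.uniform(*config.effect_range, size=config.n_planted)
        sign = np.where(rng.random(config.n_planted) < config.frac_upregulated, 1.0, -1.0)
        delta[idx] = sign * mag
        planted[idx] = True
    probe_ids = [f"TX_{i:06d}" for i in range(g)]
    truth = pd.DataFrame(
        {"delta": delta, "planted": planted.astype(int)},
        index=pd.Index(probe_ids, name="transcript_id"),
    )
    return truth, mu, sigma


def simulate_cohort(config: SimulationConfig, which: str) -> SyntheticCohort:
    """Generate one cohort ('discovery' or 'validation'), deterministic given seed.

    The truth vector (planted transcripts and their signed log2 effects) is
    drawn from a seed-derived stream shared by both cohorts, so the validation
    cohort carries the same planted effects with fresh samples.
    """
    config.validate()
    if which not in ("discovery", "validation"):
        raise ValueError(f"which must be 'discovery' or 'validation', got {which!r}")
    truth, mu, sigma = _truth(config)

    if which == "discovery":
        n0, n1 = config.n_nonrecurrent_discovery, config.n_metlethal_discovery
        rng = np.random.default_rng([config.seed, 21])
        prefix = "dis"
    else:
        n0, n1 = config.n_nonrecurrent_validation, config.n_metlethal_validation
        rng = np.random.default_rng([config.seed, 22])
        prefix = "val"
    n = n0 + n1
    g = config.n_transcripts
    case = np.concatenate([np.zeros(n0), np.ones(n1)])
    batch_labels = np.array([f"B{i % config.n_batches + 1}" for i in range(n)])
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    offset_per_sample = batch_offsets[np.arange(n) % config.n_batches]

    delta = truth["delta"].to_numpy()
    X = (
        mu[:, None]
        + delta[:, None] * case[None, :]
        + offset_per_sample[None, :]
        + rng.standard_normal((g, n)) * sigma[:, None]
    )
    sample_ids = [f"{prefix}_{i:04d}" for i in range(n)]
    values = pd.DataFrame(X, index=truth.index.rename("probe_id"), columns=sample_ids)
    gene = pd.Series(
        [f"GENE{i % 20818:05d}" for i in range(g)], index=values.index, name="gene"
    )
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]
    chrom = pd.Series(
        [chroms[i % len(chroms)] for i in range(g)], index=values.index, name="chromosome"
    )
    expression = ExpressionMatrix(
        values=values, gene_symbols=gene, chromosome=chrom, is_log2=True
    )

    gl_p = {
        "nonrecurrent": config.gleason_probs_nonrecurrent,
        "metastatic_lethal": config.gleason_probs_metlethal,
    }
    rows = []
    for i, sid in enumerate(sample_ids):
        outcome = "metastatic_lethal" if case[i] else "nonrecurrent"
        rows.append(
            {
                "sample_id": sid,
                "outcome": outcome,
                "gleason": GLEASON_LEVELS[rng.choice(4, p=gl_p[outcome])],
                "stage": STAGE_LEVELS[rng.choice(3, p=_STAGE_P[outcome])],
                "psa_cat": PSA_LEVELS[rng.choice(5, p=_PSA_P[outcome])],
                "age": round(float(rng.normal(*_AGE[outcome])), 1),
                "batch": batch_labels[i],
                "replicate_of": None,
            }
        )
    phenotype = PhenotypeTable(table=pd.DataFrame(rows))
    return SyntheticCohort(expression=expression, phenotype=phenotype, truth=truth)


def write_fixture(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write expression/phenotype/truth TSVs; returns a manifest of written files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "phenotype": directory / "phenotype.tsv",
        "truth": directory / "truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_phenotype(cohort.phenotype, paths["phenotype"])
    truth = cohort.truth.reset_index()
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    return {k: str(v) for k, v in paths.items()}
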