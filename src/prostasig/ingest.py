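"""Reading expression/phenotype tables and microarray-style preprocessing.

The preprocessing mirrors a standard bead-array workflow on formalin-fixed tumor
RNA profiles: probe quality filtering against an explicit keep list, quantile
normalization across samples, log2 transformation, a location-scale batch
adjustment, and replicate (blind duplicate) quality control.

File formats (tab-delimited):

* expression: first column ``probe_id``, optional ``gene`` and ``chromosome``
  columns, then one numeric column per sample;
* phenotype: columns ``sample_id, outcome, gleason, stage, psa_cat, age, batch,
  replicate_of`` with the enumerated category levels below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_LEVELS = ("nonrecurrent", "metastatic_lethal")
GLEASON_LEVELS = ("leq6", "g3p4", "g4p3", "g8to10")
STAGE_LEVELS = ("local", "regional", "missing")
PSA_LEVELS = ("lt4", "c4to9", "c10to19", "ge20", "missing")

PHENOTYPE_COLUMNS = (
    "sample_id",
    "outcome",
    "gleason",
    "stage",
    "psa_cat",
    "age",
    "batch",
    "replicate_of",
)


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity grid with probe annotations.

    ``values`` is a DataFrame indexed by probe id with one column per sample.
    ``is_log2`` records whether values are log2-scale (post-transform) or raw.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    chromosome: pd.Series | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe_ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dups[:5]}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PhenotypeTable:
    """Per-sample clinical annotations (outcome, Gleason, stage, PSA, age, batch)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids in phenotype: {dups[:5]}")
        for col, levels in (
            ("outcome", OUTCOME_LEVELS),
            ("gleason", GLEASON_LEVELS),
            ("stage", STAGE_LEVELS),
            ("psa_cat", PSA_LEVELS),
        ):
            bad = set(t[col].unique()) - set(levels)
            if bad:
                rows = t.index[t[col].isin(bad)].tolist()
                raise ValueError(
                    f"unknown {col} label(s) {sorted(bad)} at row(s) {rows[:5]}"
                )
        known = set(t["sample_id"])
        reps = t["replicate_of"].dropna()
        reps = reps[reps != ""]
        orphans = set(reps) - known
        if orphans:
            raise ValueError(f"replicate_of names absent sample(s): {sorted(orphans)[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def outcome01(self, sample_ids=None) -> np.ndarray:
        """Outcome as 0/1 (metastatic_lethal = 1), optionally reordered to sample_ids."""
        t = self.table.set_index("sample_id")
        if sample_ids is not None:
            t = t.loc[list(sample_ids)]
        return (t["outcome"] == "metastatic_lethal").to_numpy().astype(np.int8)

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Phenotype rows in the order of the given expression sample ids."""
        t = self.table.set_index("sample_id", drop=False)
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise ValueError(f"samples missing from phenotype: {missing[:5]}")
        return t.loc[list(sample_ids)].reset_index(drop=True)


def read_expression(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (probe_id [, gene, chromosome], samples...)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ValueError(f"first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    gene = df.pop("gene") if "gene" in df.columns else None
    chrom = df.pop("chromosome") if "chromosome" in df.columns else None
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad][0]
            raise ValueError(f"non-numeric intensity at probe {probe!r}, sample {col!r}")
        if converted.isna().any():
            probe = df.index[converted.isna()][0]
            raise ValueError(f"missing intensity at probe {probe!r}, sample {col!r}")
        df[col] = converted
    return ExpressionMatrix(values=df, gene_symbols=gene, chromosome=chrom)


def read_phenotype(path) -> PhenotypeTable:
    """Read a tab-delimited phenotype table with validated category levels."""
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "batch": str, "replicate_of": str}
    )
    if "replicate_of" in df.columns:
        df["replicate_of"] = df["replicate_of"].where(df["replicate_of"].notna(), None)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    return PhenotypeTable(table=df)


def write_expression(m: ExpressionMatrix, path, float_format: str = "%.6f") -> None:
    df = m.values.copy()
    if m.chromosome is not None:
        df.insert(0, "chromosome", m.chromosome)
    if m.gene_symbols is not None:
        df.insert(0, "gene", m.gene_symbols)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def write_phenotype(p: PhenotypeTable, path) -> None:
    p.table.to_csv(path, sep="\t", index=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column to the same empirical distribution.

    The reference distribution is the across-sample mean of order statistics;
    each column's sorted values are replaced by the reference, and ties within a
    column receive the mean of the reference values at their tied ranks.
    Normalization is applied to raw (pre-log2) intensities.
    """
    if m.is_log2:
        raise ValueError("quantile_normalize expects raw intensities (is_log2=False)")
    X = m.values.to_numpy(dtype=np.float64, copy=True)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return replace(m, values=m.values.copy())
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        assigned = np.empty(n_probes)
        assigned[order[:, j]] = ref
        # average reference values across tied ranks
        _, inverse, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    values = pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids)
    return replace(m, values=values)


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset); marks the matrix as log2-scale."""
    if m.is_log2:
        raise ValueError("matrix is already log2-transformed")
    X = m.values.to_numpy(dtype=np.float64) + offset
    if (X <= 0).any():
        g, s = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"nonpositive value after offset at probe {m.probe_ids[g]!r}, "
            f"sample {m.sample_ids[s]!r}"
        )
    values = pd.DataFrame(np.log2(X), index=m.probe_ids, columns=m.sample_ids)
    return replace(m, values=values, is_log2=True)


def filter_probes(m: ExpressionMatrix, keep_list) -> ExpressionMatrix:
    """Restrict to a probe keep list (quality-passing probes), matrix order preserved."""
    keep = list(keep_list)
    if not keep:
        raise ValueError("keep_list must be nonempty")
    keep_set = set(keep)
    mask = m.probe_ids.isin(keep_set)
    n_kept = int(mask.sum())
    if n_kept == 0:
        raise ValueError("keep_list is disjoint from the matrix probes")
    n_unknown = len(keep_set - set(m.probe_ids))
    if n_unknown:
        logger.info("filter_probes: %d keep-list ids not in matrix (ignored)", n_unknown)
    logger.info("filter_probes: %d of %d probes retained", n_kept, len(m.probe_ids))
    values = m.values.loc[mask]
    gene = m.gene_symbols.loc[mask] if m.gene_symbols is not None else None
    chrom = m.chromosome.loc[mask] if m.chromosome is not None else None
    return replace(m, values=values, gene_symbols=gene, chromosome=chrom)


def batch_adjust(m: ExpressionMatrix, batches, shrink: bool = False) -> ExpressionMatrix:
    """Location-scale batch-effect removal on log2 data.

    Per probe and batch, the batch mean is subtracted and residuals rescaled to
    the pooled within-batch SD; the probe's grand mean is then restored. With
    ``shrink``, batch means and SDs are shrunk toward their across-probe average
    with weight n_batch / (n_batch + 1) before use, and each probe is recentred
    so its grand mean is preserved exactly.

    Note a batch effect that is constant across all probes of a batch is
    indistinguishable from a global shift of those samples; the adjustment
    equalizes batch locations/scales but preserves each probe's overall mean of
    the *input* matrix.
    """
    if not m.is_log2:
        raise ValueError("batch_adjust expects log2 data (is_log2=True)")
    batches = pd.Series(list(batches), index=m.sample_ids)
    groups = {b: np.flatnonzero((batches == b).to_numpy()) for b in batches.unique()}
    if len(groups) < 2:
        raise ValueError("batch_adjust needs >= 2 batches")
    for b, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    X = m.values.to_numpy(dtype=np.float64, copy=True)
    grand = X.mean(axis=1)

    means = {b: X[:, idx].mean(axis=1) for b, idx in groups.items()}
    sds = {b: X[:, idx].std(axis=1, ddof=1) for b, idx in groups.items()}
    dof = {b: idx.size - 1 for b, idx in groups.items()}
    pooled_var = sum(dof[b] * sds[b] ** 2 for b in groups) / sum(dof.values())
    pooled_sd = np.sqrt(pooled_var)

    for b, idx in groups.items():
        mu, sd = means[b], sds[b]
        if shrink:
            w = idx.size / (idx.size + 1.0)
            mu = w * mu + (1.0 - w) * mu.mean()
            sd = w * sd + (1.0 - w) * sd.mean()
        scale = np.where(sd > 1e-12, pooled_sd / np.where(sd > 1e-12, sd, 1.0), 1.0)
        X[:, idx] = (X[:, idx] - mu[:, None]) * scale[:, None] + grand[:, None]

    # restore each probe's input grand mean (exact; a no-op without shrinkage)
    X += (grand - X.mean(axis=1))[:, None]
    values = pd.DataFrame(X, index=m.probe_ids, columns=m.sample_ids)
    return replace(m, values=values)


def replicate_qc(
    m: ExpressionMatrix, p: PhenotypeTable, threshold: float = 0.95
) -> pd.DataFrame:
    """Pearson correlation across probes for each blind-duplicate pair.

    Returns a DataFrame with columns ``sample_id, replicate_of, correlation,
    flagged``; pairs below ``threshold`` are flagged. Replicate assay quality in
    this platform class is typically r >= 0.98.
    """
    t = p.table
    pairs = t[t["replicate_of"].notna() & (t["replicate_of"] != "")]
    records = []
    for _, row in pairs.iterrows():
        a, b = row["sample_id"], row["replicate_of"]
        for s in (a, b):
            if s not in m.sample_ids:
                raise ValueError(f"replicate sample {s!r} absent from expression matrix")
        r = float(np.corrcoef(m.values[a].to_numpy(), m.values[b].to_numpy())[0, 1])
        records.append(
            {"sample_id": a, "replicate_of": b, "correlation": r, "flagged": r < threshold}
        )
    if not records:
        logger.info("replicate_qc: no replicate pairs present")
        return pd.DataFrame(columns=["sample_id", "replicate_of", "correlation", "flagged"])
    out = pd.DataFrame.from_records(records)
    n_flag = int(out["flagged"].sum())
    if n_flag:
        logger.warning("replicate_qc: %d pair(s) below threshold %.2f", n_flag, threshold)
    return out
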