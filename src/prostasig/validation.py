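"""Independent-cohort validation of a robust-marker panel.

Each panel transcript is evaluated in the validation cohort: group means,
log2 difference and fold change, AUC and pAUC on discovery-oriented scores with
permutation p-values and stratified-bootstrap CIs, a two-sided t-test,
Benjamini-Hochberg q-values across the panel, and direction concordance with
the discovery orientation. A transcript is declared validated when any of its
AUC/pAUC/t-test p-values is below ``alpha`` (default 0.05) and its q-value is
below ``fdr`` (default 0.20).

Each transcript is also combined with Gleason score in a two-covariate logistic
model and compared with the Gleason-only base model by a likelihood-ratio test
(chi-square, 1 df), with the combined model's in-sample AUC/pAUC reported.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import (
    ExpressionMatrix,
    GLEASON_LEVELS,
    PSA_LEVELS,
    PhenotypeTable,
    STAGE_LEVELS,
)
from .roc import RocConfig, _auc_pauc, bh_fdr, permutation_p, stratified_bootstrap_ci, t_test
from .selection import fit_logistic, gleason_design

logger = logging.getLogger(__name__)

__all__ = [
    "validate_panel",
    "combined_model",
    "combined_model_table",
    "table_reports",
]


def _panel_frame(panel) -> pd.DataFrame:
    """Normalize a panel argument to a DataFrame with transcript_id, orientation."""
    if isinstance(panel, pd.DataFrame):
        df = panel[["transcript_id", "orientation"]].copy()
    elif isinstance(panel, pd.Series):
        df = pd.DataFrame({"transcript_id": panel.index, "orientation": panel.to_numpy()})
    else:
        df = pd.DataFrame(list(panel), columns=["transcript_id", "orientation"])
    df["orientation"] = df["orientation"].astype(int)
    if not df["orientation"].isin([-1, 1]).all():
        raise ValueError("orientations must be +1 or -1")
    return df.reset_index(drop=True)


def validate_panel(
    m_val: ExpressionMatrix,
    p_val: PhenotypeTable,
    panel,
    cfg: RocConfig | None = None,
    alpha: float = 0.05,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Per-transcript validation statistics in the independent cohort.

    ``panel`` carries the discovery orientations (+1 = higher expression in
    metastatic-lethal); AUC/pAUC and their permutation p-values are computed on
    orientation-adjusted scores so that concordant transcripts have AUC >= 0.5.
    BH q-values are computed on the t-test p-values with m = panel size.
    """
    cfg = cfg or RocConfig()
    pf = _panel_frame(panel)
    absent = [t for t in pf["transcript_id"] if t not in m_val.probe_ids]
    if absent:
        raise ValueError(f"panel transcripts absent from validation matrix: {absent}")
    y = p_val.outcome01(m_val.sample_ids)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    fpr_max = 1.0 - cfg.specificity_floor

    gene = m_val.gene_symbols
    chrom = m_val.chromosome
    records = []
    for k, row in pf.iterrows():
        tid, orient = row["transcript_id"], int(row["orientation"])
        x = m_val.values.loc[tid].to_numpy(dtype=np.float64)
        mean0 = float(x[y == 0].mean())
        mean1 = float(x[y == 1].mean())
        diff = mean1 - mean0
        scores = orient * x
        a, pa = _auc_pauc(scores, y, fpr_max)
        tcfg = replace(cfg, seed=int(np.random.SeedSequence([cfg.seed, k]).generate_state(1)[0] % 2**31))
        p_a = permutation_p(scores, y, "auc", tcfg)
        p_pa = permutation_p(scores, y, "pauc", tcfg)
        ci_a = stratified_bootstrap_ci(scores, y, "auc", tcfg)
        ci_pa = stratified_bootstrap_ci(scores, y, "pauc", tcfg)
        t_stat, p_t = t_test(x[y == 1], x[y == 0])
        records.append(
            {
                "transcript_id": tid,
                "gene": "" if gene is None else str(gene.get(tid, "")),
                "chromosome": "" if chrom is None else str(chrom.get(tid, "")),
                "mean_nonrecurrent": mean0,
                "mean_metlethal": mean1,
                "difference": diff,
                "fold_change": float(2.0**diff),
                "auc": a,
                "p_auc": p_a,
                "ci_auc_low": ci_a[0],
                "ci_auc_high": ci_a[1],
                "pauc": pa,
                "p_pauc": p_pa,
                "ci_pauc_low": ci_pa[0],
                "ci_pauc_high": ci_pa[1],
                "t_statistic": t_stat,
                "p_ttest": p_t,
                "orientation": orient,
                "direction_concordant": bool(np.sign(diff) == orient),
            }
        )
    out = pd.DataFrame.from_records(records)
    out["q_value"] = bh_fdr(out["p_ttest"].to_numpy(), m=len(out))
    any_sig = (out[["p_auc", "p_pauc", "p_ttest"]] < alpha).any(axis=1)
    out["validated"] = any_sig & (out["q_value"] < fdr)
    logger.info(
        "validate_panel: %d of %d transcripts validated (alpha=%g, fdr=%g)",
        int(out["validated"].sum()),
        len(out),
        alpha,
        fdr,
    )
    return out


def combined_model(
    m_val: ExpressionMatrix,
    p_val: PhenotypeTable,
    transcript: str,
    cfg: RocConfig | None = None,
    gleason_coding: str = "ordinal",
) -> tuple[float, float, float]:
    """Gleason + transcript logistic model vs Gleason alone in the validation cohort.

    Returns (combined_auc, combined_pauc, p_lrt): in-sample AUC/pAUC of the
    two-covariate model's fitted probabilities and the likelihood-ratio p-value
    (deviance difference against chi-square with 1 df). Returns NaNs when either
    fit fails to converge (e.g. separation).
    """
    cfg = cfg or RocConfig()
    if transcript not in m_val.probe_ids:
        raise ValueError(f"transcript {transcript!r} absent from validation matrix")
    y = p_val.outcome01(m_val.sample_ids).astype(float)
    base = gleason_design(p_val, m_val.sample_ids, gleason_coding)
    x = m_val.values.loc[transcript].to_numpy(dtype=np.float64)
    fit0 = fit_logistic(base, y)
    fit1 = fit_logistic(np.column_stack([base, x]), y)
    if not (fit0.converged and fit1.converged):
        logger.warning("combined_model: non-converged fit for %s; metrics missing", transcript)
        return float("nan"), float("nan"), float("nan")
    fpr_max = 1.0 - cfg.specificity_floor
    a, pa = _auc_pauc(fit1.fitted, y, fpr_max)
    lr = max(0.0, fit0.deviance - fit1.deviance)
    p_lrt = float(stats.chi2.sf(lr, df=1))
    return a, pa, p_lrt


def combined_model_table(
    m_val: ExpressionMatrix,
    p_val: PhenotypeTable,
    transcripts,
    cfg: RocConfig | None = None,
    gleason_coding: str = "ordinal",
) -> pd.DataFrame:
    """Combined-model metrics for a list of transcripts, plus the Gleason-only row.

    The returned frame has one row per transcript (combined_auc, combined_pauc,
    p_lrt) and ``attrs['gleason_only']`` holding the base model's (auc, pauc).
    """
    cfg = cfg or RocConfig()
    y = p_val.outcome01(m_val.sample_ids).astype(float)
    base = gleason_design(p_val, m_val.sample_ids, gleason_coding)
    fit0 = fit_logistic(base, y)
    fpr_max = 1.0 - cfg.specificity_floor
    base_auc, base_pauc = _auc_pauc(fit0.fitted, y, fpr_max)
    rows = []
    gene = m_val.gene_symbols
    for tid in transcripts:
        a, pa, p_lrt = combined_model(m_val, p_val, tid, cfg, gleason_coding)
        rows.append(
            {
                "transcript_id": tid,
                "gene": "" if gene is None else str(gene.get(tid, "")),
                "combined_auc": a,
                "combined_pauc": pa,
                "p_lrt": p_lrt,
            }
        )
    out = pd.DataFrame.from_records(rows)
    out.attrs["gleason_only"] = {"auc": base_auc, "pauc": base_pauc}
    return out


def _fmt_p(p: float, floor: float = 0.01) -> str:
    if np.isnan(p):
        return "NA"
    if p < floor:
        return f"{p:.2e}"
    return f"{p:.2f}"


def _fmt_p_threshold(p: float, threshold: float = 0.01) -> str:
    """Categorical-test rendering: values below the threshold print as '< 0.01'."""
    if np.isnan(p):
        return "NA"
    if p < threshold:
        return f"< {threshold:g}"
    return f"{p:.2f}"


def _categorical_rows(
    tab: pd.DataFrame, col: str, levels, labels
) -> tuple[list[dict], float]:
    """Count/percent rows by outcome for one categorical variable + chi-square p."""
    groups = {
        "nonrecurrent": tab[tab["outcome"] == "nonrecurrent"],
        "metastatic_lethal": tab[tab["outcome"] == "metastatic_lethal"],
    }
    n0, n1 = len(groups["nonrecurrent"]), len(groups["metastatic_lethal"])
    counts = np.array(
        [
            [int((groups[g][col] == lv).sum()) for g in ("nonrecurrent", "metastatic_lethal")]
            for lv in levels
        ]
    )
    rows = []
    for lv, label, (c0, c1) in zip(levels, labels, counts):
        rows.append(
            {
                "variable": col,
                "category": label,
                "n_nonrecurrent": int(c0),
                "pct_nonrecurrent": f"{100.0 * c0 / n0:.1f}" if n0 else "0.0",
                "n_metlethal": int(c1),
                "pct_metlethal": f"{100.0 * c1 / n1:.1f}" if n1 else "0.0",
            }
        )
    nonzero = counts[counts.sum(axis=1) > 0]
    if nonzero.shape[0] >= 2 and (nonzero.sum(axis=0) > 0).all():
        chi2_p = float(stats.chi2_contingency(nonzero)[1])
    else:
        chi2_p = float("nan")
    return rows, chi2_p


GLEASON_LABELS = ("<=6", "7(3+4)", "7(4+3)", "8-10")
STAGE_LABELS = ("local", "regional", "missing")
PSA_LABELS = ("<4.0", "4.0-9.9", "10.0-19.9", ">=20", "missing")


def descriptive_table(p_val: PhenotypeTable) -> pd.DataFrame:
    """Cohort descriptive statistics by outcome: age (t-test) and categorical
    variables with counts, percentages and chi-square p-values."""
    tab = p_val.table
    g0 = tab[tab["outcome"] == "nonrecurrent"]
    g1 = tab[tab["outcome"] == "metastatic_lethal"]
    rows = []
    if len(g0) >= 2 and len(g1) >= 2:
        _, p_age = t_test(g0["age"], g1["age"])
    else:
        p_age = float("nan")
    rows.append(
        {
            "variable": "age",
            "category": "mean (SD)",
            "n_nonrecurrent": len(g0),
            "pct_nonrecurrent": f"{g0['age'].mean():.1f} ({g0['age'].std(ddof=1):.1f})",
            "n_metlethal": len(g1),
            "pct_metlethal": f"{g1['age'].mean():.1f} ({g1['age'].std(ddof=1):.1f})",
            "p_value": f"{p_age:.2f}" if np.isfinite(p_age) else "NA",
        }
    )
    for col, levels, labels in (
        ("gleason", GLEASON_LEVELS, GLEASON_LABELS),
        ("stage", STAGE_LEVELS, STAGE_LABELS),
        ("psa_cat", PSA_LEVELS, PSA_LABELS),
    ):
        var_rows, chi2_p = _categorical_rows(tab, col, levels, labels)
        var_rows[0]["p_value"] = _fmt_p_threshold(chi2_p)
        for r in var_rows[1:]:
            r["p_value"] = ""
        rows.extend(var_rows)
    return pd.DataFrame.from_records(rows)


def format_validation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Human-readable rendering of validation records (means/fold to 2 d.p.,
    p-values in scientific notation below 0.01)."""
    out = pd.DataFrame(
        {
            "transcript_id": records["transcript_id"],
            "gene": records["gene"],
            "chromosome": records["chromosome"],
            "mean_nonrecurrent": records["mean_nonrecurrent"].map("{:.2f}".format),
            "mean_metlethal": records["mean_metlethal"].map("{:.2f}".format),
            "difference": records["difference"].map("{:.2f}".format),
            "fold_change": records["fold_change"].map("{:.2f}".format),
            "auc": records["auc"].map("{:.2f}".format),
            "p_auc": records["p_auc"].map(_fmt_p),
            "pauc": records["pauc"].map("{:.4f}".format),
            "p_pauc": records["p_pauc"].map(_fmt_p),
            "p_ttest": records["p_ttest"].map(_fmt_p),
            "q_value": records["q_value"].map(_fmt_p),
            "validated": records["validated"].map({True: "yes", False: "no"}),
        }
    )
    return out


def format_model_table(models: pd.DataFrame) -> pd.DataFrame:
    """Rendering of combined Gleason+transcript model metrics."""
    return pd.DataFrame(
        {
            "transcript_id": models["transcript_id"],
            "gene": models["gene"],
            "combined_auc": models["combined_auc"].map("{:.2f}".format),
            "combined_pauc": models["combined_pauc"].map("{:.4f}".format),
            "p_lrt": models["p_lrt"].map(_fmt_p),
        }
    )


def table_reports(
    records: pd.DataFrame,
    p_val: PhenotypeTable,
    models: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive, validation and (optionally) combined-model report tables."""
    if records is None or len(records) == 0:
        raise ValueError("records must be nonempty")
    out = {
        "descriptive": descriptive_table(p_val),
        "validation": format_validation_table(records),
    }
    if models is not None:
        out["models"] = format_model_table(models)
    return out
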