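"""Forward transcript selection over a Gleason-score logistic base model,
stabilized by bootstrap resampling.

The base model is logistic regression of the metastatic-lethal outcome on
Gleason score (ordinal 1-4 coding by default over the categories <=6, 3+4, 4+3,
8-10). Forward model building adds one transcript at a time under one of three
figures of merit computed on the model's in-sample fitted probabilities:

* ``pauc``  — gain in pAUC at the specificity floor; stop when the best gain
  falls below ``min_pauc_gain`` (default 0.0005);
* ``auc``   — gain in AUC; stop below ``min_auc_gain`` (default 0.005);
* ``wald``  — Wald p-value of the newly added term; stop when the best p
  exceeds ``max_wald_p`` (default 0.05).

To damp the randomness of a single stepwise run, the whole procedure is
repeated on outcome-stratified bootstrap resamples (default 1000) for each
criterion; transcripts appearing in more than ``min_count`` (default 40) of the
panels for at least one criterion are declared robust markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .ingest import ExpressionMatrix, GLEASON_LEVELS, PhenotypeTable
from .roc import _auc_pauc

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "LogisticFit",
    "StabilityResult",
    "gleason_design",
    "fit_logistic",
    "forward_select",
    "stability_select",
]

CRITERIA = ("auc", "pauc", "wald")


@dataclass
class SelectionConfig:
    min_pauc_gain: float = 0.0005
    min_auc_gain: float = 0.005
    max_wald_p: float = 0.05
    n_stability: int = 1000
    min_count: int = 40
    max_panel_size: int = 10
    gleason_coding: str = "ordinal"
    specificity_floor: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_pauc_gain", "min_auc_gain", "max_wald_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.min_count < self.n_stability:
            raise ValueError(
                f"min_count ({self.min_count}) must be < n_stability ({self.n_stability})"
            )
        if self.gleason_coding not in ("ordinal", "categorical"):
            raise ValueError(f"unknown gleason_coding {self.gleason_coding!r}")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with Wald machinery."""

    coef: np.ndarray
    se: np.ndarray
    deviance: float
    fitted: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0

    def wald_p(self, j: int = -1) -> float:
        """Two-sided Wald p-value for coefficient j (default: last term)."""
        se = self.se[j]
        if not np.isfinite(se) or se == 0.0:
            return 1.0
        z = self.coef[j] / se
        return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class StabilityResult:
    """Bootstrap selection counts per transcript and criterion.

    ``table`` columns: transcript_id, count_auc, count_pauc, count_wald, robust.
    A transcript is robust when its count exceeds ``min_count`` for at least one
    criterion.
    """

    table: pd.DataFrame = field(repr=False)
    n_stability: int = 0
    min_count: int = 0

    @property
    def robust_ids(self) -> list[str]:
        return self.table.loc[self.table["robust"], "transcript_id"].tolist()


_MAX_ETA = 30.0  # logit beyond which fitted probabilities are numerically 0/1


def fit_logistic(
    design,
    outcome,
    start: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit logistic regression by iteratively reweighted least squares.

    ``design`` must include an intercept column if one is wanted. Convergence is
    declared when the relative deviance change falls below ``tol``. Perfect
    separation (a diverging coefficient with vanishing deviance contribution)
    is flagged via ``converged=False``. A rank-deficient design (e.g. duplicated
    covariates) is fit through the pseudoinverse; the redundant directions get
    infinite standard errors so their Wald p-values are 1.
    """
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome are misaligned")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=np.float64).copy()

    dev = np.inf
    singular = False
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        rhs = Xw.T @ z
        try:
            beta_new = np.linalg.solve(H, rhs)
            if not np.all(np.isfinite(beta_new)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            singular = True
            beta_new = np.linalg.lstsq(H, rhs, rcond=None)[0]
        eta_new = np.clip(X @ beta_new, -_MAX_ETA, _MAX_ETA)
        mu_new = expit(eta_new)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = y * np.log(mu_new) + (1.0 - y) * np.log(1.0 - mu_new)
        dev_new = float(-2.0 * np.nansum(ll))
        beta = beta_new
        rel = abs(dev - dev_new) / (abs(dev_new) + 1e-12) if np.isfinite(dev) else np.inf
        dev = dev_new
        if rel < tol:
            break

    eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = X.T @ (X * w[:, None])
    se = np.full(p, np.inf)
    separated = bool(np.abs(eta).max() >= _MAX_ETA - 1e-6)
    if singular or np.linalg.cond(H) > 1e10:
        # observed information is (near) singular: leave SEs infinite so the
        # redundant term's Wald test is conservative
        singular = True
    else:
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            singular = True
    converged = (it < max_iter or rel < tol) and not separated
    fitted = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return LogisticFit(
        coef=beta, se=se, deviance=dev, fitted=fitted, converged=converged, n_iter=it
    )


def gleason_design(p: PhenotypeTable, sample_ids, coding: str = "ordinal") -> np.ndarray:
    """Design matrix (with intercept) for the Gleason-score base model.

    Ordinal coding maps the four categories to 1..4 in a single column, keeping
    the base model estimable with few events; categorical coding uses indicator
    columns for the three upper categories.
    """
    aligned = p.aligned(sample_ids)
    codes = aligned["gleason"].map({lv: i + 1 for i, lv in enumerate(GLEASON_LEVELS)})
    if codes.isna().any():
        raise ValueError("unmapped gleason level")
    n = len(aligned)
    if coding == "ordinal":
        return np.column_stack([np.ones(n), codes.to_numpy(dtype=float)])
    if coding == "categorical":
        cols = [np.ones(n)]
        for i in range(2, 5):
            cols.append((codes.to_numpy() == i).astype(float))
        return np.column_stack(cols)
    raise ValueError(f"unknown gleason coding {coding!r}")


def _batched_candidate_fits(
    cur_design: np.ndarray,
    cand_cols: np.ndarray,
    y: np.ndarray,
    warm: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """IRLS fits of (cur_design | candidate) for every candidate column at once.

    Vectorizes the one-step-ahead logistic fits of forward selection across the
    candidate axis; identical per-candidate math to :func:`fit_logistic` (same
    warm start, damping, and convergence rule).
    """
    n, p0 = cur_design.shape
    C = cand_cols.shape[1]
    p = p0 + 1
    X = np.empty((C, n, p))
    X[:, :, :p0] = cur_design[None, :, :]
    X[:, :, p0] = cand_cols.T
    beta = np.tile(warm, (C, 1))
    dev = np.full(C, np.inf)
    active = np.ones(C, dtype=bool)

    for _it in range(max_iter):
        idx = np.flatnonzero(active)
        Xa = X[idx]
        eta = np.clip(np.einsum("cnp,cp->cn", Xa, beta[idx]), -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y[None, :] - mu) / w
        Xw = Xa * w[:, :, None]
        H = np.einsum("cnp,cnq->cpq", Xw, Xa)
        rhs = np.einsum("cnp,cn->cp", Xw, z)
        try:
            bnew = np.linalg.solve(H, rhs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            bnew = np.stack(
                [np.linalg.lstsq(H[i], rhs[i], rcond=None)[0] for i in range(len(idx))]
            )
        bad = ~np.all(np.isfinite(bnew), axis=1)
        for i in np.flatnonzero(bad):
            bnew[i] = np.linalg.lstsq(H[i], rhs[i], rcond=None)[0]
        eta_new = np.clip(np.einsum("cnp,cp->cn", Xa, bnew), -_MAX_ETA, _MAX_ETA)
        mu_new = expit(eta_new)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = y[None, :] * np.log(mu_new) + (1.0 - y[None, :]) * np.log(1.0 - mu_new)
        dev_new = -2.0 * np.nansum(ll, axis=1)
        rel = np.abs(dev[idx] - dev_new) / (np.abs(dev_new) + 1e-12)
        beta[idx] = bnew
        dev[idx] = dev_new
        active[idx[rel < tol]] = False
        if not active.any():
            break

    eta = np.clip(np.einsum("cnp,cp->cn", X, beta), -_MAX_ETA, _MAX_ETA)
    mu = expit(eta)
    separated = np.abs(eta).max(axis=1) >= _MAX_ETA - 1e-6
    converged = ~active & ~separated
    fitted = np.clip(mu, 1e-12, 1.0 - 1e-12)
    # Wald p for the candidate term, from the observed information; near-singular
    # designs (redundant candidate) get p = 1
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = np.einsum("cnp,cnq->cpq", X * w[:, :, None], X)
    ev = np.linalg.eigvalsh(H)
    singular = (ev[:, 0] <= 0) | (ev[:, -1] / np.maximum(ev[:, 0], 1e-300) > 1e10)
    wald_p = np.ones(C)
    ok = np.flatnonzero(~singular)
    if ok.size:
        cov = np.linalg.inv(H[ok])
        se_last = np.sqrt(np.maximum(cov[:, p - 1, p - 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.abs(beta[ok, p - 1]) / se_last
        wald_p[ok] = np.where(se_last > 0, 2.0 * stats.norm.sf(zstat), 1.0)
    return {
        "coef": beta,
        "deviance": dev,
        "fitted": fitted,
        "converged": converged,
        "wald_p": wald_p,
    }


def _forward_select_arrays(
    cand_matrix: np.ndarray,
    cand_ids: list[str],
    base_design: np.ndarray,
    y: np.ndarray,
    criterion: str,
    cfg: SelectionConfig,
) -> list[str]:
    """Forward selection on raw arrays; cand_matrix is samples x candidates."""
    fpr_max = 1.0 - cfg.specificity_floor
    base_fit = fit_logistic(base_design, y)
    cur_design = base_design
    cur_beta = base_fit.coef
    cur_auc, cur_pauc = _auc_pauc(base_fit.fitted, y, fpr_max)
    panel: list[int] = []
    remaining = np.arange(len(cand_ids))

    while len(panel) < cfg.max_panel_size and remaining.size:
        warm = np.append(cur_beta, 0.0)
        fits = _batched_candidate_fits(cur_design, cand_matrix[:, remaining], y, warm)
        merit = np.full(remaining.size, -np.inf)
        conv = np.flatnonzero(fits["converged"])
        if criterion == "wald":
            merit[conv] = -fits["wald_p"][conv]
        else:
            for i in conv:
                a, pa = _auc_pauc(fits["fitted"][i], y, fpr_max)
                merit[i] = a if criterion == "auc" else pa
        if not np.isfinite(merit).any():
            logger.info("forward_select: no candidate fit converged; stopping")
            break
        k = int(np.argmax(merit))  # ties resolve to earliest candidate
        best_merit = merit[k]
        if criterion == "auc":
            if best_merit - cur_auc < cfg.min_auc_gain:
                break
        elif criterion == "pauc":
            if best_merit - cur_pauc < cfg.min_pauc_gain:
                break
        else:
            if -best_merit > cfg.max_wald_p:
                break
        j = int(remaining[k])
        panel.append(j)
        cur_design = np.column_stack([cur_design, cand_matrix[:, j]])
        cur_beta = fits["coef"][k]
        cur_auc, cur_pauc = _auc_pauc(fits["fitted"][k], y, fpr_max)
        remaining = np.delete(remaining, k)
    return [cand_ids[j] for j in panel]


def forward_select(
    m: ExpressionMatrix,
    p: PhenotypeTable,
    candidates,
    criterion: str,
    cfg: SelectionConfig | None = None,
) -> list[str]:
    """Stepwise forward selection of transcripts over the Gleason base model.

    Returns the ordered panel of transcript ids (possibly empty). Deterministic
    given data and config: ties in the figure of merit resolve to the earliest
    candidate in the given order.
    """
    cfg = cfg or SelectionConfig()
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    cand_ids = list(candidates)
    if not cand_ids:
        raise ValueError("candidates must be nonempty")
    missing = [c for c in cand_ids if c not in m.probe_ids]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing[:5]}")
    y = p.outcome01(m.sample_ids).astype(float)
    base = gleason_design(p, m.sample_ids, cfg.gleason_coding)
    cand_matrix = m.values.loc[cand_ids].to_numpy(dtype=np.float64).T
    return _forward_select_arrays(cand_matrix, cand_ids, base, y, criterion, cfg)


def stability_select(
    m: ExpressionMatrix,
    p: PhenotypeTable,
    candidates,
    cfg: SelectionConfig | None = None,
    use_full_sample: bool = False,
) -> StabilityResult:
    """Bootstrap-stabilized forward selection under all three criteria.

    For each criterion, ``n_stability`` outcome-stratified bootstrap resamples
    are drawn and the stepwise build repeated on each; the per-transcript panel
    membership counts are tallied, and transcripts whose count exceeds
    ``min_count`` under at least one criterion are flagged robust.

    ``use_full_sample=True`` replaces every resample by the full cohort (a
    diagnostic mode: with ``n_stability=1`` it reproduces ``forward_select``).
    """
    cfg = cfg or SelectionConfig()
    cand_ids = list(candidates)
    if not cand_ids:
        raise ValueError("candidates must be nonempty")
    y = p.outcome01(m.sample_ids).astype(float)
    base = gleason_design(p, m.sample_ids, cfg.gleason_coding)
    cand_matrix = m.values.loc[cand_ids].to_numpy(dtype=np.float64).T

    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    counts = {c: np.zeros(len(cand_ids), dtype=np.int64) for c in CRITERIA}
    id_pos = {t: i for i, t in enumerate(cand_ids)}

    n_redrawn = 0
    for ci, criterion in enumerate(CRITERIA):
        rng = np.random.default_rng([cfg.seed, 31 + ci])
        for _b in range(cfg.n_stability):
            if use_full_sample:
                idx = np.arange(y.shape[0])
            else:
                for _attempt in range(100):
                    idx = np.concatenate(
                        [
                            rng.choice(case_idx, size=case_idx.size, replace=True),
                            rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
                        ]
                    )
                    if y[idx].min() != y[idx].max():
                        break
                    n_redrawn += 1
            panel = _forward_select_arrays(
                cand_matrix[idx], cand_ids, base[idx], y[idx], criterion, cfg
            )
            for t in panel:
                counts[criterion][id_pos[t]] += 1
    if n_redrawn:
        logger.info("stability_select: %d single-class resamples redrawn", n_redrawn)

    table = pd.DataFrame(
        {
            "transcript_id": cand_ids,
            "count_auc": counts["auc"],
            "count_pauc": counts["pauc"],
            "count_wald": counts["wald"],
        }
    )
    max_count = table[["count_auc", "count_pauc", "count_wald"]].max(axis=1)
    table["robust"] = max_count > cfg.min_count
    logger.info(
        "stability_select: %d of %d candidates robust (count > %d in >= 1 criterion)",
        int(table["robust"].sum()),
        len(cand_ids),
        cfg.min_count,
    )
    return StabilityResult(table=table, n_stability=cfg.n_stability, min_count=cfg.min_count)
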