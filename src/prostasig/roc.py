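"""Core ROC and inference statistics.

Empirical AUC and partial AUC (pAUC) at a fixed specificity floor, label-permutation
p-values, stratified bootstrap percentile confidence intervals, two-sample t-tests,
fold changes on the log2 scale, and Benjamini-Hochberg FDR.

Conventions
-----------
* AUC is the Mann-Whitney estimator: over all (case, control) pairs, the fraction
  with score_case > score_control, ties counted 1/2. It equals trapezoidal area
  under the tie-corrected empirical ROC curve, which is how it is computed here.
* pAUC is the *unnormalized* area under the empirical ROC curve for false-positive
  rate in [0, 1 - specificity_floor]; at the default floor of 0.95 its maximum is
  0.05 (perfect classifier) and its chance value is 0.05**2 / 2 = 0.00125. Tied
  scores produce diagonal ROC segments; the curve is linearly interpolated at the
  FPR window boundary.
* Permutation p-values use the plus-one convention
  p = (1 + #{permuted >= observed}) / (B + 1), so p is never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RocConfig",
    "RocResult",
    "auc",
    "pauc",
    "roc_points",
    "permutation_p",
    "stratified_bootstrap_ci",
    "t_test",
    "fold_change",
    "bh_fdr",
    "roc_result",
]


@dataclass
class RocConfig:
    """Resampling and windowing parameters for ROC inference.

    specificity_floor : lower bound on specificity for the pAUC window
        (default 0.95, i.e. FPR in [0, 0.05]).
    n_permutations : label permutations for p-values (default 10000).
    n_bootstrap : stratified bootstrap replicates for CIs (default 2000).
    alternative : 'greater' tests for AUC/pAUC larger than chance;
        'two_sided' tests distance from the chance value.
    """

    specificity_floor: float = 0.95
    n_permutations: int = 10_000
    n_bootstrap: int = 2_000
    seed: int = 0
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if not 0.0 < self.specificity_floor < 1.0:
            raise ValueError(
                f"specificity_floor must be in (0, 1), got {self.specificity_floor}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.alternative not in ("greater", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


@dataclass
class RocResult:
    """Point estimates and inference for one score vector."""

    auc: float
    pauc: float
    p_auc: float
    p_pauc: float
    ci_auc: tuple[float, float]
    ci_pauc: tuple[float, float]


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    y = y.astype(np.int8)
    if y.min() == y.max():
        raise ValueError("both classes must be present in labels")
    return y


def _areas_for_label_matrix(
    scores: np.ndarray, label_matrix: np.ndarray, fpr_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """AUC and pAUC for each row of a (B, n) 0/1 label matrix against fixed scores.

    The score ordering (and hence the tie structure) is shared across rows, which
    is what makes batched label permutation cheap.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    # last index of each distinct-score group = ROC vertex positions
    ends = np.flatnonzero(np.diff(s))
    ends = np.append(ends, n - 1)

    lab = np.ascontiguousarray(label_matrix[:, order], dtype=np.float64)
    n1 = lab.sum(axis=1)
    n0 = n - n1
    tp = np.cumsum(lab, axis=1)[:, ends]
    fp = (ends + 1.0)[None, :] - tp
    tpr = tp / n1[:, None]
    fpr = fp / n0[:, None]
    zeros = np.zeros((lab.shape[0], 1))
    tpr = np.concatenate([zeros, tpr], axis=1)
    fpr = np.concatenate([zeros, fpr], axis=1)

    f0, f1 = fpr[:, :-1], fpr[:, 1:]
    t0, t1 = tpr[:, :-1], tpr[:, 1:]
    width = f1 - f0
    full_auc = (width * (t0 + t1) / 2.0).sum(axis=1)

    safe_w = np.where(width > 0, width, 1.0)
    t_at_boundary = t0 + (t1 - t0) * (fpr_max - f0) / safe_w
    full_seg = width * (t0 + t1) / 2.0
    partial_seg = (fpr_max - f0) * (t0 + t_at_boundary) / 2.0
    seg = np.where(f1 <= fpr_max, full_seg, np.where(f0 < fpr_max, partial_seg, 0.0))
    partial_auc = seg.sum(axis=1)
    return full_auc, partial_auc


def _auc_pauc(scores, labels, fpr_max: float) -> tuple[float, float]:
    y = np.asarray(labels, dtype=np.int8)
    a, pa = _areas_for_label_matrix(np.asarray(scores, float), y[None, :], fpr_max)
    return float(a[0]), float(pa[0])


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (FPR, TPR) of the tie-corrected empirical ROC curve, from (0,0) to (1,1)."""
    y = _as_labels(labels)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = y[order].astype(float)
    ends = np.append(np.flatnonzero(np.diff(s)), len(s) - 1)
    tp = np.cumsum(lab)[ends]
    fp = (ends + 1.0) - tp
    n1 = lab.sum()
    n0 = len(s) - n1
    fpr = np.concatenate([[0.0], fp / n0])
    tpr = np.concatenate([[0.0], tp / n1])
    return fpr, tpr


def auc(scores, labels) -> float:
    """Mann-Whitney AUC (ties 1/2) of scores for discriminating labels 1 from 0."""
    y = _as_labels(labels)
    a, _ = _auc_pauc(scores, y, 0.05)
    return a


def pauc(scores, labels, cfg: RocConfig | None = None) -> float:
    """Unnormalized partial AUC over FPR in [0, 1 - specificity_floor]."""
    cfg = cfg or RocConfig()
    y = _as_labels(labels)
    _, pa = _auc_pauc(scores, y, 1.0 - cfg.specificity_floor)
    return pa


def _observed_and_permuted(
    scores, labels, statistic: str, cfg: RocConfig, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    y = _as_labels(labels)
    fpr_max = 1.0 - cfg.specificity_floor
    obs_a, obs_p = _auc_pauc(scores, y, fpr_max)
    obs = obs_a if statistic == "auc" else obs_p
    perm_labels = rng.permuted(
        np.tile(y, (cfg.n_permutations, 1)), axis=1
    )
    perm_a, perm_p = _areas_for_label_matrix(
        np.asarray(scores, float), perm_labels, fpr_max
    )
    perm = perm_a if statistic == "auc" else perm_p
    return obs, perm


def permutation_p(scores, labels, statistic: str, cfg: RocConfig) -> float:
    """Permutation p-value for AUC or pAUC, plus-one convention, seeded.

    For alternative='greater' the null is exceeded by large values of the
    statistic; for 'two_sided', by large distance from the chance value
    (0.5 for AUC, (1-floor)^2/2 for pAUC).
    """
    if statistic not in ("auc", "pauc"):
        raise ValueError(f"statistic must be 'auc' or 'pauc', got {statistic!r}")
    rng = np.random.default_rng(cfg.seed)
    obs, perm = _observed_and_permuted(scores, labels, statistic, cfg, rng)
    if cfg.alternative == "two_sided":
        chance = 0.5 if statistic == "auc" else (1.0 - cfg.specificity_floor) ** 2 / 2.0
        obs_d = abs(obs - chance)
        perm_d = np.abs(perm - chance)
    else:
        obs_d, perm_d = obs, perm
    n_ge = int(np.count_nonzero(perm_d >= obs_d - 1e-12))
    return (1 + n_ge) / (cfg.n_permutations + 1)


def stratified_bootstrap_ci(
    scores, labels, statistic: str, cfg: RocConfig
) -> tuple[float, float]:
    """Percentile 95% CI from class-stratified bootstrap resampling.

    Cases and controls are resampled separately with replacement so every
    replicate retains both classes. A replicate whose statistic is undefined is
    redrawn (logged).
    """
    if statistic not in ("auc", "pauc"):
        raise ValueError(f"statistic must be 'auc' or 'pauc', got {statistic!r}")
    y = _as_labels(labels)
    x = np.asarray(scores, dtype=np.float64)
    case_scores = x[y == 1]
    ctrl_scores = x[y == 0]
    if case_scores.size < 2 or ctrl_scores.size < 2:
        raise ValueError("each class needs >= 2 members for a stratified bootstrap")
    fpr_max = 1.0 - cfg.specificity_floor
    rng = np.random.default_rng(cfg.seed)
    yy = np.concatenate([np.ones(case_scores.size, np.int8), np.zeros(ctrl_scores.size, np.int8)])

    out = np.empty(cfg.n_bootstrap)
    n_redrawn = 0
    for b in range(cfg.n_bootstrap):
        for _attempt in range(100):
            sc = np.concatenate(
                [
                    rng.choice(case_scores, size=case_scores.size, replace=True),
                    rng.choice(ctrl_scores, size=ctrl_scores.size, replace=True),
                ]
            )
            a, pa = _auc_pauc(sc, yy, fpr_max)
            val = a if statistic == "auc" else pa
            if np.isfinite(val):
                break
            n_redrawn += 1
        out[b] = val
    if n_redrawn:
        logger.info("stratified bootstrap: %d degenerate replicates redrawn", n_redrawn)
    lo, hi = np.percentile(out, [2.5, 97.5])
    if cfg.n_bootstrap == 1:
        logger.warning("n_bootstrap=1: degenerate CI with equal bounds")
    return float(lo), float(hi)


def roc_result(scores, labels, cfg: RocConfig) -> RocResult:
    """Full per-score-vector ROC inference: point estimates, permutation p, bootstrap CI."""
    y = _as_labels(labels)
    fpr_max = 1.0 - cfg.specificity_floor
    a, pa = _auc_pauc(scores, y, fpr_max)
    p_a = permutation_p(scores, y, "auc", cfg)
    p_pa = permutation_p(scores, y, "pauc", cfg)
    ci_a = stratified_bootstrap_ci(scores, y, "auc", cfg)
    ci_pa = stratified_bootstrap_ci(scores, y, "pauc", cfg)
    return RocResult(auc=a, pauc=pa, p_auc=p_a, p_pauc=p_pa, ci_auc=ci_a, ci_pauc=ci_pa)


def t_test(values_a, values_b, equal_variance: bool = False) -> tuple[float, float]:
    """Two-sample t-test (Welch by default), returning (statistic, two-sided p).

    Degenerate input (zero variance in both groups with equal means) returns
    (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std() == 0.0 and b.std() == 0.0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.pvalue)


def fold_change(mean_log2_case: float, mean_log2_control: float) -> float:
    """Ratio of geometric means: 2**(mean_log2_case - mean_log2_control)."""
    return float(2.0 ** (mean_log2_case - mean_log2_control))


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Parameters
    ----------
    p_values : p-values in any order.
    m : total number of tests; defaults to ``len(p_values)`` but may be larger
        when only a subset of tests was carried forward (the omitted tests are
        assumed to have larger p-values; logged).

    Returns q-values in the input order, each capped at 1 and no smaller than
    its p-value.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if (p < 0).any() or (p > 1).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m ({m}) must be >= number of p-values ({k})")
    if m > k:
        logger.info("bh_fdr: m=%d exceeds list length %d (partial carry-forward)", m, k)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q
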