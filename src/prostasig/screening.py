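"""Genomewide per-transcript ROC screening in the discovery cohort.

Every transcript is scored by its expression values, oriented so AUC >= 0.5
(orientation recorded: +1 means higher expression in metastatic-lethal cases),
and ranked by AUC and by pAUC at the specificity floor. Transcripts in the top
``top_pauc_fraction`` by pAUC or/and the top ``top_auc_fraction`` by AUC (per
``combine_rule``, default union) form the reduced candidate panel handed to
forward selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import ExpressionMatrix, PhenotypeTable
from .roc import _auc_pauc

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "ScreenResult", "screen", "orientation_map"]


@dataclass
class ScreenConfig:
    top_pauc_fraction: float = 0.04
    top_auc_fraction: float = 0.01
    combine_rule: str = "union"
    specificity_floor: float = 0.95

    def __post_init__(self) -> None:
        for name in ("top_pauc_fraction", "top_auc_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.combine_rule not in ("union", "intersection"):
            raise ValueError(f"combine_rule must be union/intersection, got {self.combine_rule!r}")


@dataclass
class ScreenResult:
    """Per-transcript AUC/pAUC ranking with the dual-rank selection flags.

    ``table`` columns: transcript_id, gene, auc, pauc, rank_auc, rank_pauc,
    orientation, selected. Ranks are 1..m, ties broken by matrix row order.
    """

    table: pd.DataFrame = field(repr=False)
    cutoff_auc: int = 0
    cutoff_pauc: int = 0
    config: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def selected_ids(self) -> list[str]:
        return self.table.loc[self.table["selected"], "transcript_id"].tolist()


def _dense_rank_desc(metric: np.ndarray) -> np.ndarray:
    """Ranks 1..m by metric descending; ties broken by original index order."""
    order = np.lexsort((np.arange(metric.size), -metric))
    ranks = np.empty(metric.size, dtype=np.int64)
    ranks[order] = np.arange(1, metric.size + 1)
    return ranks


def screen(m: ExpressionMatrix, p: PhenotypeTable, cfg: ScreenConfig | None = None) -> ScreenResult:
    """Rank all transcripts by oriented AUC and pAUC; select the dual-rank panel."""
    cfg = cfg or ScreenConfig()
    if m.shape[0] == 0:
        raise ValueError("empty expression matrix")
    y = p.outcome01(m.sample_ids)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = m.values.to_numpy(dtype=np.float64)
    n_tx = X.shape[0]
    fpr_max = 1.0 - cfg.specificity_floor

    aucs = np.empty(n_tx)
    paucs = np.empty(n_tx)
    orient = np.empty(n_tx, dtype=np.int8)
    for g in range(n_tx):
        a, pa = _auc_pauc(X[g], y, fpr_max)
        if a >= 0.5:
            orient[g] = 1  # AUC == 0.5 oriented +1 by convention
            aucs[g], paucs[g] = a, pa
        else:
            orient[g] = -1
            aucs[g], paucs[g] = _auc_pauc(-X[g], y, fpr_max)

    rank_auc = _dense_rank_desc(aucs)
    rank_pauc = _dense_rank_desc(paucs)
    cutoff_auc = max(1, int(np.floor(n_tx * cfg.top_auc_fraction)))
    cutoff_pauc = max(1, int(np.floor(n_tx * cfg.top_pauc_fraction)))
    in_auc = rank_auc <= cutoff_auc
    in_pauc = rank_pauc <= cutoff_pauc
    selected = (in_auc | in_pauc) if cfg.combine_rule == "union" else (in_auc & in_pauc)

    genes = (
        m.gene_symbols.to_numpy()
        if m.gene_symbols is not None
        else np.array([""] * n_tx, dtype=object)
    )
    table = pd.DataFrame(
        {
            "transcript_id": m.probe_ids.to_numpy(),
            "gene": genes,
            "auc": aucs,
            "pauc": paucs,
            "rank_auc": rank_auc,
            "rank_pauc": rank_pauc,
            "orientation": orient.astype(int),
            "selected": selected,
        }
    )
    logger.info(
        "screen: %d transcripts, cutoffs auc<=%d pauc<=%d, %d selected (%s)",
        n_tx,
        cutoff_auc,
        cutoff_pauc,
        int(selected.sum()),
        cfg.combine_rule,
    )
    return ScreenResult(table=table, cutoff_auc=cutoff_auc, cutoff_pauc=cutoff_pauc, config=cfg)


def orientation_map(result: ScreenResult) -> pd.Series:
    """Per-transcript sign: +1 if raw expression is positively associated with
    the metastatic-lethal outcome, else -1. Used downstream for direction
    concordance in validation."""
    return pd.Series(
        result.table["orientation"].to_numpy(),
        index=result.table["transcript_id"].to_numpy(),
        name="orientation",
    )
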