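"""In-memory orchestration of the full two-cohort study.

Convenience layer over the stage modules for programmatic use (the CLI chains
the same stages through TSV artifacts): simulate or accept both cohorts, screen
the discovery cohort, stability-select candidates, validate the robust panel in
the independent cohort, and fit the Gleason+transcript combined models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .roc import RocConfig
from .screening import ScreenConfig, ScreenResult, orientation_map, screen
from .selection import SelectionConfig, StabilityResult, stability_select
from .synthetic import SimulationConfig, SyntheticCohort, simulate_cohort
from .validation import combined_model_table, validate_panel

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """All stage outputs of one simulated two-cohort study."""

    discovery: SyntheticCohort
    validation: SyntheticCohort
    screen: ScreenResult
    stability: StabilityResult
    records: pd.DataFrame = field(repr=False)
    models: pd.DataFrame = field(repr=False)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "screened": len(self.screen.table),
            "candidates": len(self.screen.selected_ids),
            "robust": len(self.stability.robust_ids),
            "validated": int(self.records["validated"].sum()) if len(self.records) else 0,
        }


def run_study(
    sim_cfg: SimulationConfig,
    screen_cfg: ScreenConfig | None = None,
    sel_cfg: SelectionConfig | None = None,
    roc_cfg: RocConfig | None = None,
    alpha: float = 0.05,
    fdr: float = 0.20,
    fit_models: bool = True,
) -> StudyResult:
    """Run the whole pipeline on a synthetic two-cohort pair."""
    dis = simulate_cohort(sim_cfg, "discovery")
    val = simulate_cohort(sim_cfg, "validation")
    scr = screen(dis.expression, dis.phenotype, screen_cfg)
    stab = stability_select(dis.expression, dis.phenotype, scr.selected_ids, sel_cfg)
    robust = stab.robust_ids
    if robust:
        panel = orientation_map(scr)[robust]
        records = validate_panel(val.expression, val.phenotype, panel, roc_cfg, alpha, fdr)
        if fit_models:
            models = combined_model_table(
                val.expression, val.phenotype, records["transcript_id"], roc_cfg
            )
        else:
            models = pd.DataFrame()
    else:
        records = pd.DataFrame()
        models = pd.DataFrame()
    return StudyResult(
        discovery=dis,
        validation=val,
        screen=scr,
        stability=stab,
        records=records,
        models=models,
    )
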