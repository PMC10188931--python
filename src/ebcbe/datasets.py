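"""Bundled example datasets.

Two small CSVs ship with the package, transcribed from an eight-subject
open-label crossover comparison of two commercial 100 ug/actuation
salbutamol metered-dose inhalers:

* per-subject Cmax (ng/mL) and AUC (ng*min/mL) of salbutamol in exhaled
  breath condensate over the 2-72 min sampling grid, for both inhalers;
* next-generation-impactor stage depositions (assay concentration per
  10 mL recovery solvent, 10 actuations, 30 L/min) for the same inhalers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .be_analysis import CrossoverDataset, read_wide_metrics_csv
from .impactor_apsd import ImpactorRun, read_impactor_csv

__all__ = [
    "crossover_pk_metrics_path",
    "ngi_stage_deposition_path",
    "load_crossover_pk_metrics",
    "load_ngi_runs",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("ebcbe").joinpath("data", name))


def crossover_pk_metrics_path() -> Path:
    """Path of the bundled per-subject Cmax/AUC crossover table."""
    return _data_path("crossover_pk_metrics.csv")


def ngi_stage_deposition_path() -> Path:
    """Path of the bundled impactor stage-deposition table."""
    return _data_path("ngi_stage_deposition.csv")


def load_crossover_pk_metrics() -> list[CrossoverDataset]:
    """Crossover datasets (cmax, auc) with MDI-1 as reference, MDI-2 as test."""
    return read_wide_metrics_csv(crossover_pk_metrics_path())


def load_ngi_runs() -> list[ImpactorRun]:
    """Impactor runs for the two bundled formulations (MDI-1, MDI-2)."""
    runs = read_impactor_csv(ngi_stage_deposition_path())
    return [
        ImpactorRun(
            run.formulation_id,
            run.deposits,
            flow_rate_lpm=run.flow_rate_lpm,
            n_actuations=run.n_actuations,
            label_claim_ug_per_actuation=100.0,
        )
        for run in runs
    ]
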