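"""Post-processing of scan trajectories.

Turns a :class:`~camtransit.scan.ScanTrajectory` into the model's
readouts: per-phase per-cell enzyme activity profiles, storage and K+
diagnostics, and the correlation-based classification of reactions whose
activity tracks increasing water-use efficiency:

* |r| > 0.9        -> strong up/down regulation
* 0.8 < |r| <= 0.9 -> moderate up/down regulation
* flux sign change across the trajectory -> direction flip (overrides)
* zero-variance series -> unclassified (correlation undefined)

Correlations are Pearson by default (Spearman by flag), computed against
the WUE value of each scan point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import CELLS, CombinedDielModel, prev_phase
from .scan import ScanTrajectory

#: fluxes below this magnitude are solver noise, treated as zero
FLUX_EPS = 1e-9

LABELS = (
    "strong_up",
    "moderate_up",
    "strong_down",
    "moderate_down",
    "direction_flip",
    "unclassified",
)


class AnalysisError(ValueError):
    pass


@dataclass
class PhaseCellSeries:
    """Flux of one reaction in one (phase, cell) across the scan,
    ordered by increasing WUE."""

    reaction_id: str
    cell_type: str
    phase: int
    values: list[float]


@dataclass
class ReactionClassification:
    reaction_id: str
    cell_type: str
    phase: int
    label: str
    correlation: float | None


def extract_series(
    trajectory: ScanTrajectory, reaction_id: str, cell: str, phase: int
) -> PhaseCellSeries:
    """Series of one reaction's flux along the scan (increasing WUE order).

    Scan points are recorded in decreasing-budget order, which is the
    increasing-WUE order; infeasible budgets were never recorded.
    """
    if not 1 <= phase <= 6:
        raise AnalysisError(f"phase {phase} outside 1-6")
    if cell not in CELLS:
        raise AnalysisError(f"unknown cell type {cell!r}")
    rid = trajectory.model.expanded_id(reaction_id, phase, cell)
    return PhaseCellSeries(
        reaction_id=reaction_id,
        cell_type=cell,
        phase=phase,
        values=[pt.solution.fluxes[rid] for pt in trajectory.points],
    )


def classify_series(
    values,
    wue_values,
    thresholds: tuple[float, float] = (0.8, 0.9),
    method: str = "pearson",
) -> tuple[str, float | None]:
    """Label one flux series against the WUE axis; returns (label, r)."""
    values = np.asarray(values, dtype=float)
    wue = np.asarray(wue_values, dtype=float)
    if values.shape != wue.shape:
        raise AnalysisError(
            f"series length {values.size} != WUE length {wue.size}"
        )
    if values.size < 3:
        raise AnalysisError("need at least 3 scan points to classify")

    clean = np.where(np.abs(values) < FLUX_EPS, 0.0, values)
    if clean.min() < 0.0 < clean.max():
        return "direction_flip", None
    if np.ptp(clean) < FLUX_EPS or np.ptp(wue) == 0.0:
        return "unclassified", None

    lo, hi = thresholds
    if method == "pearson":
        r = float(stats.pearsonr(clean, wue).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(clean, wue).statistic)
    else:
        raise AnalysisError(f"unknown correlation method {method!r}")
    if np.isnan(r):
        return "unclassified", None
    if r > hi:
        return "strong_up", r
    if r > lo:
        return "moderate_up", r
    if r < -hi:
        return "strong_down", r
    if r < -lo:
        return "moderate_down", r
    return "unclassified", r


def classify_reaction(
    series: PhaseCellSeries,
    wue_values,
    thresholds: tuple[float, float] = (0.8, 0.9),
    method: str = "pearson",
) -> ReactionClassification:
    label, r = classify_series(series.values, wue_values, thresholds, method)
    return ReactionClassification(
        reaction_id=series.reaction_id,
        cell_type=series.cell_type,
        phase=series.phase,
        label=label,
        correlation=r,
    )


def classify_trajectory(
    trajectory: ScanTrajectory,
    reaction_ids=None,
    thresholds: tuple[float, float] = (0.8, 0.9),
    method: str = "pearson",
) -> pd.DataFrame:
    """Classify every (reaction, phase, cell) of the trajectory.

    Returns a tidy frame with columns reaction_id, cell, phase,
    correlation, label; every triple gets exactly one label.
    """
    model = trajectory.model
    wue = trajectory.wue_values
    if reaction_ids is None:
        reaction_ids = model.base.reaction_ids
    rows = []
    for rid in reaction_ids:
        for cell in CELLS:
            for p in range(1, 7):
                s = extract_series(trajectory, rid, cell, p)
                c = classify_reaction(s, wue, thresholds, method)
                rows.append((rid, cell, p, c.correlation, c.label))
    return pd.DataFrame(
        rows, columns=["reaction_id", "cell", "phase", "correlation", "label"]
    )


def classification_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a classification table to reactions x (cell, phase) labels."""
    return table.pivot_table(
        index="reaction_id",
        columns=["cell", "phase"],
        values="label",
        aggfunc="first",
    )


# ---------------------------------------------------------------------------
# per-solution profiles
# ---------------------------------------------------------------------------


def enzyme_phase_profile(
    solution,
    model: CombinedDielModel,
    enzyme_ids,
    derived_sums: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-phase, per-cell fluxes of named enzymes plus derived sums.

    Rows ordered phase 1-6; one column per (enzyme or sum, cell).
    """
    derived_sums = derived_sums or {}
    for rid in list(enzyme_ids) + [r for ids in derived_sums.values() for r in ids]:
        if not model.base.has_reaction(rid):
            raise AnalysisError(f"unknown reaction id {rid!r}")
    data: dict[str, list[float]] = {}
    for cell in CELLS:
        for rid in enzyme_ids:
            data[f"{rid}_{cell}"] = [
                solution.fluxes[model.expanded_id(rid, p, cell)] for p in range(1, 7)
            ]
        for name, ids in derived_sums.items():
            data[f"{name}_{cell}"] = [
                sum(solution.fluxes[model.expanded_id(rid, p, cell)] for rid in ids)
                for p in range(1, 7)
            ]
    return pd.DataFrame(data, index=pd.RangeIndex(1, 7, name="phase"))


@dataclass
class StorageReport:
    """Storage and ion diagnostics along the scan (one row per point)."""

    table: pd.DataFrame
    k_uptake_by_phase: pd.DataFrame
    k_release_by_phase: pd.DataFrame


def storage_report(
    trajectory: ScanTrajectory,
    starch_id: str = "starch",
    malate_id: str | None = None,
    k_uptake_id: str = "K_UP",
    k_release_id: str = "K_REL",
) -> StorageReport:
    """Collect the headline storage fluxes per scan point.

    Reports the daytime starch carry-over (phase 3 -> 4) and nighttime
    malate carry-over (phase 6 -> 1) linker amounts in both cells, the
    day/night CO2 intake split, water loss and WUE; plus GC K+ uptake and
    release rates per phase.
    """
    model = trajectory.model
    malate_id = malate_id or model.config.malate_id
    rows = []
    k_up_rows = []
    k_rel_rows = []
    for pt in trajectory.points:
        fx = pt.solution.fluxes
        up = model.co2_uptake_by_phase(fx)
        day = sum(up[p] for p in (1, 2, 3))
        night = sum(up[p] for p in (4, 5, 6))
        rows.append(
            {
                "water_budget": pt.water_budget,
                "water_loss": pt.solution.water_loss_total,
                "wue": pt.solution.wue,
                "starch_P3_to_P4_GC": fx[model.linker_id(starch_id, 3, "GC")],
                "starch_P3_to_P4_MC": fx[model.linker_id(starch_id, 3, "MC")],
                "malate_P6_to_P1_GC": fx[model.linker_id(malate_id, 6, "GC")],
                "malate_P6_to_P1_MC": fx[model.linker_id(malate_id, 6, "MC")],
                "day_co2": day,
                "night_co2": night,
                "night_co2_share": night / (day + night) if day + night > 0 else 0.0,
            }
        )
        if model.base.has_reaction(k_uptake_id):
            k_up_rows.append(
                {f"P{p}": fx[model.expanded_id(k_uptake_id, p, "GC")] for p in range(1, 7)}
            )
            k_rel_rows.append(
                {f"P{p}": fx[model.expanded_id(k_release_id, p, "GC")] for p in range(1, 7)}
            )
    return StorageReport(
        table=pd.DataFrame(rows),
        k_uptake_by_phase=pd.DataFrame(k_up_rows),
        k_release_by_phase=pd.DataFrame(k_rel_rows),
    )


# ---------------------------------------------------------------------------
# invariant diagnostics
# ---------------------------------------------------------------------------


def diel_closure_residuals(model: CombinedDielModel, fluxes) -> dict[tuple[str, str], float]:
    """Net accumulation of each storage pool summed over the cycle.

    Zero (to solver tolerance) at every feasible solution: the cycle is
    closed, start-of-day pools equal end-of-night pools.
    """
    out = {}
    for met in model.config.storage_metabolites:
        for cell in CELLS:
            total = 0.0
            for p in range(1, 7):
                total += (
                    fluxes[model.linker_id(met, p, cell)]
                    - fluxes[model.linker_id(met, prev_phase(p), cell)]
                )
            out[(met, cell)] = total
    return out


def charge_balance_residuals(model: CombinedDielModel, fluxes) -> dict[int, float]:
    """Per GC phase: |z_mal|*d(mal) + |z_cl|*d(Cl) - |z_K|*d(K). Zero when
    the accumulated anion charge balances accumulated K+."""
    cfg = model.config
    z = {
        mid: abs(model.base.metabolite(mid).charge)
        for mid in (cfg.k_id, cfg.cl_id, cfg.malate_id)
    }

    def acc(met, p):
        return fluxes[model.linker_id(met, p, "GC")] - fluxes[
            model.linker_id(met, prev_phase(p), "GC")
        ]

    return {
        p: z[cfg.malate_id] * acc(cfg.malate_id, p)
        + z[cfg.cl_id] * acc(cfg.cl_id, p)
        - z[cfg.k_id] * acc(cfg.k_id, p)
        for p in range(1, 7)
    }


def carbon_balance(model: CombinedDielModel, fluxes, carbon_numbers: dict[str, float]) -> tuple[float, float]:
    """(total CO2 intake, total carbon leaving via phloem), duration-weighted.

    With storage pools closed over the cycle, the two are equal to solver
    tolerance on a carbon-conserving network. ``carbon_numbers`` gives
    carbons per phloem-sink unit, keyed by the cell phloem reaction's
    consumed metabolites.
    """
    co2_in = sum(model.co2_uptake_by_phase(fluxes).values())
    phl = model.base.reaction(model.config.phloem_reaction_id)
    carbons_per_unit = sum(
        -c * carbon_numbers.get(mid, 0.0) for mid, c in phl.stoichiometry.items() if c < 0
    )
    phloem_carbon = model.phloem_total(fluxes) * carbons_per_unit
    return co2_in, phloem_carbon
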