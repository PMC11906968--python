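"""The 2-step LP solver and the water-loss-reduction (C3 -> CAM) scan.

Step 1 optimizes the primary objective (phloem output by default, at its
fixed phase-uniform demand). Step 2 fixes that optimum and minimizes the
L1 norm of the enzymatic/transport fluxes (parsimonious FBA), yielding a
unique representative flux distribution. The scan then tightens a total
diel water-loss budget from the C3 reference value downwards; the last
feasible budget (refined by bisection) is the CAM endpoint.

The parsimony norm runs over the per-phase per-cell network copies plus
the GC-MC sucrose transfer path; storage linkers and the accounting
pseudo-reactions (stomatal intake, phloem drain, water tally) are
excluded, so parsimony expresses enzyme usage, not water accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cobra.util.solver import fix_objective_as_constraint

from .assembly import CombinedDielModel

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class ScanError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """One solved state of the combined model."""

    status: str
    fluxes: dict[str, float] | None = None
    objective_value: float | None = None
    objective_step1: float | None = None
    water_loss_total: float | None = None
    phloem_total: float | None = None
    wue: float | None = None
    water_budget: float | None = None
    diagnostic: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class ScanConfig:
    """Scan schedule and solver options."""

    objective_id: str | dict[str, float] | None = None  # default: phloem output
    n_steps: int = 50
    step_mode: str = "linear"  # or "geometric"
    stop_on_infeasible: bool = True
    pfba: bool = True
    pool_weight: float = 0.01
    solver_tolerance: float = 1e-9
    bisection_rel_tol: float = 1e-7
    geometric_floor: float = 0.01  # fraction of start budget for geometric mode

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ScanError("n_steps must be >= 2")
        if self.step_mode not in ("linear", "geometric"):
            raise ScanError(f"unknown step_mode {self.step_mode!r}")


@dataclass
class ScanPoint:
    water_budget: float
    solution: FluxSolution


@dataclass
class ScanTrajectory:
    """Ordered scan records; budgets strictly decreasing."""

    points: list[ScanPoint]
    c3_reference: FluxSolution
    model: CombinedDielModel

    def __post_init__(self) -> None:
        budgets = self.budgets
        for a, b in zip(budgets, budgets[1:]):
            if not b < a:
                raise ScanError("water budgets must be strictly decreasing")

    @property
    def budgets(self) -> list[float]:
        return [pt.water_budget for pt in self.points]

    @property
    def solutions(self) -> list[FluxSolution]:
        return [pt.solution for pt in self.points]

    @property
    def cam_endpoint(self) -> FluxSolution:
        if not self.points:
            raise ScanError("empty trajectory")
        return self.points[-1].solution

    @property
    def wue_values(self) -> list[float]:
        return [pt.solution.wue for pt in self.points]

    def series(self, expanded_id: str) -> list[float]:
        return [pt.solution.fluxes[expanded_id] for pt in self.points]


# ---------------------------------------------------------------------------
# 2-step solver
# ---------------------------------------------------------------------------


def _objective_dict(model: CombinedDielModel, objective) -> dict[str, float]:
    if objective is None:
        return model.phloem_objective()
    if isinstance(objective, str):
        return {objective: 1.0}
    return dict(objective)


def _parsimony_expression(model: CombinedDielModel, pool_weight: float = 0.0):
    """Duration-weighted L1 norm of the enzymatic/transport fluxes.

    Each per-phase per-cell flux (a rate) is weighted by its phase's
    duration, so the norm measures total catalytic turnover over the diel
    cycle (a flux amount). Without the weighting, work scheduled into the
    two 10-hour phases would look ten times cheaper per unit of chemistry
    than work in the 1-hour transition phases, and the solver would invert
    the day/night schedule for bookkeeping reasons alone.

    The light-capture chain is included at full weight: photosystems and
    electron transport are protein machinery like any enzyme, and pricing
    photon-derived ATP/NADPH is what keeps energetically wasteful
    decarboxylation routes (oxidize the acid, refix every carbon) more
    expensive than the PEPCK/malic-enzyme shuttle. ``pool_weight`` adds a
    small cost per unit of storage-pool carry-over (the linker amounts):
    holding pools is not free, so at equal enzyme usage the parsimonious
    solution empties stores as early as possible — the morning
    decarboxylation burst — rather than carrying them arbitrarily far
    through the cycle.
    """
    durations = {p.index: p.duration_h for p in model.phases}
    weighted: list[tuple[str, float]] = [
        (rid, durations[phase]) for (base, phase, _), rid in model.tag_map.items()
    ]
    for ids in (model.sucrose_transfer_ids, model.sucrose_import_ids):
        weighted.extend((rid, durations[p]) for p, rid in ids.items())
    terms = []
    for rid, w in weighted:
        rxn = model.cmodel.reactions.get_by_id(rid)
        terms.append(w * rxn.forward_variable)
        terms.append(w * rxn.reverse_variable)
    expr = sum(terms)
    if pool_weight:
        pool_terms = []
        for link in model.linkers:
            rxn = model.cmodel.reactions.get_by_id(link.reaction_id)
            pool_terms.append(rxn.forward_variable)
        expr = expr + pool_weight * sum(pool_terms)
    return expr


def solve_two_step(
    model: CombinedDielModel,
    objective: str | dict[str, float] | None = None,
    config: ScanConfig | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Optimize the objective, then minimize total enzymatic flux at the optimum."""
    config = config or ScanConfig()
    obj = _objective_dict(model, objective if objective is not None else config.objective_id)
    cm = model.cmodel
    with cm:
        cm.objective = {cm.reactions.get_by_id(r): c for r, c in obj.items()}
        cm.objective_direction = direction
        cm.slim_optimize()
        status = cm.solver.status
        if status == INFEASIBLE:
            return FluxSolution(status=INFEASIBLE, diagnostic="step-1 LP infeasible")
        if status != OPTIMAL:
            loose = [
                r.id
                for r in cm.reactions
                if abs(r.lower_bound) >= 1e9 or abs(r.upper_bound) >= 1e9
            ]
            return FluxSolution(
                status=UNBOUNDED if status == UNBOUNDED else status,
                diagnostic=(
                    f"step-1 LP status {status}; candidate unbounded-ray members "
                    f"(reactions with ~infinite bounds): {loose[:10]}"
                ),
            )
        obj1 = cm.solver.objective.value

        if config.pfba:
            fix_objective_as_constraint(cm, fraction=1.0)
            cm.objective = cm.problem.Objective(
                _parsimony_expression(model, config.pool_weight), direction="min"
            )
            cm.slim_optimize()
            if cm.solver.status != OPTIMAL:  # pragma: no cover - should not happen
                return FluxSolution(
                    status=cm.solver.status,
                    diagnostic="step-2 parsimony LP failed at fixed optimum",
                )
        fluxes = {r.id: r.flux for r in cm.reactions}

    achieved = sum(c * fluxes[r] for r, c in obj.items())
    water = fluxes[model.water_tally_id] if model.water_tally_id else None
    phloem = model.phloem_total(fluxes)
    wue = phloem / water if water else None
    return FluxSolution(
        status=OPTIMAL,
        fluxes=fluxes,
        objective_value=achieved,
        objective_step1=obj1,
        water_loss_total=water,
        phloem_total=phloem,
        wue=wue,
    )


# ---------------------------------------------------------------------------
# C3 reference
# ---------------------------------------------------------------------------

DEFAULT_C3_CONSTRAINTS = {"night_co2_zero": True, "bounds": {}}


def c3_reference_solution(
    model: CombinedDielModel,
    c3_constraints: dict | None = None,
    config: ScanConfig | None = None,
) -> FluxSolution:
    """Maximize WUE under C3 constraints.

    With phloem output fixed, maximizing WUE is minimizing total diel water
    loss; C3 constraints bound nighttime stomatal CO2 intake to zero (plus
    any user-supplied reaction bounds). The solution's water loss is the
    scan's starting budget.
    """
    if model.water_tally_id is None:
        raise ScanError("water coupling not attached; call attach_water_coupling first")
    cons = dict(DEFAULT_C3_CONSTRAINTS, **(c3_constraints or {}))
    cm = model.cmodel
    with cm:
        if cons.get("night_co2_zero", True):
            for p in model.phases:
                if not p.is_light:
                    cm.reactions.get_by_id(model.stomatal_co2_ids[p.index]).upper_bound = 0.0
        for rid, (lb, ub) in cons.get("bounds", {}).items():
            rxn = cm.reactions.get_by_id(rid)
            rxn.bounds = (lb, ub)
        sol = solve_two_step(model, objective=model.water_tally_id, config=config, direction="min")
    if not sol.optimal:
        sol.diagnostic = (
            "C3-constrained model infeasible: phloem demand cannot be met with "
            "daytime-only CO2 uptake. " + sol.diagnostic
        )
    return sol


# ---------------------------------------------------------------------------
# water-loss scan
# ---------------------------------------------------------------------------


def _budget_schedule(start: float, config: ScanConfig) -> list[float]:
    n = config.n_steps
    if config.step_mode == "linear":
        return [start * (1.0 - k / n) for k in range(n)]
    r = config.geometric_floor ** (1.0 / (n - 1))
    return [start * r**k for k in range(n)]


def _feasible_at(model: CombinedDielModel, budget: float) -> bool:
    cm = model.cmodel
    with cm:
        cm.reactions.get_by_id(model.water_tally_id).upper_bound = budget
        cm.objective = {
            cm.reactions.get_by_id(r): c for r, c in model.phloem_objective().items()
        }
        cm.objective_direction = "max"
        cm.slim_optimize()
        return cm.solver.status == OPTIMAL


def _solve_at(model: CombinedDielModel, budget: float, config: ScanConfig) -> FluxSolution:
    cm = model.cmodel
    with cm:
        cm.reactions.get_by_id(model.water_tally_id).upper_bound = budget
        sol = solve_two_step(model, config=config, direction="max")
    sol.water_budget = budget
    return sol


def run_water_scan(
    model: CombinedDielModel,
    config: ScanConfig | None = None,
    start_budget: float | None = None,
    c3_reference: FluxSolution | None = None,
) -> ScanTrajectory:
    """Trace the C3 -> CAM transition by tightening the water budget.

    Budgets decrease from the C3 reference water loss; each point is solved
    with the 2-step method under ``W_total <= budget``. The scan stops at
    the first infeasible budget and bisects the feasibility boundary to
    ``config.bisection_rel_tol``; the last recorded point is the CAM
    endpoint.
    """
    config = config or ScanConfig()
    if model.water_tally_id is None:
        raise ScanError("water coupling not attached; call attach_water_coupling first")
    if c3_reference is None:
        c3_reference = c3_reference_solution(model, config=config)
    if not c3_reference.optimal:
        raise ScanError("C3 reference solution is not optimal: " + c3_reference.diagnostic)
    if start_budget is None:
        start_budget = c3_reference.water_loss_total

    # the C3 reference is the trajectory's starting point: the state whose
    # water loss defines the first budget. Free scan points follow at
    # strictly smaller budgets.
    c3_reference.water_budget = start_budget
    points: list[ScanPoint] = [ScanPoint(start_budget, c3_reference)]
    budgets = [b for b in _budget_schedule(start_budget, config) if b < start_budget]
    first_infeasible: float | None = None
    free_points = 0
    for budget in budgets:
        sol = _solve_at(model, budget, config)
        if not sol.optimal:
            if free_points == 0:
                raise ScanError(
                    f"C3 reference violated: starting budget {budget:g} is infeasible"
                )
            first_infeasible = budget
            if config.stop_on_infeasible:
                break
            continue
        free_points += 1
        points.append(ScanPoint(budget, sol))
        logger.info(
            "scan: budget=%.6g water=%.6g objective=%.6g",
            budget,
            sol.water_loss_total,
            sol.objective_value,
        )
    if not points:
        raise ScanError("no feasible scan points")

    # bisection refinement of the feasibility boundary
    hi = points[-1].water_budget
    lo = first_infeasible if first_infeasible is not None else 0.0
    while hi - lo > config.bisection_rel_tol * max(hi, 1e-12):
        mid = 0.5 * (hi + lo)
        if _feasible_at(model, mid):
            hi = mid
        else:
            lo = mid
    if hi < points[-1].water_budget:
        # solve at the refined boundary; nudge upward if the marginal LP
        # is rejected at the solver's tighter two-step tolerances
        endpoint = None
        budget = hi
        eps = 10.0 * config.bisection_rel_tol
        for _ in range(8):
            cand = _solve_at(model, budget, config)
            if cand.optimal:
                endpoint = cand
                break
            budget = min(points[-1].water_budget, hi * (1.0 + eps))
            eps *= 10.0
        if endpoint is not None and budget < points[-1].water_budget:
            points.append(ScanPoint(budget, endpoint))

    return ScanTrajectory(points=points, c3_reference=c3_reference, model=model)


def minimum_water_oracle(model: CombinedDielModel, pfba: bool = False) -> FluxSolution:
    """Direct LP: minimize W_total at the fixed phloem output, no budget.

    Independent route to the CAM endpoint's water loss, used to
    cross-check the scan's bisection boundary.
    """
    return solve_two_step(
        model,
        objective=model.water_tally_id,
        config=ScanConfig(pfba=pfba),
        direction="min",
    )


# ---------------------------------------------------------------------------
# malate-charge-fraction sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepRecord:
    fraction: float
    error: str | None = None
    c3_water_loss: float | None = None
    day_pepc_gc: float | None = None
    day_pepc_mc: float | None = None
    mc_exceeds_gc: bool | None = None
    cam_water_loss: float | None = None


def daytime_flux(
    model: CombinedDielModel, fluxes, rid: str, cell: str, leaf_scale: bool = False
) -> float:
    """Duration-weighted flux of a reaction summed over the light phases.

    With ``leaf_scale`` the MC flux is multiplied by the MC:GC cell-number
    ratio — the leaf-area basis on which the coupled model's activities are
    reported and compared across cell types.
    """
    scale = model.config.n_mc_per_gc if (leaf_scale and cell == "MC") else 1.0
    return scale * sum(
        fluxes[model.expanded_id(rid, p.index, cell)] * p.duration_h
        for p in model.phases
        if p.is_light
    )


def malate_fraction_sweep(
    model_builder,
    fractions,
    pepc_id: str = "PEPC",
    run_scan: bool = False,
    scan_config: ScanConfig | None = None,
) -> dict[float, SweepRecord]:
    """Re-run the C3 reference (and optionally the scan) per malate fraction.

    ``model_builder(fraction)`` must return a fully assembled model with
    the charge constraint at that fraction. Reports whether daytime PEPC
    flux in MC exceeds GC (per-cell basis) in the C3 state — the
    plausibility flag that bounds the admissible fraction range from below.
    Build failures are recorded per fraction; the sweep continues.
    """
    out: dict[float, SweepRecord] = {}
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            out[f] = SweepRecord(fraction=f, error=f"fraction {f} outside [0, 1]")
            continue
        try:
            model = model_builder(f)
            c3 = c3_reference_solution(model, config=scan_config)
            if not c3.optimal:
                out[f] = SweepRecord(fraction=f, error="C3 reference infeasible")
                continue
            gc = daytime_flux(model, c3.fluxes, pepc_id, "GC", leaf_scale=True)
            mc = daytime_flux(model, c3.fluxes, pepc_id, "MC", leaf_scale=True)
            rec = SweepRecord(
                fraction=f,
                c3_water_loss=c3.water_loss_total,
                day_pepc_gc=gc,
                day_pepc_mc=mc,
                mc_exceeds_gc=mc > gc + 1e-9,
            )
            if run_scan:
                traj = run_water_scan(model, config=scan_config, c3_reference=c3)
                rec.cam_water_loss = traj.cam_endpoint.water_loss_total
            out[f] = rec
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            out[f] = SweepRecord(fraction=f, error=str(exc))
    return out


def find_flip_fraction(
    model_builder,
    lo: float = 0.0,
    hi: float = 1.0,
    tol: float = 0.01,
    pepc_id: str = "PEPC",
) -> float:
    """Bisection for the malate fraction below which daytime MC PEPC
    exceeds GC PEPC in the C3 solution. Returns the boundary fraction."""

    def flag(f: float) -> bool:
        model = model_builder(f)
        c3 = c3_reference_solution(model)
        if not c3.optimal:
            raise ScanError(f"C3 reference infeasible at fraction {f}")
        return daytime_flux(model, c3.fluxes, pepc_id, "MC", leaf_scale=True) > (
            daytime_flux(model, c3.fluxes, pepc_id, "GC", leaf_scale=True) + 1e-9
        )

    if flag(hi):
        return hi  # flipped everywhere in range
    if not flag(lo):
        return lo  # never flipped
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flag(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
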