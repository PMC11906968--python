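"""Assembly of the combined 6-phase guard-cell / mesophyll diel model.

A single-cell network is replicated per diel phase (dawn, mid-day,
afternoon, dusk, midnight, end of night) and per cell type (GC, MC),
then coupled by

* cyclic storage *linker* pseudo-reactions that carry starch, malate,
  sucrose and ions from each phase to the next (phase 6 wraps to 1),
* a shared per-phase atmospheric CO2 pool filled by a stomatal intake
  reaction and drawn on by both cell types (MC contributions scaled by
  the number of MCs per GC),
* a sucrose transfer path MC -> apoplast -> GC (the MC supplies one of
  the GC osmolytes),
* a shared phloem sink at a fixed, phase-uniform output rate.

Fluxes are rates (µmol·m⁻²·s⁻¹); linker variables are amounts
(µmol·m⁻²). A linker out of phase p has stoichiometric coefficient
-1/duration(p) on the phase-p species and +1/duration(p+1) on the
phase-(p+1) species, so each phase's steady-state row stays in rate units
while unequal phase lengths conserve mass over the cycle.

Guard-cell ionic balance and stomatal opening are added by
:func:`add_osmolyte_charge_constraint` and
:func:`add_osmotic_opening_constraint`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import cobra

from .network import MetabolicNetwork

logger = logging.getLogger(__name__)

CELLS = ("GC", "MC")
_BIG = 1e9

PHASE_NAMES = ("dawn", "midday", "afternoon", "dusk", "midnight", "end_of_night")


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class DielPhase:
    """One of the six blocks tiling the 24-h cycle."""

    index: int
    name: str
    start_h: float
    end_h: float
    is_light: bool

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 6:
            raise AssemblyError(f"phase index {self.index} outside 1-6")
        if self.duration_h <= 0:
            raise AssemblyError(f"phase {self.index}: non-positive duration")


def default_phases() -> list[DielPhase]:
    """The canonical schedule: dawn 0-1 h, mid-day 1-11, afternoon 11-12,
    dusk 12-13, midnight 13-23, end of night 23-24."""
    bounds = [(0, 1), (1, 11), (11, 12), (12, 13), (13, 23), (23, 24)]
    return [
        DielPhase(i + 1, PHASE_NAMES[i], s, e, is_light=i < 3)
        for i, (s, e) in enumerate(bounds)
    ]


def validate_phases(phases: list[DielPhase]) -> None:
    if len(phases) != 6:
        raise AssemblyError(f"need exactly 6 phases, got {len(phases)}")
    if [p.index for p in phases] != [1, 2, 3, 4, 5, 6]:
        raise AssemblyError("phases must be ordered with indices 1-6")
    t = 0.0
    for p in phases:
        if abs(p.start_h - t) > 1e-9:
            raise AssemblyError(f"phases do not tile [0, 24]: gap/overlap at {p.start_h} h")
        t = p.end_h
    if abs(t - 24.0) > 1e-9:
        raise AssemblyError(f"phases end at {t} h, not 24 h")
    for p in phases:
        if p.is_light != (p.index <= 3):
            raise AssemblyError("phases 1-3 must be light, 4-6 dark")


def next_phase(p: int) -> int:
    return p % 6 + 1


def prev_phase(p: int) -> int:
    return (p - 2) % 6 + 1


@dataclass
class ApertureParams:
    """Affine stomatal conductance law g(p) = g_min + slope * S(p).

    S(p) is the guard-cell osmotic content carried out of phase p:
    potassium-salt pairs count 2 per K+ (cation + counter-anion), sucrose
    counts 1 per molecule. g bounds the phase's stomatal CO2 intake and is
    capped at g_max.
    """

    g_min: float = 0.0
    slope: float = 1.0
    g_max: float = 1.5


@dataclass
class AssemblyConfig:
    """Parameters of the combined-model construction.

    ``n_mc_per_gc`` scales every MC contribution to shared pools (a leaf
    carries roughly 270-400 mesophyll cells per guard cell; 300 is the
    intermediate default). ``malate_charge_fraction`` is the share of the
    negative charge balancing K+ provided by malate (charge -2); the rest
    is Cl-. ``phloem_demand`` is the fixed phase-uniform phloem output rate
    of the whole 1 GC + n MC system.
    """

    n_mc_per_gc: int = 300
    malate_charge_fraction: float = 0.90
    storage_metabolites: tuple[str, ...] = ("starch", "mal", "suc", "k", "cl")
    phloem_reaction_id: str = "PHLOEM"
    co2_uptake_id: str = "CO2_UP"
    light_uptake_id: str = "PHOTON_UP"
    light_cap: float = 80.0
    # light-capture pseudo-machinery: dark-gated and excluded from the
    # parsimony norm (photon flux is not an enzyme-usage cost)
    light_reaction_ids: tuple[str, ...] = ("PHOTON_UP", "ATP_LIGHT", "NADPH_LIGHT")
    linker_caps: dict[str, float] = field(
        default_factory=lambda: {"suc:GC": 0.5, "suc:MC": 5e-4}
    )
    maintenance_reaction_id: str = "MAINT"
    maintenance_cost: float = 0.01
    maintenance_costs: dict[int, float] = field(default_factory=dict)
    k_id: str = "k"
    cl_id: str = "cl"
    malate_id: str = "mal"
    sucrose_id: str = "suc"
    phloem_demand: float = 0.05
    aperture: ApertureParams = field(default_factory=ApertureParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.malate_charge_fraction <= 1.0:
            raise AssemblyError(
                f"malate_charge_fraction {self.malate_charge_fraction} outside [0, 1]"
            )
        if self.n_mc_per_gc < 1:
            raise AssemblyError("n_mc_per_gc must be >= 1")
        if not 270 <= self.n_mc_per_gc <= 400:
            logger.warning(
                "n_mc_per_gc=%d outside the typical 270-400 leaf anatomy range",
                self.n_mc_per_gc,
            )
        for ion in (self.k_id, self.cl_id, self.malate_id, self.sucrose_id):
            if ion not in self.storage_metabolites:
                raise AssemblyError(
                    f"storage_metabolites must include {ion!r} "
                    "(required by the osmolyte constraints)"
                )

    def maintenance_for(self, phase: int) -> float:
        return self.maintenance_costs.get(phase, self.maintenance_cost)


@dataclass(frozen=True)
class LinkerReaction:
    """Record of one storage linker pseudo-reaction."""

    metabolite_id: str
    from_phase: int
    to_phase: int
    cell_type: str
    reaction_id: str


def tag(rid: str, phase: int, cell: str) -> str:
    return f"{rid}_P{phase}_{cell}"


@dataclass
class CombinedDielModel:
    """The assembled 6-phase x 2-cell LP model.

    ``cmodel`` is the backing :class:`cobra.Model`; ``tag_map`` maps
    (original reaction id, phase, cell) to the expanded reaction id and is
    a bijection onto the per-phase per-cell network copies (linkers and
    coupling pseudo-reactions are registered separately).
    """

    base: MetabolicNetwork
    cmodel: cobra.Model
    phases: list[DielPhase]
    config: AssemblyConfig
    tag_map: dict[tuple[str, int, str], str] = field(default_factory=dict)
    linkers: list[LinkerReaction] = field(default_factory=list)
    linker_ids: dict[tuple[str, int, str], str] = field(default_factory=dict)
    stomatal_co2_ids: dict[int, str] = field(default_factory=dict)
    light_intake_ids: dict[int, str] = field(default_factory=dict)
    phloem_export_ids: dict[int, str] = field(default_factory=dict)
    sucrose_transfer_ids: dict[int, str] = field(default_factory=dict)
    sucrose_import_ids: dict[int, str] = field(default_factory=dict)
    water_tally_id: str | None = None
    water_coefficients: dict[int, float] = field(default_factory=dict)
    environment = None
    gas_params = None
    charge_fraction: float | None = None
    aperture: ApertureParams | None = None

    # -- lookups ---------------------------------------------------------

    def phase(self, index: int) -> DielPhase:
        return self.phases[index - 1]

    def expanded_id(self, rid: str, phase: int, cell: str) -> str:
        key = (rid, phase, cell)
        if key not in self.tag_map:
            raise KeyError(f"no expanded copy of reaction {rid!r} in phase {phase}, {cell}")
        return self.tag_map[key]

    def linker_id(self, met_id: str, from_phase: int, cell: str) -> str:
        key = (met_id, from_phase, cell)
        if key not in self.linker_ids:
            raise KeyError(f"no {met_id!r} linker out of phase {from_phase} in {cell}")
        return self.linker_ids[key]

    def _flux_expr(self, rid: str):
        return self.cmodel.reactions.get_by_id(rid).flux_expression

    def linker_expr(self, met_id: str, from_phase: int, cell: str):
        return self._flux_expr(self.linker_id(met_id, from_phase, cell))

    def accumulation_expr(self, met_id: str, phase: int, cell: str):
        """Net accumulation of a storage pool during ``phase`` (amount)."""
        return self.linker_expr(met_id, phase, cell) - self.linker_expr(
            met_id, prev_phase(phase), cell
        )

    def phloem_objective(self) -> dict[str, float]:
        """Duration-weighted total phloem output, as an objective dict."""
        return {
            self.phloem_export_ids[p.index]: p.duration_h for p in self.phases
        }

    # -- solution-level helpers -------------------------------------------

    def phloem_total(self, fluxes) -> float:
        return sum(
            fluxes[self.phloem_export_ids[p.index]] * p.duration_h for p in self.phases
        )

    def co2_uptake_by_phase(self, fluxes) -> dict[int, float]:
        """Duration-weighted stomatal CO2 intake per phase (amounts)."""
        return {
            p.index: fluxes[self.stomatal_co2_ids[p.index]] * p.duration_h
            for p in self.phases
        }

    def night_co2_share(self, fluxes) -> float:
        up = self.co2_uptake_by_phase(fluxes)
        total = sum(up.values())
        if total <= 0:
            return 0.0
        return sum(up[p] for p in (4, 5, 6)) / total


def build_combined_model(
    cell_net: MetabolicNetwork,
    phases: list[DielPhase] | None = None,
    config: AssemblyConfig | None = None,
) -> CombinedDielModel:
    """Replicate ``cell_net`` into the coupled 6-phase GC+MC model."""
    from .io import to_cobra  # local import to avoid cycle

    phases = phases or default_phases()
    config = config or AssemblyConfig()
    validate_phases(phases)
    cell_net.validate()

    for met in config.storage_metabolites:
        if not cell_net.has_metabolite(met):
            raise AssemblyError(f"storage metabolite {met!r} missing from cell network")
    required = [config.co2_uptake_id, config.phloem_reaction_id]
    if config.light_uptake_id:
        required.append(config.light_uptake_id)
    for rid in required:
        if not cell_net.has_reaction(rid):
            raise AssemblyError(f"required reaction {rid!r} missing from cell network")

    base_cobra = to_cobra(cell_net)  # validates convertibility
    del base_cobra

    cm = cobra.Model("combined_diel")
    try:  # tight primal tolerance: the scan's bisection probes marginal LPs
        cm.solver.configuration.tolerances.feasibility = 1e-9
    except Exception:  # pragma: no cover - solver without tunable tolerances
        logger.warning("could not tighten solver feasibility tolerance")
    n_mc = float(config.n_mc_per_gc)
    mets: dict[str, cobra.Metabolite] = {}

    def add_met(mid: str, compartment: str) -> cobra.Metabolite:
        m = cobra.Metabolite(mid, name=mid, compartment=compartment)
        mets[mid] = m
        return m

    # shared per-phase species
    for p in phases:
        add_met(f"co2_ext_P{p.index}", "extracellular")
        add_met(f"suc_apo_P{p.index}", "extracellular")
        add_met(f"phloem_P{p.index}", "extracellular")
        if config.light_uptake_id:
            add_met(f"photon_ext_P{p.index}", "extracellular")

    # per-phase per-cell species
    for p in phases:
        for cell in CELLS:
            for m in cell_net.metabolites:
                add_met(f"{m.id}_P{p.index}_{cell}", m.compartment)
    cm.add_metabolites(list(mets.values()))

    model = CombinedDielModel(base=cell_net, cmodel=cm, phases=phases, config=config)

    new_rxns: list[tuple[cobra.Reaction, dict[str, float]]] = []

    def queue(rid, name, stoich, lb, ub):
        r = cobra.Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
        new_rxns.append((r, stoich))
        return r

    # shared coupling reactions
    for p in phases:
        i = p.index
        rid = f"CO2_STOMATA_P{i}"
        queue(rid, f"stomatal CO2 intake, phase {i}", {f"co2_ext_P{i}": 1.0}, 0.0, _BIG)
        model.stomatal_co2_ids[i] = rid

        rid = f"EX_PHLOEM_P{i}"
        queue(
            rid,
            f"phloem output, phase {i}",
            {f"phloem_P{i}": -1.0},
            config.phloem_demand,
            config.phloem_demand,
        )
        model.phloem_export_ids[i] = rid

        rid = f"SUC_TRANSFER_P{i}"
        queue(
            rid,
            f"sucrose export MC->apoplast, phase {i}",
            {f"suc_P{i}_MC": -1.0, f"suc_apo_P{i}": n_mc},
            0.0,
            _BIG,
        )
        model.sucrose_transfer_ids[i] = rid

        rid = f"SUC_IMPORT_P{i}"
        queue(
            rid,
            f"sucrose import apoplast->GC, phase {i}",
            {f"suc_apo_P{i}": -1.0, f"suc_P{i}_GC": 1.0},
            0.0,
            _BIG,
        )
        model.sucrose_import_ids[i] = rid

        if config.light_uptake_id:
            rid = f"LIGHT_P{i}"
            queue(
                rid,
                f"incident light, phase {i}",
                {f"photon_ext_P{i}": 1.0},
                0.0,
                config.light_cap if p.is_light else 0.0,
            )
            model.light_intake_ids[i] = rid

    # per-phase per-cell network copies
    for p in phases:
        i = p.index
        for cell in CELLS:
            scale = 1.0 if cell == "GC" else n_mc
            for r in cell_net.reactions:
                rid = tag(r.id, i, cell)
                lb, ub = r.lower_bound, r.upper_bound
                if r.id in config.light_reaction_ids and not p.is_light:
                    ub = 0.0
                    lb = min(lb, 0.0) if lb > 0 else lb
                if r.id == config.maintenance_reaction_id:
                    lb = config.maintenance_for(i)
                stoich = {
                    f"{mid}_P{i}_{cell}": coeff for mid, coeff in r.stoichiometry.items()
                }
                if r.id == config.co2_uptake_id:
                    # rewire atmospheric intake to the shared phase pool
                    stoich = {
                        f"co2_ext_P{i}": -scale,
                        f"{_produced_species(cell_net, r.id)}_P{i}_{cell}": 1.0,
                    }
                if config.light_uptake_id and r.id == config.light_uptake_id:
                    stoich = {
                        f"photon_ext_P{i}": -scale,
                        f"{_produced_species(cell_net, r.id)}_P{i}_{cell}": 1.0,
                    }
                if r.id == config.phloem_reaction_id:
                    stoich[f"phloem_P{i}"] = scale
                queue(rid, f"{r.name or r.id} [P{i} {cell}]", stoich, lb, ub)
                model.tag_map[(r.id, i, cell)] = rid

    # storage linkers (cyclic, amounts; 1/duration coefficients keep rows in rates)
    for met in config.storage_metabolites:
        for cell in CELLS:
            for p in phases:
                i = p.index
                j = next_phase(i)
                dur_to = model.phase(j).duration_h
                rid = f"LINK_{met}_P{i}to{j}_{cell}"
                queue(
                    rid,
                    f"{met} carry-over P{i}->P{j} [{cell}]",
                    {
                        f"{met}_P{i}_{cell}": -1.0 / p.duration_h,
                        f"{met}_P{j}_{cell}": 1.0 / dur_to,
                    },
                    0.0,
                    config.linker_caps.get(
                        f"{met}:{cell}", config.linker_caps.get(met, _BIG)
                    ),
                )
                model.linkers.append(LinkerReaction(met, i, j, cell, rid))
                model.linker_ids[(met, i, cell)] = rid

    cm.add_reactions([r for r, _ in new_rxns])
    for r, stoich in new_rxns:
        r.add_metabolites({mets[mid]: c for mid, c in stoich.items()})

    cm.objective = {
        cm.reactions.get_by_id(rid): c for rid, c in model.phloem_objective().items()
    }
    cm.objective_direction = "max"
    return model


def _produced_species(cell_net: MetabolicNetwork, rid: str) -> str:
    """The single species produced by a boundary intake reaction."""
    r = cell_net.reaction(rid)
    produced = [m for m, c in r.stoichiometry.items() if c > 0]
    if len(produced) != 1:
        raise AssemblyError(
            f"intake reaction {rid!r} must produce exactly one species, found {produced}"
        )
    return produced[0]


# ---------------------------------------------------------------------------
# guard-cell constraints
# ---------------------------------------------------------------------------


def add_osmolyte_charge_constraint(model: CombinedDielModel, f_mal: float | None = None) -> CombinedDielModel:
    """Tie guard-cell malate and Cl- accumulation to K+ accumulation.

    Per GC phase, with z the absolute ionic charges,

        z_mal * d(malate) = f_mal * d(K+)      (malate's charge share)
        z_cl  * d(Cl-)    = (1 - f_mal) * d(K+)

    where d() is the net pool accumulation over that phase. Summed, the
    accumulated negative charge balances the accumulated K+ charge exactly.
    """
    cfg = model.config
    if f_mal is None:
        f_mal = cfg.malate_charge_fraction
    if not 0.0 <= f_mal <= 1.0:
        raise AssemblyError(f"malate charge fraction {f_mal} outside [0, 1]")
    if model.charge_fraction is not None:
        raise AssemblyError("osmolyte charge constraint already attached")

    charges = {}
    for mid in (cfg.k_id, cfg.cl_id, cfg.malate_id):
        if not model.base.has_metabolite(mid):
            raise AssemblyError(f"ion species {mid!r} missing from cell network")
        z = model.base.metabolite(mid).charge
        if z == 0:
            raise AssemblyError(f"ion species {mid!r} must carry a nonzero charge")
        charges[mid] = abs(z)

    cons = []
    Constraint = model.cmodel.problem.Constraint
    for p in model.phases:
        i = p.index
        d_k = model.accumulation_expr(cfg.k_id, i, "GC")
        d_mal = model.accumulation_expr(cfg.malate_id, i, "GC")
        d_cl = model.accumulation_expr(cfg.cl_id, i, "GC")
        cons.append(
            Constraint(
                charges[cfg.malate_id] * d_mal - f_mal * charges[cfg.k_id] * d_k,
                lb=0.0,
                ub=0.0,
                name=f"charge_malate_P{i}",
            )
        )
        cons.append(
            Constraint(
                charges[cfg.cl_id] * d_cl - (1.0 - f_mal) * charges[cfg.k_id] * d_k,
                lb=0.0,
                ub=0.0,
                name=f"charge_cl_P{i}",
            )
        )
    model.cmodel.add_cons_vars(cons)
    model.charge_fraction = f_mal
    return model


def add_osmotic_opening_constraint(
    model: CombinedDielModel, aperture: ApertureParams | None = None
) -> CombinedDielModel:
    """Bound each phase's stomatal CO2 intake by guard-cell osmotic content.

    v_stomata(p) <= g_min + slope * S(p), with the osmotic content
    S(p) = 2 * K_pool_out(p) + sucrose_pool_out(p) (GC linkers). The MC->GC
    sucrose path must exist (the MC supplies sucrose, one of the osmolytes).
    """
    cfg = model.config
    aperture = aperture or cfg.aperture
    if model.aperture is not None:
        raise AssemblyError("osmotic opening constraint already attached")
    if not model.sucrose_transfer_ids or not model.sucrose_import_ids:
        raise AssemblyError(
            "missing MC->GC sucrose transfer (MC supplies sucrose, one of the osmolytes)"
        )

    cons = []
    Constraint = model.cmodel.problem.Constraint
    for p in model.phases:
        i = p.index
        osmotic = 2.0 * model.linker_expr(cfg.k_id, i, "GC") + model.linker_expr(
            cfg.sucrose_id, i, "GC"
        )
        v_sto = model._flux_expr(model.stomatal_co2_ids[i])
        cons.append(
            Constraint(
                v_sto - aperture.slope * osmotic,
                ub=aperture.g_min,
                name=f"aperture_P{i}",
            )
        )
        model.cmodel.reactions.get_by_id(model.stomatal_co2_ids[i]).upper_bound = (
            aperture.g_max
        )
    model.cmodel.add_cons_vars(cons)
    model.aperture = aperture
    return model


def assemble(
    cell_net: MetabolicNetwork,
    env,
    phases: list[DielPhase] | None = None,
    config: AssemblyConfig | None = None,
    gas_params=None,
) -> CombinedDielModel:
    """One-call assembly: build + charge balance + aperture + water coupling."""
    from .gas import attach_water_coupling

    model = build_combined_model(cell_net, phases, config)
    add_osmolyte_charge_constraint(model)
    add_osmotic_opening_constraint(model)
    attach_water_coupling(model, env, gas_params)
    return model
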