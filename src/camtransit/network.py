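"""Lightweight stoichiometric-network containers.

A :class:`MetabolicNetwork` describes a single cell type (one set of
metabolites and reactions with flux bounds). It is deliberately minimal:
richer constraint-based functionality lives in the assembled diel model,
which is backed by a :class:`cobra.Model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

DEFAULT_LOWER = -1000.0
DEFAULT_UPPER = 1000.0

#: compartments understood out of the box; the field is extensible.
KNOWN_COMPARTMENTS = (
    "cytosol",
    "chloroplast",
    "mitochondrion",
    "vacuole",
    "extracellular",
)


class NetworkError(ValueError):
    """Structural problem in a metabolic network definition."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``charge`` is the elementary charge used by the guard-cell
    charge-balance constraint (only K+, Cl-, malate and sucrose strictly
    need correct values). ``is_storage`` marks species eligible for
    phase-to-phase linker transfer in the diel assembly.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    charge: int = 0
    is_storage: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A reaction with stoichiometry and flux bounds.

    Stoichiometry maps metabolite id to a signed coefficient (negative =
    consumed). Fluxes are on a leaf-area basis, µmol·m⁻²·s⁻¹.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER
    upper_bound: float = DEFAULT_UPPER
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """True when the reaction crosses the system boundary.

        Operationally: it involves at most one metabolite (pure
        source/sink), which is how boundary reactions are written here.
        """
        return len(self.stoichiometry) <= 1


@dataclass
class MetabolicNetwork:
    """A single-cell metabolic network."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_candidates: list[str] = field(default_factory=list)
    id: str = "cell"

    def __post_init__(self) -> None:
        self._met_index: dict[str, Metabolite] = {}
        self._rxn_index: dict[str, Reaction] = {}
        self.reindex()

    # -- bookkeeping ------------------------------------------------------

    def reindex(self) -> None:
        self._met_index = {}
        for m in self.metabolites:
            if m.id in self._met_index:
                raise NetworkError(f"duplicate metabolite id {m.id!r}")
            self._met_index[m.id] = m
        self._rxn_index = {}
        for r in self.reactions:
            if r.id in self._rxn_index:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            self._rxn_index[r.id] = r

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`NetworkError` on structural inconsistencies."""
        self.reindex()
        for r in self.reactions:
            if not r.stoichiometry and not r.is_exchange:
                raise NetworkError(f"reaction {r.id!r} has empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
        for rid in self.objective_candidates:
            if rid not in self._rxn_index:
                raise NetworkError(f"objective candidate {rid!r} is not a reaction")

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            objective_candidates=list(self.objective_candidates),
            id=self.id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        mine = {m.id: (m.compartment, m.charge) for m in self.metabolites}
        theirs = {m.id: (m.compartment, m.charge) for m in other.metabolites}
        if mine != theirs:
            return False
        rx_mine = {
            r.id: (dict(r.stoichiometry), r.lower_bound, r.upper_bound)
            for r in self.reactions
        }
        rx_theirs = {
            r.id: (dict(r.stoichiometry), r.lower_bound, r.upper_bound)
            for r in other.reactions
        }
        return rx_mine == rx_theirs
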