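"""Read and write metabolic networks (SBML and a tabular CSV dialect).

SBML handling is delegated to :mod:`cobra.io` (libsbml under the hood);
this module converts between :class:`cobra.Model` and the package's
:class:`~camtransit.network.MetabolicNetwork`. The tabular dialect is the
CSV export of the usual two-sheet spreadsheet layout: one table of
reactions with equation strings, one of metabolites.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import cobra
import pandas as pd

from .network import (
    DEFAULT_LOWER,
    DEFAULT_UPPER,
    MetabolicNetwork,
    Metabolite,
    NetworkError,
    Reaction,
)

logger = logging.getLogger(__name__)

_STORAGE_NOTE = "camtransit_storage"


class ParseError(ValueError):
    """Input file could not be parsed; message names the offending element."""


# ---------------------------------------------------------------------------
# cobra conversion
# ---------------------------------------------------------------------------


def to_cobra(net: MetabolicNetwork) -> cobra.Model:
    """Convert a :class:`MetabolicNetwork` to a :class:`cobra.Model`."""
    net.validate()
    model = cobra.Model(net.id)
    mets = {}
    for m in net.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name or m.id, compartment=m.compartment)
        cm.charge = int(m.charge)
        if m.is_storage:
            cm.notes[_STORAGE_NOTE] = "true"
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in net.reactions:
        cr = cobra.Reaction(
            r.id,
            name=r.name or r.id,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
        )
        cr.subsystem = r.subsystem
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in net.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    return model


def from_cobra(model: cobra.Model) -> MetabolicNetwork:
    """Convert a :class:`cobra.Model` to a :class:`MetabolicNetwork`."""
    metabolites = []
    missing_charge = []
    for m in model.metabolites:
        charge = m.charge
        if charge is None:
            charge = 0
            missing_charge.append(m.id)
        metabolites.append(
            Metabolite(
                id=m.id,
                name=m.name or m.id,
                compartment=m.compartment or "cytosol",
                charge=int(charge),
                is_storage=str(m.notes.get(_STORAGE_NOTE, "")).lower() == "true",
            )
        )
    if missing_charge:
        logger.warning(
            "%d metabolite(s) without a charge attribute; defaulting to 0 (e.g. %s)",
            len(missing_charge),
            ", ".join(missing_charge[:5]),
        )
    reactions = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if lb is None or ub is None:  # pragma: no cover - cobra normally fills these
            logger.warning("reaction %s missing bounds; applying defaults", r.id)
            lb = DEFAULT_LOWER if lb is None else lb
            ub = DEFAULT_UPPER if ub is None else ub
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                subsystem=r.subsystem or "",
            )
        )
    net = MetabolicNetwork(metabolites=metabolites, reactions=reactions, id=model.id or "cell")
    net.validate()
    return net


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML (L2 or L3, FBC bounds honoured) file into a network.

    When both FBC and kinetic-law bounds are present the FBC values win
    (cobra's convention). Species without a charge attribute get charge 0
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML file not found: {path}")
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise ParseError(f"failed to parse SBML file {path}: {exc}") from exc
    return from_cobra(model)


def write_sbml(net: MetabolicNetwork, path: str | Path) -> None:
    """Write a network as SBML L3 + FBC."""
    cobra.io.write_sbml_model(to_cobra(net), str(Path(path)))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, row: int) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"row {row}: cannot parse equation term {term.strip()!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        out[met] = out.get(met, 0.0) + coeff
    return out


def parse_equation(equation: str, row: int = 0) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` / ``"A <=> B"`` into (stoichiometry, reversible)."""
    if "<=>" in equation:
        arrow, reversible = "<=>", True
    elif "->" in equation:
        arrow, reversible = "->", False
    else:
        raise ParseError(f"row {row}: equation {equation!r} has no '->' or '<=>' arrow")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}
    for met, coeff in _parse_side(left, row).items():
        stoich[met] = stoich.get(met, 0.0) - coeff
    for met, coeff in _parse_side(right, row).items():
        stoich[met] = stoich.get(met, 0.0) + coeff
    return stoich, reversible


def format_equation(reaction: Reaction) -> str:
    def fmt(items):
        parts = []
        for met, coeff in items:
            coeff = abs(coeff)
            parts.append(met if coeff == 1 else f"{coeff:g} {met}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in reaction.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in reaction.stoichiometry.items() if c > 0)
    arrow = "<=>" if reaction.reversible else "->"
    return f"{fmt(subs)} {arrow} {fmt(prods)}".strip()


def read_tabular(
    reactions_path: str | Path, metabolites_path: str | Path | None = None
) -> MetabolicNetwork:
    """Read a network from reaction/metabolite CSV tables.

    ``reactions_path`` needs columns ``reaction_id, equation`` and
    optionally ``lower_bound, upper_bound, name, subsystem``. The optional
    metabolite table carries ``id, name, compartment, charge, is_storage``;
    metabolites referenced only in equations get defaults.
    """
    rx = pd.read_csv(reactions_path)
    required = {"reaction_id", "equation"}
    if not required.issubset(rx.columns):
        raise ParseError(
            f"{reactions_path}: missing required columns "
            f"{sorted(required - set(rx.columns))}"
        )

    met_info: dict[str, Metabolite] = {}
    if metabolites_path is not None:
        mt = pd.read_csv(metabolites_path)
        if "id" not in mt.columns:
            raise ParseError(f"{metabolites_path}: missing required column 'id'")
        for _, row in mt.iterrows():
            met_info[str(row["id"])] = Metabolite(
                id=str(row["id"]),
                name=str(row.get("name", "") or row["id"]),
                compartment=str(row.get("compartment", "cytosol") or "cytosol"),
                charge=int(row.get("charge", 0) or 0),
                is_storage=bool(row.get("is_storage", False)),
            )

    reactions = []
    seen_mets: dict[str, Metabolite] = dict(met_info)
    for i, row in rx.iterrows():
        rownum = i + 2  # 1-based + header
        stoich, reversible = parse_equation(str(row["equation"]), rownum)
        if met_info:
            unknown = [m for m in stoich if m not in met_info]
            if unknown:
                raise ParseError(
                    f"row {rownum}: unknown metabolite(s) {unknown} "
                    "not present in metabolite table"
                )
        for m in stoich:
            seen_mets.setdefault(m, Metabolite(id=m, name=m))
        lb = row.get("lower_bound")
        ub = row.get("upper_bound")
        if pd.isna(lb):
            lb = DEFAULT_LOWER if reversible else 0.0
        if pd.isna(ub):
            ub = DEFAULT_UPPER
        reactions.append(
            Reaction(
                id=str(row["reaction_id"]),
                name=str(row.get("name", "") or row["reaction_id"]),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                subsystem=str(row.get("subsystem", "") or ""),
            )
        )

    net = MetabolicNetwork(metabolites=list(seen_mets.values()), reactions=reactions)
    net.validate()
    return net


def write_tabular(
    net: MetabolicNetwork,
    reactions_path: str | Path,
    metabolites_path: str | Path | None = None,
) -> None:
    """Write the network as reaction/metabolite CSV tables."""
    rx = pd.DataFrame(
        {
            "reaction_id": [r.id for r in net.reactions],
            "name": [r.name for r in net.reactions],
            "equation": [format_equation(r) for r in net.reactions],
            "lower_bound": [r.lower_bound for r in net.reactions],
            "upper_bound": [r.upper_bound for r in net.reactions],
            "subsystem": [r.subsystem for r in net.reactions],
        }
    )
    rx.to_csv(reactions_path, index=False)
    if metabolites_path is not None:
        mt = pd.DataFrame(
            {
                "id": [m.id for m in net.metabolites],
                "name": [m.name for m in net.metabolites],
                "compartment": [m.compartment for m in net.metabolites],
                "charge": [m.charge for m in net.metabolites],
                "is_storage": [m.is_storage for m in net.metabolites],
            }
        )
        mt.to_csv(metabolites_path, index=False)


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"^(?P<base>.+)_P(?P<phase>[1-6])_(?P<cell>GC|MC)$")


def parse_tag(expanded_id: str) -> tuple[str, int | None, str]:
    """Split ``RXN_P3_GC`` into ``("RXN", 3, "GC")``.

    Shared/coupling reactions without the suffix come back with phase None
    and cell ``"shared"`` (a trailing ``_P<k>`` alone still yields the
    phase).
    """
    m = _TAG_RE.match(expanded_id)
    if m:
        return m.group("base"), int(m.group("phase")), m.group("cell")
    m2 = re.match(r"^(?P<base>.+)_P(?P<phase>[1-6])$", expanded_id)
    if m2:
        return m2.group("base"), int(m2.group("phase")), "shared"
    return expanded_id, None, "shared"


def write_solution(solution, path: str | Path) -> None:
    """Write a flux solution as a tidy CSV.

    Columns: ``reaction_id, phase, cell_type, flux``; rows sorted by
    reaction id then phase; fluxes printed with 12 significant digits.
    """
    rows = []
    fluxes = solution.fluxes or {}
    for rid, flux in fluxes.items():
        base, phase, cell = parse_tag(rid)
        rows.append((base, phase if phase is not None else "", cell, flux))
    rows.sort(key=lambda t: (t[0], t[1] if t[1] != "" else 0, t[2]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id,phase,cell_type,flux\n")
        for base, phase, cell, flux in rows:
            fh.write(f"{base},{phase},{cell},{flux:.12g}\n")


def read_solution(path: str | Path) -> pd.DataFrame:
    """Read back a solution CSV written by :func:`write_solution`."""
    return pd.read_csv(path, dtype={"reaction_id": str, "cell_type": str})
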