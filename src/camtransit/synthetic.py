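"""Synthetic test systems: a toy plant-cell network and diel T/RH profiles.

The toy network is a ~30-reaction carbon-bookkeeping abstraction of leaf
primary metabolism: Calvin-cycle carboxylation (light-dependent through
photon-derived NADPH), glycolysis/gluconeogenesis, the PEPC/PEPCK/ME/MDH
carboxylation-decarboxylation shuttle, starch/malate/sucrose storage
pools, K+/Cl- transport with an ATP cost, a phloem sink (sucrose plus a
small amino-acid fraction), and maintenance. Carbon is conserved exactly
(each metabolite carries an integer carbon number), which makes daytime
C3 fixation, nighttime PEPC fixation into malate, and the day-time malate
decarboxylation/refixation route all feasible — and makes night fixation
strictly cheaper in water under a day-hot/night-cool environment.

It reproduces the *structure and qualitative behaviour* the analysis
assumes, not any particular organism's fluxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .gas import EnvironmentProfile
from .network import MetabolicNetwork, Metabolite, Reaction

logger = logging.getLogger(__name__)

#: carbons per toy metabolite (used by carbon-closure checks)
CARBON_NUMBERS = {
    "co2": 1,
    "tp": 3,
    "pep": 3,
    "pyr": 3,
    "oaa": 4,
    "mal": 4,
    "aa": 4,
    "starch": 6,
    "suc": 12,
}

#: amino-acid units exported per sucrose unit in the phloem sink
PHLOEM_AA_FRACTION = 0.2


@dataclass
class ToyNetworkSpec:
    """Options for the toy network generator (deterministic given a spec)."""

    include_ppp: bool = True
    include_tca: bool = True
    n_futile_pairs: int = 0
    seed: int = 0


@dataclass
class EnvSpec:
    """Diel environment: day sine, night decay.

    Temperature follows a half-sine over the photoperiod, peaking (and
    humidity dipping) at ``t_peak_h``; after dusk it decays monotonically
    to a pre-dawn minimum, as in real diel courses. Mid-day is therefore
    the hottest/driest phase and end-of-night the coolest/moistest."""

    t_mean_C: float = 25.0
    t_amplitude_C: float = 8.0
    rh_mean: float = 0.60
    rh_amplitude: float = 0.25
    t_peak_h: float = 6.5
    seed: int = 0


def make_toy_cell_network(spec: ToyNetworkSpec | None = None) -> MetabolicNetwork:
    """Build the toy single-cell network."""
    spec = spec or ToyNetworkSpec()

    M = Metabolite
    metabolites = [
        M("co2", "carbon dioxide", "cytosol"),
        M("tp", "triose phosphate", "chloroplast"),
        M("pep", "phosphoenolpyruvate", "cytosol"),
        M("pyr", "pyruvate", "cytosol"),
        M("oaa", "oxaloacetate", "cytosol"),
        M("mal", "malate", "vacuole", charge=-2, is_storage=True),
        M("aa", "amino acid pool", "cytosol"),
        M("starch", "starch (glucosyl unit)", "chloroplast", is_storage=True),
        M("suc", "sucrose", "cytosol", is_storage=True),
        M("k", "potassium ion", "vacuole", charge=1, is_storage=True),
        M("cl", "chloride ion", "vacuole", charge=-1, is_storage=True),
        M("photon", "photon", "chloroplast"),
        M("atp", "ATP (energy unit)", "cytosol"),
        M("nadph", "NADPH (photoredox unit)", "chloroplast"),
        M("nadh", "NADH (respiratory redox unit)", "cytosol"),
    ]

    R = Reaction
    reactions = [
        # boundary / light
        R("CO2_UP", "CO2 uptake", {"co2": 1}, 0, 1000, "transporter"),
        R("PHOTON_UP", "photon capture", {"photon": 1}, 0, 1000, "ETC"),
        R("ATP_LIGHT", "photophosphorylation", {"photon": -1, "atp": 1}, 0, 1000, "ETC"),
        R(
            "NADPH_LIGHT",
            "photosynthetic electron transport",
            {"photon": -2, "nadph": 1},
            0,
            1000,
            "ETC",
        ),
        # Calvin cycle (lumped). The small direct photon requirement encodes
        # light activation (Rubisco activase): no dark Calvin flux even when
        # NADPH is available from the oxidative PPP.
        R(
            "RUBISCO",
            "Calvin cycle carboxylation (lumped, light-activated)",
            {"co2": -3, "atp": -9, "nadph": -6, "photon": -0.5, "tp": 1},
            0,
            1000,
            "Calvin cycle",
        ),
        # glycolysis / gluconeogenesis
        R("GLYC", "glycolysis tp->pep", {"tp": -1, "pep": 1, "atp": 1, "nadh": 1}, 0, 1000, "glycolysis"),
        R(
            "GNEO",
            "gluconeogenesis pep->tp",
            {"pep": -1, "atp": -1, "nadh": -1, "tp": 1},
            0,
            1000,
            "gluconeogenesis",
        ),
        R("PK", "pyruvate kinase", {"pep": -1, "pyr": 1, "atp": 1}, 0, 1000, "glycolysis"),
        R("PPDK", "pyruvate-orthophosphate dikinase", {"pyr": -1, "atp": -2, "pep": 1}, 0, 1000, "gluconeogenesis"),
        # carboxylation-decarboxylation shuttle
        R("PEPC", "PEP carboxylase", {"pep": -1, "co2": -1, "oaa": 1}, 0, 1000, "carboxylation"),
        R("PEPCK", "PEP carboxykinase", {"oaa": -1, "atp": -1, "pep": 1, "co2": 1}, 0, 1000, "decarboxylation"),
        # reducing direction only: malate is re-mobilised through ME, the
        # NADP-ME-type decarboxylation route
        R("MDH", "malate dehydrogenase (cytosolic)", {"oaa": -1, "nadh": -1, "mal": 1}, 0, 1000, "carboxylation"),
        R("ME", "malic enzyme", {"mal": -1, "pyr": 1, "co2": 1, "nadh": 1}, 0, 1000, "decarboxylation"),
        # nitrogen assimilation (skeleton only)
        R("AA_SYN", "amino acid synthesis from OAA", {"oaa": -1, "atp": -1, "nadh": -1, "aa": 1}, 0, 1000, "nitrogen assimilation"),
        # storage
        R("STARCH_SYN", "starch synthesis", {"tp": -2, "atp": -1, "starch": 1}, 0, 1000, "starch"),
        R("STARCH_DEG", "starch degradation", {"starch": -1, "tp": 2}, 0, 1000, "starch"),
        R("SUC_SYN", "sucrose synthesis", {"tp": -4, "atp": -2, "suc": 1}, 0, 1000, "sucrose"),
        R("SUC_DEG", "sucrose cleavage", {"suc": -1, "tp": 4}, 0, 1000, "sucrose"),
        # respiration / redox
        R("RESP", "respiration (lumped)", {"tp": -1, "co2": 3, "atp": 12}, 0, 1000, "TCA cycle"),
        R("NADH_OX", "oxidative phosphorylation", {"nadh": -1, "atp": 2}, 0, 1000, "ETC"),
        R("NADPH_OX", "NADPH overflow", {"nadph": -1}, 0, 1000, "ETC"),
        # ion transport (uptake pays a pumping cost; release is free)
        R("K_UP", "K+ uptake", {"atp": -0.25, "k": 1}, 0, 1000, "transporter"),
        R("K_REL", "K+ release", {"k": -1}, 0, 1000, "transporter"),
        R("CL_UP", "Cl- uptake", {"atp": -0.25, "cl": 1}, 0, 1000, "transporter"),
        R("CL_REL", "Cl- release", {"cl": -1}, 0, 1000, "transporter"),
        # sinks
        R("MAINT", "maintenance ATP drain", {"atp": -1}, 0, 1000, "maintenance"),
        R(
            "PHLOEM",
            "phloem output (sucrose + amino acids)",
            {"suc": -1, "aa": -PHLOEM_AA_FRACTION},
            0,
            1000,
            "sink",
        ),
    ]

    if spec.include_ppp:
        reactions.append(
            R(
                "PPP_OX",
                "oxidative pentose phosphate pathway (lumped)",
                {"tp": -1, "co2": 3, "nadph": 2},
                0,
                1000,
                "PPP",
            )
        )
    if spec.include_tca:
        reactions.append(
            R(
                "MAL_RESP",
                "malate oxidation via TCA (lumped)",
                {"mal": -1, "co2": 4, "atp": 10},
                0,
                1000,
                "TCA cycle",
            )
        )
    for i in range(spec.n_futile_pairs):
        fm = Metabolite(f"fut{i}", f"futile intermediate {i}", "cytosol")
        metabolites.append(fm)
        reactions.append(R(f"FUTILE{i}_F", f"futile cycle {i} fwd", {"tp": -1, f"fut{i}": 1}, 0, 1000, "futile"))
        reactions.append(R(f"FUTILE{i}_R", f"futile cycle {i} rev", {f"fut{i}": -1, "tp": 1}, 0, 1000, "futile"))

    net = MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        objective_candidates=["PHLOEM"],
        id=f"toy_cell_seed{spec.seed}",
    )
    net.validate()
    assert_carbon_conserving(net)
    return net


def assert_carbon_conserving(net: MetabolicNetwork) -> None:
    """Every non-boundary toy reaction conserves carbon exactly."""
    for r in net.reactions:
        coeffs = list(r.stoichiometry.values())
        if r.is_exchange or all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs):
            continue  # boundary source/sink
        balance = sum(
            c * CARBON_NUMBERS.get(m, 0) for m, c in r.stoichiometry.items()
        )
        if abs(balance) > 1e-12 and not r.id.startswith("FUTILE"):
            raise AssertionError(f"reaction {r.id} does not conserve carbon: {balance}")


_PHASE_MIDPOINTS = (0.5, 6.0, 11.5, 12.5, 18.0, 23.5)

#: shape of the nocturnal cooling (power-law decay toward the pre-dawn minimum)
_NIGHT_EXPONENT = 0.7


def _diel_shape(t: float, t_peak: float) -> float:
    """Normalized diel curve in [-1, 1]: half-sine over the 12-h photoperiod
    with its maximum at ``t_peak``, monotone decay to -1 just before dawn."""
    if t < 12.0:
        if t <= t_peak:
            return math.sin(0.5 * math.pi * t / t_peak)
        return math.cos(0.5 * math.pi * (t - t_peak) / (12.0 - t_peak))
    return -(((t - 12.0) / 12.0) ** _NIGHT_EXPONENT)


def make_env_profile(spec: EnvSpec | None = None) -> EnvironmentProfile:
    """Sample the diel T/RH curves at the six phase midpoints."""
    spec = spec or EnvSpec()
    if not 0.0 < spec.t_peak_h < 12.0:
        raise ValueError("t_peak_h must fall inside the 12-h photoperiod")
    temps = []
    rhs = []
    clipped = False
    for t in _PHASE_MIDPOINTS:
        c = _diel_shape(t, spec.t_peak_h)
        temps.append(spec.t_mean_C + spec.t_amplitude_C * c)
        rh = spec.rh_mean - spec.rh_amplitude * c
        if rh < 0.0 or rh > 1.0:
            clipped = True
            rh = min(1.0, max(0.0, rh))
        rhs.append(rh)
    if clipped:
        logger.warning("relative humidity clipped to [0, 1]")
    return EnvironmentProfile(
        temperature_C=tuple(temps),
        relative_humidity=tuple(rhs),
        label=f"sinusoid_seed{spec.seed}",
    )
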