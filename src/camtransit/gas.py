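"""Leaf gas exchange: vapour pressure, water-per-CO2 coupling coefficients.

Transpiration and CO2 uptake share the stomatal diffusion path, so the
water cost of carbon is the ratio of the two driving gradients times the
H2O/CO2 diffusivity ratio (~1.6). Per diel phase p,

    E(p) = 1.6 * VPD(p) / dCO2 * A(p)

with VPD = es(T)*(1 - RH) the vapour pressure deficit (kPa), dCO2 the
CO2 partial-pressure gradient across the stoma (kPa), and A(p) the phase's
CO2 uptake. The coefficients enter the LP as fixed per-phase constants,
which keeps the water coupling linear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: id of the pseudo-reaction whose flux tallies total diel water loss
WATER_TALLY_ID = "EX_WATER_LOSS"
_WATER_MET_ID = "water_loss_tally"


class GasExchangeError(ValueError):
    pass


def saturation_vapor_pressure(t_c: float) -> float:
    """Saturation vapour pressure (kPa) at ``t_c`` °C, Tetens formula.

    es = 0.6108 * exp(17.27*T / (T + 237.3)); valid -20..60 °C.
    """
    if not -20.0 <= t_c <= 60.0:
        raise GasExchangeError(f"temperature {t_c} °C outside supported range [-20, 60]")
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def vapor_pressure_deficit(t_c: float, rh: float) -> float:
    """VPD (kPa) for temperature ``t_c`` and relative humidity ``rh`` in [0,1]."""
    if not 0.0 <= rh <= 1.0:
        raise GasExchangeError(f"relative humidity {rh} outside [0, 1]")
    return saturation_vapor_pressure(t_c) * (1.0 - rh)


@dataclass
class GasExchangeParams:
    """Constants of the stomatal diffusion model.

    ``ci_ratio`` fixes internal CO2 as a fraction of ambient (linear
    coupling); set ``internal_co2_ppm`` to override with an absolute value.
    """

    diffusivity_ratio_h2o_co2: float = 1.6
    ambient_co2_ppm: float = 400.0
    ci_ratio: float = 0.7
    internal_co2_ppm: float | None = None
    atmospheric_pressure_kPa: float = 101.325

    def __post_init__(self) -> None:
        if self.diffusivity_ratio_h2o_co2 <= 1.0:
            raise GasExchangeError("diffusivity ratio must exceed 1")
        ci = self.internal_co2()
        if ci >= self.ambient_co2_ppm:
            raise GasExchangeError(
                f"internal CO2 ({ci} ppm) must be below ambient ({self.ambient_co2_ppm} ppm)"
            )

    def internal_co2(self) -> float:
        if self.internal_co2_ppm is not None:
            return self.internal_co2_ppm
        return self.ci_ratio * self.ambient_co2_ppm


@dataclass
class EnvironmentProfile:
    """Per-phase temperature (°C) and relative humidity (fraction).

    Exactly one record per phase index 1-6.
    """

    temperature_C: tuple[float, ...]
    relative_humidity: tuple[float, ...]
    label: str = "default"

    def __post_init__(self) -> None:
        self.temperature_C = tuple(float(t) for t in self.temperature_C)
        self.relative_humidity = tuple(float(r) for r in self.relative_humidity)
        if len(self.temperature_C) != 6 or len(self.relative_humidity) != 6:
            raise GasExchangeError("environment profile needs exactly 6 phase records")
        for r in self.relative_humidity:
            if not 0.0 <= r <= 1.0:
                raise GasExchangeError(f"relative humidity {r} outside [0, 1]")

    def temperature(self, phase: int) -> float:
        return self.temperature_C[phase - 1]

    def humidity(self, phase: int) -> float:
        return self.relative_humidity[phase - 1]


def water_per_co2(t_c: float, rh: float, params: GasExchangeParams | None = None) -> float:
    """mol H2O transpired per mol CO2 taken up at (T, RH).

    ratio = D_ratio * VPD / dpCO2 with dpCO2 = (Ca - Ci) * 1e-6 * P.
    Zero iff RH = 1 (no vapour gradient).
    """
    params = params or GasExchangeParams()
    vpd = vapor_pressure_deficit(t_c, rh)
    dp_co2 = (
        (params.ambient_co2_ppm - params.internal_co2())
        * 1e-6
        * params.atmospheric_pressure_kPa
    )
    if dp_co2 <= 0:
        raise GasExchangeError("ambient CO2 must exceed internal CO2")
    return params.diffusivity_ratio_h2o_co2 * vpd / dp_co2


def phase_water_coefficients(
    env: EnvironmentProfile, params: GasExchangeParams | None = None
) -> dict[int, float]:
    """Water-per-CO2 coefficient for each phase 1-6."""
    return {
        p: water_per_co2(env.temperature(p), env.humidity(p), params)
        for p in range(1, 7)
    }


def attach_water_coupling(model, env: EnvironmentProfile, params: GasExchangeParams | None = None):
    """Add the transpiration tally to an assembled diel model.

    Transpiration runs through the open stoma whether or not CO2 is being
    taken up, so water loss is tied to the stomatal conductance
    g(p) = g_min + slope * S(p) (S(p) the guard-cell osmotic content that
    the aperture constraint derives from the K+/sucrose linker pools):

        W_total = sum_p wpc(p) * duration_h(p) * slope * S(p)

    with wpc the water-per-CO2 gas-diffusion coefficient. Because CO2
    intake is bounded by the same g(p) and the osmolyte pools are costly,
    optimal solutions open the stoma exactly as far as uptake requires, so
    at the reported solutions W_total equals
    sum_p wpc(p) * duration_h(p) * CO2_uptake(p) — the diffusion-model
    water/carbon coupling — while idle open stomata still pay their water
    cost. The tally is the flux of the pseudo-reaction ``EX_WATER_LOSS``,
    which can be minimised (WUE maximisation at fixed phloem output) or
    capped (water-budget constraint). Returns the model.

    Requires the osmotic opening constraint to be attached first.
    """
    import cobra

    params = params or GasExchangeParams()
    cm = model.cmodel
    if WATER_TALLY_ID in [r.id for r in cm.reactions]:
        raise GasExchangeError("water coupling already attached")
    if model.aperture is None:
        raise GasExchangeError(
            "attach the osmotic opening constraint before the water coupling "
            "(water loss is conductance-based)"
        )
    for phase in model.phases:
        if model.stomatal_co2_ids.get(phase.index) is None:
            raise GasExchangeError(
                f"no stomatal CO2 intake reaction for phase {phase.index}"
            )
    coeffs = phase_water_coefficients(env, params)
    slope = model.aperture.slope
    cfg = model.config

    pool = cobra.Metabolite(_WATER_MET_ID, name="diel water loss pool", compartment="extracellular")
    for phase in model.phases:
        p = phase.index
        w = coeffs[p] * phase.duration_h * slope
        k_link = cm.reactions.get_by_id(model.linker_id(cfg.k_id, p, "GC"))
        k_link.add_metabolites({pool: 2.0 * w})  # K-salt pair: 2 osmotica per K+
        suc_link = cm.reactions.get_by_id(model.linker_id(cfg.sucrose_id, p, "GC"))
        suc_link.add_metabolites({pool: w})
    drain = cobra.Reaction(WATER_TALLY_ID, name="total diel transpirational water loss")
    drain.lower_bound = 0.0
    drain.upper_bound = 1e12
    cm.add_reactions([drain])
    drain.add_metabolites({pool: -1.0})

    model.water_tally_id = WATER_TALLY_ID
    model.water_coefficients = coeffs
    model.environment = env
    model.gas_params = params
    return model


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------


def read_env_profile(path: str | Path, label: str | None = None) -> EnvironmentProfile:
    """Read a profile CSV with columns ``phase, temperature_C, relative_humidity``."""
    df = pd.read_csv(path)
    required = {"phase", "temperature_C", "relative_humidity"}
    if not required.issubset(df.columns):
        raise GasExchangeError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    df = df.sort_values("phase")
    if list(df["phase"]) != [1, 2, 3, 4, 5, 6]:
        raise GasExchangeError(f"{path}: need exactly one record per phase 1-6")
    return EnvironmentProfile(
        temperature_C=tuple(df["temperature_C"]),
        relative_humidity=tuple(df["relative_humidity"]),
        label=label or str(Path(path).stem),
    )


def write_env_profile(env: EnvironmentProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "phase": range(1, 7),
            "temperature_C": env.temperature_C,
            "relative_humidity": env.relative_humidity,
        }
    ).to_csv(path, index=False)
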