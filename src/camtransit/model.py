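"""High-level Model/Results interface.

:class:`CamTransitionModel` bundles a single-cell network, a diel
environment and the assembly/gas/scan configuration; ``fit()`` runs the
full workflow — assemble, C3 reference, water-loss-reduction scan,
classification — and returns a :class:`CamTransitionResults` holding the
trajectory, the storage diagnostics and the reaction classification, with
a ``summary()`` for the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as model_io
from .analysis import classify_trajectory, storage_report
from .assembly import (
    AssemblyConfig,
    CombinedDielModel,
    DielPhase,
    assemble,
    default_phases,
)
from .gas import EnvironmentProfile, GasExchangeParams, read_env_profile
from .network import MetabolicNetwork
from .scan import (
    FluxSolution,
    ScanConfig,
    ScanTrajectory,
    c3_reference_solution,
    run_water_scan,
)


class CamTransitionModel:
    """Coupled guard-cell/mesophyll diel model of the C3 -> CAM transition.

    Parameters
    ----------
    network:
        Single-cell metabolic network (replicated per phase and cell type).
    environment:
        Per-phase temperature/relative-humidity profile.
    assembly_config, gas_params, scan_config:
        Tunables of the assembly, the gas-diffusion water coupling and the
        scan schedule; defaults follow the package's documented choices.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        environment: EnvironmentProfile,
        assembly_config: AssemblyConfig | None = None,
        gas_params: GasExchangeParams | None = None,
        scan_config: ScanConfig | None = None,
        phases: list[DielPhase] | None = None,
    ) -> None:
        self.network = network
        self.environment = environment
        self.assembly_config = assembly_config or AssemblyConfig()
        self.gas_params = gas_params or GasExchangeParams()
        self.scan_config = scan_config or ScanConfig()
        self.phases = phases or default_phases()
        self._combined: CombinedDielModel | None = None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_sbml(cls, model_path: str | Path, env_path: str | Path, **kwargs) -> "CamTransitionModel":
        return cls(model_io.read_sbml(model_path), read_env_profile(env_path), **kwargs)

    @classmethod
    def from_tabular(
        cls,
        reactions_path: str | Path,
        env_path: str | Path,
        metabolites_path: str | Path | None = None,
        **kwargs,
    ) -> "CamTransitionModel":
        return cls(
            model_io.read_tabular(reactions_path, metabolites_path),
            read_env_profile(env_path),
            **kwargs,
        )

    @classmethod
    def from_toy(cls, toy_spec=None, env_spec=None, **kwargs) -> "CamTransitionModel":
        from .synthetic import make_env_profile, make_toy_cell_network

        return cls(make_toy_cell_network(toy_spec), make_env_profile(env_spec), **kwargs)

    # -- workflow ----------------------------------------------------------

    @property
    def combined(self) -> CombinedDielModel:
        """The assembled LP model (built lazily, cached)."""
        if self._combined is None:
            self._combined = assemble(
                self.network,
                self.environment,
                phases=self.phases,
                config=self.assembly_config,
                gas_params=self.gas_params,
            )
        return self._combined

    def rebuild(self, malate_charge_fraction: float | None = None) -> CombinedDielModel:
        """Assemble a fresh combined model (optionally at another malate
        charge fraction); does not touch the cached one."""
        cfg = self.assembly_config
        if malate_charge_fraction is not None:
            import dataclasses

            cfg = dataclasses.replace(cfg, malate_charge_fraction=malate_charge_fraction)
        return assemble(
            self.network,
            self.environment,
            phases=self.phases,
            config=cfg,
            gas_params=self.gas_params,
        )

    def fit(self, c3_constraints: dict | None = None) -> "CamTransitionResults":
        """Run C3 reference + scan + post-processing."""
        combined = self.combined
        c3 = c3_reference_solution(combined, c3_constraints, self.scan_config)
        trajectory = run_water_scan(combined, self.scan_config, c3_reference=c3)
        classification = classify_trajectory(trajectory)
        storage = storage_report(trajectory)
        return CamTransitionResults(
            model=self,
            combined=combined,
            c3=c3,
            trajectory=trajectory,
            classification=classification,
            storage=storage,
        )


@dataclass
class CamTransitionResults:
    """Fitted trajectory of the C3 -> CAM transition."""

    model: CamTransitionModel
    combined: CombinedDielModel
    c3: FluxSolution
    trajectory: ScanTrajectory
    classification: pd.DataFrame
    storage: object
    _summary_cache: str | None = field(default=None, repr=False)

    @property
    def cam(self) -> FluxSolution:
        return self.trajectory.cam_endpoint

    @property
    def intermediate(self) -> FluxSolution:
        """The scan point nearest the midpoint of the C3/CAM water range."""
        target = 0.5 * (self.c3.water_loss_total + self.cam.water_loss_total)
        return min(
            self.trajectory.solutions,
            key=lambda s: abs(s.water_loss_total - target),
        )

    def label_counts(self) -> pd.Series:
        return self.classification["label"].value_counts()

    def summary(self) -> str:
        c3 = self.c3
        cam = self.cam
        inter = self.intermediate
        st = self.storage.table
        counts = self.label_counts()
        lines = [
            "C3 -> CAM transition scan",
            "=" * 54,
            f"scan points (feasible)     : {len(self.trajectory.points)}",
            f"C3 water loss              : {c3.water_loss_total:,.4g}",
            f"intermediate water loss    : {inter.water_loss_total:,.4g}",
            f"CAM water loss (endpoint)  : {cam.water_loss_total:,.4g}",
            f"water-loss reduction       : {1 - cam.water_loss_total / c3.water_loss_total:.1%}",
            f"phloem output (fixed)      : {c3.phloem_total:,.4g}",
            f"WUE  C3 / CAM              : {c3.wue:.4g} / {cam.wue:.4g}",
            f"night CO2 share  C3 -> CAM : "
            f"{st['night_co2_share'].iloc[0]:.3f} -> {st['night_co2_share'].iloc[-1]:.3f}",
            f"starch P3->P4 (GC) C3->CAM : "
            f"{st['starch_P3_to_P4_GC'].iloc[0]:.4g} -> {st['starch_P3_to_P4_GC'].iloc[-1]:.4g}",
            f"malate P6->P1 (GC) C3->CAM : "
            f"{st['malate_P6_to_P1_GC'].iloc[0]:.4g} -> {st['malate_P6_to_P1_GC'].iloc[-1]:.4g}",
            "reaction-phase-cell labels :",
        ]
        for label, n in counts.items():
            lines.append(f"    {label:<16} {n}")
        return "\n".join(lines)
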