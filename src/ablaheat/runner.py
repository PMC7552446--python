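"""Coupled frequency-transient simulation driver and parametric sweeps.

Each internal time step re-solves the frequency-domain electric problem with
the tissue conductivity evaluated at the current temperature, rescales it to
the prescribed RF power, advances the bioheat equation one implicit step and
accumulates Arrhenius damage.  Protected runs precool the device for 5
minutes before RF starts.  Outputs are sampled on a 1 s grid by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import damage as dmg
from . import electric, fem, mesh as meshmod, thermal
from .geometry import Geometry, build_geometry
from .materials import BODY_TEMP_K, MaterialSet, PerfusionParams
from .mesh import Mesh, SamplingLine

KELVIN = 273.15


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Complete description of one ablation simulation."""

    study: int = 1
    protected: bool = False
    power: float = 30.0  # W
    T_water: float | None = None  # degC, protected runs only
    duration: float = 20.0  # s
    output_interval: float = 1.0  # s
    internal_dt: float = 0.1  # s
    target_elements: int = 8000
    refinement_radius: float = 2.0  # mm
    frequency: float = 500e3  # Hz
    precool_dt: float = 5.0  # s
    omega_b: float = 0.0  # blood perfusion rate, 1/s
    layer_overrides: dict = field(default_factory=dict)
    catheter_overrides: dict = field(default_factory=dict)
    material_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.study not in (1, 2):
            raise ConfigurationError(f"study must be 1 or 2, got {self.study!r}")
        if not 0.0 <= self.power <= 100.0:
            raise ConfigurationError(f"power must be in [0, 100] W, got {self.power}")
        if self.protected:
            if self.T_water is None:
                raise ConfigurationError("protected runs require T_water")
            if not 0.0 <= self.T_water <= 40.0:
                raise ConfigurationError(f"T_water must be in [0, 40] degC, got {self.T_water}")
        elif self.T_water is not None:
            warnings.warn("T_water is ignored for control (unprotected) runs", stacklevel=3)
            self.T_water = None
        if not self.duration > 0:
            raise ConfigurationError("duration must be positive")
        if not 0 < self.internal_dt <= self.output_interval:
            raise ConfigurationError("need 0 < internal_dt <= output_interval")
        if self.frequency <= 0:
            raise ConfigurationError("frequency must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OutputRecord:
    time: float  # s since RF start
    T_line_C: np.ndarray  # temperature along the sampling line, degC
    fraction_line: np.ndarray  # fraction of damage along the line, %
    impedance: float  # ohms


@dataclass
class SimulationResult:
    config: SimulationConfig
    line: SamplingLine
    records: list
    metrics: dmg.LesionMetrics
    mesh_stats: dict
    provenance: dict

    @property
    def impedance_trace(self) -> np.ndarray:
        return np.array([[r.time, r.impedance] for r in self.records])


class SimulationContext:
    """Geometry, mesh and solver spaces shared by runs on one layout."""

    def __init__(self, config: SimulationConfig):
        self.geometry: Geometry = build_geometry(
            config.study, config.protected, config.layer_overrides, config.catheter_overrides
        )
        self.mesh: Mesh = meshmod.generate_mesh(
            self.geometry, config.target_elements, config.refinement_radius
        )
        self.space = fem.build_space(self.mesh)
        self.terminal_nodes, self.ground_nodes = electric.terminal_and_ground_nodes(self.mesh)
        self.materials = MaterialSet(overrides=dict(config.material_overrides))
        labels = np.unique(self.mesh.element_subdomain)
        self._label_elements = {
            lab: np.flatnonzero(self.mesh.element_subdomain == lab) for lab in labels
        }
        self._props = {lab: self.materials.props(lab) for lab in labels}
        self.eps_r = np.zeros(self.mesh.n_elements)
        for lab, idx in self._label_elements.items():
            self.eps_r[idx] = self._props[lab].eps_r
        self.line = meshmod.sampling_line(self.mesh)
        self.damage_A, self.damage_dE, self.damage_mask = dmg.node_damage_params(self.mesh)

    def element_sigma(self, T_nodal: np.ndarray) -> np.ndarray:
        """Per-element electric conductivity at the current temperature."""
        Te = T_nodal[self.mesh.triangles].mean(axis=1)
        sigma = np.zeros(self.mesh.n_elements)
        for lab, idx in self._label_elements.items():
            sigma[idx] = self._props[lab].sigma(Te[idx])
        return sigma

    def sigma_complex(self, T_nodal: np.ndarray, frequency: float) -> np.ndarray:
        return electric.complex_conductivity(self.element_sigma(T_nodal), self.eps_r, frequency)

    def mesh_stats(self) -> dict:
        stats = {"n_nodes": int(self.mesh.n_nodes), "n_elements": int(self.mesh.n_elements)}
        for lab, idx in self._label_elements.items():
            stats[f"elements_{lab}"] = int(len(idx))
        return stats


def run_simulation(config: SimulationConfig, context: SimulationContext | None = None) -> SimulationResult:
    """Run one coupled electro-thermal-damage simulation."""
    config.validate()
    ctx = context or SimulationContext(config)
    boundaries = thermal.BoundarySet(
        T_water=None if config.T_water is None else config.T_water + KELVIN
    )
    problem = thermal.ThermalProblem(
        ctx.space,
        materials=ctx.materials,
        boundaries=boundaries,
        perfusion=PerfusionParams(omega_b=config.omega_b),
    )
    state = problem.initial_state(config.protected)
    if config.protected:
        state = problem.run_precooling(state, dt=config.precool_dt)

    damage = dmg.DamageState(alpha=np.zeros(ctx.mesh.n_nodes))
    line_z = ctx.line.z_m

    def solve_electric(T):
        sc = ctx.sigma_complex(T, config.frequency)
        power = config.power if config.power > 0 else None
        return electric.solve_terminal(ctx.space, sc, ctx.terminal_nodes, ctx.ground_nodes, power)

    def record(state, impedance):
        T_line = meshmod.interp_on_axis(ctx.mesh, state.T, line_z)
        frac_line = meshmod.interp_on_axis(ctx.mesh, dmg.fraction_of_damage(damage), line_z)
        return OutputRecord(
            time=round(state.time, 9),
            T_line_C=T_line - KELVIN,
            fraction_line=frac_line,
            impedance=impedance,
        )

    sol = solve_electric(state.T)
    records = [record(state, sol.impedance)]

    n_steps = int(round(config.duration / config.internal_dt))
    out_every = int(round(config.output_interval / config.internal_dt))
    if abs(n_steps * config.internal_dt - config.duration) > 1e-9 * max(1.0, config.duration):
        raise ConfigurationError("duration must be an integer number of internal steps")

    for istep in range(1, n_steps + 1):
        sol = solve_electric(state.T)
        Q = sol.Q_rh if config.power > 0 else None
        new_state = problem.step(state, Q, config.internal_dt)
        damage = dmg.integrate_damage_step(
            damage,
            state.T,
            new_state.T,
            config.internal_dt,
            ctx.damage_A,
            ctx.damage_dE,
            ctx.damage_mask,
        )
        state = new_state
        if istep % out_every == 0:
            records.append(record(state, sol.impedance))

    final = records[-1]
    metrics = dmg.line_metrics(ctx.line, final.T_line_C + KELVIN, final.fraction_line)
    return SimulationResult(
        config=config,
        line=ctx.line,
        records=records,
        metrics=metrics,
        mesh_stats=ctx.mesh_stats(),
        provenance={"config": config.to_dict(), "solver": "ablaheat-fem-p1-axisym"},
    )


METRIC_COLUMNS = [
    "study",
    "protected",
    "power_W",
    "T_water_C",
    "duration_s",
    "esoph_depth_mm",
    "max_esoph_fraction_pct",
    "peak_T_C",
    "myoc_max_fraction_pct",
    "myoc_depth_mm",
    "initial_impedance_ohm",
    "final_impedance_ohm",
    "error",
]


def _metrics_row(config: SimulationConfig, result: SimulationResult | None, error: str = "") -> dict:
    row = {
        "study": config.study,
        "protected": config.protected,
        "power_W": config.power,
        "T_water_C": np.nan if config.T_water is None else config.T_water,
        "duration_s": config.duration,
        "error": error,
    }
    if result is None:
        row.update(
            {
                k: np.nan
                for k in (
                    "esoph_depth_mm",
                    "max_esoph_fraction_pct",
                    "peak_T_C",
                    "myoc_max_fraction_pct",
                    "myoc_depth_mm",
                    "initial_impedance_ohm",
                    "final_impedance_ohm",
                )
            }
        )
    else:
        m = result.metrics
        row.update(
            {
                "esoph_depth_mm": m.esophageal_lesion_depth,
                "max_esoph_fraction_pct": m.max_esophageal_fraction,
                "peak_T_C": m.peak_temperature,
                "myoc_max_fraction_pct": m.myocardial_max_fraction,
                "myoc_depth_mm": m.myocardial_lesion_depth,
                "initial_impedance_ohm": result.records[0].impedance,
                "final_impedance_ohm": result.records[-1].impedance,
            }
        )
    return row


def run_sweep(
    base_config: SimulationConfig,
    powers: list,
    T_waters: list | None = None,
    include_controls: bool = False,
    studies: list | None = None,
) -> pd.DataFrame:
    """Run the rectangular (power x coolant temperature) parametric sweep.

    Returns one lesion-metrics row per combination in deterministic order
    (study, protected, power, T_water).  Individual run failures are recorded
    in the ``error`` column and the sweep continues.
    """
    if not powers:
        raise ConfigurationError("power list must be non-empty")
    protected_sweep = T_waters is not None and len(T_waters) > 0
    if T_waters is not None and len(T_waters) == 0:
        raise ConfigurationError("T_water list must be non-empty when given")
    studies = sorted(studies or [base_config.study])

    from dataclasses import replace

    rows = []
    contexts: dict = {}
    for study in studies:
        combos = []
        if include_controls or not protected_sweep:
            combos += [(False, float(p), None) for p in sorted(powers)]
        if protected_sweep:
            combos += [
                (True, float(p), float(tw)) for p in sorted(powers) for tw in sorted(T_waters)
            ]
        combos.sort(key=lambda c: (c[0], c[1], -1.0 if c[2] is None else c[2]))
        for protected, power, tw in combos:
            cfg = replace(
                base_config, study=study, protected=protected, power=power, T_water=tw
            )
            key = (study, protected, cfg.target_elements)
            try:
                if key not in contexts:
                    contexts[key] = SimulationContext(cfg)
                result = run_simulation(cfg, contexts[key])
                rows.append(_metrics_row(cfg, result))
            except Exception as exc:  # record-and-continue failure policy
                rows.append(_metrics_row(cfg, None, error=f"{type(exc).__name__}: {exc}"))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


_GRID_METRICS = {
    "esoph_depth": "esoph_depth_mm",
    "esoph_max_fraction": "max_esoph_fraction_pct",
    "myoc_peak_T": "peak_T_C",
    "myoc_max_fraction": "myoc_max_fraction_pct",
}


def contour_grid(sweep_table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot a protected sweep into a (T_water x power) grid for one metric."""
    if metric not in _GRID_METRICS:
        raise ConfigurationError(
            f"unknown metric {metric!r}; expected one of {sorted(_GRID_METRICS)}"
        )
    col = _GRID_METRICS[metric]
    prot = sweep_table[sweep_table["protected"].astype(bool)]
    if prot.empty:
        raise ConfigurationError("sweep table contains no protected runs")
    grid = prot.pivot_table(index="T_water_C", columns="power_W", values=col, aggfunc="first")
    if grid.isna().any().any():
        raise ConfigurationError("sweep does not cover a full rectangular grid")
    counts = prot.groupby(["T_water_C", "power_W"]).size()
    if (counts > 1).any():
        raise ConfigurationError("duplicate sweep cells")
    return grid
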