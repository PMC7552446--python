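"""Transient Pennes bioheat solver on the axisymmetric mesh.

The blood pool is excluded from the thermal unknowns and replaced by
convective (Robin) boundary conditions: h_t = 610 W/(m2 K) on blood-tissue
interfaces and h_e = 3346 W/(m2 K) on blood-wetted catheter surfaces, both
referenced to 37 degC blood.  The cooling-device water layer is held at the
coolant temperature (a well-mixed, high-flow coolant), so the device wall
conducts against a fixed-temperature sink.  Time stepping is backward Euler
with lumped mass and one-step-lagged property linearization; perfusion acts
as a linear sink in tissue subdomains (default perfusion rate is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from . import fem
from .materials import BODY_TEMP_K, TISSUE_LABELS, MaterialSet, PerfusionParams
from .mesh import Mesh


class ThermalSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class ThermalState:
    """Nodal temperature field (K) at a simulation time (s).

    Time is negative during the precooling phase and zero when RF starts.
    """

    T: np.ndarray
    time: float


@dataclass(frozen=True)
class BoundarySet:
    """Thermal boundary data: convective blood replacement and coolant inlet."""

    h_t: float = 610.0  # blood-tissue film coefficient, W/(m2 K)
    h_e: float = 3346.0  # blood-catheter film coefficient, W/(m2 K)
    T_blood: float = BODY_TEMP_K  # K
    T_water: float | None = None  # K; None for control runs


class ThermalProblem:
    """Assembled, re-usable thermal problem on one mesh."""

    def __init__(
        self,
        space: fem.FemSpace,
        materials: MaterialSet | None = None,
        boundaries: BoundarySet | None = None,
        perfusion: PerfusionParams | None = None,
        extra_dirichlet: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        self.space = space
        self.mesh: Mesh = space.mesh
        self.materials = materials or MaterialSet()
        self.boundaries = boundaries or BoundarySet()
        self.perfusion = perfusion or PerfusionParams()
        mesh = self.mesh

        self.active = np.flatnonzero(mesh.element_subdomain != "blood")
        self.tissue_elements = np.flatnonzero(
            np.isin(mesh.element_subdomain, sorted(TISSUE_LABELS))
        )
        self._label_elements = {
            label: np.flatnonzero(mesh.element_subdomain == label)
            for label in np.unique(mesh.element_subdomain)
        }
        self._props = {label: self.materials.props(label) for label in self._label_elements}

        # Robin edge sets
        ht_edges = mesh.edges_by_tag("blood_tissue_interface")
        he_edges = [tuple(e) for e in mesh.edges_by_tag("blood_catheter_interface")]
        for edge in mesh.edges_by_tag("tip_surface"):
            if "blood" in mesh.edge_neighbors.get(tuple(edge), ()):
                he_edges.append(tuple(edge))
        he_edges = np.asarray(sorted(he_edges), dtype=int).reshape(-1, 2)
        self._robin_diag = np.zeros(mesh.n_nodes)
        self._robin_rhs = np.zeros(mesh.n_nodes)
        for edges, h in ((ht_edges, self.boundaries.h_t), (he_edges, self.boundaries.h_e)):
            w = fem.edge_weights(mesh, edges)
            if len(edges):
                np.add.at(self._robin_diag, edges.ravel(), h * w.ravel())
        self._robin_rhs = self._robin_diag * self.boundaries.T_blood

        # Dirichlet coolant nodes (protected geometry only)
        protected = mesh.geometry is not None and mesh.geometry.protected
        if protected and self.boundaries.T_water is None:
            raise ValueError("protected geometry requires a coolant temperature")
        if protected:
            self.water_nodes = mesh.subdomain_nodes("device_water")
        else:
            self.water_nodes = np.empty(0, dtype=int)

        if extra_dirichlet is not None:
            self.extra_nodes = np.asarray(extra_dirichlet[0], dtype=int)
            self.extra_values = np.asarray(extra_dirichlet[1], dtype=float)
        else:
            self.extra_nodes = np.empty(0, dtype=int)
            self.extra_values = np.empty(0)

        active_nodes = np.unique(mesh.triangles[self.active])
        self.fixed_nodes = np.setdiff1d(np.arange(mesh.n_nodes), active_nodes)
        self.fixed_nodes = np.union1d(self.fixed_nodes, self.water_nodes)
        self.fixed_nodes = np.union1d(self.fixed_nodes, self.extra_nodes)

    # -- properties ---------------------------------------------------------
    def _element_T(self, T: np.ndarray) -> np.ndarray:
        return T[self.mesh.triangles].mean(axis=1)

    def element_properties(self, T: np.ndarray):
        """Per-element k and rho*cp evaluated at the element-mean temperature."""
        Te = self._element_T(T)
        k = np.zeros(self.mesh.n_elements)
        rhocp = np.zeros(self.mesh.n_elements)
        for label, idx in self._label_elements.items():
            if label == "blood":
                continue
            p = self._props[label]
            k[idx] = p.k(Te[idx])
            rhocp[idx] = p.rho(Te[idx]) * p.cp
        return k, rhocp

    # -- stepping -----------------------------------------------------------
    def initial_state(self, protected: bool | None = None) -> ThermalState:
        """Uniform body temperature; protected runs start 300 s before RF."""
        if protected is None:
            protected = bool(self.mesh.geometry and self.mesh.geometry.protected)
        T = np.full(self.mesh.n_nodes, BODY_TEMP_K)
        if protected:
            T[self.water_nodes] = self.boundaries.T_water
        return ThermalState(T=T, time=-300.0 if protected else 0.0)

    def step(self, state: ThermalState, Q_rh: np.ndarray | None, dt: float) -> ThermalState:
        """One backward-Euler step with the given Joule density (W/m3/element)."""
        if not dt > 0:
            raise ValueError(f"dt must be positive, got {dt}")
        T_old = state.T
        k_e, rhocp_e = self.element_properties(T_old)
        K = fem.assemble_stiffness(self.space, k_e, self.active)
        M = fem.lumped_mass(self.space, rhocp_e, self.active)

        diag = M / dt + self._robin_diag
        rhs = (M / dt) * T_old + self._robin_rhs
        pp = self.perfusion
        if pp.omega_b > 0:
            perf_coef = np.zeros(self.mesh.n_elements)
            perf_coef[self.tissue_elements] = pp.rho_b * pp.cp_b * pp.omega_b
            P = fem.lumped_mass(self.space, perf_coef, self.active)
            diag += P
            rhs += P * pp.T_b
        if pp.Q_met != 0.0:
            met = np.zeros(self.mesh.n_elements)
            met[self.tissue_elements] = pp.Q_met
            rhs += fem.element_load(self.space, met, self.active)
        if Q_rh is not None:
            rhs += fem.element_load(self.space, np.asarray(Q_rh), self.active)

        A = K + sp.diags(diag)
        fixed = self.fixed_nodes
        fixed_vals = T_old[fixed].copy()
        if len(self.water_nodes):
            keep = np.isin(fixed, self.water_nodes)
            fixed_vals[keep] = self.boundaries.T_water
        if len(self.extra_nodes):
            pos = np.searchsorted(fixed, self.extra_nodes)
            fixed_vals[pos] = self.extra_values
        T_new = fem.solve_dirichlet(A, rhs, fixed, fixed_vals)
        if not np.all(np.isfinite(T_new)):
            raise ThermalSolverError(f"non-finite temperatures at t={state.time + dt:.3f} s")
        return ThermalState(T=T_new, time=state.time + dt)

    def run_precooling(self, state: ThermalState, dt: float = 5.0) -> ThermalState:
        """Advance the 5-minute source-free precooling phase to t = 0."""
        if not (self.mesh.geometry and self.mesh.geometry.protected):
            raise ValueError("precooling applies only to protected geometries")
        if state.time >= 0:
            raise ValueError("precooling already complete")
        while state.time < -1e-9:
            step_dt = min(dt, -state.time)
            state = self.step(state, None, step_dt)
        return replace(state, time=0.0)
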