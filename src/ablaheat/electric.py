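"""Frequency-domain electric solver with a power-controlled terminal.

Solves current conservation div((sigma + j w eps0 eps_r) grad V) = 0 in the
axisymmetric domain at the RF frequency, with the electrode tip held
equipotential (terminal) and the truncated far-field boundary grounded.  The
problem is linear, so it is solved once at unit terminal voltage and the
complex amplitude is rescaled to deliver the prescribed time-averaged power
P = Re(V I*) / 2.  The time-averaged resistive heating density Q = Re(J.E*)/2
= sigma |E|^2 / 2 feeds the thermal solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .materials import EPS0
from .mesh import Mesh


class ElectricSolverError(RuntimeError):
    pass


@dataclass
class ElectricSolution:
    """Complex potential/field solution scaled to the prescribed power."""

    V: np.ndarray  # complex nodal potential, volts (amplitude phasor)
    E: np.ndarray  # (M,2) complex field per element, V/m
    J: np.ndarray  # (M,2) complex current density per element, A/m2
    Q_rh: np.ndarray  # (M,) time-averaged Joule heating density, W/m3
    terminal_voltage: complex
    terminal_current: complex
    impedance: float  # |V_t / I_t|, ohms
    dissipated_power: float  # discrete integral of Q_rh, W


def complex_conductivity(sigma: np.ndarray, eps_r: np.ndarray, frequency: float) -> np.ndarray:
    """sigma + j*omega*eps0*eps_r per element."""
    omega = 2.0 * np.pi * frequency
    return np.asarray(sigma, dtype=complex) + 1j * omega * EPS0 * np.asarray(eps_r)


def solve_terminal(
    space: fem.FemSpace,
    sigma_c: np.ndarray,
    terminal_nodes: np.ndarray,
    ground_nodes: np.ndarray,
    power: float | None = None,
) -> ElectricSolution:
    """Solve the terminal problem on a prebuilt FEM space.

    ``sigma_c`` is the per-element complex conductivity.  With ``power`` given
    the solution is rescaled so the time-averaged dissipated power equals it;
    otherwise the unit-terminal-voltage solution is returned.
    """
    if power is not None and not power > 0:
        raise ValueError(f"power must be positive, got {power}")
    if len(terminal_nodes) == 0 or len(ground_nodes) == 0:
        raise ElectricSolverError("terminal or ground node set is empty")

    K = fem.assemble_stiffness(space, np.asarray(sigma_c, dtype=complex))
    fixed = np.concatenate([terminal_nodes, ground_nodes])
    vals = np.concatenate(
        [np.ones(len(terminal_nodes), dtype=complex), np.zeros(len(ground_nodes), dtype=complex)]
    )
    V = fem.solve_dirichlet(K, np.zeros(space.n_nodes, dtype=complex), fixed, vals)

    # terminal current from the reaction at constrained nodes; for the unit
    # solve, I = V^H K V, whose real part is twice the dissipated power
    reactions = K @ V
    I_t = complex(reactions[terminal_nodes].sum())
    P_unit = 0.5 * I_t.real
    if not np.isfinite(P_unit) or P_unit <= 0:
        raise ElectricSolverError("terminal delivers no power (disconnected ground?)")

    scale = 1.0 if power is None else float(np.sqrt(power / P_unit))
    V = V * scale
    tri = space.mesh.triangles
    Ve = V[tri]
    Er = -(space.grad_r * Ve).sum(axis=1)
    Ez = -(space.grad_z * Ve).sum(axis=1)
    E = np.column_stack([Er, Ez])
    J = sigma_c[:, None] * E
    e2 = np.abs(Er) ** 2 + np.abs(Ez) ** 2
    Q_rh = 0.5 * np.real(sigma_c) * e2
    dissipated = float((Q_rh * space.volume).sum())
    return ElectricSolution(
        V=V,
        E=E,
        J=J,
        Q_rh=Q_rh,
        terminal_voltage=scale + 0j,
        terminal_current=I_t * scale,
        impedance=compute_impedance_from_terminal(1.0 + 0j, I_t),
        dissipated_power=dissipated,
    )


def compute_impedance_from_terminal(V_t: complex, I_t: complex) -> float:
    if I_t == 0:
        raise ElectricSolverError("zero terminal current")
    return float(abs(V_t / I_t))


def compute_impedance(solution: ElectricSolution) -> float:
    """Terminal impedance magnitude |V_t / I_t| in ohms."""
    return compute_impedance_from_terminal(solution.terminal_voltage, solution.terminal_current)


def terminal_and_ground_nodes(mesh: Mesh):
    """Node sets for the ablation problem: whole platinum tip + outer boundary.

    The tip is a near-perfect conductor, so every node of the tip subdomain is
    constrained to the terminal potential (equipotential electrode); external
    boundary edges are grounded.
    """
    tip = mesh.subdomain_nodes("catheter_tip")
    ext = np.unique(mesh.edges_by_tag("external"))
    return tip, np.setdiff1d(ext, tip)
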