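"""Configuration files, result serialization, VTK export and oracle fixtures.

Temperatures are degC in every user-facing file and Kelvin inside the
solvers; the conversion happens only at this module's boundary.  CSV output
uses comma separators, '.' decimals, a header row, UTF-8 and LF endings, with
a fixed float format so identical configurations produce byte-identical
payloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import Mesh, triangulate_grid
from .runner import (
    METRIC_COLUMNS,
    ConfigurationError,
    SimulationConfig,
    SimulationResult,
    _metrics_row,
)

FLOAT_FMT = "%.6f"
_CONFIG_KEYS = {f.name for f in fields(SimulationConfig)}


def load_config(path) -> SimulationConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def dump_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Inventory of one output directory with content checksums."""

    config: dict
    mesh_stats: dict
    files: dict  # name -> sha256

    def verify(self, out_dir) -> bool:
        out_dir = Path(out_dir)
        for name, digest in self.files.items():
            p = out_dir / name
            if not p.exists() or _sha256(p) != digest:
                return False
        return True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_results(result, out_dir) -> RunManifest:
    """Write a SimulationResult (or sweep DataFrame) and its manifest.

    A single run produces a lesion-metrics CSV, one line-profile CSV per
    output step and the impedance trace; a sweep produces one metrics table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    if isinstance(result, pd.DataFrame):
        path = out_dir / "sweep_metrics.csv"
        _write_csv(result, path)
        written.append(path)
        config_echo, mesh_stats = {}, {}
    elif isinstance(result, SimulationResult):
        metrics = pd.DataFrame([_metrics_row(result.config, result)], columns=METRIC_COLUMNS)
        path = out_dir / "lesion_metrics.csv"
        _write_csv(metrics, path)
        written.append(path)

        trace = pd.DataFrame(result.impedance_trace, columns=["time_s", "impedance_ohm"])
        path = out_dir / "impedance_trace.csv"
        _write_csv(trace, path)
        written.append(path)

        for rec in result.records:
            df = pd.DataFrame(
                {
                    "arc_mm": result.line.arc_mm,
                    "subdomain": result.line.labels,
                    "T_C": rec.T_line_C,
                    "fraction_pct": rec.fraction_line,
                }
            )
            path = out_dir / f"profile_t{rec.time:06.2f}s.csv"
            _write_csv(df, path)
            written.append(path)
        config_echo = result.config.to_dict()
        mesh_stats = result.mesh_stats
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")

    from . import __version__

    manifest = RunManifest(
        config=config_echo,
        mesh_stats=mesh_stats,
        files={p.name: _sha256(p) for p in written},
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config": manifest.config,
                "mesh_stats": manifest.mesh_stats,
                "files": manifest.files,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return manifest


def write_vtk(mesh: Mesh, point_data: dict, path) -> None:
    """Legacy ASCII VTK export of the triangle mesh with nodal fields."""
    lines = [
        "# vtk DataFile Version 3.0",
        "ablaheat axisymmetric mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9e} {z:.9e} 0.0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for tri in mesh.triangles:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in np.asarray(values, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# analytic-oracle fixtures
# ---------------------------------------------------------------------------

def _ensure_ccw(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    areas = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    flip = areas < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _slab_fixture() -> dict:
    """1D slab in z (constant fat properties) with Fourier-series reference.

    Both faces are clamped at body temperature and the interior starts 1 K
    hotter; the axisymmetric solve on an r-offset strip must reproduce the
    plane-wall series solution.
    """
    from .materials import material_table

    L = 2e-3  # slab thickness, m
    props = material_table("fat")
    k, rho, cp = props.k(310.15), props.rho(310.15), props.cp
    alpha = k / (rho * cp)
    rpts = np.linspace(10e-3, 11e-3, 4)
    zpts = np.linspace(0.0, L, 81)
    R, Z = np.meshgrid(rpts, zpts, indexing="ij")
    nodes, tris, _ = triangulate_grid(R, Z)
    mesh = Mesh(
        nodes=nodes,
        triangles=_ensure_ccw(nodes, tris),
        element_subdomain=np.full(len(tris), "fat", dtype="<U16"),
        boundary_tags={},
        geometry=None,
    )

    def reference(z, t, n_terms=200):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for n in range(1, n_terms + 1, 2):
            out += (4.0 / (n * np.pi)) * np.sin(n * np.pi * z / L) * np.exp(
                -alpha * (n * np.pi / L) ** 2 * t
            )
        return out

    face_nodes = np.flatnonzero((np.abs(nodes[:, 1]) < 1e-12) | (np.abs(nodes[:, 1] - L) < 1e-12))
    return {
        "kind": "slab_1d",
        "mesh": mesh,
        "length": L,
        "diffusivity": alpha,
        "face_nodes": face_nodes,
        "reference": reference,
    }


def _concentric_fixture() -> dict:
    """Concentric hemispherical electrodes in a uniform conductor.

    The analytic resistance between hemispheres of radii a < b in a medium of
    conductivity sigma (insulated equatorial plane) is
    R = (1/a - 1/b) / (2 pi sigma).
    """
    a, b, sigma = 2e-3, 40e-3, 0.5
    n_rho, n_theta = 90, 48
    rho = a * (b / a) ** np.linspace(0.0, 1.0, n_rho)  # geometric grading
    theta = np.linspace(0.0, np.pi / 2, n_theta)
    P, T = np.meshgrid(rho, theta, indexing="ij")
    R = P * np.sin(T)
    Z = P * np.cos(T)
    nodes, tris, _ = triangulate_grid(R, Z)
    # collapse duplicate apex nodes is unnecessary: theta=0 column lies on the
    # axis with distinct radii, no degenerate cells appear for theta>0; the
    # first theta interval produces thin but valid triangles
    tris = _ensure_ccw(nodes, tris)
    p = nodes[tris]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    keep = areas > 1e-18
    mesh = Mesh(
        nodes=nodes,
        triangles=tris[keep],
        element_subdomain=np.full(int(keep.sum()), "medium", dtype="<U16"),
        boundary_tags={},
        geometry=None,
    )
    radii = np.hypot(nodes[:, 0], nodes[:, 1])
    inner = np.flatnonzero(np.abs(radii - a) < 1e-9)
    outer = np.flatnonzero(np.abs(radii - b) < 1e-9)
    return {
        "kind": "concentric_electrodes",
        "mesh": mesh,
        "sigma": sigma,
        "inner_nodes": inner,
        "outer_nodes": outer,
        "resistance": (1.0 / a - 1.0 / b) / (2.0 * np.pi * sigma),
    }


def _damage_fixture() -> dict:
    """Constant-temperature Arrhenius closed-form references."""
    from .materials import FAT_DAMAGE, GAS_CONSTANT, TISSUE_DAMAGE

    cases = []
    for params, label in ((TISSUE_DAMAGE, "tissue"), (FAT_DAMAGE, "fat")):
        for T in (310.15, 330.15, 353.15, 373.15):
            for t in (1.0, 5.0, 20.0):
                k = params.A * np.exp(-params.dE / (GAS_CONSTANT * T))
                cases.append(
                    {
                        "label": label,
                        "A": params.A,
                        "dE": params.dE,
                        "T": T,
                        "t": t,
                        "alpha_ref": 1.0 - np.exp(-k * t),
                    }
                )
    return {"kind": "constant_T_damage", "cases": cases}


def make_oracle_fixture(kind: str) -> dict:
    """Purpose-built mesh/parameter bundles with closed-form reference values."""
    builders = {
        "slab_1d": _slab_fixture,
        "concentric_electrodes": _concentric_fixture,
        "constant_T_damage": _damage_fixture,
    }
    if kind not in builders:
        raise ConfigurationError(f"unknown fixture kind {kind!r}; expected one of {sorted(builders)}")
    return builders[kind]()
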