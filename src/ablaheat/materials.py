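"""Electrical and thermal material properties per subdomain.

All properties are SI (S/m, W/(m K), J/(kg K), kg/m3) and temperatures are
Kelvin.  Tissue electrical conductivity, thermal conductivity and density are
temperature dependent; everything else is constant.  Outside the stated
validity range of a temperature-dependent property the value is clamped to the
nearest endpoint (ablation at high power drives tissue past the upper end of
the fitted range, so a defined extrapolation is mandatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

GAS_CONSTANT = 8.314  # J/(mol K)
BODY_TEMP_K = 310.15  # 37 degC
EPS0 = 8.8541878128e-12  # F/m

#: subdomains treated as perfused, damage-accumulating tissue
TISSUE_LABELS = frozenset(
    {"thoracic_outer", "thoracic", "myocardium", "fat", "esophagus"}
)

#: subdomains that participate in the thermal problem (blood is replaced by
#: convective boundary conditions and carries only electrical properties)
THERMAL_LABELS = frozenset(
    {
        "thoracic_outer",
        "thoracic",
        "catheter_body",
        "catheter_tip",
        "myocardium",
        "fat",
        "esophagus",
        "device_wall",
        "device_water",
    }
)

ALL_LABELS = frozenset(THERMAL_LABELS | {"blood"})


def tissue_sigma(T):
    """Tissue electrical conductivity sigma_a(T) in S/m.

    Piecewise linear in temperature: a rising branch up to 348.15 K (ionic
    mobility increases with temperature), a plateau at 0.735 S/m to 358.15 K,
    a gentle decline to 378.15 K as tissue desiccates, then a steep drop.
    The function is continuous except at 378.15 K where the printed pieces
    leave a step (0.665 -> 0.57); the step is kept as printed.  Clamped to
    [293.15, 388.15) endpoint values outside that range.
    """
    T = np.asarray(T, dtype=float)
    Tc = np.clip(T, 293.15, np.nextafter(388.15, -np.inf))
    out = np.where(
        Tc < 348.15,
        9e-3 * (Tc - 313.15) + 0.42,
        np.where(
            Tc < 358.15,
            9e-3 * (348.15 - 313.15) + 0.42,
            np.where(
                Tc < 378.15,
                -3.5e-3 * (Tc - 358.15) + 0.735,
                -52e-3 * (Tc - 378.15) + 0.57,
            ),
        ),
    )
    return out if out.ndim else float(out)


def tissue_k(T):
    """Tissue thermal conductivity k_a(T) in W/(m K), clamped to [276.15, 373.15)."""
    T = np.asarray(T, dtype=float)
    Tc = np.clip(T, 276.15, np.nextafter(373.15, -np.inf))
    out = 0.493 * (1.0 + 1.2e-3 * (Tc - 310.15))
    return out if out.ndim else float(out)


def tissue_rho(T):
    """Tissue density rho_a(T) in kg/m3, clamped to [276.15, 373.15)."""
    T = np.asarray(T, dtype=float)
    Tc = np.clip(T, 276.15, np.nextafter(373.15, -np.inf))
    num = 0.493 * (1.0 + 1.2e-3 * (Tc - 310.15))
    den = 3212.0 * (1.474e-7 * (1.0 + 3.39e-3 * (Tc - 310.15)))
    out = num / den
    return out if out.ndim else float(out)


def _const(value: float) -> Callable:
    def f(T):
        T = np.asarray(T, dtype=float)
        out = np.full_like(T, value)
        return out if out.ndim else float(out)

    return f


@dataclass(frozen=True)
class MaterialProps:
    """Per-subdomain material constants and property functions of T [K]."""

    sigma: Callable  # electric conductivity S/m
    eps_r: float  # relative permittivity
    k: Callable | None  # thermal conductivity W/(m K); None = not thermal
    cp: float | None  # heat capacity J/(kg K)
    rho: Callable | None  # density kg/m3


@dataclass(frozen=True)
class PerfusionParams:
    """Blood perfusion constants of the bioheat sink term.

    The perfusion rate carries no published value for this model and the
    ablation horizon is 20 s, so omega_b defaults to zero (perfusion off);
    the metabolic source is neglected.
    """

    rho_b: float = 1050.0
    cp_b: float = 3617.0
    omega_b: float = 0.0  # 1/s
    T_b: float = BODY_TEMP_K
    Q_met: float = 0.0  # W/m3


@dataclass(frozen=True)
class DamageParams:
    """Arrhenius injury kinetics: rate = A * exp(-dE / (R T))."""

    A: float  # frequency factor, 1/s
    dE: float  # activation energy, J/mol
    R: float = GAS_CONSTANT

    def rate(self, T):
        T = np.asarray(T, dtype=float)
        out = self.A * np.exp(-self.dE / (self.R * T))
        return out if out.ndim else float(out)


#: myocardium, esophagus and averaged thoracic tissue kinetics
TISSUE_DAMAGE = DamageParams(A=2.94e38, dE=2.596e5)
#: pericardial fat kinetics
FAT_DAMAGE = DamageParams(A=4.43e16, dE=1.3e5)

_TISSUE = MaterialProps(sigma=tissue_sigma, eps_r=8000.0, k=tissue_k, cp=3212.0, rho=tissue_rho)
_SILICONE = MaterialProps(sigma=_const(10e-12), eps_r=11.7, k=_const(130.0), cp=700.0, rho=_const(2329.0))
_PLATINUM = MaterialProps(sigma=_const(8.9e6), eps_r=1.0, k=_const(71.6), cp=133.0, rho=_const(21450.0))
_BLOOD = MaterialProps(sigma=_const(1.50), eps_r=2.2e4, k=None, cp=None, rho=None)
_FAT = MaterialProps(sigma=_const(0.5), eps_r=80.0, k=_const(0.21), cp=2348.0, rho=_const(911.0))
_WATER = MaterialProps(sigma=_const(5.5e-6), eps_r=75.0, k=_const(0.5), cp=4000.0, rho=_const(1000.0))

_TABLE = {
    "thoracic_outer": _TISSUE,
    "thoracic": _TISSUE,
    "myocardium": _TISSUE,
    "esophagus": _TISSUE,
    "catheter_body": _SILICONE,
    "device_wall": _SILICONE,
    "catheter_tip": _PLATINUM,
    "blood": _BLOOD,
    "fat": _FAT,
    "device_water": _WATER,
}


def material_table(label: str) -> MaterialProps:
    """Material properties for a subdomain label.

    Raises
    ------
    KeyError-free ``ValueError`` for unknown labels so configuration mistakes
    surface with a readable message.
    """
    try:
        return _TABLE[label]
    except KeyError:
        raise ValueError(f"unknown subdomain label: {label!r}") from None


def damage_params(label: str) -> DamageParams | None:
    """Arrhenius kinetics for a subdomain, or None for non-tissue."""
    if label not in ALL_LABELS:
        raise ValueError(f"unknown subdomain label: {label!r}")
    if label not in TISSUE_LABELS:
        return None
    return FAT_DAMAGE if label == "fat" else TISSUE_DAMAGE


@dataclass(frozen=True)
class MaterialSet:
    """Material table with optional per-(subdomain, property) overrides."""

    overrides: dict = field(default_factory=dict)

    def props(self, label: str) -> MaterialProps:
        base = material_table(label)
        key_fields = {}
        for (lab, prop), value in self.overrides.items():
            if lab != label:
                continue
            if prop not in ("sigma", "eps_r", "k", "cp", "rho"):
                raise ValueError(f"unknown material property: {prop!r}")
            key_fields[prop] = _const(float(value)) if prop in ("sigma", "k", "rho") else float(value)
        if not key_fields:
            return base
        from dataclasses import replace

        return replace(base, **key_fields)
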