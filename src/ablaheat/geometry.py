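"""Axisymmetric layered geometry of the ablation site.

The model is a 2D axisymmetric (r, z) slice.  z = 0 is the plane where the
catheter tip contacts the myocardium; z increases toward the blood pool, so
the tissue layers (myocardium, pericardial fat, esophagus and — when the
cooling device is present — device wall / water / wall) stack downward at
negative z.  The electrode indents the endocardial surface by the insertion
depth, leaving exactly the nominal myocardium thickness beneath the tip along
the axis.  A truncated thoracic-tissue padding surrounds the stack and carries
the far-field (grounded, insulated) boundary conditions.

All user-facing lengths are millimetres; internal coordinates are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MM = 1e-3
UM = 1e-6

#: (myocardium, fat, esophagus) thickness presets in mm per anatomy study
_STUDY_PRESETS = {
    1: (2.00, 1.00, 2.50),
    2: (1.50, 0.50, 2.50),
}


@dataclass(frozen=True)
class LayerStack:
    """Layer thicknesses and lateral extents, all in millimetres."""

    myocardium_thickness: float
    fat_thickness: float
    esophagus_thickness: float
    device_wall_thickness: float = 0.5
    water_layer_thickness: float = 11.0
    blood_chamber_height: float = 20.0
    radial_extent: float = 40.0
    outer_padding_thickness: float = 80.0

    def __post_init__(self):
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"LayerStack.{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class CatheterSpec:
    """Ablation catheter dimensions.

    The insertion depth is tied to the tip height (height / 25), matching the
    default 160 um indentation of a 4 mm tip.
    """

    tip_radius: float = 1.1665  # mm
    tip_height: float = 4.0  # mm
    body_radius: float = 1.1665  # mm
    body_length: float = 20.0  # mm

    def __post_init__(self):
        for name, value in vars(self).items():
            if not value > 0:
                raise ValueError(f"CatheterSpec.{name} must be strictly positive, got {value}")

    @property
    def insertion_depth(self) -> float:
        """Indentation of the tip into the myocardium, mm (tip_height / 25)."""
        return self.tip_height / 25.0


@dataclass(frozen=True)
class Geometry:
    """Resolved axisymmetric layout: layer stack + catheter + z interfaces (m)."""

    study: int
    protected: bool
    layers: LayerStack
    catheter: CatheterSpec
    # z coordinates in metres, z=0 at the tip contact plane
    z_interfaces: dict = field(default_factory=dict)

    @property
    def tissue_span_mm(self) -> float:
        """Thickness of tissue crossed by the axial sampling line, mm."""
        L = self.layers
        return L.myocardium_thickness + L.fat_thickness + L.esophagus_thickness

    def subdomains(self) -> tuple:
        """Labels present in this layout."""
        base = (
            "thoracic_outer",
            "thoracic",
            "catheter_body",
            "catheter_tip",
            "blood",
            "myocardium",
            "fat",
            "esophagus",
        )
        if self.protected:
            return base + ("device_wall", "device_water")
        return base


def build_geometry(
    study: int,
    protected: bool,
    layer_overrides: dict | None = None,
    catheter_overrides: dict | None = None,
) -> Geometry:
    """Assemble the layered layout for one anatomy preset.

    Study 1 models a thicker posterior wall (2.00 / 1.00 / 2.50 mm of
    myocardium / fat / esophagus); Study 2 a thin wall (1.50 / 0.50 / 2.50 mm).
    ``protected`` adds the cooling-device wall/water/wall layers beneath the
    esophagus (wall + water + wall spanning the 12 mm device diameter); the
    control (collapsed esophagus) layout omits them.
    """
    if study not in _STUDY_PRESETS:
        raise ValueError(f"unknown study preset {study!r}; expected 1 or 2")
    myo, fat, eso = _STUDY_PRESETS[study]
    layers = LayerStack(myocardium_thickness=myo, fat_thickness=fat, esophagus_thickness=eso)
    if layer_overrides:
        layers = replace(layers, **dict(layer_overrides))
    catheter = CatheterSpec()
    if catheter_overrides:
        catheter = replace(catheter, **dict(catheter_overrides))

    ins = catheter.insertion_depth * MM
    z = {
        "myocardium_top": ins,  # endocardial surface away from the indented tip
        "tip_bottom": 0.0,
        "myo_fat": -layers.myocardium_thickness * MM,
        "fat_eso": -(layers.myocardium_thickness + layers.fat_thickness) * MM,
        "eso_bottom": -(layers.myocardium_thickness + layers.fat_thickness + layers.esophagus_thickness) * MM,
        "blood_top": ins + layers.blood_chamber_height * MM,
        "tip_top": catheter.tip_height * MM,
    }
    z["body_top"] = min(z["tip_top"] + catheter.body_length * MM, z["blood_top"])
    if protected:
        z["wall1_bottom"] = z["eso_bottom"] - layers.device_wall_thickness * MM
        z["water_bottom"] = z["wall1_bottom"] - layers.water_layer_thickness * MM
        z["wall2_bottom"] = z["water_bottom"] - layers.device_wall_thickness * MM
        z["stack_bottom"] = z["wall2_bottom"]
    else:
        z["stack_bottom"] = z["eso_bottom"]
    return Geometry(study=study, protected=protected, layers=layers, catheter=catheter, z_interfaces=z)
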