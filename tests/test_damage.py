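import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ablaheat import make_oracle_fixture
from ablaheat.damage import (
    DamageState,
    fraction_of_damage,
    integrate_damage_step,
    lesion_depth,
    line_metrics,
)
from ablaheat.materials import FAT_DAMAGE, TISSUE_DAMAGE
from ablaheat.mesh import SamplingLine


def integrate_constant_T(params, T, t_total, n_steps):
    A = np.array([params.A])
    dE = np.array([params.dE])
    damage = DamageState(alpha=np.zeros(1))
    dt = t_total / n_steps
    T_arr = np.array([T])
    for _ in range(n_steps):
        damage = integrate_damage_step(damage, T_arr, T_arr, dt, A, dE)
    return damage.alpha[0]


class TestArrheniusIntegration:
    def test_constant_temperature_closed_form_suite(self):
        """Stepping at constant T reproduces alpha = 1 - exp(-k t) to 1e-6."""
        fx = make_oracle_fixture("constant_T_damage")
        for case in fx["cases"]:
            params = TISSUE_DAMAGE if case["label"] == "tissue" else FAT_DAMAGE
            alpha = integrate_constant_T(params, case["T"], case["t"], 200)
            assert alpha == pytest.approx(case["alpha_ref"], rel=1e-6, abs=1e-300)

    def test_body_temperature_myocardium_20s(self):
        # k(310.15 K) for tissue kinetics gives alpha ~ 1.1e-4 over 20 s
        alpha = integrate_constant_T(TISSUE_DAMAGE, 310.15, 20.0, 200)
        k = TISSUE_DAMAGE.rate(310.15)
        assert alpha == pytest.approx(1.0 - np.exp(-k * 20.0), rel=1e-9)
        assert alpha == pytest.approx(1.1e-4, rel=0.05)

    def test_boiling_fat_20s(self):
        alpha = integrate_constant_T(FAT_DAMAGE, 373.15, 20.0, 400)
        assert alpha == pytest.approx(0.43, abs=0.01)

    def test_zero_rate_identity(self):
        damage = DamageState(alpha=np.array([0.3]))
        out = integrate_damage_step(
            damage, np.array([310.0]), np.array([310.0]), 1.0,
            np.array([0.0]), np.array([1e5]),
        )
        assert out.alpha[0] == pytest.approx(0.3, rel=1e-14)

    def test_mask_freezes_non_tissue_nodes(self):
        damage = DamageState(alpha=np.zeros(2))
        T = np.array([360.0, 360.0])
        out = integrate_damage_step(
            damage, T, T, 1.0,
            np.full(2, TISSUE_DAMAGE.A), np.full(2, TISSUE_DAMAGE.dE),
            mask=np.array([True, False]),
        )
        assert out.alpha[0] > 0
        assert out.alpha[1] == 0

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=300.0, max_value=390.0),
        st.floats(min_value=300.0, max_value=390.0),
        st.floats(min_value=0.0, max_value=0.999),
    )
    def test_alpha_monotone_nondecreasing(self, T0, T1, a0):
        damage = DamageState(alpha=np.array([a0]))
        out = integrate_damage_step(
            damage, np.array([T0]), np.array([T1]), 0.1,
            np.array([TISSUE_DAMAGE.A]), np.array([TISSUE_DAMAGE.dE]),
        )
        assert out.alpha[0] >= a0
        assert out.alpha[0] <= 1.0


class TestFractionOfDamage:
    @pytest.mark.parametrize("alpha, expected", [(1.2, 100.0), (0.0, 0.0), (0.0257, 2.57)])
    def test_clamped_percentage(self, alpha, expected):
        damage = DamageState(alpha=np.array([alpha]))
        assert fraction_of_damage(damage)[0] == pytest.approx(expected)


def make_line(arc, labels, t_myo=2.0, t_fat=1.0, t_eso=2.5):
    return SamplingLine(
        arc_mm=np.asarray(arc, dtype=float),
        z_m=-np.asarray(arc, dtype=float) * 1e-3,
        labels=np.asarray(labels),
        interfaces={"myo_fat": t_myo, "fat_eso": t_myo + t_fat, "eso_end": t_myo + t_fat + t_eso},
    )


@pytest.fixture
def simple_line():
    arc = np.round(np.arange(0.0, 5.51, 0.05), 10)
    labels = np.where(arc < 2.0, "myocardium", np.where(arc < 3.0, "fat", "esophagus"))
    return make_line(arc, labels)


class TestLesionDepth:
    def test_all_below_threshold_gives_zero(self, simple_line):
        depth = lesion_depth(simple_line, np.full(len(simple_line.arc_mm), 1.0))
        assert depth == 0.0

    def test_linear_ramp_crossing(self, simple_line):
        # 10% at the fat-esophagus interface decaying linearly to 0% at 2.5 mm
        frac = np.zeros(len(simple_line.arc_mm))
        eso = simple_line.mask("esophagus")
        depth_in_eso = simple_line.arc_mm[eso] - 3.0
        frac[eso] = np.maximum(10.0 * (1 - depth_in_eso / 2.5), 0.0)
        assert lesion_depth(simple_line, frac) == pytest.approx(2.0, abs=1e-6)

    def test_full_thickness_capped(self, simple_line):
        frac = np.full(len(simple_line.arc_mm), 50.0)
        assert lesion_depth(simple_line, frac) == pytest.approx(2.5)

    def test_misaligned_profile_rejected(self, simple_line):
        with pytest.raises(ValueError, match="aligned"):
            lesion_depth(simple_line, np.zeros(3))


class TestLineMetrics:
    def test_uniform_body_temperature_all_zero(self, simple_line):
        n = len(simple_line.arc_mm)
        m = line_metrics(simple_line, np.full(n, 310.15), np.zeros(n))
        assert m.peak_temperature == pytest.approx(37.0)
        assert m.esophageal_lesion_depth == 0.0
        assert m.max_esophageal_fraction == 0.0
        assert m.myocardial_max_fraction == 0.0

    def test_metrics_track_layer_maxima(self, simple_line):
        n = len(simple_line.arc_mm)
        T = np.full(n, 310.15)
        frac = np.zeros(n)
        frac[simple_line.mask("myocardium")] = 80.0
        frac[simple_line.mask("esophagus")] = 12.0
        T[10] = 360.15
        m = line_metrics(simple_line, T, frac)
        assert m.peak_temperature == pytest.approx(87.0)
        assert m.myocardial_max_fraction == 80.0
        assert m.max_esophageal_fraction == 12.0
        assert m.esophageal_lesion_depth == pytest.approx(2.5)
        assert m.myocardial_lesion_depth == pytest.approx(2.0, abs=0.01)
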