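import numpy as np
import pytest
from hypothesis import given, strategies as st

from semdust.edx_measurement import (
    SRM_INTRINSIC,
    BeamConfig,
    measure_batch,
    measure_on_planchette,
    measure_particle,
    srm_flake_thickness,
    srm_like_population,
    substrate_mixing_fraction,
)
from semdust.particle_model import default_substrate

from .conftest import make_particle


class TestMixingFraction:
    def test_thick_particle_limit(self):
        assert substrate_mixing_fraction(10.0, 2.0) == 1.0

    def test_saturates_at_depth(self):
        assert substrate_mixing_fraction(2.0, 2.0) == 1.0

    def test_thin_limit(self):
        assert substrate_mixing_fraction(1e-9, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp(self):
        assert substrate_mixing_fraction(1.0, 2.0) == pytest.approx(0.5)

    @given(
        t1=st.floats(min_value=1e-6, max_value=100.0),
        t2=st.floats(min_value=1e-6, max_value=100.0),
        d=st.floats(min_value=1e-3, max_value=50.0),
    )
    def test_monotone_in_thickness(self, t1, t2, d):
        lo, hi = sorted([t1, t2])
        assert substrate_mixing_fraction(lo, d) <= substrate_mixing_fraction(hi, d)

    @pytest.mark.parametrize("t,d", [(0.0, 2.0), (-1.0, 2.0), (1.0, 0.0), (1.0, -2.0)])
    def test_nonpositive_rejected(self, t, d):
        with pytest.raises(ValueError):
            substrate_mixing_fraction(t, d)


class TestMeasureParticle:
    def test_zero_noise_thick_returns_intrinsic(self, quiet_beam, rng):
        p = make_particle(L=10.0, thickness=5.0, C=82.0, O=17.0, Si=1.0)
        m = measure_particle(p, quiet_beam, default_substrate(), rng)
        assert m.measured_composition.values == pytest.approx(
            p.intrinsic_composition.values, abs=1e-12
        )

    def test_zero_noise_thin_returns_substrate(self, quiet_beam, rng):
        p = make_particle(L=10.0, thickness=1e-9, C=10.0, O=80.0, Si=10.0)
        m = measure_particle(p, quiet_beam, default_substrate(), rng)
        assert m.measured_composition.carbon == pytest.approx(94.0, abs=1e-6)
        assert m.measured_composition.oxygen == pytest.approx(6.0, abs=1e-6)

    def test_half_mix_hand_arithmetic(self, quiet_beam, rng):
        # f=0.5 of (82,17,1) with substrate (94,6):
        # C = .5*82+.5*94 = 88; O = .5*17+.5*6 = 11.5; Si = 0.5; sums to 100
        p = make_particle(L=10.0, thickness=1.0, C=82.0, O=17.0, Si=1.0)
        m = measure_particle(p, quiet_beam, default_substrate(), rng)
        assert m.measured_composition.carbon == pytest.approx(88.0, abs=1e-12)
        assert m.measured_composition.oxygen == pytest.approx(11.5, abs=1e-12)
        assert m.measured_composition["Si"] == pytest.approx(0.5, abs=1e-12)

    def test_requires_thickness(self, beam, rng):
        p = make_particle(thickness=None)
        with pytest.raises(ValueError, match="thickness"):
            measure_particle(p, beam, default_substrate(), rng)

    def test_zero_noise_convex_hull(self, quiet_beam, rng):
        # measured C must lie between intrinsic and substrate C
        sub = default_substrate()
        for thickness in (0.1, 0.5, 1.0, 1.7, 2.0):
            p = make_particle(L=10.0, thickness=thickness, C=60.0, O=30.0, Si=10.0)
            m = measure_particle(p, quiet_beam, sub, rng)
            assert 60.0 - 1e-9 <= m.measured_composition.carbon <= 94.0 + 1e-9

    def test_morphology_passthrough(self, quiet_beam, rng):
        p = make_particle()
        m = measure_particle(p, quiet_beam, default_substrate(), rng)
        assert m.observed_morphology is p.morphology
        assert m.decision is None

    def test_morphology_confusion_applies(self, rng):
        beam = BeamConfig(noise_2sigma_atpct=0.0, morphology_confusion_prob=1.0)
        p = make_particle()
        m = measure_particle(p, beam, default_substrate(), rng)
        assert m.observed_morphology is not p.morphology


class TestPlanchette:
    def test_zero_noise_is_identity(self, quiet_beam, rng):
        p = make_particle(thickness=0.01, L=1.0, C=82.0, O=17.0, Si=1.0)
        m = measure_on_planchette(p, quiet_beam, rng)
        assert m.measured_composition.values == pytest.approx(
            p.intrinsic_composition.values, abs=1e-12
        )

    def test_population_mean_carbon(self, beam, rng):
        # reference-material mean measured C on a carbon-free mount: 82 +- 0.5
        n = 10_000
        intr = np.tile(SRM_INTRINSIC.as_array(), (n, 1))
        meas = measure_batch(
            intr, np.ones(n), SRM_INTRINSIC.as_array(), beam.noise_2sigma_atpct / 2, rng
        )
        assert abs(meas[:, 0].mean() - 82.0) < 0.5

    def test_agrees_with_tape_at_f1(self, rng):
        # planchette/tape consistency: f=1 makes the two routes identical
        beam = BeamConfig(noise_2sigma_atpct=0.0)
        p = make_particle(L=10.0, thickness=5.0, C=70.0, O=25.0, Si=5.0)
        on_tape = measure_particle(p, beam, default_substrate(), rng)
        on_be = measure_on_planchette(p, beam, rng)
        assert on_tape.measured_composition == on_be.measured_composition

    def test_noise_variance_closure_corrected(self, rng):
        # Independent oracle: direct simulation of the stated law (noise on
        # C/O then closure).  Closure shrinks var(C) from (3/2)^2 = 2.25 to
        # ~1.59 for the (82,17,1) composition; both routes must agree.
        n = 60_000
        sd = 1.5  # noise_2sigma = 3
        oracle_rng = np.random.default_rng(777)
        raw = np.tile(SRM_INTRINSIC.as_array(), (n, 1))
        raw[:, :2] += oracle_rng.normal(0.0, sd, size=(n, 2))
        raw = np.clip(raw, 0.0, None)
        oracle = 100.0 * raw / raw.sum(axis=1, keepdims=True)
        var_oracle = oracle[:, 0].var()

        intr = np.tile(SRM_INTRINSIC.as_array(), (n, 1))
        meas = measure_batch(intr, np.ones(n), SRM_INTRINSIC.as_array(), sd, rng)
        var_impl = meas[:, 0].var()

        assert var_impl == pytest.approx(var_oracle, rel=0.05)
        # linearized closure prediction: 2.25 * ((1-c)^2 + c^2), c = 0.82
        assert var_impl == pytest.approx(2.25 * (0.18**2 + 0.82**2), rel=0.05)

    def test_noise_variance_scales_quadratically(self, rng):
        n = 40_000
        intr = np.tile(SRM_INTRINSIC.as_array(), (n, 1))
        v1 = measure_batch(intr, np.ones(n), intr[0], 0.75, rng)[:, 0].var()
        v2 = measure_batch(intr, np.ones(n), intr[0], 1.5, rng)[:, 0].var()
        assert v2 / v1 == pytest.approx(4.0, rel=0.1)


class TestSubstrateDrift:
    def test_small_vs_large_calibration(self, beam, rng):
        # on-tape means: ~93 At.% C below the size limit, ~87 above (+-1.4)
        sub = default_substrate().as_array()
        for size_range, target in (("small", 93.0), ("large", 87.0)):
            L, t = srm_like_population(20_000, rng, size_range)
            f = np.minimum(1.0, t / beam.penetration_depth_um)
            intr = np.tile(SRM_INTRINSIC.as_array(), (len(L), 1))
            meas = measure_batch(intr, f, sub, beam.noise_2sigma_atpct / 2, rng)
            assert abs(meas[:, 0].mean() - target) < 1.4, size_range

    def test_drift_direction(self, beam, rng):
        # mean measured C is strictly higher for sub-limit particles when
        # intrinsic C < substrate C
        sub = default_substrate().as_array()
        means = {}
        for size_range in ("small", "large"):
            L, t = srm_like_population(5_000, rng, size_range)
            f = np.minimum(1.0, t / beam.penetration_depth_um)
            intr = np.tile(SRM_INTRINSIC.as_array(), (len(L), 1))
            meas = measure_batch(intr, f, sub, beam.noise_2sigma_atpct / 2, rng)
            means[size_range] = meas[:, 0].mean()
        assert means["small"] > means["large"]

    def test_flake_thickness_never_exceeds_length(self):
        L = np.geomspace(0.1, 200.0, 500)
        t = srm_flake_thickness(L)
        assert np.all(t <= L + 1e-12)
        assert np.all(np.diff(t) > 0)  # monotone in L

    def test_population_validation(self, rng):
        with pytest.raises(ValueError, match="size_range"):
            srm_like_population(10, rng, "medium")
        L_small, _ = srm_like_population(1000, rng, "small")
        assert np.all((L_small >= 0.5) & (L_small <= 5.0))
        L_large, _ = srm_like_population(1000, rng, "large")
        assert np.all(L_large > 5.0)


class TestBeamConfig:
    def test_defaults(self, beam):
        assert beam.accelerating_kv == 15.0
        assert beam.penetration_depth_um == 2.0
        assert beam.noise_2sigma_atpct == 1.4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"accelerating_kv": 0.0},
            {"penetration_depth_um": -1.0},
            {"noise_2sigma_atpct": -0.1},
            {"morphology_confusion_prob": 1.5},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            BeamConfig(**kwargs)
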