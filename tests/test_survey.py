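import itertools

import numpy as np
import pytest

from semdust.particle_model import ProtocolConfig, StopCheck
from semdust.survey import (
    AreaPosition,
    RegionExhausted,
    StopReason,
    layout_area_positions,
    order_particles_in_fov,
    run_survey,
)
from semdust.synthetic_dust import SampleConfig, _mineral_spec, generate_sample

from .conftest import make_particle


def rect_overlap(a: AreaPosition, b: AreaPosition) -> float:
    dx = min(a.x_mm + a.fov_width_mm / 2, b.x_mm + b.fov_width_mm / 2) - max(
        a.x_mm - a.fov_width_mm / 2, b.x_mm - b.fov_width_mm / 2
    )
    dy = min(a.y_mm + a.fov_height_mm / 2, b.y_mm + b.fov_height_mm / 2) - max(
        a.y_mm - a.fov_height_mm / 2, b.y_mm - b.fov_height_mm / 2
    )
    return max(dx, 0.0) * max(dy, 0.0)


class TestLayout:
    def test_nine_positions_with_expected_area(self, protocol):
        positions = layout_area_positions(8.0, 8.0, 1, protocol)
        assert len(positions) == 9
        total = sum(p.area_mm2 for p in positions)
        assert total == pytest.approx(9 * 0.066, rel=1e-12)  # 0.594 mm^2

    def test_positions_pairwise_non_overlapping(self, protocol):
        positions = layout_area_positions(8.0, 8.0, 1, protocol)
        for a, b in itertools.combinations(positions, 2):
            assert rect_overlap(a, b) == 0.0

    def test_positions_inside_region(self, protocol):
        for p in layout_area_positions(8.0, 8.0, 1, protocol):
            assert 0.0 <= p.x_mm - p.fov_width_mm / 2
            assert p.x_mm + p.fov_width_mm / 2 <= 8.0
            assert 0.0 <= p.y_mm - p.fov_height_mm / 2
            assert p.y_mm + p.fov_height_mm / 2 <= 8.0

    def test_sets_do_not_overlap(self, protocol):
        set1 = layout_area_positions(8.0, 8.0, 1, protocol)
        set2 = layout_area_positions(8.0, 8.0, 2, protocol)
        for a, b in itertools.product(set1, set2):
            assert rect_overlap(a, b) == 0.0

    def test_deterministic(self, protocol):
        assert layout_area_positions(8.0, 8.0, 3, protocol) == layout_area_positions(
            8.0, 8.0, 3, protocol
        )

    def test_region_smaller_than_grid_rejected(self, protocol):
        with pytest.raises(ValueError, match="cannot hold"):
            layout_area_positions(0.1, 0.1, 1, protocol)

    def test_region_exhausted(self, protocol):
        # 8x8 region with 4 mm tiles holds exactly 4 sets
        layout_area_positions(8.0, 8.0, 4, protocol)
        with pytest.raises(RegionExhausted):
            layout_area_positions(8.0, 8.0, 5, protocol)


def fov_at_origin(width=1.0) -> AreaPosition:
    return AreaPosition(
        set_index=1, index=1, x_mm=0.0, y_mm=0.0, fov_width_mm=width, fov_height_mm=width
    )


class TestOrdering:
    def test_anticlockwise_from_east(self):
        pos = fov_at_origin()
        pts = {
            "E": (0.2, 0.0),
            "N": (0.0, 0.2),
            "W": (-0.2, 0.0),
            "S": (0.0, -0.2),
        }
        particles = [
            make_particle(pid=name, x=x, y=y, L=10.0) for name, (x, y) in pts.items()
        ]
        ordered = order_particles_in_fov(particles, pos, 5.0)
        assert [p.id for p in ordered] == ["E", "N", "W", "S"]

    def test_radius_breaks_angle_ties(self):
        pos = fov_at_origin()
        far = make_particle(pid="far", x=0.4, y=0.0, L=10.0)
        near = make_particle(pid="near", x=0.2, y=0.0, L=10.0)
        ordered = order_particles_in_fov([far, near], pos, 5.0)
        assert [p.id for p in ordered] == ["near", "far"]

    def test_id_breaks_full_ties(self):
        pos = fov_at_origin()
        a = make_particle(pid="a", x=0.2, y=0.0, L=10.0)
        b = make_particle(pid="b", x=0.2, y=0.0, L=10.0)
        assert [p.id for p in order_particles_in_fov([b, a], pos, 5.0)] == ["a", "b"]

    def test_sub_limit_particles_excluded(self):
        pos = fov_at_origin()
        particles = [
            make_particle(pid=f"s{i}", x=0.1 * i, y=0.0, L=4.0, thickness=1.0)
            for i in range(1, 4)
        ]
        assert order_particles_in_fov(particles, pos, 5.0) == []

    def test_boundary_size_excluded(self):
        pos = fov_at_origin()
        particles = [make_particle(pid="edge", x=0.1, y=0.0, L=5.0, thickness=1.0)]
        assert order_particles_in_fov(particles, pos, 5.0) == []

    def test_outside_fov_excluded(self):
        pos = fov_at_origin(width=0.2)
        particles = [make_particle(pid="out", x=0.5, y=0.5, L=10.0)]
        assert order_particles_in_fov(particles, pos, 5.0) == []


def mineral_only_sample(loading: float, seed: int = 0, region=4.0):
    spec = _mineral_spec(weight=1.0)
    cfg = SampleConfig(
        class_specs=[spec],
        total_loading_per_mm2=loading,
        region_width_mm=region,
        region_height_mm=region,
        seed=seed,
    )
    return generate_sample(cfg)


class TestRunSurvey:
    def test_empty_sample(self, protocol):
        res = run_survey([], protocol, seed=1)
        assert res.n_analyzed == 0
        assert res.n_coal == 0
        assert res.stop_reason is StopReason.SAMPLE_EXHAUSTED

    def test_no_coal_sample_hits_total_limit(self, protocol):
        sample = mineral_only_sample(600.0, seed=2)
        res = run_survey(sample, protocol, seed=2, region_width_mm=4, region_height_mm=4)
        assert res.stop_reason is StopReason.TOTAL_LIMIT
        assert res.n_coal == 0
        assert res.n_analyzed >= protocol.stop_total

    def test_total_limit_overshoot_bounded_by_position(self, protocol):
        sample = mineral_only_sample(600.0, seed=3)
        res = run_survey(sample, protocol, seed=3, region_width_mm=4, region_height_mm=4)
        max_per_position = max(len(p.analyzed) for p in res.positions)
        assert res.n_analyzed <= protocol.stop_total + max_per_position

    def test_no_particle_analyzed_twice(self, protocol):
        sample = mineral_only_sample(300.0, seed=4)
        res = run_survey(sample, protocol, seed=4, region_width_mm=4, region_height_mm=4)
        ids = [m.particle.id for m in res.analyzed_particles()]
        assert len(ids) == len(set(ids))

    def test_counts_match_log(self, protocol):
        sample = mineral_only_sample(300.0, seed=5)
        res = run_survey(sample, protocol, seed=5, region_width_mm=4, region_height_mm=4)
        assert res.n_analyzed == len(res.analyzed_particles())
        assert res.n_area_positions_used == len(res.positions)

    def test_deterministic_rerun(self, protocol):
        sample = mineral_only_sample(300.0, seed=6)
        a = run_survey(sample, protocol, seed=6, region_width_mm=4, region_height_mm=4)
        b = run_survey(sample, protocol, seed=6, region_width_mm=4, region_height_mm=4)
        assert a == b

    def test_light_sample_exhausts_region(self, protocol):
        sample = mineral_only_sample(5.0, seed=7)
        res = run_survey(sample, protocol, seed=7, region_width_mm=4, region_height_mm=4)
        assert res.stop_reason is StopReason.SAMPLE_EXHAUSTED
        assert res.n_area_positions_used == 9  # one full set, region exhausted

    def test_stop_check_per_particle_stops_exactly_at_limit(self):
        protocol = ProtocolConfig(stop_check=StopCheck.PER_PARTICLE)
        sample = mineral_only_sample(600.0, seed=8)
        res = run_survey(sample, protocol, seed=8, region_width_mm=4, region_height_mm=4)
        assert res.stop_reason is StopReason.TOTAL_LIMIT
        assert res.n_analyzed == protocol.stop_total

    def test_stop_check_per_group_stops_at_group_boundary(self):
        protocol = ProtocolConfig(stop_check=StopCheck.PER_GROUP)
        sample = mineral_only_sample(600.0, seed=9)
        res = run_survey(sample, protocol, seed=9, region_width_mm=4, region_height_mm=4)
        assert res.stop_reason is StopReason.TOTAL_LIMIT
        # overshoot bounded by one group
        assert res.n_analyzed <= protocol.stop_total + protocol.group_size - 1

    def test_coal_limit_reached_on_coal_rich_sample(self, protocol):
        from semdust.synthetic_dust import coal_terminal_mixture

        cfg = coal_terminal_mixture(
            coal_fraction_above_limit=0.5, seed=10,
            region_width_mm=4.0, region_height_mm=4.0,
        )
        sample = generate_sample(cfg)
        res = run_survey(sample, protocol, seed=10, region_width_mm=4, region_height_mm=4)
        assert res.stop_reason is StopReason.COAL_LIMIT
        assert res.n_coal >= protocol.stop_coal

    def test_all_analyzed_particles_above_size_limit(self, protocol):
        sample = mineral_only_sample(300.0, seed=11)
        res = run_survey(sample, protocol, seed=11, region_width_mm=4, region_height_mm=4)
        assert all(
            m.particle.L_um > protocol.size_limit_um for m in res.analyzed_particles()
        )
        assert all(m.decision is not None for m in res.analyzed_particles())
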