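"""Stop-rule field-of-view survey of a particle table.

Mirrors the manual SEM protocol: nine area positions are laid out per set
inside a low-magnification parent tile; within each 500x field of view,
above-limit particles are selected anticlockwise from the FOV center in
groups of ten, measured, and classified; the survey stops once at least
five coal particles are identified or 100 total particles are analyzed,
whichever comes first.  When a set of positions is exhausted without
reaching a stop limit, a new non-overlapping set is laid out, up to a
configurable maximum, after which the sample is reported exhausted.

Stop rules are evaluated at area-position boundaries by default (work in
progress is completed first); per-group and per-particle evaluation are
available via ``ProtocolConfig.stop_check``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from ._seeding import stage_rng
from .classify import classify_particle
from .edx_measurement import BeamConfig, measure_particle
from .particle_model import (
    Composition,
    Decision,
    MeasuredParticle,
    ParticleRecord,
    ProtocolConfig,
)

__all__ = [
    "AreaPosition",
    "PositionLog",
    "SurveyResult",
    "StopReason",
    "RegionExhausted",
    "layout_area_positions",
    "order_particles_in_fov",
    "run_survey",
]


class StopReason(str, Enum):
    COAL_LIMIT = "coal_limit"
    TOTAL_LIMIT = "total_limit"
    SAMPLE_EXHAUSTED = "sample_exhausted"


class RegionExhausted(Exception):
    """No room on the tape region for another non-overlapping position set."""


@dataclass(frozen=True)
class AreaPosition:
    """One saved 500x field of view (axis-aligned rectangle)."""

    set_index: int
    index: int  # 1..n within the set
    x_mm: float  # center
    y_mm: float
    fov_width_mm: float
    fov_height_mm: float

    @property
    def area_mm2(self) -> float:
        return self.fov_width_mm * self.fov_height_mm

    def contains(self, x_mm: float, y_mm: float) -> bool:
        return (
            abs(x_mm - self.x_mm) <= self.fov_width_mm / 2.0
            and abs(y_mm - self.y_mm) <= self.fov_height_mm / 2.0
        )


def layout_area_positions(
    region_width_mm: float,
    region_height_mm: float,
    set_index: int,
    config: ProtocolConfig,
) -> list[AreaPosition]:
    """Nine FOVs on a 3x3 grid centered in the set's parent tile.

    Parent tiles tile the region row-major from the lower-left corner, so
    successive sets never overlap; deterministic given (region, set_index).
    Raises :class:`RegionExhausted` when ``set_index`` exceeds the number
    of tiles that fit, and ``ValueError`` for a region that cannot hold
    one set at all.
    """
    if set_index < 1:
        raise ValueError("set_index starts at 1")
    fov_side = math.sqrt(config.fov_area_mm2)
    n_grid = math.isqrt(config.n_area_positions_per_set)
    if n_grid * n_grid != config.n_area_positions_per_set:
        raise ValueError("n_area_positions_per_set must be a perfect square")
    tile = min(config.set_tile_mm, region_width_mm, region_height_mm)
    if tile < n_grid * fov_side:
        raise ValueError(
            f"region/tile of {tile:.3f} mm cannot hold a {n_grid}x{n_grid} grid "
            f"of non-overlapping {fov_side:.3f} mm FOVs"
        )
    n_x = int(region_width_mm // tile)
    n_y = int(region_height_mm // tile)
    if set_index > n_x * n_y:
        raise RegionExhausted(
            f"set {set_index} does not fit: region holds {n_x * n_y} tile(s)"
        )
    ix = (set_index - 1) % n_x
    iy = (set_index - 1) // n_x
    x0, y0 = ix * tile, iy * tile
    positions = []
    k = 1
    for gy in range(n_grid):
        for gx in range(n_grid):
            positions.append(
                AreaPosition(
                    set_index=set_index,
                    index=k,
                    x_mm=x0 + tile * (gx + 0.5) / n_grid,
                    y_mm=y0 + tile * (gy + 0.5) / n_grid,
                    fov_width_mm=fov_side,
                    fov_height_mm=fov_side,
                )
            )
            k += 1
    return positions


def order_particles_in_fov(
    particles: Sequence[ParticleRecord],
    position: AreaPosition,
    size_limit_um: float,
) -> list[ParticleRecord]:
    """Above-limit particles of one FOV in analysis order.

    Particles (centroid inside the FOV, L strictly above the limit) are
    sorted by polar angle about the FOV center, anticlockwise starting due
    east; ties break by increasing radial distance, then by id.
    """
    eligible = [
        p
        for p in particles
        if p.L_um > size_limit_um and position.contains(p.x_mm, p.y_mm)
    ]

    def key(p: ParticleRecord):
        dx, dy = p.x_mm - position.x_mm, p.y_mm - position.y_mm
        angle = math.atan2(dy, dx) % (2.0 * math.pi)
        return (angle, math.hypot(dx, dy), p.id)

    return sorted(eligible, key=key)


@dataclass(frozen=True)
class PositionLog:
    """Ordered record of the particles analyzed at one area position."""

    position: AreaPosition
    analyzed: tuple[MeasuredParticle, ...]


@dataclass(frozen=True)
class SurveyResult:
    """Full ordered log of one survey plus its termination bookkeeping."""

    positions: tuple[PositionLog, ...]
    n_area_positions_used: int
    n_analyzed: int
    n_coal: int
    stop_reason: StopReason

    def __post_init__(self) -> None:
        total = sum(len(p.analyzed) for p in self.positions)
        if total != self.n_analyzed:
            raise ValueError("n_analyzed does not match the analyzed log")
        if self.n_coal > self.n_analyzed:
            raise ValueError("n_coal cannot exceed n_analyzed")

    def analyzed_particles(self) -> list[MeasuredParticle]:
        return [m for log in self.positions for m in log.analyzed]


def run_survey(
    sample: Sequence[ParticleRecord],
    config: ProtocolConfig,
    beam: BeamConfig | None = None,
    substrate: Composition | None = None,
    seed: int = 0,
    region_width_mm: float = 8.0,
    region_height_mm: float = 8.0,
) -> SurveyResult:
    """Execute the survey protocol over a synthetic particle table.

    Each selected particle is measured through the substrate-aware EDX
    forward model and classified; measurement noise draws come from the
    ``measure`` stream of the master ``seed``.  An empty sample terminates
    with ``sample_exhausted`` and zero counts.
    """
    beam = beam if beam is not None else BeamConfig(
        penetration_depth_um=config.penetration_depth_um
    )
    substrate = substrate if substrate is not None else config.substrate_composition
    rng = stage_rng(seed, "measure")

    # coarse spatial prefilter per FOV via arrays
    xs = np.array([p.x_mm for p in sample])
    ys = np.array([p.y_mm for p in sample])
    Ls = np.array([p.L_um for p in sample])

    logs: list[PositionLog] = []
    n_analyzed = 0
    n_coal = 0
    n_positions = 0
    stop: StopReason | None = None

    def limit_reached() -> StopReason | None:
        if n_coal >= config.stop_coal:
            return StopReason.COAL_LIMIT
        if n_analyzed >= config.stop_total:
            return StopReason.TOTAL_LIMIT
        return None

    for set_index in range(1, config.max_position_sets + 1):
        try:
            positions = layout_area_positions(
                region_width_mm, region_height_mm, set_index, config
            )
        except RegionExhausted:
            break
        for position in positions:
            n_positions += 1
            if len(sample) > 0:
                near = (
                    (np.abs(xs - position.x_mm) <= position.fov_width_mm / 2.0)
                    & (np.abs(ys - position.y_mm) <= position.fov_height_mm / 2.0)
                    & (Ls > config.size_limit_um)
                )
                candidates = [sample[i] for i in np.flatnonzero(near)]
            else:
                candidates = []
            ordered = order_particles_in_fov(candidates, position, config.size_limit_um)
            analyzed_here: list[MeasuredParticle] = []
            for g0 in range(0, len(ordered), config.group_size):
                group = ordered[g0 : g0 + config.group_size]
                for particle in group:
                    measured = measure_particle(particle, beam, substrate, rng)
                    classified = classify_particle(measured, config)
                    analyzed_here.append(classified)
                    n_analyzed += 1
                    if classified.decision is Decision.COAL:
                        n_coal += 1
                    if config.stop_check.value == "particle":
                        stop = limit_reached()
                        if stop:
                            break
                if stop:
                    break
                if config.stop_check.value == "group":
                    stop = limit_reached()
                    if stop:
                        break
            logs.append(PositionLog(position=position, analyzed=tuple(analyzed_here)))
            if stop is None and config.stop_check.value == "position":
                stop = limit_reached()
            if stop:
                break
        if stop:
            break

    return SurveyResult(
        positions=tuple(logs),
        n_area_positions_used=n_positions,
        n_analyzed=n_analyzed,
        n_coal=n_coal,
        stop_reason=stop if stop is not None else StopReason.SAMPLE_EXHAUSTED,
    )
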