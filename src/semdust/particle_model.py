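"""Shared domain types for the settled-dust SEM-EDX pipeline.

All compositional data are closed elemental compositions in atomic percent
(At.%) over the ten analyzed elements C, O, Na, Mg, Al, Si, P, S, Ca, Fe.
The instrument reports semi-quantitative closed compositions summing to
100 At.%; unanalyzed mass is not modeled, and any other element in an input
is a hard error rather than being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import numpy as np

#: The ten analyzed elements, in fixed column order.
ELEMENTS: tuple[str, ...] = ("C", "O", "Na", "Mg", "Al", "Si", "P", "S", "Ca", "Fe")

_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}

_CLOSURE_TOL = 1e-6


class ParticleClass(str, Enum):
    """Ground-truth particle type used by the synthetic generator."""

    COAL = "coal"
    MINERAL = "mineral"
    FIBER = "fiber"
    SOOT_SPHERE = "soot_sphere"
    METAL = "metal"
    OTHER = "other"


class Morphology(str, Enum):
    """Categorical morphology call made by the operator."""

    MINERAL_LIKE = "mineral_like"
    FIBROUS = "fibrous"
    SPHERICAL = "spherical"
    OTHER = "other"


class RejectReason(str, Enum):
    """Criterion a particle failed during coal classification."""

    SIZE = "size"
    CARBON_LOW = "carbon_low"
    OXYGEN_HIGH = "oxygen_high"
    MORPHOLOGY = "morphology"


class Decision(str, Enum):
    COAL = "coal"
    NOT_COAL = "not_coal"


@dataclass(frozen=True)
class Composition:
    """A closed elemental composition (At.%) over the ten analyzed elements.

    ``values`` holds atomic percents in :data:`ELEMENTS` order; they are
    non-negative and sum to 100 within 1e-6.  Build instances with
    :func:`normalize_composition` or :meth:`from_atpct`.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(ELEMENTS):
            raise ValueError(
                f"composition needs {len(ELEMENTS)} values, got {len(self.values)}"
            )
        for el, v in zip(ELEMENTS, self.values):
            if not math.isfinite(v) or v < 0.0 or v > 100.0 + _CLOSURE_TOL:
                raise ValueError(f"{el} = {v} At.% outside [0, 100]")
        total = sum(self.values)
        if abs(total - 100.0) > _CLOSURE_TOL * 100.0:
            raise ValueError(f"composition sums to {total}, expected 100")

    # -- element access -------------------------------------------------
    def __getitem__(self, element: str) -> float:
        try:
            return self.values[_ELEMENT_INDEX[element]]
        except KeyError:
            raise KeyError(f"unknown element {element!r}; analyzed set is {ELEMENTS}")

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(ELEMENTS, self.values))

    @property
    def carbon(self) -> float:
        return self.values[0]

    @property
    def oxygen(self) -> float:
        return self.values[1]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ELEMENTS, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Composition":
        return cls(tuple(float(v) for v in arr))

    @classmethod
    def from_atpct(cls, **atpct: float) -> "Composition":
        """Build from keyword At.% values (absent elements are 0).

        The values must already close to 100; use
        :func:`normalize_composition` for raw, unclosed data.
        """
        return cls(_to_vector(atpct))


def _to_vector(raw: Mapping[str, float]) -> tuple[float, ...]:
    unknown = sorted(set(raw) - set(ELEMENTS))
    if unknown:
        raise ValueError(
            f"unknown element(s) {unknown}; analyzed set is exactly {ELEMENTS}"
        )
    return tuple(float(raw.get(el, 0.0)) for el in ELEMENTS)


def normalize_composition(raw: Mapping[str, float]) -> Composition:
    """Close a raw element→weight mapping to a 100 At.% :class:`Composition`.

    Values are scaled proportionally so they sum to 100.  Elements outside
    the ten-element analyzed set are rejected, negative values raise, and
    an all-zero input signals an empty analysis.
    """
    vec = _to_vector(raw)
    for el, v in zip(ELEMENTS, vec):
        if not math.isfinite(v):
            raise ValueError(f"{el} is not finite: {v}")
        if v < 0.0:
            raise ValueError(f"{el} = {v} is negative")
    total = sum(vec)
    if total <= 0.0:
        raise ValueError("all-zero composition: empty analysis")
    return Composition(tuple(v * 100.0 / total for v in vec))


def normalize_rows(raw: np.ndarray) -> np.ndarray:
    """Row-wise closure of an (n, 10) non-negative array to sum 100.

    Vectorized counterpart of :func:`normalize_composition` used by the
    generator and forward model; rows must have a positive sum.
    """
    raw = np.asarray(raw, dtype=float)
    totals = raw.sum(axis=1, keepdims=True)
    if np.any(totals <= 0.0):
        raise ValueError("row with non-positive total: empty analysis")
    return raw * (100.0 / totals)


# ---------------------------------------------------------------------------
# particle records


@dataclass(frozen=True)
class ParticleRecord:
    """One physical particle on the tape region.

    ``thickness_um`` and ``particle_class`` are synthetic ground truth;
    tables of real measurements omit them and downstream code must not
    require them (``thickness_um`` may be ``None``).
    """

    id: str
    x_mm: float
    y_mm: float
    L_um: float
    morphology: Morphology
    intrinsic_composition: Composition
    particle_class: ParticleClass | None = None
    thickness_um: float | None = None

    def __post_init__(self) -> None:
        if not self.L_um > 0.0:
            raise ValueError(f"L_um must be > 0, got {self.L_um}")
        if self.thickness_um is not None:
            if not self.thickness_um > 0.0:
                raise ValueError(f"thickness_um must be > 0, got {self.thickness_um}")
            if self.thickness_um > self.L_um * (1.0 + 1e-12):
                raise ValueError(
                    f"thickness_um {self.thickness_um} exceeds L_um {self.L_um}"
                )


@dataclass(frozen=True)
class MeasuredParticle:
    """A particle together with its EDX-measured composition and, once
    classified, the coal/not-coal decision and the full set of failed
    criteria (never just the first)."""

    particle: ParticleRecord
    measured_composition: Composition
    observed_morphology: Morphology
    decision: Decision | None = None
    reject_reasons: frozenset[RejectReason] = frozenset()

    def __post_init__(self) -> None:
        if self.decision is not None:
            is_coal = self.decision is Decision.COAL
            if is_coal != (len(self.reject_reasons) == 0):
                raise ValueError("decision=coal iff reject_reasons is empty")


# ---------------------------------------------------------------------------
# protocol configuration


def default_substrate() -> Composition:
    """Bare conductive carbon tape: C 94 / O 6 At.%."""
    return Composition.from_atpct(C=94.0, O=6.0)


class StopCheck(str, Enum):
    """When the survey stop rules are evaluated (work in progress is
    completed before checking)."""

    PER_PARTICLE = "particle"
    PER_GROUP = "group"
    PER_POSITION = "position"


@dataclass(frozen=True)
class ProtocolConfig:
    """Survey and classification protocol settings.

    Defaults encode the manual 500x protocol: 0.066 mm^2 fields of view,
    nine pre-saved area positions per set, groups of ten particles selected
    anticlockwise, stop at >=5 coal or >=100 total particles, size limit
    L > 5 um, compositional limits C >= 75 / O <= 20 At.%.
    """

    fov_area_mm2: float = 0.066
    n_area_positions_per_set: int = 9
    group_size: int = 10
    stop_coal: int = 5
    stop_total: int = 100
    size_limit_um: float = 5.0
    carbon_min_atpct: float = 75.0
    oxygen_max_atpct: float = 20.0
    substrate_composition: Composition = field(default_factory=default_substrate)
    penetration_depth_um: float = 2.0
    stop_check: StopCheck = StopCheck.PER_POSITION
    max_position_sets: int = 10
    #: side of the square low-magnification parent field in which one set of
    #: nine positions is laid out; successive sets tile the region.
    set_tile_mm: float = 4.0

    def __post_init__(self) -> None:
        for name in ("n_area_positions_per_set", "group_size", "stop_coal",
                     "stop_total", "max_position_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fov_area_mm2", "size_limit_um", "penetration_depth_um",
                     "set_tile_mm"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("carbon_min_atpct", "oxygen_max_atpct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be within [0, 100], got {v}")


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample summary: counts, analyzed area, loadings, coal fraction.

    Raw (unrounded) quantities are kept alongside the report-convention
    rounded ones; loadings are reported per mm^2 of analyzed area and the
    coal fraction as a percentage of analyzed particles.
    """

    n_area_positions: int
    area_analyzed_mm2: float          # raw: positions x fov area
    n_particles_analyzed: int
    n_coal: int
    # raw values
    total_loading_raw: float
    coal_loading_raw: float
    coal_fraction_raw: float
    # report-rounded values (see metrics.summarize_counts for conventions)
    area_analyzed_mm2_2dp: float
    total_loading_per_mm2: float
    coal_loading_per_mm2: float
    coal_fraction_pct: float
    fraction_defined: bool = True

    def __post_init__(self) -> None:
        if self.n_coal > self.n_particles_analyzed:
            raise ValueError("n_coal cannot exceed n_particles_analyzed")
        # 0.5 slack: total rounds to integer, coal to one decimal, so the
        # rounded pair can invert by up to half a unit at tiny counts
        if self.coal_loading_per_mm2 > self.total_loading_per_mm2 + 0.5:
            raise ValueError("coal loading cannot exceed total loading")
        if self.coal_loading_raw > self.total_loading_raw + 1e-9:
            raise ValueError("raw coal loading cannot exceed raw total loading")
        if not 0.0 <= self.coal_fraction_pct <= 100.0:
            raise ValueError("coal fraction must lie in [0, 100]")
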