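"""Synthetic settled-dust sample generator.

Produces particle tables with full ground truth (class, thickness,
intrinsic composition) whose statistical structure matches the calibration
measurements of the analysis: a terminal-coal class with measured carbon
83 At.% / oxygen 14 At.% on average, inorganic minerals with low carbon and
high oxygen, plus carbonaceous fibrous and spherical confounders and
metallic particles.

Particle counts are Poisson in the region area, positions are uniform,
sizes are lognormal per class, and intrinsic compositions are per-element
truncated-normal draws re-closed to 100 At.%.

The default size distributions and the confounder abundances are
illustrative: the calibration data report only the observed 0.5-100 um
size range and no confounder statistics, so all of them are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._seeding import stage_rng
from .particle_model import (
    ELEMENTS,
    Composition,
    Morphology,
    ParticleClass,
    ParticleRecord,
    normalize_rows,
)

__all__ = [
    "ClassSpec",
    "SampleConfig",
    "generate_sample",
    "generate_blank",
    "coal_terminal_mixture",
    "default_class_specs",
    "fraction_above_size_limit",
]


@dataclass(frozen=True)
class ClassSpec:
    """Generator parameters for one particle class.

    ``composition_2sigma`` gives per-element 2-sigma spreads (At.%) of the
    raw pre-closure draws; per-element SD is half of it.  ``thickness_ratio``
    is the thickness/L ratio (flakes are thin, spheres have ratio 1).
    """

    particle_class: ParticleClass
    abundance_weight: float
    size_median_um: float
    size_gsd: float
    thickness_ratio: float
    composition_mean: Composition
    composition_2sigma: Mapping[str, float]
    morphology: Morphology

    def __post_init__(self) -> None:
        if self.abundance_weight < 0.0:
            raise ValueError("abundance_weight must be >= 0")
        if not self.size_median_um > 0.0:
            raise ValueError("size_median_um must be > 0")
        if self.size_gsd < 1.0:
            raise ValueError("size_gsd must be >= 1")
        if not 0.0 < self.thickness_ratio <= 1.0:
            raise ValueError("thickness_ratio must be in (0, 1]")
        unknown = sorted(set(self.composition_2sigma) - set(ELEMENTS))
        if unknown:
            raise ValueError(f"unknown element(s) in composition_2sigma: {unknown}")
        if self.particle_class is ParticleClass.COAL and (
            self.morphology is not Morphology.MINERAL_LIKE
        ):
            # generator contract: ground-truth coal is mineral-like;
            # measurement-side morphology confusion is applied separately
            raise ValueError("ground-truth coal must have mineral_like morphology")

    def sigma_vector(self) -> np.ndarray:
        return np.array(
            [self.composition_2sigma.get(el, 0.0) / 2.0 for el in ELEMENTS]
        )


@dataclass(frozen=True)
class SampleConfig:
    """Full configuration of one synthetic sample."""

    class_specs: Sequence[ClassSpec]
    total_loading_per_mm2: float
    region_width_mm: float = 8.0
    region_height_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.region_width_mm > 0.0 or not self.region_height_mm > 0.0:
            raise ValueError("region extents must be > 0")
        if self.total_loading_per_mm2 < 0.0:
            raise ValueError("total_loading_per_mm2 must be >= 0")
        if self.total_loading_per_mm2 > 0 and not self.class_specs:
            raise ValueError("class_specs must be non-empty for a loaded sample")
        if self.class_specs:
            total_w = sum(cs.abundance_weight for cs in self.class_specs)
            if self.total_loading_per_mm2 > 0 and not total_w > 0.0:
                raise ValueError("abundance weights must sum to a positive number")

    @property
    def region_area_mm2(self) -> float:
        return self.region_width_mm * self.region_height_mm


def _draw_compositions(
    spec: ClassSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, 10) intrinsic At.% rows: truncated-normal per element, re-closed."""
    mean = spec.composition_mean.as_array()
    sigma = spec.sigma_vector()
    raw = mean[None, :] + rng.normal(0.0, 1.0, size=(n, len(ELEMENTS))) * sigma[None, :]
    np.clip(raw, 0.0, None, out=raw)
    return normalize_rows(raw)


def generate_sample(config: SampleConfig) -> list[ParticleRecord]:
    """Generate one synthetic sample (deterministic for a given config).

    Particle count ~ Poisson(loading x area); positions uniform over the
    region; class by abundance weight; L lognormal per class; thickness =
    thickness_ratio x L; intrinsic composition truncated-normal re-closed;
    morphology from the class.
    """
    if not config.region_area_mm2 > 0.0:
        raise ValueError("zero-area region")
    rng = stage_rng(config.seed, "generate")
    n = int(rng.poisson(config.total_loading_per_mm2 * config.region_area_mm2))
    if n == 0:
        return []
    specs = list(config.class_specs)
    weights = np.array([cs.abundance_weight for cs in specs], dtype=float)
    probs = weights / weights.sum()
    class_idx = rng.choice(len(specs), size=n, p=probs)
    x = rng.uniform(0.0, config.region_width_mm, size=n)
    y = rng.uniform(0.0, config.region_height_mm, size=n)
    L = np.empty(n)
    thickness = np.empty(n)
    comps = np.empty((n, len(ELEMENTS)))
    for k, spec in enumerate(specs):
        mask = class_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        L_k = rng.lognormal(np.log(spec.size_median_um), np.log(spec.size_gsd), m)
        L[mask] = L_k
        thickness[mask] = spec.thickness_ratio * L_k
        comps[mask] = _draw_compositions(spec, m, rng)
    width = len(str(n))
    return [
        ParticleRecord(
            id=f"p{i + 1:0{width}d}",
            x_mm=float(x[i]),
            y_mm=float(y[i]),
            L_um=float(L[i]),
            morphology=specs[class_idx[i]].morphology,
            intrinsic_composition=Composition.from_array(comps[i]),
            particle_class=specs[class_idx[i]].particle_class,
            thickness_um=float(thickness[i]),
        )
        for i in range(n)
    ]


def generate_blank(
    region_width_mm: float = 8.0,
    region_height_mm: float = 8.0,
    seed: int = 0,
    trace_loading_per_mm2: float = 0.0,
    trace_spec: ClassSpec | None = None,
) -> list[ParticleRecord]:
    """A laboratory/field blank: zero-to-trace loading, never any coal.

    The default is an empty tape.  A positive ``trace_loading_per_mm2``
    deposits particles of ``trace_spec`` (default: the mineral class).
    """
    if trace_loading_per_mm2 < 0.0:
        raise ValueError("trace_loading_per_mm2 must be >= 0")
    if trace_loading_per_mm2 == 0.0:
        return []
    spec = trace_spec if trace_spec is not None else _mineral_spec()
    if spec.particle_class is ParticleClass.COAL:
        raise ValueError("a blank cannot contain coal-class particles")
    cfg = SampleConfig(
        class_specs=[replace(spec, abundance_weight=1.0)],
        total_loading_per_mm2=trace_loading_per_mm2,
        region_width_mm=region_width_mm,
        region_height_mm=region_height_mm,
        seed=seed,
    )
    return generate_sample(cfg)


# ---------------------------------------------------------------------------
# default mixture anchored to the calibration measurements


def _coal_spec(weight: float = 1.0) -> ClassSpec:
    # Terminal-coal composition: mean C 83 / O 14 At.% with mineral residue.
    # Raw 2-sigma spreads are calibrated so the closed composition
    # reproduces the observed spread and an out-of-limits (C < 75 or
    # O > 20) rate of ~7 % under planchette measurement noise; closure
    # anti-correlates C and O, so raw spreads exceed the closed ones.
    return ClassSpec(
        particle_class=ParticleClass.COAL,
        abundance_weight=weight,
        size_median_um=8.0,
        size_gsd=2.0,
        thickness_ratio=0.5,
        composition_mean=Composition.from_atpct(C=83.0, O=14.0, Si=1.5, Al=0.5, S=1.0),
        composition_2sigma={"C": 13.0, "O": 9.4, "Si": 1.5, "Al": 0.8, "S": 1.0},
        morphology=Morphology.MINERAL_LIKE,
    )


def _mineral_spec(weight: float = 0.55) -> ClassSpec:
    return ClassSpec(
        particle_class=ParticleClass.MINERAL,
        abundance_weight=weight,
        size_median_um=6.0,
        size_gsd=2.2,
        thickness_ratio=0.5,
        composition_mean=Composition.from_atpct(
            C=5.0, O=55.0, Si=25.0, Al=8.0, Fe=3.0, Ca=2.0, Mg=1.0, Na=1.0
        ),
        composition_2sigma={
            "C": 4.0, "O": 6.0, "Si": 6.0, "Al": 3.0, "Fe": 2.0,
            "Ca": 1.5, "Mg": 1.0, "Na": 1.0,
        },
        morphology=Morphology.MINERAL_LIKE,
    )


def _fiber_spec(weight: float = 0.06) -> ClassSpec:
    # carbonaceous fibers: coal-like composition, excluded by morphology
    return ClassSpec(
        particle_class=ParticleClass.FIBER,
        abundance_weight=weight,
        size_median_um=20.0,
        size_gsd=2.0,
        thickness_ratio=0.1,
        composition_mean=Composition.from_atpct(C=85.0, O=14.0, S=1.0),
        composition_2sigma={"C": 6.0, "O": 5.0, "S": 1.0},
        morphology=Morphology.FIBROUS,
    )


def _soot_spec(weight: float = 0.30) -> ClassSpec:
    return ClassSpec(
        particle_class=ParticleClass.SOOT_SPHERE,
        abundance_weight=weight,
        size_median_um=1.0,
        size_gsd=1.8,
        thickness_ratio=1.0,
        composition_mean=Composition.from_atpct(C=95.0, O=5.0),
        composition_2sigma={"C": 3.0, "O": 3.0},
        morphology=Morphology.SPHERICAL,
    )


def _metal_spec(weight: float = 0.09) -> ClassSpec:
    # oxidized steel/aluminum debris: rejected on composition
    return ClassSpec(
        particle_class=ParticleClass.METAL,
        abundance_weight=weight,
        size_median_um=6.0,
        size_gsd=2.0,
        thickness_ratio=0.5,
        composition_mean=Composition.from_atpct(Fe=70.0, O=25.0, C=3.0, Si=2.0),
        composition_2sigma={"Fe": 8.0, "O": 6.0, "C": 2.0, "Si": 1.0},
        morphology=Morphology.MINERAL_LIKE,
    )


def default_class_specs() -> list[ClassSpec]:
    """The five default classes with placeholder coal abundance 1.0."""
    return [_coal_spec(), _mineral_spec(), _fiber_spec(), _soot_spec(), _metal_spec()]


def fraction_above_size_limit(spec: ClassSpec, size_limit_um: float) -> float:
    """P(L > limit) for one class under its lognormal size law."""
    if spec.size_gsd == 1.0:  # degenerate: all particles exactly at the median
        return 1.0 if spec.size_median_um > size_limit_um else 0.0
    return float(
        stats.lognorm.sf(
            size_limit_um, s=np.log(spec.size_gsd), scale=spec.size_median_um
        )
    )


def coal_terminal_mixture(
    total_above_limit_loading_per_mm2: float = 155.0,
    coal_fraction_above_limit: float = 0.09,
    size_limit_um: float = 5.0,
    region_width_mm: float = 8.0,
    region_height_mm: float = 8.0,
    seed: int = 0,
) -> SampleConfig:
    """Default mixture emulating a heavily loaded sample near a coal terminal.

    The two leading parameters are the calibration anchors: an above-limit
    total loading of 155 particles/mm^2 and a coal share of 9 % of
    above-limit particles.  The coal abundance weight and the all-particle
    Poisson loading are solved from these targets using the analytic
    lognormal size laws, so a full survey of the generated sample recovers
    them in expectation.
    """
    if not 0.0 <= coal_fraction_above_limit < 1.0:
        raise ValueError("coal_fraction_above_limit must be in [0, 1)")
    if total_above_limit_loading_per_mm2 < 0.0:
        raise ValueError("total_above_limit_loading_per_mm2 must be >= 0")
    others = [_mineral_spec(), _fiber_spec(), _soot_spec(), _metal_spec()]
    p_above = {
        cs.particle_class: fraction_above_size_limit(cs, size_limit_um)
        for cs in others + [_coal_spec()]
    }
    # above-limit share of class k is w_k p_k / sum(w p); solve the coal
    # weight so that share equals the requested fraction
    other_mass = sum(cs.abundance_weight * p_above[cs.particle_class] for cs in others)
    p_coal = p_above[ParticleClass.COAL]
    s = coal_fraction_above_limit
    w_coal = s * other_mass / (p_coal * (1.0 - s))
    specs = [_coal_spec(weight=w_coal)] + others
    total_w = sum(cs.abundance_weight for cs in specs)
    p_above_mixture = (
        sum(cs.abundance_weight * p_above[cs.particle_class] for cs in specs) / total_w
    )
    total_loading = (
        total_above_limit_loading_per_mm2 / p_above_mixture
        if total_above_limit_loading_per_mm2 > 0.0
        else 0.0
    )
    return SampleConfig(
        class_specs=specs,
        total_loading_per_mm2=total_loading,
        region_width_mm=region_width_mm,
        region_height_mm=region_height_mm,
        seed=seed,
    )
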