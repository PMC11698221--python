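"""Summary metrics: analyzed area, particle loadings, coal fraction.

Report rounding conventions are fixed to reproduce the published summary
table digit-for-digit (half-up rounding): analyzed area to 2 decimals,
coal loading to 1 decimal, total loading and coal fraction to integers.
Loadings are computed from the 2-decimal rounded area, which is what the
printed values imply (7 coal / 0.528 mm^2 raw would round to 13.3, while
the printed value 13.2 equals 7 / 0.53); raw unrounded quantities are
retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .particle_model import ProtocolConfig, SampleSummary
from .survey import SurveyResult

__all__ = [
    "round_half_up",
    "summarize_counts",
    "summarize_survey",
    "compare_sites",
    "SiteComparison",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts(
    n_area_positions: int,
    n_particles_analyzed: int,
    n_coal: int,
    config: ProtocolConfig,
) -> SampleSummary:
    """Build a :class:`SampleSummary` from survey counts.

    Raw loadings use the raw area (positions x FOV area); the report
    loadings use the 2-decimal area, matching the published convention.
    A sample with zero analyzed particles gets zero loadings and an
    explicitly flagged undefined fraction.
    """
    if n_area_positions <= 0:
        raise ValueError("n_area_positions must be positive")
    if n_coal > n_particles_analyzed:
        raise ValueError("n_coal cannot exceed n_particles_analyzed")
    area_raw = n_area_positions * config.fov_area_mm2
    area_2dp = round_half_up(area_raw, 2)
    fraction_defined = n_particles_analyzed > 0
    if fraction_defined:
        total_raw = n_particles_analyzed / area_raw
        coal_raw = n_coal / area_raw
        frac_raw = 100.0 * n_coal / n_particles_analyzed
        total_rounded = round_half_up(n_particles_analyzed / area_2dp, 0)
        coal_rounded = round_half_up(n_coal / area_2dp, 1)
        frac_rounded = round_half_up(frac_raw, 0)
    else:
        total_raw = coal_raw = frac_raw = 0.0
        total_rounded = coal_rounded = frac_rounded = 0.0
    return SampleSummary(
        n_area_positions=n_area_positions,
        area_analyzed_mm2=area_raw,
        n_particles_analyzed=n_particles_analyzed,
        n_coal=n_coal,
        total_loading_raw=total_raw,
        coal_loading_raw=coal_raw,
        coal_fraction_raw=frac_raw,
        area_analyzed_mm2_2dp=area_2dp,
        total_loading_per_mm2=total_rounded,
        coal_loading_per_mm2=coal_rounded,
        coal_fraction_pct=frac_rounded,
        fraction_defined=fraction_defined,
    )


def summarize_survey(result: SurveyResult, config: ProtocolConfig) -> SampleSummary:
    """Summarize a completed survey (see :func:`summarize_counts`)."""
    return summarize_counts(
        n_area_positions=result.n_area_positions_used,
        n_particles_analyzed=result.n_analyzed,
        n_coal=result.n_coal,
        config=config,
    )


_CAVEAT = (
    "Descriptive comparison of two single physical samples; no hypothesis "
    "test is performed and no statistically significant difference can be "
    "established from n = 1 sample per site."
)


@dataclass(frozen=True)
class SiteComparison:
    """Descriptive (non-inferential) comparison of two site summaries."""

    coal_loading_a: float
    coal_loading_b: float
    ratio: float | None
    difference: float
    caveat: str = _CAVEAT

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def compare_sites(summary_a: SampleSummary, summary_b: SampleSummary) -> SiteComparison:
    """Ratio and difference of the two report coal loadings (a vs b).

    The ratio is flagged undefined (None) when site b has zero coal
    loading.  Deliberately no significance test: one physical sample per
    site supports only a descriptive comparison.
    """
    a = summary_a.coal_loading_per_mm2
    b = summary_b.coal_loading_per_mm2
    return SiteComparison(
        coal_loading_a=a,
        coal_loading_b=b,
        ratio=(a / b) if b > 0 else None,
        difference=a - b,
    )
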