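"""Three-criterion coal-particle classification.

A measured particle is identified as coal iff it passes all of:

* size:        L > size limit (strict; default 5 um)
* composition: measured C >= 75 At.% and measured O <= 20 At.% (inclusive)
* morphology:  observed morphology is mineral-like (angular/rough, not
               fibrous or spherical)

Every failed criterion is recorded, not just the first, mirroring the
reject-reason bookkeeping an operator performs during the survey.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .particle_model import (
    Decision,
    MeasuredParticle,
    Morphology,
    ParticleClass,
    ProtocolConfig,
    RejectReason,
)

__all__ = ["classify_particle", "classification_confusion", "ConfusionCounts"]


def classify_particle(measured: MeasuredParticle, config: ProtocolConfig) -> MeasuredParticle:
    """Return a copy of ``measured`` with decision and reject_reasons set.

    Boundary behaviour is literal: C = 75 and O = 20 pass, L = 5 um fails.
    """
    if measured.observed_morphology is None:
        raise ValueError("morphology call is required for classification")
    comp = measured.measured_composition
    reasons: set[RejectReason] = set()
    if not measured.particle.L_um > config.size_limit_um:
        reasons.add(RejectReason.SIZE)
    if comp.carbon < config.carbon_min_atpct:
        reasons.add(RejectReason.CARBON_LOW)
    if comp.oxygen > config.oxygen_max_atpct:
        reasons.add(RejectReason.OXYGEN_HIGH)
    if measured.observed_morphology is not Morphology.MINERAL_LIKE:
        reasons.add(RejectReason.MORPHOLOGY)
    decision = Decision.COAL if not reasons else Decision.NOT_COAL
    return replace(measured, decision=decision, reject_reasons=frozenset(reasons))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 ground-truth-class vs decision counts over above-limit particles."""

    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int

    @property
    def n(self) -> int:
        return (self.true_positive + self.false_positive
                + self.false_negative + self.true_negative)

    @property
    def false_negative_rate(self) -> float:
        """FN / (TP + FN); 0 when no ground-truth coal is present."""
        denom = self.true_positive + self.false_negative
        return self.false_negative / denom if denom else 0.0

    @property
    def false_positive_rate(self) -> float:
        """FP / (FP + TN); 0 when no ground-truth non-coal is present."""
        denom = self.false_positive + self.true_negative
        return self.false_positive / denom if denom else 0.0


def classification_confusion(
    classified: list[MeasuredParticle], config: ProtocolConfig
) -> ConfusionCounts:
    """Tally decisions against synthetic ground truth.

    Only particles above the size limit are counted (sub-limit particles
    are never selected by the protocol).  Requires ``particle_class``
    ground truth on every record.
    """
    tp = fp = fn = tn = 0
    for m in classified:
        if m.decision is None:
            raise ValueError(f"particle {m.particle.id} has no decision")
        if m.particle.particle_class is None:
            raise ValueError(f"particle {m.particle.id} has no ground-truth class")
        if not m.particle.L_um > config.size_limit_um:
            continue
        is_coal_truth = m.particle.particle_class is ParticleClass.COAL
        is_coal_decided = m.decision is Decision.COAL
        if is_coal_truth and is_coal_decided:
            tp += 1
        elif is_coal_truth:
            fn += 1
        elif is_coal_decided:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)
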