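"""Variant classification cascade.

Variants pass through four rules:

1. a VQSR quality filter (default threshold 35; unscored variants pass and
   are tallied),
2. rarity at the 1% VAF threshold (VAF < 0.01 is rare; exactly 1% is
   common),
3. a consensus deleteriousness vote for missense variants — damaging when
   at least half of the available SIFT/PolyPhen2/PROVEAN calls are
   damaging, with missing calls removed from the denominator,
4. loss-of-function assignment for splice acceptor/donor, start-lost and
   stop-gained consequences, with an optional CADD PHRED demotion filter
   for the splice categories.

"Functional" variants are the union of deleterious missense and
loss-of-function variants.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Tuple

from .model import (
    LOF_CONSEQUENCES,
    PREDICTORS,
    ClassifiedVariant,
    Consequence,
    FunctionalClass,
    PredictorCall,
    Rarity,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Default VQSR filtration threshold (Phred-scaled).
DEFAULT_VQSR_THRESHOLD = 35.0

#: VAF below which a variant is rare.
RARE_VAF_THRESHOLD = 0.01


def filter_vqsr(
    records: Iterable[VariantRecord], threshold: float = DEFAULT_VQSR_THRESHOLD
) -> Tuple[List[VariantRecord], List[VariantRecord], int]:
    """Split records into (kept, dropped) at a VQSR score threshold.

    Records without a score pass the filter; their count is returned as the
    third element so the run manifest can report the unscored tally.
    """
    if threshold < 0:
        raise ValueError(f"VQSR threshold must be non-negative, got {threshold}")
    kept: List[VariantRecord] = []
    dropped: List[VariantRecord] = []
    n_unscored = 0
    for rec in records:
        if rec.vqsr_score is None:
            n_unscored += 1
            kept.append(rec)
        elif rec.vqsr_score >= threshold:
            kept.append(rec)
        else:
            dropped.append(rec)
    if n_unscored:
        logger.info("VQSR filter: %d unscored variants passed through", n_unscored)
    return kept, dropped, n_unscored


def classify_rarity(vaf: float) -> Rarity:
    """RARE when VAF < 1%, COMMON otherwise (a VAF of exactly 1% is common)."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    return Rarity.RARE if vaf < RARE_VAF_THRESHOLD else Rarity.COMMON


def consensus_missense(calls) -> FunctionalClass:
    """Consensus deleteriousness vote over the three predictors.

    Missing calls shrink the denominator; a variant with no available call
    is UNCLASSIFIED_MISSENSE, kept out of both the deleterious and neutral
    tallies.
    """
    calls = {k: PredictorCall(v) for k, v in calls.items()}
    if set(calls) != set(PREDICTORS):
        raise ValueError(f"calls must have exactly the keys {PREDICTORS}")
    available = [c for c in calls.values() if c is not PredictorCall.MISSING]
    if not available:
        return FunctionalClass.UNCLASSIFIED_MISSENSE
    n_damaging = sum(c is PredictorCall.DAMAGING for c in available)
    if n_damaging / len(available) >= 0.5:
        return FunctionalClass.DELETERIOUS_MISSENSE
    return FunctionalClass.NEUTRAL_MISSENSE


def classify_lof(
    consequence: Consequence,
    cadd_phred: Optional[float] = None,
    cadd_threshold: Optional[float] = None,
) -> bool:
    """Whether a consequence is putative loss-of-function.

    Splice acceptor/donor, start-lost and stop-gained qualify.  When
    ``cadd_threshold`` is set, a splice variant whose CADD PHRED score is
    present and below the threshold is demoted (and the demotion logged);
    by default no CADD filtering is applied.
    """
    consequence = Consequence(consequence)
    if consequence not in LOF_CONSEQUENCES:
        return False
    if (
        cadd_threshold is not None
        and consequence in (Consequence.SPLICE_ACCEPTOR, Consequence.SPLICE_DONOR)
        and cadd_phred is not None
        and cadd_phred < cadd_threshold
    ):
        logger.info(
            "splice variant demoted from LoF: CADD %.2f < threshold %.2f",
            cadd_phred,
            cadd_threshold,
        )
        return False
    return True


def classify_variant(
    record: VariantRecord, cadd_threshold: Optional[float] = None
) -> ClassifiedVariant:
    """Assign rarity and functional class to one variant record."""
    rarity = classify_rarity(record.vaf)
    if record.consequence is Consequence.MISSENSE:
        functional_class = consensus_missense(record.predictor_calls)
    elif classify_lof(record.consequence, record.cadd_phred, cadd_threshold):
        functional_class = FunctionalClass.LOF
    else:
        functional_class = FunctionalClass.NON_FUNCTIONAL
    return ClassifiedVariant(record=record, rarity=rarity, functional_class=functional_class)


def classify_all(
    records: Iterable[VariantRecord], cadd_threshold: Optional[float] = None
) -> List[ClassifiedVariant]:
    """Classify a collection of records (VQSR filtering is done separately)."""
    return [classify_variant(r, cadd_threshold) for r in records]
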