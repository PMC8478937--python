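"""Core data model for the pharmacogene variant-landscape pipeline.

The pipeline works on bi-allelic variant records annotated with a gene
symbol, a consequence category, per-predictor deleteriousness calls
(SIFT, PolyPhen2, PROVEAN) and a cohort variant allele frequency (VAF).
Gene panel entries carry the pharmacogene family used for all family-level
summaries, and population rows carry per-population VAFs with the allele
number needed to reconstruct count tables for contingency testing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple


class Consequence(str, enum.Enum):
    """Closed vocabulary of variant consequence categories."""

    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UTR = "utr"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    START_LOST = "start_lost"
    STOP_GAINED = "stop_gained"


#: Consequences treated as putative loss-of-function.
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
        Consequence.START_LOST,
        Consequence.STOP_GAINED,
    }
)

#: Consequences counted as exonic in the cohort overview.  UTR variants are
#: non-coding but sit inside exons and are counted here.
EXONIC_CONSEQUENCES = frozenset(
    {Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.UTR} | LOF_CONSEQUENCES
)


class Family(str, enum.Enum):
    """Pharmacogene family labels."""

    ABC = "ABC"
    SLC = "SLC"
    PHASE1 = "PHASE1"
    PHASE2 = "PHASE2"
    NUCLEAR_RECEPTOR = "NUCLEAR_RECEPTOR"
    OTHER = "OTHER"


class PredictorCall(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


PREDICTORS = ("SIFT", "PolyPhen2", "PROVEAN")


class Rarity(str, enum.Enum):
    RARE = "RARE"
    COMMON = "COMMON"


class FunctionalClass(str, enum.Enum):
    DELETERIOUS_MISSENSE = "DELETERIOUS_MISSENSE"
    NEUTRAL_MISSENSE = "NEUTRAL_MISSENSE"
    UNCLASSIFIED_MISSENSE = "UNCLASSIFIED_MISSENSE"
    LOF = "LOF"
    NON_FUNCTIONAL = "NON_FUNCTIONAL"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated bi-allelic variant.

    Parameters
    ----------
    chrom, pos
        VCF-style coordinate: 1-based position on a chromosome label.
    variant_id
        External identifier (e.g. an rs number); ``None`` marks the variant
        as novel.
    vaf
        Alternate-allele frequency in the cohort, a fraction in [0, 1].
    vqsr_score
        Optional Phred-scaled variant-quality score; ``None`` when the
        source does not provide per-variant scores.
    predictor_calls
        Mapping with exactly the keys SIFT, PolyPhen2 and PROVEAN.
    """

    chrom: str
    pos: int
    variant_id: Optional[str]
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    vaf: float
    consequence: Consequence
    predictor_calls: Mapping[str, PredictorCall] = field(
        default_factory=lambda: {p: PredictorCall.MISSING for p in PREDICTORS}
    )
    vqsr_score: Optional[float] = None
    cadd_phred: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele}")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))
        calls = {k: PredictorCall(v) for k, v in self.predictor_calls.items()}
        if set(calls) != set(PREDICTORS):
            raise ValueError(
                f"predictor_calls must have exactly the keys {PREDICTORS}, got {sorted(calls)}"
            )
        object.__setattr__(self, "predictor_calls", calls)

    @property
    def is_novel(self) -> bool:
        """True when the variant carries no external identifier."""
        return self.variant_id is None

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GeneInfo:
    """A pharmacogene panel entry with 1-based inclusive coordinates."""

    symbol: str
    family: Family
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not isinstance(self.family, Family):
            object.__setattr__(self, "family", Family(self.family))
        if self.end < self.start:
            raise ValueError(f"{self.symbol}: end ({self.end}) < start ({self.start})")
        if self.start < 1:
            raise ValueError(f"{self.symbol}: start must be >= 1")

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


@dataclass(frozen=True)
class PopulationVAF:
    """A per-population allele frequency observation for one variant."""

    variant_key: Tuple[str, int, str, str]
    population: str
    vaf: float
    n_alleles: int

    def __post_init__(self) -> None:
        if self.n_alleles <= 0:
            raise ValueError(f"n_alleles must be positive, got {self.n_alleles}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant record plus its rarity and functional class."""

    record: VariantRecord
    rarity: Rarity
    functional_class: FunctionalClass

    @property
    def is_functional(self) -> bool:
        """True for deleterious missense and loss-of-function variants."""
        return self.functional_class in (
            FunctionalClass.DELETERIOUS_MISSENSE,
            FunctionalClass.LOF,
        )
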