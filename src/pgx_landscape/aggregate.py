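"""Per-gene, per-family and cohort-level summaries of the variant landscape.

The central per-gene quantity is the aggregated functional-variant
frequency: the sum of VAFs over a gene's functional variants (deleterious
missense plus loss-of-function), reported in percent.  Summation makes the
quantity additive — adding one functional variant with VAF v raises it by
exactly 100·v — and genes with no functional variants sit at exactly 0.
An alternative union-probability aggregation, 1 − Π(1 − VAF), is exposed
via ``method="union"`` for sensitivity checks.

All reported percentages are rounded half-up to one decimal; the
underlying fractions are retained at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    EXONIC_CONSEQUENCES,
    ClassifiedVariant,
    Consequence,
    Family,
    FunctionalClass,
    GeneInfo,
    Rarity,
)

#: The 12 ordered single-nucleotide substitution types.
SUBSTITUTION_TYPES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

#: Transitions: purine<->purine and pyrimidine<->pyrimidine.
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, matching conventionally reported percentages."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage of numerator over denominator, rounded half-up."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class GeneSummary:
    symbol: str
    family: Family
    n_total: int
    consequence_counts: Dict[str, int]
    n_novel: int
    n_rare: int
    n_functional: int
    n_functional_rare: int
    n_functional_common: int
    aggregated_functional_freq_pct: float

    @property
    def rare_fraction_of_functional(self) -> Optional[float]:
        """Fraction of functional variants that are rare; None when a gene
        has no functional variants (not-applicable, distinct from 0)."""
        if self.n_functional == 0:
            return None
        return self.n_functional_rare / self.n_functional


@dataclass(frozen=True)
class FamilySummary:
    family: Family
    n_genes: int
    n_variants: int
    n_lof: int
    functional_per_gene_mean: float
    functional_per_gene_sd: Optional[float]  # sample SD; None for a single gene
    deleterious_missense_rare_count: int
    deleterious_missense_count: int

    @property
    def deleterious_missense_rare_pct(self) -> float:
        return pct(self.deleterious_missense_rare_count, self.deleterious_missense_count)


@dataclass(frozen=True)
class SpectrumSummary:
    counts: Dict[str, int]
    n_indels: int

    @property
    def n_snv(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[str, float]:
        total = self.n_snv
        if total == 0:
            return {t: 0.0 for t in SUBSTITUTION_TYPES}
        return {t: self.counts[t] / total for t in SUBSTITUTION_TYPES}

    @property
    def titv_ratio(self) -> float:
        """Transition/transversion ratio; inf when no transversions."""
        ti = sum(self.counts[t] for t in SUBSTITUTION_TYPES if t in TRANSITIONS)
        tv = sum(self.counts[t] for t in SUBSTITUTION_TYPES if t not in TRANSITIONS)
        if tv == 0:
            return math.inf
        return ti / tv


def summarize_gene(
    classified: Sequence[ClassifiedVariant],
    gene: GeneInfo,
    aggregation: str = "sum",
) -> GeneSummary:
    """Summarize one gene's classified variants.

    ``aggregation`` selects the functional-frequency formula: ``"sum"``
    (sum of VAFs, the default) or ``"union"`` (1 − Π(1 − VAF)).
    """
    foreign = [c for c in classified if c.record.gene_symbol != gene.symbol]
    if foreign:
        raise ValueError(
            f"records from another gene passed to summarize_gene({gene.symbol}): "
            f"{foreign[0].record.gene_symbol}"
        )
    counts = {c.value: 0 for c in Consequence}
    for cv in classified:
        counts[cv.record.consequence.value] += 1
    functional = [cv for cv in classified if cv.is_functional]
    n_functional_rare = sum(cv.rarity is Rarity.RARE for cv in functional)
    vafs = [cv.record.vaf for cv in functional]
    if aggregation == "sum":
        agg = sum(vafs)
    elif aggregation == "union":
        agg = 1.0 - float(np.prod([1.0 - v for v in vafs])) if vafs else 0.0
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}; use 'sum' or 'union'")
    return GeneSummary(
        symbol=gene.symbol,
        family=gene.family,
        n_total=len(classified),
        consequence_counts=counts,
        n_novel=sum(cv.record.is_novel for cv in classified),
        n_rare=sum(cv.rarity is Rarity.RARE for cv in classified),
        n_functional=len(functional),
        n_functional_rare=n_functional_rare,
        n_functional_common=len(functional) - n_functional_rare,
        aggregated_functional_freq_pct=100.0 * agg,
    )


def summarize_family(
    gene_summaries: Sequence[GeneSummary],
    lof_counts: Optional[Dict[str, int]] = None,
    deleterious_counts: Optional[Dict[str, Dict[str, int]]] = None,
) -> FamilySummary:
    """Aggregate gene summaries of a single family.

    ``lof_counts`` and ``deleterious_counts`` map gene symbol to that
    gene's LoF count and to ``{"rare": r, "total": t}`` deleterious-missense
    counts; when omitted they are treated as zero (gene summaries alone do
    not separate the two functional classes).
    """
    families = {gs.family for gs in gene_summaries}
    if len(families) != 1:
        raise ValueError(f"summarize_family needs exactly one family, got {sorted(f.value for f in families)}")
    (family,) = families
    per_gene = [gs.n_functional for gs in gene_summaries]
    mean = float(np.mean(per_gene))
    sd = float(np.std(per_gene, ddof=1)) if len(per_gene) > 1 else None
    lof_counts = lof_counts or {}
    deleterious_counts = deleterious_counts or {}
    del_rare = sum(d.get("rare", 0) for d in deleterious_counts.values())
    del_total = sum(d.get("total", 0) for d in deleterious_counts.values())
    return FamilySummary(
        family=family,
        n_genes=len(gene_summaries),
        n_variants=sum(gs.n_total for gs in gene_summaries),
        n_lof=sum(lof_counts.values()),
        functional_per_gene_mean=mean,
        functional_per_gene_sd=sd,
        deleterious_missense_rare_count=del_rare,
        deleterious_missense_count=del_total,
    )


def substitution_spectrum(records: Iterable) -> SpectrumSummary:
    """Tally the 12 single-nucleotide substitution types over SNVs.

    Accepts VariantRecord or ClassifiedVariant items; indels are excluded
    from the spectrum and counted separately.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    n_indels = 0
    for item in records:
        rec = item.record if isinstance(item, ClassifiedVariant) else item
        if rec.is_snv:
            counts[f"{rec.ref_allele}>{rec.alt_allele}"] += 1
        else:
            n_indels += 1
    return SpectrumSummary(counts=counts, n_indels=n_indels)


def cohort_overview(classified: Sequence[ClassifiedVariant]) -> dict:
    """Cohort-level totals and the headline fractions.

    Exonic variants are missense, synonymous, UTR and the four
    loss-of-function categories; UTR variants are non-coding but exonic.
    Percentages are rounded half-up to one decimal for reporting; the raw
    fractions are included under ``*_fraction`` keys.
    """
    n = len(classified)
    n_novel = sum(cv.record.is_novel for cv in classified)
    n_rare = sum(cv.rarity is Rarity.RARE for cv in classified)
    n_exonic = sum(cv.record.consequence in EXONIC_CONSEQUENCES for cv in classified)
    n_lof = sum(cv.functional_class is FunctionalClass.LOF for cv in classified)
    n_del = sum(
        cv.functional_class is FunctionalClass.DELETERIOUS_MISSENSE for cv in classified
    )
    n_del_rare = sum(
        cv.functional_class is FunctionalClass.DELETERIOUS_MISSENSE
        and cv.rarity is Rarity.RARE
        for cv in classified
    )
    n_lof_rare = sum(
        cv.functional_class is FunctionalClass.LOF and cv.rarity is Rarity.RARE
        for cv in classified
    )
    return {
        "n_variants": n,
        "n_novel": n_novel,
        "n_rare": n_rare,
        "n_exonic": n_exonic,
        "n_lof": n_lof,
        "n_deleterious_missense": n_del,
        "n_deleterious_missense_rare": n_del_rare,
        "n_lof_rare": n_lof_rare,
        "novel_pct": pct(n_novel, n),
        "rare_pct": pct(n_rare, n),
        "exonic_pct": pct(n_exonic, n),
        "deleterious_missense_rare_pct": pct(n_del_rare, n_del),
        "lof_rare_pct": pct(n_lof_rare, n_lof),
        "novel_fraction": n_novel / n if n else 0.0,
        "rare_fraction": n_rare / n if n else 0.0,
        "exonic_fraction": n_exonic / n if n else 0.0,
    }


def fold_range(gene_summaries: Sequence[GeneSummary]) -> dict:
    """Max/min fold of the positive aggregated functional frequencies.

    Genes whose aggregated frequency is exactly zero carry no functional
    variants and are excluded from the minimum.
    """
    positive = [gs for gs in gene_summaries if gs.aggregated_functional_freq_pct > 0]
    if len(positive) < 2:
        raise ValueError(
            "fold_range requires at least two genes with a positive "
            "aggregated functional-variant frequency"
        )
    hi = max(positive, key=lambda gs: gs.aggregated_functional_freq_pct)
    lo = min(positive, key=lambda gs: gs.aggregated_functional_freq_pct)
    fold = hi.aggregated_functional_freq_pct / lo.aggregated_functional_freq_pct
    return {
        "fold": fold,
        "fold_rounded": round_half_up(fold, 1),
        "max_gene": hi.symbol,
        "max_pct": hi.aggregated_functional_freq_pct,
        "min_gene": lo.symbol,
        "min_pct": lo.aggregated_functional_freq_pct,
    }


# ---------------------------------------------------------------------------
# Tabular views used by the report writer
# ---------------------------------------------------------------------------

def gene_summaries_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    rows = []
    for gs in sorted(summaries, key=lambda g: g.symbol):
        row = {
            "symbol": gs.symbol,
            "family": gs.family.value,
            "n_total": gs.n_total,
            "n_novel": gs.n_novel,
            "n_rare": gs.n_rare,
            "n_functional": gs.n_functional,
            "n_functional_rare": gs.n_functional_rare,
            "n_functional_common": gs.n_functional_common,
            "aggregated_functional_freq_pct": gs.aggregated_functional_freq_pct,
            "rare_fraction_of_functional": (
                "NA"
                if gs.rare_fraction_of_functional is None
                else f"{gs.rare_fraction_of_functional:.10g}"
            ),
        }
        row.update({f"n_{c.value}": gs.consequence_counts[c.value] for c in Consequence})
        rows.append(row)
    return pd.DataFrame(rows)


def family_summaries_frame(summaries: Sequence[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": fs.family.value,
                "n_genes": fs.n_genes,
                "n_variants": fs.n_variants,
                "n_lof": fs.n_lof,
                "functional_per_gene_mean": fs.functional_per_gene_mean,
                "functional_per_gene_sd": (
                    "NA" if fs.functional_per_gene_sd is None else f"{fs.functional_per_gene_sd:.10g}"
                ),
                "deleterious_missense_rare_count": fs.deleterious_missense_rare_count,
                "deleterious_missense_count": fs.deleterious_missense_count,
                "deleterious_missense_rare_pct": fs.deleterious_missense_rare_pct,
            }
            for fs in sorted(summaries, key=lambda f: f.family.value)
        ]
    )


def spectrum_frame(spectrum: SpectrumSummary) -> pd.DataFrame:
    fractions = spectrum.fractions
    rows = [
        {"substitution": t, "count": spectrum.counts[t], "fraction": fractions[t]}
        for t in SUBSTITUTION_TYPES
    ]
    titv = spectrum.titv_ratio
    rows.append(
        {
            "substitution": "Ti/Tv",
            "count": spectrum.n_snv,
            "fraction": "inf" if math.isinf(titv) else titv,
        }
    )
    rows.append({"substitution": "indels", "count": spectrum.n_indels, "fraction": ""})
    return pd.DataFrame(rows)
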