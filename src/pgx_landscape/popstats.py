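"""Statistical layer: population VAF comparison, family tests, regressions.

Population allele frequencies are compared pairwise on reconstructed 2x2
allele-count tables (alt/ref x population) with a Pearson chi-square test
without continuity correction, falling back to Fisher's exact test when
any expected cell count is below 5.  Family-wise error is controlled with
a Bonferroni threshold alpha/m.

Per-gene variant counts are compared across pharmacogene families with a
tie-corrected Kruskal-Wallis test, and regressed on gene length (kb) by
ordinary least squares with a two-sided t-test of zero slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .aggregate import round_half_up
from .model import PopulationVAF

#: Default multiple-testing family sizes: 6 families x 3 responses for the
#: length regressions; 8 variants x 9 non-reference populations for the
#: population comparisons.
DEFAULT_M_REGRESSIONS = 18
DEFAULT_M_COMPARISONS = 72


@dataclass(frozen=True)
class ComparisonResult:
    variant_key: Tuple[str, int, str, str]
    population_a: str
    population_b: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    test_used: str  # "chi_square" | "fisher_exact" | "degenerate"
    statistic: Optional[float]
    p_value: float
    alpha_adjusted: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


@dataclass(frozen=True)
class RegressionResult:
    family: str
    response: str  # "total" | "missense" | "deleterious"
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    alpha_adjusted: float
    n_genes: int

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def vaf_to_counts(vaf: float, n_alleles: int) -> Tuple[int, int]:
    """Reconstruct (alt, ref) allele counts from a frequency.

    The alternate count is round-half-up(vaf * n_alleles), so a published
    frequency maps back to the integer count it was computed from.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if n_alleles <= 0:
        raise ValueError(f"n_alleles must be positive, got {n_alleles}")
    alt = int(round_half_up(vaf * n_alleles, 0))
    return alt, n_alleles - alt


def bonferroni_alpha(family_wise_alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m at full precision."""
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    if not 0.0 < family_wise_alpha < 1.0:
        raise ValueError(f"family-wise alpha must be in (0, 1), got {family_wise_alpha}")
    return family_wise_alpha / m


def compare_populations(
    a: PopulationVAF,
    b: PopulationVAF,
    alpha_adjusted: float,
    continuity_correction: bool = False,
) -> ComparisonResult:
    """Test whether two populations share an allele frequency.

    Counts are reconstructed with :func:`vaf_to_counts`; Fisher's exact
    test (two-sided) is used when any expected cell count is below 5,
    otherwise a Pearson chi-square without continuity correction (Yates
    correction is available as an option).  A table with a zero marginal
    (e.g. the allele absent from both populations) is flagged degenerate
    and reported with p = 1 rather than raising.
    """
    if a.variant_key != b.variant_key:
        raise ValueError(
            f"cannot compare different variants: {a.variant_key} vs {b.variant_key}"
        )
    alt_a, ref_a = vaf_to_counts(a.vaf, a.n_alleles)
    alt_b, ref_b = vaf_to_counts(b.vaf, b.n_alleles)
    table = np.array([[alt_a, ref_a], [alt_b, ref_b]], dtype=np.int64)

    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        return ComparisonResult(
            variant_key=a.variant_key,
            population_a=a.population,
            population_b=b.population,
            table=((alt_a, ref_a), (alt_b, ref_b)),
            test_used="degenerate",
            statistic=None,
            p_value=1.0,
            alpha_adjusted=alpha_adjusted,
            degenerate=True,
        )

    expected = np.outer(row_tot, col_tot) / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        test_used, statistic = "fisher_exact", None
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
        test_used, statistic = "chi_square", float(chi2)
    return ComparisonResult(
        variant_key=a.variant_key,
        population_a=a.population,
        population_b=b.population,
        table=((alt_a, ref_a), (alt_b, ref_b)),
        test_used=test_used,
        statistic=statistic,
        p_value=float(min(p, 1.0)),
        alpha_adjusted=alpha_adjusted,
    )


def compare_against_reference(
    rows: Sequence[PopulationVAF],
    reference_population: str,
    family_wise_alpha: float = 0.05,
    m: Optional[int] = None,
) -> List[ComparisonResult]:
    """Compare every other population against a reference, per variant.

    ``m`` defaults to the actual number of comparisons performed.
    """
    by_variant: Dict[tuple, Dict[str, PopulationVAF]] = {}
    for row in rows:
        by_variant.setdefault(row.variant_key, {})[row.population] = row
    pairs = []
    for key in sorted(by_variant):
        pops = by_variant[key]
        if reference_population not in pops:
            raise ValueError(
                f"reference population {reference_population!r} missing for variant {key}"
            )
        ref = pops[reference_population]
        for name in sorted(pops):
            if name != reference_population:
                pairs.append((ref, pops[name]))
    m = m if m is not None else len(pairs)
    alpha = bonferroni_alpha(family_wise_alpha, max(m, 1))
    return [compare_populations(ref, other, alpha) for ref, other in pairs]


def kruskal_wallis_by_family(groups: Dict[str, Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across per-gene count groups.

    Returns (H, p) with p from the chi-square approximation on
    len(groups) - 1 degrees of freedom.
    """
    nonempty = {k: list(v) for k, v in groups.items() if len(v) > 0}
    if len(nonempty) < 2:
        raise ValueError("Kruskal-Wallis requires at least two non-empty groups")
    values = list(nonempty.values())
    if all(len(set(v)) == 1 for v in values) and len({v[0] for v in values}) == 1:
        # All observations identical: no rank variation, H = 0 by definition.
        return 0.0, 1.0
    h, p = stats.kruskal(*values)
    return float(h), float(p)


def regress_counts_on_length(
    per_gene: Sequence[Tuple[float, float]],
    response_label: str,
    family: str = "",
    alpha_adjusted: Optional[float] = None,
) -> RegressionResult:
    """OLS of a per-gene variant count on gene length in kb.

    ``per_gene`` is a sequence of (length_kb, count) pairs; the p-value is
    the two-sided t-test of zero slope.
    """
    if len(per_gene) < 3:
        raise ValueError(f"regression requires >= 3 genes, got {len(per_gene)}")
    x = np.asarray([p[0] for p in per_gene], dtype=float)
    y = np.asarray([p[1] for p in per_gene], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("gene lengths have zero variance; slope is unidentifiable")
    if alpha_adjusted is None:
        alpha_adjusted = bonferroni_alpha(0.05, DEFAULT_M_REGRESSIONS)
    if np.allclose(y, y[0]):
        # A constant response carries no length signal: flat fit, p = 1.
        slope, intercept, r_squared, p_value = 0.0, float(y[0]), 0.0, 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared, p_value = float(fit.rvalue**2), float(fit.pvalue)
    return RegressionResult(
        family=family,
        response=response_label,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        p_value=p_value,
        alpha_adjusted=alpha_adjusted,
        n_genes=len(per_gene),
    )
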