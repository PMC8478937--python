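"""Classify a handful of variants through the full cascade.

Builds a few annotated records in memory, applies the rarity threshold
(VAF < 1%), the SIFT/PolyPhen2/PROVEAN consensus vote and the
loss-of-function rule, and prints the resulting classes.
"""

from pgx_landscape import classify_variant
from pgx_landscape.model import VariantRecord

variants = [
    # a rare missense called damaging by 2 of 3 predictors (>= 50% -> deleterious)
    VariantRecord(chrom="13", pos=48_611_934, variant_id="rs186364861",
                  ref_allele="G", alt_allele="A", gene_symbol="NUDT15",
                  vaf=0.01607, consequence="missense",
                  predictor_calls={"SIFT": "damaging", "PolyPhen2": "damaging",
                                   "PROVEAN": "tolerated"}),
    # a common splice donor: loss-of-function regardless of rarity
    VariantRecord(chrom="16", pos=28_631_383, variant_id="rs79527462",
                  ref_allele="C", alt_allele="G", gene_symbol="SULT1A1",
                  vaf=0.0871, consequence="splice_donor"),
    # missense with one available call, tolerated -> neutral
    VariantRecord(chrom="12", pos=21_331_549, variant_id="rs4149056",
                  ref_allele="T", alt_allele="C", gene_symbol="SLCO1B1",
                  vaf=0.002, consequence="missense",
                  predictor_calls={"SIFT": "tolerated", "PolyPhen2": "missing",
                                   "PROVEAN": "missing"}),
    # a common synonymous variant: non-functional
    VariantRecord(chrom="6", pos=18_130_918, variant_id="rs1142345",
                  ref_allele="T", alt_allele="C", gene_symbol="TPMT",
                  vaf=0.0129, consequence="synonymous"),
]

print(f"{'gene':<10}{'vaf':>9}  {'rarity':<8}{'class':<24}functional")
for record in variants:
    cv = classify_variant(record)
    print(
        f"{record.gene_symbol:<10}{record.vaf:>9.4f}  "
        f"{cv.rarity.value:<8}{cv.functional_class.value:<24}{cv.is_functional}"
    )

# 'functional' marks the union of deleterious missense and loss-of-function
# variants -- the classes whose per-gene VAF sum forms the aggregated
# functional-variant frequency.
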