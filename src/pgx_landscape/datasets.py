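"""Bundled reference data.

``clinical_vaf_table`` carries the published multi-population variant
allele frequencies for eight clinically relevant pharmacogene variants
(ABCC4, SLCO1B1, ALDH2, TPMT, UGT1A1, VDR and NUDT15 polymorphisms) in
the CMDB Chinese cohort (141,431 genomes) and nine gnomAD v3.1
populations.  The CMDB allele number is 2 x 141,431 = 282,862; gnomAD
per-population allele numbers are not part of the published summary and
must be supplied by the caller before contingency testing.

``PUBLISHED_COUNTS`` carries the study's headline numerator/denominator
pairs (total, novel, rare, exonic variants and the rare fractions of the
functional classes), used as worked-example inputs for the reporting
layer.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from .model import PopulationVAF

#: 2 x 141,431 genomes.
CMDB_N_ALLELES = 282_862

CMDB_POPULATION = "CMDB_Chinese"

GNOMAD_POPULATIONS = (
    "African",
    "Ashkenazi_Jewish",
    "Amish",
    "Middle_Eastern",
    "Latino",
    "European_non_Finnish",
    "European_Finnish",
    "East_Asian",
    "South_Asian",
)

# Per variant: key, gene, rsid, then the nine gnomAD VAFs in the order of
# GNOMAD_POPULATIONS followed by the CMDB Chinese VAF.
_CLINICAL_VAF_ROWS = [
    ("13", 95_859_035, "C", "A", "ABCC4", "rs2274407",
     [0.167, 0.1325, 0.01429, 0.121, 0.08122, 0.06825, 0.06309, 0.1759, 0.1456], 0.126),
    ("13", 95_863_008, "C", "A", "ABCC4", "rs11568658",
     [0.004779, 0.0415, 0.1404, 0.05063, 0.08711, 0.02346, 0.04566, 0.1146, 0.05763], 0.1155),
    ("12", 21_331_549, "T", "C", "SLCO1B1", "rs4149056",
     [0.03168, 0.1771, 0.06798, 0.2057, 0.13, 0.1587, 0.2178, 0.1279, 0.04888], 0.1085),
    ("12", 112_241_766, "G", "A", "ALDH2", "rs671",
     [0.0001931, 0.0, 0.0, 0.0, 0.0009178, 0.0000294, 0.00009436, 0.2247, 0.0008292], 0.2021),
    ("6", 18_130_918, "T", "C", "TPMT", "rs1142345",
     [0.05485, 0.01902, 0.0165, 0.02532, 0.05058, 0.04227, 0.0293, 0.01366, 0.01863], 0.01291),
    ("2", 234_676_872, "C", "T", "UGT1A1", "rs34946978",
     [0.0002171, 0.0, 0.0, 0.0, 0.001767, 0.0000294, 0.0, 0.01196, 0.001242], 0.01986),
    ("12", 48_272_895, "A", "G", "VDR", "rs2228570",
     [0.7799, 0.5716, 0.7368, 0.7025, 0.5778, 0.6162, 0.644, 0.5698, 0.7387], 0.5141),
    ("13", 48_611_934, "G", "A", "NUDT15", "rs186364861",
     [0.0, 0.000288, 0.0, 0.0, 0.0, 0.0000147, 0.0, 0.01121, 0.0008271], 0.01607),
]


def clinical_vaf_table(
    gnomad_n_alleles: Optional[Dict[str, int]] = None,
    default_gnomad_n_alleles: int = 50_000,
) -> List[PopulationVAF]:
    """The eight clinically relevant variants as population VAF records.

    Parameters
    ----------
    gnomad_n_alleles
        Mapping gnomAD population name -> total allele number.  gnomAD
        allele numbers are not part of the bundled summary; callers who
        need faithful contingency tests must supply the real values.
    default_gnomad_n_alleles
        Fallback allele number for populations absent from the mapping.
    """
    gnomad_n_alleles = gnomad_n_alleles or {}
    rows: List[PopulationVAF] = []
    for chrom, pos, ref, alt, _gene, _rsid, gnomad_vafs, cmdb_vaf in _CLINICAL_VAF_ROWS:
        key = (chrom, pos, ref, alt)
        rows.append(
            PopulationVAF(
                variant_key=key,
                population=CMDB_POPULATION,
                vaf=cmdb_vaf,
                n_alleles=CMDB_N_ALLELES,
            )
        )
        for name, vaf in zip(GNOMAD_POPULATIONS, gnomad_vafs):
            rows.append(
                PopulationVAF(
                    variant_key=key,
                    population=name,
                    vaf=vaf,
                    n_alleles=gnomad_n_alleles.get(name, default_gnomad_n_alleles),
                )
            )
    return rows


#: Headline numerator/denominator count pairs from the source cohort, used
#: as worked-example inputs for the percentage-reporting layer.
PUBLISHED_COUNTS = {
    "n_variants": 38_188,
    "n_novel": 1_038,
    "n_rare": 14_294,
    "n_exonic": 2_554,
    "n_missense": 1_063,
    "n_utr": 799,
    "n_synonymous": 638,
    "n_deleterious_missense": 617,
    "n_deleterious_missense_rare": 562,
    "n_deleterious_missense_common": 55,
    "n_lof": 54,
    "n_lof_rare": 53,
    "n_abc_deleterious_missense_rare": 157,
    "n_abc_deleterious_missense": 163,
    "n_rare_majority_genes": 98,
    "n_genes": 125,
}

#: Highest and lowest positive per-gene aggregated functional-variant
#: frequencies (percent) in the source cohort (GSTA5 and IFNL3).
PUBLISHED_FREQ_EXTREMES = {"max_pct": 88.17, "min_pct": 0.09}
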