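"""Synthetic cohort-scale variant tables with known ground truth.

The generator emulates the summary-level shape of a large biobank variant
table over a pharmacogene panel: a 125-gene panel split across six
families, per-gene variant counts proportional to gene length, a
configurable rare-variant fraction (default 37.4% below 1% VAF), a
consequence mix dominated by intronic variants with a small exonic slice,
a transition-biased substitution spectrum with C>T and G>A most frequent,
a configurable novel-ID probability, and a latent-deleteriousness model
for missense variants observed through three noisy predictors.

Population VAF tables are drawn from the Balding-Nichols model: around an
ancestral frequency p, each population's frequency is Beta(p(1-F)/F,
(1-p)(1-F)/F) for divergence F, then discretized to allele counts.

Every operation draws from a named substream of one integer seed, so a
fixed configuration reproduces byte-identical output files.  A truth
table records each missense variant's latent state for recovery tests; it
is written separately and never read by the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import round_half_up
from .model import (
    PREDICTORS,
    Consequence,
    Family,
    GeneInfo,
    PopulationVAF,
    PredictorCall,
    VariantRecord,
)

#: Family sizes of the default pharmacogene panel (125 genes).
DEFAULT_GENES_PER_FAMILY = {
    Family.ABC: 16,
    Family.SLC: 50,
    Family.PHASE1: 17,
    Family.PHASE2: 26,
    Family.NUCLEAR_RECEPTOR: 9,
    Family.OTHER: 7,
}

#: Log-normal gene-length parameters per family: (mean, sigma) of log kb.
#: ABC transporters are the longest genes on average.
DEFAULT_LENGTH_KB_LOGNORMAL = {
    Family.ABC: (np.log(80.0), 0.7),
    Family.SLC: (np.log(45.0), 0.7),
    Family.PHASE1: (np.log(40.0), 0.7),
    Family.PHASE2: (np.log(35.0), 0.7),
    Family.NUCLEAR_RECEPTOR: (np.log(50.0), 0.7),
    Family.OTHER: (np.log(35.0), 0.7),
}

# Consequence mix: ~93.3% non-coding; the exonic slice (6.69%) split into
# missense/UTR/synonymous with a thin loss-of-function tail across the four
# LoF categories.
DEFAULT_CONSEQUENCE_PROBS = {
    Consequence.INTRONIC: 0.800,
    Consequence.UPSTREAM: 0.070,
    Consequence.DOWNSTREAM: 0.0631203,
    Consequence.MISSENSE: 1063 / 38188,
    Consequence.UTR: 799 / 38188,
    Consequence.SYNONYMOUS: 638 / 38188,
    Consequence.SPLICE_ACCEPTOR: 4 / 38188,
    Consequence.SPLICE_DONOR: 4 / 38188,
    Consequence.START_LOST: 8 / 38188,
    Consequence.STOP_GAINED: 38 / 38188,
}

# Substitution-type probabilities: C>T and G>A dominate; overall Ti/Tv ~2.2.
_TI = {"C>T": 0.253, "G>A": 0.248, "A>G": 0.092, "T>C": 0.092}
_TV_TYPES = ["A>C", "A>T", "C>A", "C>G", "G>C", "G>T", "T>A", "T>G"]
DEFAULT_SUBSTITUTION_PROBS = {
    **_TI,
    **{t: (1.0 - sum(_TI.values())) / len(_TV_TYPES) for t in _TV_TYPES},
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic variant-table generator.

    Attributes
    ----------
    rare_target
        Intended fraction of variants with VAF < 1%.  VAF is a two-bin
        uniform mixture: with probability ``rare_target`` draw
        Uniform(1/(2N), 0.01), else Uniform(0.01, 0.5).
    p_deleterious_latent
        Probability that a missense variant is truly deleterious; the
        three predictors observe this latent state with per-tool accuracy
        ``predictor_accuracy`` and missingness ``p_missing_call``.
    fst
        Balding-Nichols divergence used for population VAF tables.
    """

    seed: int = 0
    genes_per_family: Dict[Family, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_FAMILY)
    )
    length_kb_lognormal: Dict[Family, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_KB_LOGNORMAL)
    )
    variants_per_kb: float = 5.0
    rare_target: float = 0.374
    n_cohort_alleles: int = 2 * 141_431
    consequence_probs: Dict[Consequence, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS)
    )
    substitution_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_PROBS)
    )
    p_deleterious_latent: float = 617 / 1063
    predictor_accuracy: float = 0.95
    p_missing_call: float = 0.05
    p_novel: float = 0.027
    p_low_quality: float = 0.02
    vqsr_threshold: float = 35.0
    fst: float = 0.1
    n_populations: int = 10
    n_alleles_per_population: int = 20_000

    def __post_init__(self) -> None:
        for name in (
            "rare_target",
            "p_deleterious_latent",
            "predictor_accuracy",
            "p_missing_call",
            "p_novel",
            "p_low_quality",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.variants_per_kb <= 0:
            raise ValueError("variants_per_kb must be positive")
        total = sum(self.consequence_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"consequence_probs must sum to 1, got {total}")
        total = sum(self.substitution_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"substitution_probs must sum to 1, got {total}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Named independent substream of the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(hash_stream(stream),))
    )


def hash_stream(name: str) -> int:
    """Stable small integer for a stream name (platform-independent)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def generate_panel(config: SimConfig) -> List[GeneInfo]:
    """Sample a synthetic gene panel with non-overlapping coordinates.

    One synthetic chromosome per family; genes are laid end-to-end with a
    100 kb gap so coordinates never overlap.
    """
    if sum(config.genes_per_family.values()) == 0:
        raise ValueError("panel must contain at least one gene")
    rng = _rng(config, "panel")
    genes: List[GeneInfo] = []
    for family in Family:
        count = config.genes_per_family.get(family, 0)
        if count == 0:
            continue
        mu, sigma = config.length_kb_lognormal[family]
        lengths_kb = np.exp(rng.normal(mu, sigma, size=count))
        chrom = f"chr_{family.value}"
        cursor = 1
        for i, length_kb in enumerate(lengths_kb):
            length_bp = max(int(round(length_kb * 1000)), 1000)
            genes.append(
                GeneInfo(
                    symbol=f"{family.value}{i + 1}",
                    family=family,
                    chrom=chrom,
                    start=cursor,
                    end=cursor + length_bp - 1,
                )
            )
            cursor += length_bp + 100_000
    return genes


def _draw_vaf(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Two-bin uniform VAF mixture with a controllable rare fraction."""
    lo = 1.0 / config.n_cohort_alleles
    rare = rng.random(n) < config.rare_target
    vaf = np.where(
        rare,
        rng.uniform(lo, 0.01, size=n),
        rng.uniform(0.01, 0.5, size=n),
    )
    return vaf


def generate_variants(
    panel: Sequence[GeneInfo], config: SimConfig
) -> Tuple[List[VariantRecord], pd.DataFrame]:
    """Generate annotated variant records and the latent truth table.

    Per gene the variant count is Poisson(length_kb x variants_per_kb)
    with positions uniform within the gene.  Missense variants receive a
    latent deleterious state and three noisy predictor calls; the truth
    table records the latent state for every variant so classifier
    recovery can be measured without leaking into the pipeline.
    """
    rng = _rng(config, "variants")
    consequences = list(config.consequence_probs)
    cons_p = np.array([config.consequence_probs[c] for c in consequences])
    cons_p = cons_p / cons_p.sum()
    sub_types = sorted(config.substitution_probs)
    sub_p = np.array([config.substitution_probs[t] for t in sub_types])
    sub_p = sub_p / sub_p.sum()

    records: List[VariantRecord] = []
    truth_rows: List[dict] = []
    rs_counter = 1_000_000
    for gene in panel:
        n = int(rng.poisson(gene.length_kb * config.variants_per_kb))
        n = min(n, gene.end - gene.start + 1)
        positions = np.sort(
            rng.choice(gene.end - gene.start + 1, size=n, replace=False)
        ) + gene.start
        subs = rng.choice(len(sub_types), size=n, p=sub_p)
        cons_idx = rng.choice(len(consequences), size=n, p=cons_p)
        vafs = _draw_vaf(rng, config, n)
        novel = rng.random(n) < config.p_novel
        low_quality = rng.random(n) < config.p_low_quality
        vqsr = np.where(
            low_quality,
            rng.uniform(0.0, config.vqsr_threshold, size=n),
            rng.uniform(config.vqsr_threshold, 99.0, size=n),
        )
        for i in range(n):
            ref, alt = sub_types[subs[i]].split(">")
            consequence = consequences[cons_idx[i]]
            latent_deleterious = False
            calls = {p: PredictorCall.MISSING for p in PREDICTORS}
            if consequence is Consequence.MISSENSE:
                latent_deleterious = bool(rng.random() < config.p_deleterious_latent)
                for pred in PREDICTORS:
                    if rng.random() < config.p_missing_call:
                        continue
                    correct = rng.random() < config.predictor_accuracy
                    damaging = latent_deleterious if correct else not latent_deleterious
                    calls[pred] = (
                        PredictorCall.DAMAGING if damaging else PredictorCall.TOLERATED
                    )
            if novel[i]:
                variant_id = None
            else:
                variant_id = f"rs{rs_counter}"
                rs_counter += 1
            record = VariantRecord(
                chrom=gene.chrom,
                pos=int(positions[i]),
                variant_id=variant_id,
                ref_allele=ref,
                alt_allele=alt,
                gene_symbol=gene.symbol,
                vaf=float(round(vafs[i], 10)),
                consequence=consequence,
                predictor_calls=calls,
                vqsr_score=float(round(vqsr[i], 4)),
                cadd_phred=None,
            )
            records.append(record)
            truth_rows.append(
                {
                    "chrom": record.chrom,
                    "pos": record.pos,
                    "ref": record.ref_allele,
                    "alt": record.alt_allele,
                    "gene": gene.symbol,
                    "consequence": consequence.value,
                    "vaf": record.vaf,
                    "latent_deleterious": latent_deleterious,
                    "low_quality": bool(low_quality[i]),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene",
            "consequence",
            "vaf",
            "latent_deleterious",
            "low_quality",
        ],
    )
    return records, truth


def generate_population_table(
    variants: Sequence[VariantRecord], config: SimConfig
) -> List[PopulationVAF]:
    """Draw per-population VAFs around each variant's cohort frequency.

    Balding-Nichols: population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
    for ancestral frequency p and divergence F; frequencies are then
    discretized to allele counts at ``n_alleles_per_population`` and
    converted back, so every reported VAF is an achievable count ratio.
    F = 0 degenerates to all populations sharing p exactly.
    """
    if not 0.0 <= config.fst < 1.0:
        raise ValueError(f"fst must be in [0, 1), got {config.fst}")
    rng = _rng(config, "populations")
    n_alleles = config.n_alleles_per_population
    rows: List[PopulationVAF] = []
    for rec in variants:
        p = rec.vaf
        for k in range(config.n_populations):
            name = f"POP{k + 1}"
            if config.fst == 0.0 or p in (0.0, 1.0):
                freq = p
            else:
                scale = (1.0 - config.fst) / config.fst
                freq = float(rng.beta(p * scale, (1.0 - p) * scale))
            alt = int(round_half_up(freq * n_alleles, 0))
            rows.append(
                PopulationVAF(
                    variant_key=rec.key,
                    population=name,
                    vaf=alt / n_alleles,
                    n_alleles=n_alleles,
                )
            )
    return rows
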