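"""End-to-end orchestration: simulate/ingest -> classify -> aggregate -> stats.

A run is driven by one YAML config with either a ``simulate`` block (the
synthetic generator writes and then consumes its own inputs) or an
``inputs`` block pointing at a VCF, annotation table and gene panel.  All
report tables plus a JSON manifest land in the output directory; a rerun
with identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    cohort_overview,
    family_summaries_frame,
    fold_range,
    gene_summaries_frame,
    spectrum_frame,
    substitution_spectrum,
    summarize_family,
    summarize_gene,
)
from .classify import DEFAULT_VQSR_THRESHOLD, classify_all, filter_vqsr
from .io import (
    ReportBundle,
    read_gene_panel,
    read_population_table,
    read_variant_table,
    write_annotations,
    write_gene_panel,
    write_population_table,
    write_report,
    write_vcf,
)
from .model import ClassifiedVariant, Family, FunctionalClass, GeneInfo, Rarity
from .popstats import (
    DEFAULT_M_COMPARISONS,
    DEFAULT_M_REGRESSIONS,
    bonferroni_alpha,
    compare_against_reference,
    kruskal_wallis_by_family,
    regress_counts_on_length,
)
from .synthetic import (
    SimConfig,
    generate_panel,
    generate_population_table,
    generate_variants,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for malformed or incomplete run configurations."""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _sim_config_from_dict(block: dict, seed: Optional[int]) -> SimConfig:
    kwargs = dict(block or {})
    if "genes_per_family" in kwargs:
        kwargs["genes_per_family"] = {
            Family(k): int(v) for k, v in kwargs["genes_per_family"].items()
        }
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def _variants_frame(classified: List[ClassifiedVariant]) -> pd.DataFrame:
    rows = []
    for cv in classified:
        rec = cv.record
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "id": rec.variant_id or ".",
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "gene": rec.gene_symbol,
                "consequence": rec.consequence.value,
                "vaf": rec.vaf,
                "novel": rec.is_novel,
                "rarity": cv.rarity.value,
                "functional_class": cv.functional_class.value,
                "is_functional": cv.is_functional,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "id", "ref", "alt", "gene", "consequence", "vaf",
            "novel", "rarity", "functional_class", "is_functional",
        ],
    )
    return frame.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(
        drop=True
    )


def analyze(
    classified: List[ClassifiedVariant],
    panel: List[GeneInfo],
    population_rows=None,
    aggregation: str = "sum",
    m_regressions: int = DEFAULT_M_REGRESSIONS,
    m_comparisons: int = DEFAULT_M_COMPARISONS,
    reference_population: Optional[str] = None,
) -> ReportBundle:
    """Aggregate classified variants over a panel and run the statistics.

    Returns a :class:`ReportBundle` ready for :func:`pgx_landscape.io.write_report`.
    """
    by_gene: Dict[str, List[ClassifiedVariant]] = {g.symbol: [] for g in panel}
    rejects = []
    resolved: List[ClassifiedVariant] = []
    for cv in classified:
        bucket = by_gene.get(cv.record.gene_symbol)
        if bucket is None:
            rejects.append({"key": cv.record.key, "reason": "gene not in panel"})
        else:
            bucket.append(cv)
            resolved.append(cv)

    gene_summaries = [
        summarize_gene(by_gene[g.symbol], g, aggregation=aggregation) for g in panel
    ]
    lof_counts = {
        g.symbol: sum(
            cv.functional_class is FunctionalClass.LOF for cv in by_gene[g.symbol]
        )
        for g in panel
    }
    deleterious_counts = {}
    for g in panel:
        dels = [
            cv
            for cv in by_gene[g.symbol]
            if cv.functional_class is FunctionalClass.DELETERIOUS_MISSENSE
        ]
        deleterious_counts[g.symbol] = {
            "total": len(dels),
            "rare": sum(cv.rarity is Rarity.RARE for cv in dels),
        }
    families = sorted({g.family for g in panel}, key=lambda f: f.value)
    family_summaries = []
    for family in families:
        members = [gs for gs in gene_summaries if gs.family is family]
        symbols = {gs.symbol for gs in members}
        family_summaries.append(
            summarize_family(
                members,
                lof_counts={s: lof_counts[s] for s in symbols},
                deleterious_counts={s: deleterious_counts[s] for s in symbols},
            )
        )

    overview = cohort_overview(resolved)
    try:
        overview["fold_range"] = fold_range(gene_summaries)
    except ValueError:
        overview["fold_range"] = None

    fam_groups = {
        f.value: [gs.n_total for gs in gene_summaries if gs.family is f] for f in families
    }
    fam_groups = {k: v for k, v in fam_groups.items() if v}
    if len(fam_groups) >= 2:
        h, p = kruskal_wallis_by_family(fam_groups)
        overview["kruskal_wallis_total_counts"] = {"H": h, "p_value": p}

    length_by_symbol = {g.symbol: g.length_kb for g in panel}
    alpha_reg = bonferroni_alpha(0.05, m_regressions)
    regression_rows = []
    for family in families:
        members = [gs for gs in gene_summaries if gs.family is family]
        if len(members) < 3:
            continue
        lengths = [length_by_symbol[gs.symbol] for gs in members]
        if len(set(lengths)) < 2:
            continue
        responses = {
            "total": [gs.n_total for gs in members],
            "missense": [gs.consequence_counts["missense"] for gs in members],
            "deleterious": [
                deleterious_counts[gs.symbol]["total"] for gs in members
            ],
        }
        for label, counts in responses.items():
            result = regress_counts_on_length(
                list(zip(lengths, counts)),
                response_label=label,
                family=family.value,
                alpha_adjusted=alpha_reg,
            )
            regression_rows.append(
                {
                    "family": result.family,
                    "response": result.response,
                    "n_genes": result.n_genes,
                    "slope_per_kb": result.slope,
                    "intercept": result.intercept,
                    "r_squared": result.r_squared,
                    "p_value": result.p_value,
                    "alpha_adjusted": result.alpha_adjusted,
                    "significant": result.significant,
                }
            )
    regressions = pd.DataFrame(regression_rows) if regression_rows else None

    comparisons = None
    if population_rows:
        if reference_population is None:
            reference_population = sorted({r.population for r in population_rows})[0]
        results = compare_against_reference(
            population_rows, reference_population, m=m_comparisons
        )
        comparisons = pd.DataFrame(
            [
                {
                    "chrom": r.variant_key[0],
                    "pos": r.variant_key[1],
                    "ref": r.variant_key[2],
                    "alt": r.variant_key[3],
                    "population_a": r.population_a,
                    "population_b": r.population_b,
                    "alt_a": r.table[0][0],
                    "ref_a": r.table[0][1],
                    "alt_b": r.table[1][0],
                    "ref_b": r.table[1][1],
                    "test_used": r.test_used,
                    "statistic": "" if r.statistic is None else f"{r.statistic:.10g}",
                    "p_value": r.p_value,
                    "alpha_adjusted": r.alpha_adjusted,
                    "significant": r.significant,
                    "degenerate": r.degenerate,
                }
                for r in results
            ]
        )

    spectrum = substitution_spectrum(resolved)
    return ReportBundle(
        variants=_variants_frame(resolved),
        gene_summaries=gene_summaries_frame(gene_summaries),
        family_summaries=family_summaries_frame(family_summaries),
        spectrum=spectrum_frame(spectrum),
        overview=overview,
        regressions=regressions,
        comparisons=comparisons,
        rejects=rejects,
    )


def run_landscape(
    config_path,
    out_dir=None,
    seed: Optional[int] = None,
) -> dict:
    """Execute a full run from a YAML config; returns the manifest dict.

    The config has a ``simulate`` or ``inputs`` section, plus optional
    ``classify`` (vqsr_threshold, cadd_threshold), ``aggregate``
    (aggregation), ``stats`` (m_regressions, m_comparisons,
    reference_population) and ``report`` (out_dir) sections.  ``out_dir``
    and ``seed`` arguments override the config.
    """
    config_path = Path(config_path)
    with open(config_path, "r", encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}

    out = Path(out_dir or config.get("report", {}).get("out_dir", "landscape_out"))
    out.mkdir(parents=True, exist_ok=True)

    classify_cfg = config.get("classify", {}) or {}
    vqsr_threshold = float(classify_cfg.get("vqsr_threshold", DEFAULT_VQSR_THRESHOLD))
    cadd_threshold = classify_cfg.get("cadd_threshold")
    cadd_threshold = None if cadd_threshold in (None, "none") else float(cadd_threshold)
    aggregation = (config.get("aggregate", {}) or {}).get("aggregation", "sum")
    stats_cfg = config.get("stats", {}) or {}

    input_digests = {}
    annot_rejects: List[dict] = []
    if "simulate" in config:
        sim = _sim_config_from_dict(config["simulate"], seed)
        logger.info("simulating cohort with seed %d", sim.seed)
        panel = generate_panel(sim)
        records, truth = generate_variants(panel, sim)
        population_rows = generate_population_table(
            [r for r in records if r.vaf >= 0.01][:200], sim
        )
        write_vcf(records, out / "variants.vcf")
        write_annotations(records, out / "annotations.tsv")
        write_gene_panel(panel, out / "panel.tsv")
        write_population_table(population_rows, out / "populations.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.10g")
        seed_used = sim.seed
    elif "inputs" in config:
        inputs = config["inputs"] or {}
        for key in ("vcf", "annotations", "panel"):
            if key not in inputs:
                raise ConfigError(f"inputs section is missing {key!r}")
        base = config_path.parent
        paths = {
            k: (base / v if not Path(v).is_absolute() else Path(v))
            for k, v in inputs.items()
        }
        for key, path in paths.items():
            if not path.exists():
                raise ConfigError(f"input {key!r} not found: {path}")
            input_digests[key] = _sha256(path)
        panel = read_gene_panel(paths["panel"])
        records, annot_rejects = read_variant_table(paths["vcf"], paths["annotations"])
        population_rows = (
            read_population_table(paths["populations"]) if "populations" in paths else None
        )
        seed_used = seed if seed is not None else int(config.get("seed", 0))
    else:
        raise ConfigError("config must contain a 'simulate' or an 'inputs' section")

    n_input = len(records)
    kept, dropped, n_unscored = filter_vqsr(records, vqsr_threshold)
    logger.info(
        "VQSR filter at %.1f: kept %d / %d (%d unscored)",
        vqsr_threshold,
        len(kept),
        n_input,
        n_unscored,
    )
    classified = classify_all(kept, cadd_threshold=cadd_threshold)

    bundle = analyze(
        classified,
        panel,
        population_rows=population_rows,
        aggregation=aggregation,
        m_regressions=int(stats_cfg.get("m_regressions", DEFAULT_M_REGRESSIONS)),
        m_comparisons=int(stats_cfg.get("m_comparisons", DEFAULT_M_COMPARISONS)),
        reference_population=stats_cfg.get("reference_population"),
    )
    bundle.rejects = annot_rejects + bundle.rejects

    manifest = {
        "software": "pgx-landscape",
        "version": __version__,
        "seed": seed_used,
        "config": config,
        "input_digests": input_digests,
        "counts": {
            "input": n_input,
            "post_vqsr": len(kept),
            "vqsr_dropped": len(dropped),
            "vqsr_unscored": n_unscored,
            "classified": len(bundle.variants),
            "rejected_no_annotation": len(annot_rejects),
            "rejected_gene_not_in_panel": len(classified) - len(bundle.variants),
        },
    }
    bundle.manifest = manifest

    written = []
    try:
        written = write_report(bundle, out)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    logger.info("wrote %d report files to %s", len(written), out)
    return manifest
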