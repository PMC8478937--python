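"""Readers and writers for the pipeline's external table formats.

Variant sites arrive as a minimal VCF (CHROM, POS, ID, REF, ALT, INFO:AF,
plain or gzipped) paired with a tab-separated annotation table keyed by
(chrom, pos, ref, alt); the gene panel, population VAF table and all
report outputs are tab-separated UTF-8 with a header row.  The VCF reader
is a purpose-built minimal parser so allele frequencies round-trip at
full decimal precision (a general-purpose htslib reader stores INFO
floats at single precision).  Coordinates are 1-based inclusive
(VCF convention) throughout; a panel supplied as ``.bed`` is converted
from 0-based half-open on read.

Predictor annotations may be categorical calls (damaging / tolerated /
missing) or raw scores; scores are converted at each tool's published
default cutoff: SIFT < 0.05, PolyPhen2 >= 0.446, PROVEAN <= -2.5 are
damaging.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gzip

import pandas as pd

from .model import (
    PREDICTORS,
    Consequence,
    Family,
    GeneInfo,
    PopulationVAF,
    PredictorCall,
    VariantRecord,
)

# Published default deleteriousness cutoffs for score-valued annotations.
SCORE_CUTOFFS = {
    "SIFT": lambda s: s < 0.05,
    "PolyPhen2": lambda s: s >= 0.446,
    "PROVEAN": lambda s: s <= -2.5,
}

_PREDICTOR_COLUMNS = {"SIFT": "sift", "PolyPhen2": "polyphen2", "PROVEAN": "provean"}


def _left_trim(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim the shared leading prefix of an allele pair, keeping >= 1 base."""
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def _normalize_key(chrom: str, pos: int, ref: str, alt: str) -> Tuple[str, int, str, str]:
    pos, ref, alt = _left_trim(int(pos), str(ref).upper(), str(alt).upper())
    return (str(chrom), pos, ref, alt)


def _parse_predictor_cell(predictor: str, cell: object) -> PredictorCall:
    """A cell is a call token, a numeric score, or empty (= missing)."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return PredictorCall.MISSING
    text = str(cell).strip()
    if text == "" or text.lower() in ("na", "nan", "."):
        return PredictorCall.MISSING
    lowered = text.lower()
    if lowered in ("damaging", "tolerated", "missing"):
        return PredictorCall(lowered)
    try:
        score = float(text)
    except ValueError as exc:
        raise ValueError(
            f"unrecognized {predictor} annotation {text!r}: expected damaging/"
            "tolerated/missing or a numeric score"
        ) from exc
    return (
        PredictorCall.DAMAGING if SCORE_CUTOFFS[predictor](score) else PredictorCall.TOLERATED
    )


def _parse_consequence(text: str) -> Consequence:
    try:
        return Consequence(str(text).strip().lower())
    except ValueError:
        allowed = ", ".join(c.value for c in Consequence)
        raise ValueError(
            f"unknown consequence {text!r}; allowed values: {allowed}"
        ) from None


def _read_annotations(path: os.PathLike) -> Dict[Tuple[str, int, str, str], dict]:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    annotations: Dict[Tuple[str, int, str, str], dict] = {}
    for row in table.itertuples(index=False):
        key = _normalize_key(row.chrom, row.pos, row.ref, row.alt)
        if key in annotations:
            raise ValueError(f"annotation key collision for {key}")
        calls = {
            pred: _parse_predictor_cell(pred, getattr(row, col, None))
            for pred, col in _PREDICTOR_COLUMNS.items()
        }
        cadd = getattr(row, "cadd_phred", None)
        cadd = None if cadd is None or pd.isna(cadd) else float(cadd)
        vqsr = getattr(row, "vqsr", None)
        vqsr = None if vqsr is None or pd.isna(vqsr) else float(vqsr)
        annotations[key] = {
            "gene_symbol": str(row.gene),
            "consequence": _parse_consequence(row.consequence),
            "predictor_calls": calls,
            "cadd_phred": cadd,
            "vqsr_score": vqsr,
        }
    return annotations


def read_variant_table(
    vcf_path: os.PathLike, annotation_path: os.PathLike
) -> Tuple[List[VariantRecord], List[dict]]:
    """Read a minimal VCF joined to its annotation table.

    Multi-allelic rows are split into one record per ALT allele.  Rows
    whose (chrom, pos, ref, alt) key has no annotation are rejected and
    returned in the second element as ``{"key", "reason"}`` dicts.

    Raises
    ------
    ValueError
        If a row lacks an INFO AF value, an annotation key occurs twice,
        or a consequence string falls outside the vocabulary.
    """
    annotations = _read_annotations(annotation_path)
    records: List[VariantRecord] = []
    rejected: List[dict] = []
    opener = gzip.open if str(vcf_path).endswith(".gz") else open
    with opener(os.fspath(vcf_path), "rt", encoding="utf-8") as vcf:
        for line_no, line in enumerate(vcf, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"VCF line {line_no}: expected >= 8 columns, got {len(fields)}")
            chrom, pos, vid, ref, alt_field, _qual, _filter, info = fields[:8]
            alts = alt_field.split(",")
            info_map = dict(
                entry.split("=", 1) if "=" in entry else (entry, True)
                for entry in info.split(";")
                if entry
            )
            if "AF" not in info_map:
                raise ValueError(f"missing INFO AF at VCF line {line_no} ({chrom}:{pos})")
            afs = str(info_map["AF"]).split(",")
            if len(afs) != len(alts):
                raise ValueError(
                    f"VCF line {line_no} ({chrom}:{pos}): {len(afs)} AF values "
                    f"for {len(alts)} ALT alleles"
                )
            variant_id = None if vid in (".", "") else vid
            for alt, af in zip(alts, afs):
                key = _normalize_key(chrom, int(pos), ref, alt)
                annot = annotations.get(key)
                if annot is None:
                    rejected.append({"key": key, "reason": "no annotation"})
                    continue
                records.append(
                    VariantRecord(
                        chrom=key[0],
                        pos=key[1],
                        variant_id=variant_id,
                        ref_allele=key[2],
                        alt_allele=key[3],
                        vaf=float(af),
                        **annot,
                    )
                )
    return records, rejected


def read_gene_panel(path: os.PathLike) -> List[GeneInfo]:
    """Read a gene panel from TSV (1-based inclusive) or BED (0-based half-open).

    The dialect is declared by the file extension: ``.bed`` means BED4+
    columns chrom/start/end/symbol/family without a header; anything else
    is a TSV with header columns symbol/family/chrom/start/end.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "symbol", "family"],
            dtype={"chrom": str},
        )
        table["start"] = table["start"] + 1  # BED start is 0-based
    else:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"symbol", "family", "chrom", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"gene panel missing columns: {sorted(missing)}")
    dup = table["symbol"][table["symbol"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene symbols in panel: {sorted(dup.unique())}")
    genes = []
    for row in table.itertuples(index=False):
        try:
            family = Family(str(row.family))
        except ValueError:
            allowed = ", ".join(f.value for f in Family)
            raise ValueError(
                f"unknown family {row.family!r} for gene {row.symbol}; "
                f"allowed: {allowed}"
            ) from None
        genes.append(
            GeneInfo(
                symbol=str(row.symbol),
                family=family,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
            )
        )
    return genes


def read_population_table(path: os.PathLike) -> List[PopulationVAF]:
    """Read a long-format population VAF table.

    Columns: chrom, pos, ref, alt, population, vaf, n_alleles.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "population", "vaf", "n_alleles"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    return [
        PopulationVAF(
            variant_key=_normalize_key(row.chrom, row.pos, row.ref, row.alt),
            population=str(row.population),
            vaf=float(row.vaf),
            n_alleles=int(row.n_alleles),
        )
        for row in table.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

VCF_HEADER_TEMPLATE = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
    '##INFO=<ID=VQSR,Number=1,Type=Float,Description="Phred-scaled VQSR score">\n'
)


def write_vcf(records: Sequence[VariantRecord], path: os.PathLike) -> None:
    """Write variant records as a plain-text sorted VCF."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele))
    contigs = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    with open(path, "w", encoding="utf-8") as out:
        out.write(VCF_HEADER_TEMPLATE)
        for chrom in sorted(contigs):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = f"AF={rec.vaf:.10g}"
            if rec.vqsr_score is not None:
                info += f";VQSR={rec.vqsr_score:.6g}"
            out.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.variant_id or '.'}\t"
                f"{rec.ref_allele}\t{rec.alt_allele}\t.\t.\t{info}\n"
            )


def write_annotations(records: Sequence[VariantRecord], path: os.PathLike) -> None:
    """Write the annotation TSV matching :func:`read_variant_table`."""
    rows = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele, r.alt_allele)):
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref_allele,
            "alt": rec.alt_allele,
            "gene": rec.gene_symbol,
            "consequence": rec.consequence.value,
        }
        for pred, col in _PREDICTOR_COLUMNS.items():
            call = rec.predictor_calls[pred]
            row[col] = "" if call is PredictorCall.MISSING else call.value
        row["cadd_phred"] = "" if rec.cadd_phred is None else f"{rec.cadd_phred:.10g}"
        row["vqsr"] = "" if rec.vqsr_score is None else f"{rec.vqsr_score:.10g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gene_panel(genes: Sequence[GeneInfo], path: os.PathLike) -> None:
    rows = [
        {
            "symbol": g.symbol,
            "family": g.family.value,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
        }
        for g in sorted(genes, key=lambda g: g.symbol)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_population_table(rows: Sequence[PopulationVAF], path: os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            {
                "chrom": r.variant_key[0],
                "pos": r.variant_key[1],
                "ref": r.variant_key[2],
                "alt": r.variant_key[3],
                "population": r.population,
                "vaf": f"{r.vaf:.10g}",
                "n_alleles": r.n_alleles,
            }
            for r in rows
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, ready to be written."""

    variants: pd.DataFrame
    gene_summaries: pd.DataFrame
    family_summaries: pd.DataFrame
    spectrum: pd.DataFrame
    overview: dict
    regressions: Optional[pd.DataFrame] = None
    comparisons: Optional[pd.DataFrame] = None
    rejects: List[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def write_report(bundle: ReportBundle, out_dir: os.PathLike) -> List[Path]:
    """Write deterministic TSVs plus a JSON manifest; returns written paths.

    Given identical inputs and seed the bytes are identical across runs:
    floats are serialized to 10 significant digits and JSON keys sorted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _tsv(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    _tsv(bundle.variants, "classified_variants.tsv")
    _tsv(bundle.gene_summaries, "gene_summaries.tsv")
    _tsv(bundle.family_summaries, "family_summaries.tsv")
    _tsv(bundle.spectrum, "spectrum.tsv")
    if bundle.regressions is not None:
        _tsv(bundle.regressions, "regressions.tsv")
    if bundle.comparisons is not None:
        _tsv(bundle.comparisons, "comparisons.tsv")
    rejects = pd.DataFrame(bundle.rejects, columns=["key", "reason"])
    _tsv(rejects, "rejected_variants.tsv")

    for name, payload in (("overview.json", bundle.overview), ("manifest.json", bundle.manifest)):
        path = out_dir / name
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=2, sort_keys=True)
            out.write("\n")
        written.append(path)
    return written
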