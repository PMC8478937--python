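from pathlib import Path

import pytest

from pgx_landscape.model import PredictorCall, VariantRecord
from pgx_landscape.synthetic import SimConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def toy_paths(data_dir):
    return {
        "vcf": data_dir / "toy.vcf",
        "annotations": data_dir / "toy_annotations.tsv",
        "panel": data_dir / "toy_panel.tsv",
    }


@pytest.fixture
def small_sim_config() -> SimConfig:
    """A reduced-size generator config for fast end-to-end tests."""
    return SimConfig(seed=11, variants_per_kb=0.5)


def make_record(
    vaf=0.005,
    consequence="missense",
    calls=("damaging", "damaging", "damaging"),
    **kwargs,
) -> VariantRecord:
    defaults = dict(
        chrom="1",
        pos=100,
        variant_id="rs1",
        ref_allele="G",
        alt_allele="A",
        gene_symbol="GENEA",
        vaf=vaf,
        consequence=consequence,
        predictor_calls={
            "SIFT": PredictorCall(calls[0]),
            "PolyPhen2": PredictorCall(calls[1]),
            "PROVEAN": PredictorCall(calls[2]),
        },
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)
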