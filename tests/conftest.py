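import numpy as np
import pytest

from neoscreen import (
    ExpressionTable,
    MockRankPredictor,
    PatientBundle,
    PipelineConfig,
    ProteinRecord,
    Proteome,
    SomaticVariant,
    VariantKind,
    parse_hla_alleles,
)
from neoscreen.io import AMINO_ACIDS


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def toy_protein():
    # the reconstructed wild-type 27-mer around the ACAD8 T105I site,
    # used as a stand-alone toy protein with the substitution at position 14
    return ProteinRecord(
        id="ACAD8_toy", gene="ACAD8", sequence="QTDVGGSGLSRLDTSVIFEALATGCTS"
    )


@pytest.fixture
def toy_snv():
    return SomaticVariant(
        gene="ACAD8", protein_id="ACAD8_toy", kind=VariantKind.SNV,
        position=14, wt="T", alt="I", vaf=0.31,
    )


def random_protein(rng: np.random.Generator, pid: str, gene: str, length: int) -> ProteinRecord:
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(id=pid, gene=gene, sequence=seq)


@pytest.fixture
def random_proteome():
    rng = np.random.default_rng(42)
    return Proteome(
        random_protein(rng, f"P{i:03d}", f"G{i:03d}", 200) for i in range(50)
    )


def make_bundle(proteome, variants, tpm, allele_names="HLA-A*02:01,HLA-DRB1*11:01",
                patient_id="test"):
    return PatientBundle(
        patient_id=patient_id,
        proteome=proteome,
        variants=variants,
        expression=ExpressionTable(tpm),
        alleles=parse_hla_alleles(allele_names),
    )


@pytest.fixture
def mock_predictor():
    return MockRankPredictor(seed=7)
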