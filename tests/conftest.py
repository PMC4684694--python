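import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polarix.io_formats import TranscriptModel
from polarix.rna_ensemble import EnergyModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def energy_model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture()
def toy_transcript() -> TranscriptModel:
    """60 nt UTR5 + 10-codon CDS + 40 nt UTR3, junctions at 55 and 100.

    CDS codons: ATG AAA CCC GGG TTT ACG CAT GAC TGG TAA
    (codon 2 = AAA at positions 63-65).
    """
    utr5 = "ACGT" * 15
    cds = "ATGAAACCCGGGTTTACGCATGACTGGTAA"
    utr3 = "TGCA" * 10
    return TranscriptModel(
        tx_id="toy",
        gene_id="gene_toy",
        seq=utr5 + cds + utr3,
        utr5=(0, 60),
        cds=(60, 90),
        utr3=(90, 130),
        exon_ends=(55, 100),
    )


@pytest.fixture(scope="session")
def small_transcriptome():
    from polarix.synthetic_data import simulate_transcriptome

    return simulate_transcriptome(
        n_genes=30, mean_utr5=80, mean_cds_codons=80, mean_utr3=120, seed=11
    )


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
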