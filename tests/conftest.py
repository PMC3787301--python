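import numpy as np
import pytest

from melacog.pipeline import run_pipeline
from melacog.sequence_io import ProteinRecord, SimilarityHit
from melacog.synthetic_data import SimulationConfig

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20130926)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def make_hit():
    """Hit factory with sensible defaults for rule-level tests."""

    def _make(
        query="q",
        subject="s",
        pident=90.0,
        length=100,
        evalue=1e-30,
        bitscore=200.0,
        **kwargs,
    ):
        fields = dict(
            query_id=query,
            subject_id=subject,
            pident=pident,
            length=length,
            mismatch=int(round(length * (100 - pident) / 100)),
            gapopen=0,
            qstart=1,
            qend=length,
            sstart=1,
            send=length,
            evalue=evalue,
            bitscore=bitscore,
        )
        fields.update(kwargs)
        return SimilarityHit(**fields)

    return _make


@pytest.fixture(scope="session")
def default_pipeline_run():
    """One full pipeline run at the study's default conditions (4 genomes,
    200 families, divergence 0.05, no duplication/loss), seed fixed."""
    return run_pipeline(SimulationConfig(seed=1))
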