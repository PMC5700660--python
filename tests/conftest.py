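import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle_overlap importable

from genecontext import FixtureConfig, GenomeSet, make_dataset, run_analysis
from genecontext.annotation import DomainHit, ModelKind


def make_hit(
    ali_from=1,
    ali_to=100,
    score=100.0,
    model_len=100,
    protein_id="P1",
    model_acc="COG0001",
    kind=ModelKind.COG,
    evalue=1e-10,
):
    return DomainHit(
        protein_id=protein_id,
        model_acc=model_acc,
        model_kind=kind,
        model_len=model_len,
        ali_from=ali_from,
        ali_to=ali_to,
        score=score,
        evalue=evalue,
    )


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset: 10 genomes, operon planted in 4."""
    return make_dataset(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def analysis(dataset):
    """Full pipeline result for the target family on the default dataset."""
    return run_analysis(
        GenomeSet(dataset.replicons),
        dataset.cog_hits,
        dataset.pfam_hits,
        dataset.config.target_model,
        k=9,
        threshold=1.0,
        clans=dataset.clans,
    )
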