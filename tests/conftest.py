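from __future__ import annotations

import numpy as np
import pytest

from txomeval import orf_toolkit, peptide_evidence, synthetic_data
from txomeval.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_coding=40, n_noncoding=20, n_frameshifted=10,
        peptide_sampling_rate=1.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A fully generated small synthetic study shared across tests."""
    transcripts, truths = synthetic_data.generate_transcriptome(small_config)
    peptide_table = synthetic_data.digest_and_sample_peptides(truths, small_config)
    observed = synthetic_data.observed_peptides(peptide_table)
    search_db = orf_toolkit.build_search_db(transcripts)
    hits = peptide_evidence.match_peptides(observed["peptide"].tolist(), search_db)
    return {
        "config": small_config,
        "transcripts": transcripts,
        "truths": truths,
        "peptide_table": peptide_table,
        "observed": observed,
        "search_db": search_db,
        "hits": hits,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
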