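import numpy as np
import pytest

from pathmrt.fixtures import FixtureConfig, generate_fixture
from pathmrt.io import EmbeddingMatrix, EnrichmentTable


@pytest.fixture(scope="session")
def default_fixture():
    """The canonical benchmark fixture: 5 clusters x 20, dim 16, low noise."""
    return generate_fixture(FixtureConfig())


@pytest.fixture
def tiny_embeddings():
    return EmbeddingMatrix(
        pathway_ids=["GO:A", "GO:B", "GO:C", "GO:D"],
        vectors=np.array(
            [
                [1.0, 0.0, 0.0],
                [0.9, 0.1, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.9, 0.1],
            ]
        ),
    )


@pytest.fixture
def tiny_table():
    return EnrichmentTable(
        pathway_ids=["GO:A", "GO:B", "GO:C", "GO:D"],
        analysis_names=["up", "down"],
        values=np.array([[1.5, -0.2], [0.7, np.nan], [-1.1, 2.0], [0.0, -0.5]]),
    )


def write_fixture_files(tmp_path, embeddings, table):
    """Write a (table, embeddings) pair to disk in the formats `run` reads."""
    from pathmrt.io import write_embeddings, write_enrichment_table

    enr = tmp_path / "enrichment.tsv"
    emb = tmp_path / "embeddings.tsv"
    write_enrichment_table(table, enr)
    write_embeddings(embeddings, emb)
    return enr, emb
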