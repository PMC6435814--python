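import numpy as np
import pytest

from curated_blast import build_database, run_pipeline
from curated_blast.fixtures import (
    PlantSpec,
    curated_sequences_for_plants,
    make_curated_fixture,
    make_genome_with_plants,
    random_protein,
)
from curated_blast.query import Query


@pytest.fixture(scope="session")
def curated_fixture():
    """All eight sources, every retention rule exercised, 20% duplicates."""
    return make_curated_fixture(
        n_sources=8, n_entries_per_source=15, dup_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def curated_db(curated_fixture):
    return build_database(curated_fixture.entries, curated_fixture.sequences)


@pytest.fixture(scope="session")
def planted():
    """Genome with one plant per mode, plus the curated db describing them."""
    rng = np.random.default_rng(7)
    plants = [
        PlantSpec("annotated", random_protein(rng, 120),
                  "as_predicted_protein"),
        PlantSpec("unannotated", random_protein(rng, 150), "as_intact_orf"),
        PlantSpec("frameshifted", random_protein(rng, 140),
                  "as_frameshifted_orf"),
        PlantSpec("missing", random_protein(rng, 100), "absent"),
    ]
    genome_fix = make_genome_with_plants(
        plants, background_kb=8.0, gc_frac=0.5, seed=7)
    entries, lookup = curated_sequences_for_plants(plants, "planted protein")
    db = build_database(entries, lookup)
    seq_ids = {
        spec.seq_id: next(
            s.seq_id for s in db.sequences.values()
            if s.sequence == spec.protein)
        for spec in plants
    }
    return {"plants": plants, "genome": genome_fix, "db": db,
            "seq_ids": seq_ids}


@pytest.fixture(scope="session")
def planted_report(planted):
    return run_pipeline(
        planted["db"], planted["genome"].proteome,
        Query("planted protein"), genome=planted["genome"].contigs)
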