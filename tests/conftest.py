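import numpy as np
import pytest

import microhap as mh


def _repeat_to(pattern: str, length: int) -> str:
    reps = length // len(pattern) + 1
    return (pattern * reps)[:length]


@pytest.fixture()
def tiny_db() -> mh.Database:
    """Hand-built two-chromosome database with overlapping markers.

    mh01KK-001 and mh01KK-002 overlap on chr1 and share the component
    variant rs1002; mh02CP-010 on chr2 has no frequency data and no stored
    sequence.
    """
    db = mh.Database()
    db.markers = [
        mh.MarkerDefinition(
            name="mh01KK-001",
            chromosome="chr1",
            positions=(1055, 1075, 1092),
            rsids=("rs1001", "rs1002", "rs1003"),
            source="KK2018",
        ),
        mh.MarkerDefinition(
            name="mh01KK-002",
            chromosome="chr1",
            positions=(1075, 1130),
            rsids=("rs1002", "rs1004"),
            source="KK2018",
        ),
        mh.MarkerDefinition(
            name="mh02CP-010",
            chromosome="chr2",
            positions=(500, 504),
            rsids=("rs2001", "rs2002"),
            source="CP2019",
        ),
    ]
    db.populations = [
        mh.PopulationSample(id="AFR", name="African ancestry", source="KK2018"),
        mh.PopulationSample(id="EUR", name="European ancestry", source="KK2018"),
    ]
    db.frequencies = [
        mh.FrequencyRecord("mh01KK-001", "AFR", "A,C,G", 0.25, 25),
        mh.FrequencyRecord("mh01KK-001", "AFR", "A,C,T", 0.25, 25),
        mh.FrequencyRecord("mh01KK-001", "AFR", "G,C,T", 0.5, 50),
        mh.FrequencyRecord("mh01KK-001", "EUR", "A,C,G", 0.6, 60),
        mh.FrequencyRecord("mh01KK-001", "EUR", "G,C,T", 0.4, 40),
        mh.FrequencyRecord("mh01KK-002", "EUR", "C,A", 1.0, 100),
    ]
    db.idmap = [("SI664726F", "mh01KK-001")]
    db.variantmap = sorted((rs, m.name) for m in db.markers for rs in m.rsids)
    db.sequences = {
        "mh01KK-001": (1000, _repeat_to("ACGTTGCA", 200)),
        "mh01KK-002": (1000, _repeat_to("ACGTTGCA", 200)),
    }
    db.validate()
    return db


@pytest.fixture(scope="session")
def small_sim():
    """Session-wide simulated cohort: 6 markers (2 on chrX), 3 populations."""
    sim = mh.simulate_markers(
        6, chromosomes=("chr1", "chr2", "chrX"), seed=11, snp_count_range=(2, 4)
    )
    model = mh.random_model(
        sim, populations=("POP1", "POP2", "POP3"), n_per_pop=40, seed=11
    )
    simulated = mh.simulate_panel(model)
    return sim, model, simulated


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
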