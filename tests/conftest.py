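import pytest

from diaquant.formats_io import PsmRecord, QuantTable


@pytest.fixture(scope="session")
def benchmark_replicates():
    """Ten seeded replicates of the full synthetic benchmark (engine +
    Top3/Welch baseline); shared because each replicate takes a few
    seconds."""
    from diaquant.baselines_benchmark import run_synthetic_benchmark

    return [run_synthetic_benchmark(seed) for seed in range(1, 11)]


def make_record(
    run="A1",
    condition="A",
    charge=2,
    score=3.0,
    intensity=1000.0,
    peptide="PEPTIDEK",
    proteins=("P1_HUMAN",),
    is_decoy=False,
):
    return PsmRecord(
        run_id=run,
        condition=condition,
        charge=charge,
        search_score=score,
        intensity=intensity,
        peptide=peptide,
        protein_ids=tuple(proteins),
        is_decoy=is_decoy,
    )


@pytest.fixture
def toy_table():
    """Two proteins, two conditions with two runs each, one missing value."""
    records = [
        make_record("A1", "A", 2, 3.0, 100.0, "AAAK", ("P1_HUMAN",)),
        make_record("A2", "A", 2, 2.5, 110.0, "AAAK", ("P1_HUMAN",)),
        make_record("B1", "B", 2, 3.1, 95.0, "AAAK", ("P1_HUMAN",)),
        make_record("B2", "B", 2, 2.9, None, "AAAK", ("P1_HUMAN",)),
        make_record("A1", "A", 2, 4.0, 500.0, "CCCR", ("P2_YEAST",)),
        make_record("A2", "A", 2, 4.1, 520.0, "CCCR", ("P2_YEAST",)),
        make_record("B1", "B", 2, 3.9, 250.0, "CCCR", ("P2_YEAST",)),
        make_record("B2", "B", 2, 4.2, 260.0, "CCCR", ("P2_YEAST",)),
    ]
    return QuantTable(records)
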