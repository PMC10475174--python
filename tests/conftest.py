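import pytest

from dnvqc import DNVRecord, DNVTable


@pytest.fixture
def toy_table() -> DNVTable:
    """Four records, one of each variant class, across three chromosomes."""
    return DNVTable(
        (
            DNVRecord("s1", "1", 100, "A", "G"),  # SNV, transition
            DNVRecord("s1", "2", 200, "A", "ACG"),  # insertion, length 2
            DNVRecord("s2", "X", 300, "ATT", "A"),  # deletion, length 2
            DNVRecord("s2", "3", 400, "AT", "GC"),  # MNV, length 2
        ),
        provenance="toy",
    )


@pytest.fixture
def annotated_record() -> DNVRecord:
    return DNVRecord("s1", "1", 2, "C", "T", at_cpg=True)
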