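import pytest

from isomirseq import (
    CollapsedRead,
    HairpinRecord,
    MatureAnnotation,
    ReferenceSet,
)

# Toy hairpin: 3-nt flank + 22-nt 5p mature + 8-nt loop + 22-nt 3p mature
# + 3-nt flank, 58 nt in total.
M5 = "ACGTACGTACGTACGTACGTAC"
M3 = "GTACTTACGTACGTACGTAAGC"
H1_SEQ = "TTT" + M5 + "GGGAAGGG" + M3 + "CAT"


@pytest.fixture
def h1() -> HairpinRecord:
    return HairpinRecord("H1", H1_SEQ)


@pytest.fixture
def mature5(h1) -> MatureAnnotation:
    return MatureAnnotation("m5", "H1", 3, 25, "5p", M5)


@pytest.fixture
def mature3(h1) -> MatureAnnotation:
    return MatureAnnotation("m3", "H1", 33, 55, "3p", M3)


@pytest.fixture
def toy_ref(h1, mature5, mature3) -> ReferenceSet:
    return ReferenceSet(hairpins={"H1": h1}, matures=[mature5, mature3])


def collapsed(seq: str, count: int = 1, sample: str = "s1") -> CollapsedRead:
    return CollapsedRead(seq, count, sample)
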