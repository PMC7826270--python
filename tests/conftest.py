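import numpy as np
import pytest

from meioscan.delscan import KmerIndex
from meioscan.synthgenome import (
    DEFAULT_CHROM_SPEC,
    ParentalGenomes,
    build_reference,
    make_male_genome,
    place_snps,
)

#: small karyotyped genome for tests that do not need the full default scale
MINI_CHROM_SPEC = [
    ("X", 30_000, "X"),
    ("2", 40_000, "A"),
    ("3", 40_000, "A"),
    ("Y", 15_000, "Y"),
]


@pytest.fixture(scope="session")
def ref():
    return build_reference(DEFAULT_CHROM_SPEC, seed=1)


@pytest.fixture(scope="session")
def index(ref):
    return KmerIndex(ref)


@pytest.fixture(scope="session")
def snps(ref):
    return place_snps(ref, 500.0, seed=2, chroms=ref.female_chroms())


@pytest.fixture(scope="session")
def male(ref, snps):
    return make_male_genome(ref, seed=4, exclude=snps)


@pytest.fixture(scope="session")
def parents(ref, snps):
    return ParentalGenomes.from_reference(ref, snps)


@pytest.fixture(scope="session")
def mini_ref():
    return build_reference(MINI_CHROM_SPEC, seed=7)


@pytest.fixture(scope="session")
def mini_index(mini_ref):
    return KmerIndex(mini_ref)


def expected_events_from_painting(calls, pos, min_flank=2, max_gc_span=10_000):
    """Independent brute-force segmentation of a truth marker painting.

    Re-derives the expected CO/NCO-GC calls from the offspring chromatid's
    parental-origin vector with plain loops; used as the oracle for the
    read-backed calling pipeline.
    """
    blocks = []
    for i, c in enumerate(calls):
        if blocks and blocks[-1][0] == c:
            blocks[-1][2] = i
        else:
            blocks.append([c, i, i])
    events = []
    changed = True
    while changed:
        changed = False
        for bi in range(1, len(blocks) - 1):
            _, i0, i1 = blocks[bi]
            ln = blocks[bi - 1][2] - blocks[bi - 1][1] + 1
            rn = blocks[bi + 1][2] - blocks[bi + 1][1] + 1
            if pos[i1] - pos[i0] <= max_gc_span and ln >= min_flank and rn >= min_flank:
                events.append(("NCO_GC", int(pos[i0]), int(pos[i1])))
                del blocks[bi]
                merged = []
                for b in blocks:
                    if merged and merged[-1][0] == b[0]:
                        merged[-1][2] = b[2]
                    else:
                        merged.append(b)
                blocks = merged
                changed = True
                break
    for bi in range(1, len(blocks)):
        events.append(("CO", int(pos[blocks[bi - 1][2]]), int(pos[blocks[bi][1]])))
    return sorted(events)
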