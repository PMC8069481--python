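import numpy as np
import pytest

from relapse_evo.genome_reference import (
    AnalysisConstants,
    ChromosomeSpec,
    assembly_index,
    default_assembly,
)
from relapse_evo.scar_genomics import Segment, SegmentProfile

#: allele states drawn by the random-profile generator
CN_PALETTE = [(1, 1), (1, 0), (2, 1), (2, 2), (2, 0), (3, 1), (0, 0), (3, 2)]


@pytest.fixture(scope="session")
def toy_assembly():
    """3-chromosome toy assembly: 100/80/60 Mb, centromeres around 50/40/30 Mb."""
    mb = 1_000_000
    return [
        ChromosomeSpec("c1", 100 * mb, 46 * mb + 1, 54 * mb, True),
        ChromosomeSpec("c2", 80 * mb, 36 * mb + 1, 44 * mb, True),
        ChromosomeSpec("c3", 60 * mb, 26 * mb + 1, 34 * mb, True),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_assembly):
    return assembly_index(toy_assembly)


@pytest.fixture(scope="session")
def hg19_assembly():
    return default_assembly()


@pytest.fixture(scope="session")
def hg19_index(hg19_assembly):
    return assembly_index(hg19_assembly)


@pytest.fixture(scope="session")
def constants():
    return AnalysisConstants()


def random_profile(rng: np.random.Generator, assembly, max_segments=8) -> SegmentProfile:
    """Small random (possibly unmerged) valid profile on the given assembly."""
    mb = 1_000_000
    segments = []
    for spec in assembly:
        pos = 1 + int(rng.integers(0, 10)) * mb
        for _ in range(int(rng.integers(0, max_segments + 1))):
            span = int(rng.integers(2, 29)) * mb
            end = min(pos + span - 1, spec.length_bp)
            if end < pos:
                break
            major, minor = CN_PALETTE[int(rng.integers(len(CN_PALETTE)))]
            segments.append(Segment(spec.name, pos, end, major, minor))
            pos = end + 1 + int(rng.integers(0, 13)) * (mb // 2)
            if pos > spec.length_bp:
                break
    if not segments:
        spec = assembly[0]
        segments.append(Segment(spec.name, 1, 20 * mb, 1, 1))
    return SegmentProfile(sample_id="rand", segments=segments)
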