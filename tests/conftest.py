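import numpy as np
import pytest

from m6adyn.config import SimulationConfig
from m6adyn.core import GenomicInterval, TranscriptModel
from m6adyn.simulate import run_simulation


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulation under the default study conditions."""
    return run_simulation(SimulationConfig(n_transcripts=2000, seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """The complete analysis chain on the default simulation."""
    from m6adyn.pipeline import run_analysis

    return run_analysis(default_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_transcript(rng, chrom="chr1", strand=None, coding=True,
                      n_exons=None) -> TranscriptModel:
    """A randomized spliced transcript for coordinate-mapping tests."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = n_exons or int(rng.integers(1, 5))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 300))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(20, 100))
    total = sum(len(e) for e in exons)
    cds_start = cds_end = None
    if coding and total >= 30:
        t = TranscriptModel("tmp", "g", "mRNA", exons)
        a = int(rng.integers(0, total - 10))
        b = int(rng.integers(a + 6, min(total, a + 200)))
        ga = t.transcript_to_genome(a)
        gb = t.transcript_to_genome(b - 1)
        cds_start, cds_end = min(ga, gb), max(ga, gb) + 1
    return TranscriptModel(
        f"t_{int(rng.integers(1e9))}", "g", "mRNA" if coding else "ncRNA",
        exons, cds_start, cds_end,
    )
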