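import numpy as np
import pytest

from regstage.core.types import AnalysisConfig, GenomicInterval, Peak, PeakSet


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def small_genome():
    from regstage.simulate import sim_genome

    return sim_genome(2, 50_000, 42)


def make_peak(chrom, summit, width=400, name="p", strand="."):
    start = max(0, summit - width // 2)
    return Peak(GenomicInterval(chrom, start, start + width, strand), summit, name)


def make_peakset(label, summits, chrom="chr1", width=400):
    return PeakSet(
        label,
        [make_peak(chrom, s, width, f"{label}_{i}") for i, s in enumerate(summits)],
    )


@pytest.fixture
def anchored_sets():
    """Three peak sets with a known planted Venn structure (no jitter)."""
    from regstage.simulate import sim_peak_sets

    spec = {"ABC": 50, "AB": 20, "A": 30, "B": 10, "C": 40}
    sets, truth = sim_peak_sets(spec, {"chr1": 500_000}, seed=11)
    return sets, spec
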