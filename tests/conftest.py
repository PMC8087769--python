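import numpy as np
import pytest

from isoscreen.screen_model import (
    CONTROL_GENE,
    CountMatrix,
    GuideLibrary,
    GuideRecord,
    ReferenceGeneSets,
    SampleRecord,
    SampleSheet,
)


@pytest.fixture
def tiny_library() -> GuideLibrary:
    return GuideLibrary(
        [
            GuideRecord("GA_g1", "GA", "ACGTACGTACGTACGTACGT"),
            GuideRecord("GA_g2", "GA", "TTTTACGTACGTACGTACGT"),
            GuideRecord("GB_g1", "GB", "CCCCACGTACGTACGTACGT"),
            GuideRecord("GB_g2", "GB", "GGGGACGTACGTACGTACGT"),
            GuideRecord("CTRL_g1", CONTROL_GENE, "AAAAACGTACGTACGTACGT", "control"),
        ]
    )


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        [
            SampleRecord("plasmid", "plasmid", "lib", 0.0),
            SampleRecord("ko_1", "knockout", "1", 21.0),
            SampleRecord("ko_2", "knockout", "2", 21.0),
            SampleRecord("wt_1", "wildtype", "1", 21.0),
            SampleRecord("wt_2", "wildtype", "2", 21.0),
        ]
    )


@pytest.fixture
def tiny_counts(tiny_library, tiny_sheet) -> CountMatrix:
    rng = np.random.default_rng(0)
    counts = rng.integers(50, 200, size=(len(tiny_library), len(tiny_sheet)))
    return CountMatrix(tiny_library.guide_ids, tiny_sheet.sample_ids, counts)


@pytest.fixture
def tiny_refsets() -> ReferenceGeneSets:
    return ReferenceGeneSets(frozenset({"GA"}), frozenset({"GB"}))


@pytest.fixture(scope="session")
def small_screen():
    """A small stochastic simulated screen shared by read-only tests."""
    from isoscreen import synthetic_data as sd

    cfg = sd.SimConfig(
        n_genes=120,
        n_control_guides=10,
        n_core_essential=20,
        n_ko_specific=8,
        depth=200_000,
    )
    return sd.simulate(cfg, seed=7)
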