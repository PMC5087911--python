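import pytest

from ejscar.insertion_origin import ReferenceCollection, ReferenceSource
from ejscar.reporter_model import ReporterSubstrate
from ejscar.synthetic_data import (
    preset_config,
    reporter_sequence,
    simulate_junctions,
)

# Hand-designed substrate for exact classification arithmetic: both arm/overhang
# boundaries are C|A and A|G, so constructed reads only share joint bases where
# the test plants them.
DESIGNED_LEFT = "CCCTGTGGTCTCTTGGTTCAATTCCAAGCC"
DESIGNED_RIGHT = "GGCGTTCGAACTGCACTGGCCAACCTTTGG"
DESIGNED_OVERHANG = "ATAA"


@pytest.fixture(scope="session")
def designed_sub() -> ReporterSubstrate:
    return ReporterSubstrate(
        name="designed",
        left_arm=DESIGNED_LEFT,
        right_arm=DESIGNED_RIGHT,
        overhang=DESIGNED_OVERHANG,
        spacer_len=34,
    )


@pytest.fixture(scope="session")
def distant_cfg():
    return preset_config("distant", seed=11, n_reads=300)


@pytest.fixture(scope="session")
def distant_sims(distant_cfg):
    return simulate_junctions(distant_cfg)


@pytest.fixture(scope="session")
def distant_refs(distant_cfg) -> ReferenceCollection:
    reporter, cuts = reporter_sequence(distant_cfg.substrate, distant_cfg.spacer_seq)
    return ReferenceCollection(
        [
            ReferenceSource("reporter", reporter, cut_sites=cuts),
            ReferenceSource("genome", distant_cfg.donor_genome),
        ]
    )
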