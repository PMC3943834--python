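import pytest

from paneldx import GenePanel, TargetRegion
from paneldx.synthetic_fixtures import SimConfig


@pytest.fixture
def small_panel() -> GenePanel:
    """Two-gene toy panel with CDS, splice-site and UTR regions."""
    return GenePanel(
        regions=[
            TargetRegion("chr7", 100, 200, "GCK", "CDS", exon_index=1),
            TargetRegion("chr7", 200, 202, "GCK", "splice_site"),
            TargetRegion("chr7", 300, 302, "GCK", "splice_site"),
            TargetRegion("chr7", 302, 402, "GCK", "CDS", exon_index=2),
            TargetRegion("chr7", 402, 502, "GCK", "UTR3"),
            TargetRegion("chr12", 1000, 1150, "HNF1A", "CDS", exon_index=1),
        ]
    )


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=7)
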