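import numpy as np
import pytest

from zogscan import (
    GROUP_D_REFERENCE_MOTIF,
    ProteinRecord,
    build_default_profile,
    group_o_consensus,
)

#: residues that never appear in any profile column, for inert flanks
INERT = "AIKMNRTV"


@pytest.fixture(scope="session")
def profile():
    return build_default_profile()


@pytest.fixture(scope="session")
def d_motif():
    """The printed 44-aa PSPG motif of Arabidopsis cisZOG1 (AY573820.1)."""
    return GROUP_D_REFERENCE_MOTIF


@pytest.fixture(scope="session")
def o_motif(profile):
    """A 44-aa window realizing the group-O consensus."""
    return group_o_consensus(profile)


def random_flank(rng: np.random.Generator, n: int) -> str:
    """Random sequence over residues absent from every profile column."""
    return "".join(INERT[i] for i in rng.integers(0, len(INERT), n))


@pytest.fixture()
def embedded_d_record(d_motif):
    """The printed motif between seeded random flanks (30 + 44 + 10 aa)."""
    rng = np.random.default_rng(20260925)
    seq = random_flank(rng, 30) + d_motif + random_flank(rng, 10)
    return ProteinRecord("AY573820.1", "Arabidopsis thaliana", seq)
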