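import pytest
from hypothesis import HealthCheck, settings

from sirnaselect import NucleotideSequence, SiRNACandidate, default_parameters
from sirnaselect.core_seq import revcomp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """The packaged Freier 1986 RNA/RNA nearest-neighbor parameter set."""
    return default_parameters()


# Guide with a single G/C residue, placed at position 19: satisfies all five
# selection conditions, and when its target window is embedded in a poly-A
# background the mRNA carries exactly one G/C, so position 19 can only be
# satisfied at the planted window start.
PLANTED_GUIDE = "AAAAAAAA" + "UUUUUUUUUU" + "G" + "AU"
PLANTED_WINDOW = revcomp(PLANTED_GUIDE) + "AA"


@pytest.fixture(scope="session")
def planted_mrna():
    """Poly-A mRNA with one all-pass candidate window planted at start 31."""
    return NucleotideSequence("A" * 30 + PLANTED_WINDOW + "A" * 30, id="planted")


@pytest.fixture(scope="session")
def planted_candidate():
    return SiRNACandidate.from_window(PLANTED_WINDOW, target_id="planted", window_start=31)
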