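import pytest

from gsacc.cli_tables import reproduce_table2, reproduce_table3

# Replicate count used for the published-grid Monte-Carlo reproduction; the
# source protocol uses 100 replicates per scenario.
FULL_REPLICATES = 100


@pytest.fixture(scope="session")
def table2_mc_rows():
    """Published uniform-frequency grid recomputed at full replicate count
    (shared by several acceptance criteria; ~2 min)."""
    return reproduce_table2(replicates=FULL_REPLICATES, seed=20170366)


@pytest.fixture(scope="session")
def table3_mc_rows():
    """Published U-shape grid recomputed at full replicate count."""
    return reproduce_table3(replicates=FULL_REPLICATES, seed=20170366)
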