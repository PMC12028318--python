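import pytest

import phagekit as pk


@pytest.fixture(scope="session")
def small_genomes():
    """A small simulated genome collection shared across tests (read-only)."""
    return pk.simulate_phage_genomes(
        n_taxa=8, n_core=30, n_accessory=6, subst_rate=0.02, recomb_events=5, seed=11
    )
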