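import pytest

from kturn_m6a import synthetic_data as syn


@pytest.fixture(scope="session")
def snorna_bundle():
    """Default planted snoRNA set with its truth table (seed fixed)."""
    return syn.gen_snorna_set(syn.SnoRNAConfig(n_sequences=20), seed=11)


@pytest.fixture(scope="session")
def sheared_duplex():
    residues, truth = syn.gen_duplex_coords(
        syn.DuplexConfig(planted_class="sheared_GA"), seed=1
    )
    return {(r.chain, r.number): r for r in residues}, truth


@pytest.fixture(scope="session")
def wc_duplex():
    residues, truth = syn.gen_duplex_coords(syn.DuplexConfig(planted_class="wc"), seed=1)
    return {(r.chain, r.number): r for r in residues}, truth


@pytest.fixture(scope="session")
def tandem_duplex():
    residues, truth = syn.gen_duplex_coords(
        syn.DuplexConfig(planted_class="tandem_sheared"), seed=1
    )
    return residues, truth


@pytest.fixture(scope="session")
def displaced_duplex():
    residues, truth = syn.gen_duplex_coords(
        syn.DuplexConfig(planted_class="displaced_G6MA"), seed=1
    )
    return {(r.chain, r.number): r for r in residues}, truth
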