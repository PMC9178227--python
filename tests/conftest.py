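import pytest

import orthodelta as od


@pytest.fixture(scope="session")
def smap():
    """Default species resolution: label prefix before '|'."""
    return od.SpeciesMap.from_delimiter("|")


@pytest.fixture(scope="session")
def stree6():
    """Fixed 6-species ultrametric tree, internal branches of 1 coalescent
    unit (discordance well above the 5% testing gate)."""
    return od.parse_newick(
        "(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);"
    )


@pytest.fixture(scope="session")
def stree12():
    return od.sim_species_tree(12, seed=7)


@pytest.fixture(scope="session")
def dl_families(stree12):
    """300 duplication-loss families at the study conditions."""
    cfg = od.SimConfig(n_species=12, dup_rate=0.3, loss_rate=0.3, seed=11)
    fams = od.sim_dl_families(stree12, cfg, 300)
    return [f for f in fams if not f.empty]
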