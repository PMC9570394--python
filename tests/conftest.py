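import pytest

from sexlinkscan import synthdata


@pytest.fixture(scope="session")
def small_study():
    """Two noiseless XY species with planted sex-linked and autosomal loci."""
    cfg = synthdata.SimulationConfig(
        n_species=2,
        n_males=5,
        n_females=5,
        n_autosomal_loci=30,
        n_xy_snp_loci=10,
        n_y_limited_loci=4,
        species_tree="(sp1:1.0,sp2:1.0);",
        seed=11,
    )
    return synthdata.simulate_catalog(cfg)


@pytest.fixture(scope="session")
def nine_species_tree():
    """Nine-tip species phylogeny: one eastern tip sister to eight western."""
    return (
        "(A_wuyiensis:31,((A_chunganensis:14,A_sp:14):9,((A_xinduqiao:14,"
        "A_jinjiangensis:14):5,((A_lifanensis:14,A_loloensis:14):2,"
        "(A_mantzorum:14,A_tuberodepressus:14):2):3):4):8);"
    )


@pytest.fixture(scope="session")
def nine_species_identities():
    western = [
        "A_chunganensis", "A_sp", "A_xinduqiao", "A_jinjiangensis",
        "A_lifanensis", "A_loloensis", "A_mantzorum", "A_tuberodepressus",
    ]
    states = {sp: "chr5-homologous" for sp in western}
    states["A_wuyiensis"] = "other"
    return states
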