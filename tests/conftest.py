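import pytest

from maglink.pathways import default_panel
from maglink.synthetic import simulate_community


def full_truth(n_populations, panel, absent=()):
    """pathway_truth marking every (population, metabolite) present
    except the listed (population, metabolite) pairs."""
    truth = {}
    for p in range(1, n_populations + 1):
        for pw in panel:
            truth[(f"pop{p}", pw.metabolite)] = (f"pop{p}", pw.metabolite) not in absent
    return truth


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_community(panel):
    """3 planted populations x 2 members, 6 kb genomes, with a few
    planted auxotrophies."""
    absent = {("pop1", "vitamin-b12"), ("pop2", "vitamin-b12"),
              ("pop3", "vitamin-b12"), ("pop1", "biotin"),
              ("pop2", "riboflavin")}
    truth = full_truth(3, panel, absent=absent)
    return simulate_community(3, 2, 0.01, 0.10, truth, seed=11,
                              genome_length=6000, panel=panel)
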