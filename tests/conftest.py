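import numpy as np
import pytest

from divshift import (
    BDParams,
    RichnessTable,
    join,
    read_chronogram,
    simulate_with_shift,
)
from divshift.synthetic_data import collapse, simulate_taxon_tree


@pytest.fixture()
def three_tip_tree(tmp_path):
    """((A:10,B:10):5,C:15); — root age 15, crown split at 10."""
    p = tmp_path / "three.nwk"
    p.write_text("((A:10,B:10):5,C:15);\n")
    return read_chronogram(p)


@pytest.fixture()
def three_tip_rt(three_tip_tree):
    return join(three_tip_tree, RichnessTable({"A": 1, "B": 1, "C": 1}))


@pytest.fixture(scope="session")
def yule_taxon_tree():
    """Higher-taxon Yule tree from the exact taxon-tree sampler (r=0.05)."""
    return simulate_taxon_tree(BDParams(0.05, 0.0), crown_age=150,
                               family_prob=0.5, seed=101)


@pytest.fixture(scope="session")
def two_regime_case():
    """A collapsed tree with one strong, known upshift (r2 = 5 r1).

    Returns (richness_tree, true_terminal_leafset).
    """
    chrono, species_leafset, _ = simulate_with_shift(
        BDParams(0.04, 0.0), BDParams(0.2, 0.0),
        shift_age=28, crown_age=100, seed=42,
    )
    rt, membership = collapse(chrono, 9.0)
    true_terms = frozenset(lab for lab, sp in membership.items()
                           if sp <= species_leafset)
    return rt, true_terms


@pytest.fixture(scope="session")
def two_regime_search(two_regime_case):
    """Accepted-model sequence of the stepwise search on the two-regime tree."""
    from divshift import stepwise_search

    rt, _ = two_regime_case
    return stepwise_search(rt)
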