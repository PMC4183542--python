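import math

import numpy as np
import pytest

from divshift import (
    BDParams,
    pseudo_posterior,
    simulate_bd,
    simulate_with_shift,
    transients,
)
from divshift.synthetic_data import (
    SimulationError,
    collapse,
    simulate_collapsed_tree,
    simulate_taxon_tree,
)


class TestSimulateBd:
    def test_seed_determinism(self):
        a, na = simulate_bd(BDParams(0.1, 0.3), crown_age=30, seed=5)
        b, nb = simulate_bd(BDParams(0.1, 0.3), crown_age=30, seed=5)
        assert na == nb and a.newick() == b.newick()

    def test_pure_birth_no_pruning(self):
        # with mu=0 every simulated lineage survives: tips == extant count
        chrono, n = simulate_bd(BDParams(0.1, 0.0), crown_age=40, seed=2)
        assert chrono.n_tips == n

    def test_crown_tree_has_requested_crown_age(self):
        chrono, _ = simulate_bd(BDParams(0.08, 0.4), crown_age=35, seed=8)
        assert chrono.root_age == pytest.approx(35.0)

    def test_ntips_stop_rule(self):
        chrono, n = simulate_bd(BDParams(0.1, 0.0), ntips=64, seed=3)
        assert n == 64 and chrono.n_tips == 64

    def test_unconditioned_stem_may_die(self):
        # high turnover, long time: extinction happens in some replicates
        rng = np.random.default_rng(0)
        outcomes = {simulate_bd(BDParams(0.01, 0.9), stem_age=50, seed=rng,
                                condition="none")[0] is None
                    for _ in range(20)}
        assert True in outcomes

    def test_stop_rule_exclusivity(self):
        with pytest.raises(ValueError):
            simulate_bd(BDParams(0.1), crown_age=10, stem_age=10)

    def test_survival_fraction_matches_transients(self):
        """Monte-Carlo check of P_s(t) on a small stem design."""
        p = BDParams(0.1, 0.5)
        t = 10.0
        n = 800
        rng = np.random.default_rng(17)
        survived = 0
        for _ in range(n):
            chrono, n_ext = simulate_bd(p, stem_age=t, seed=rng, condition="none")
            survived += n_ext > 0
        ps = transients(t, p).p_survival
        se = math.sqrt(ps * (1 - ps) / n)
        assert abs(survived / n - ps) < 3 * se


class TestSimulateWithShift:
    def test_true_clade_reported_and_deterministic(self):
        a = simulate_with_shift(BDParams(0.04, 0.0), BDParams(0.2, 0.0),
                                shift_age=20, crown_age=60, seed=9)
        b = simulate_with_shift(BDParams(0.04, 0.0), BDParams(0.2, 0.0),
                                shift_age=20, crown_age=60, seed=9)
        assert a[0].newick() == b[0].newick() and a[1] == b[1]
        chrono, leafset, n = a
        assert 2 <= len(leafset) <= chrono.n_tips
        node = chrono.mrca(leafset)
        assert chrono.leafset(node) == leafset  # the true shift is a clade

    def test_invalid_shift_age(self):
        with pytest.raises(ValueError):
            simulate_with_shift(BDParams(0.1), BDParams(0.2), shift_age=70,
                                crown_age=60)


class TestCollapse:
    def test_conserves_total_richness(self):
        chrono, n = simulate_bd(BDParams(0.1, 0.2), crown_age=50, seed=4)
        for age in (5.0, 20.0, 40.0):
            rt, membership = collapse(chrono, age)
            assert rt.total_richness == chrono.n_tips
            assert sum(len(m) for m in membership.values()) == chrono.n_tips

    def test_tiny_collapse_age_keeps_topology(self):
        chrono, _ = simulate_bd(BDParams(0.1, 0.0), crown_age=30, seed=6)
        youngest = min(chrono.age(i) for i in chrono.internal_ids)
        rt, _ = collapse(chrono, youngest / 2)
        assert rt.n_terminals == chrono.n_tips
        assert all(n == 1 for n in rt.richness.counts.values())

    def test_invalid_ages_rejected(self):
        chrono, _ = simulate_bd(BDParams(0.1, 0.0), crown_age=30, seed=6)
        for bad in (0.0, -3.0, 31.0):
            with pytest.raises(ValueError):
                collapse(chrono, bad)

    def test_convenience_pipeline_min_size(self):
        rt = simulate_collapsed_tree(BDParams(0.05, 0.0), crown_age=100,
                                     collapse_age=30, seed=12, min_terminals=10)
        assert rt.n_terminals >= 10


class TestTaxonTreeSampler:
    def test_deterministic_and_valid(self):
        a = simulate_taxon_tree(BDParams(0.05, 0.2), crown_age=120, seed=3)
        b = simulate_taxon_tree(BDParams(0.05, 0.2), crown_age=120, seed=3)
        assert a.chronogram.newick() == b.chronogram.newick()
        assert a.richness.counts == b.richness.counts
        a.chronogram.validate()
        assert a.total_richness >= a.n_terminals

    def test_family_prob_zero_gives_monotypic_tips(self):
        rt = simulate_taxon_tree(BDParams(0.06, 0.0), crown_age=80,
                                 family_prob=0.0, seed=7)
        assert all(n == 1 for n in rt.richness.counts.values())


class TestPseudoPosterior:
    def test_zero_jitter_identity(self, yule_taxon_tree):
        chrono = yule_taxon_tree.chronogram
        samples = pseudo_posterior(chrono, 3, jitter_scale=0.0, seed=1)
        for s in samples:
            for nid in chrono.nodes:
                assert s.age(nid) == pytest.approx(chrono.age(nid), abs=1e-12)

    def test_samples_remain_valid_chronograms(self, yule_taxon_tree):
        chrono = yule_taxon_tree.chronogram
        for s in pseudo_posterior(chrono, 20, jitter_scale=0.3, seed=4):
            s.validate()  # parent > child, tips at zero

    def test_median_unbiased_root_age(self, yule_taxon_tree):
        chrono = yule_taxon_tree.chronogram
        samples = pseudo_posterior(chrono, 400, jitter_scale=0.05, seed=8)
        roots = np.array([s.root_age for s in samples])
        se = roots.std(ddof=1) / math.sqrt(len(roots))
        assert abs(roots.mean() - chrono.root_age) < 3 * se

    def test_topology_and_labels_untouched(self, yule_taxon_tree):
        chrono = yule_taxon_tree.chronogram
        (s,) = pseudo_posterior(chrono, 1, jitter_scale=0.2, seed=5)
        assert {s.leafset(i) for i in s.nodes} == {chrono.leafset(i) for i in chrono.nodes}
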