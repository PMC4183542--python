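import math
import subprocess
import textwrap

import numpy as np
import pytest

from divshift import (
    BDParams,
    RichnessTable,
    combined_loglik,
    expected_richness,
    fit_params,
    internal_loglik,
    join,
    richness_pmf,
    richness_quantile,
    simulate_bd,
    transients,
)
from divshift.bdcore import FitError, RegimeData, richness_logpmf
from divshift.shiftsearch import build_regimes


def nee_loglik(r, eps, chrono):
    """Independent closed-form oracle: the Nee et al. conditioned likelihood of
    branching times as coded in ape::birthdeath (includes an (N-1)! constant)."""
    N = chrono.n_tips
    x = sorted((chrono.age(i) for i in chrono.internal_ids), reverse=True)
    x = [x[0]] + x
    return (math.lgamma(N) + (N - 2) * math.log(r) + r * sum(x[2:N])
            + N * math.log(1 - eps)
            - 2 * sum(math.log(math.exp(r * xi) - eps) for xi in x[1:N]))


class TestTransients:
    def test_boundary_t0(self):
        tr = transients(0.0, BDParams(0.1, 0.5))
        assert (tr.beta, tr.alpha, tr.p_survival) == (0.0, 0.0, 1.0)

    def test_pure_birth_closed_form(self):
        tr = transients(10.0, BDParams(0.1, 0.0))
        assert tr.beta == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert tr.alpha == 0.0 and tr.p_survival == 1.0

    def test_general_closed_form(self):
        r, e, t = 0.07, 0.6, 30.0
        tr = transients(t, BDParams(r, e))
        ert = math.exp(r * t)
        assert tr.beta == pytest.approx((ert - 1) / (ert - e), rel=1e-12)
        assert tr.alpha == pytest.approx(e * tr.beta, rel=1e-12)
        assert tr.p_survival == pytest.approx((1 - e) / (1 - e * math.exp(-r * t)), rel=1e-12)

    def test_numerically_stable_at_extreme_ages(self):
        p = BDParams(0.1, 0.9)
        tr = transients(7000.0, p)  # r*t = 700, e^{rt} overflows naively
        assert 0.0 < tr.beta <= 1.0 and 0.0 < tr.p_survival <= 1.0
        assert math.isfinite(tr.alpha)
        # log-space machinery stays finite where the probabilities underflow
        assert math.isfinite(richness_logpmf(5, 7000.0, p))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            transients(-1.0, BDParams(0.1))


class TestRichnessPmf:
    def test_pure_birth_monotypic(self):
        assert richness_pmf(1, 10.0, BDParams(0.1, 0.0)) == pytest.approx(math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("r,eps,t", [(0.1, 0.0, 10), (0.05, 0.5, 40), (0.02, 0.9, 100)])
    def test_unconditioned_normalises_with_zero_mass_alpha(self, r, eps, t):
        p = BDParams(r, eps)
        tr = transients(t, p)
        assert richness_pmf(0, t, p, conditioned=False) == pytest.approx(tr.alpha, rel=1e-10)
        n = np.arange(0, 5000)
        head = richness_pmf(n, t, p, conditioned=False).sum()
        tail = (1 - tr.alpha) * tr.beta ** 5000  # geometric tail closed form
        assert head + tail == pytest.approx(1.0, abs=1e-10)

    def test_conditioned_zero_rejected(self):
        with pytest.raises(ValueError):
            richness_pmf(0, 10.0, BDParams(0.1), conditioned=True)

    def test_logpmf_matches_pmf(self):
        p = BDParams(0.08, 0.4)
        n = np.array([1, 5, 50])
        assert np.allclose(np.exp(richness_logpmf(n, 20.0, p)), richness_pmf(n, 20.0, p))


class TestExpectedRichness:
    def test_t0_and_paper_scale_value(self):
        assert expected_richness(0.0, BDParams(0.05)) == 1.0
        # e^{r t} at the hexapod-scale background rate over 100 Myr
        assert expected_richness(100.0, BDParams(0.0087352, 0.0)) == pytest.approx(
            math.exp(0.87352), rel=1e-9)

    def test_conditioning_inflates_mean(self):
        p = BDParams(0.05, 0.6)
        for t in (10, 50, 200):
            assert expected_richness(t, p, conditioned=True) >= expected_richness(
                t, p, conditioned=False)


class TestRichnessQuantile:
    def test_half_beta_example(self):
        # eps=0: beta=0.5 at rt=ln 2; smallest n with 1-0.5^n >= 0.75 is 2
        assert richness_quantile(0.75, math.log(2), BDParams(1.0, 0.0)) == 2

    def test_small_q_gives_support_minimum(self):
        assert richness_quantile(1e-12, 50.0, BDParams(0.05, 0.5)) == 1

    def test_monotone_in_q_and_t(self):
        p = BDParams(0.05, 0.3)
        qs = [0.025, 0.25, 0.5, 0.75, 0.975]
        for t in (10, 50, 100):
            vals = [richness_quantile(q, t, p) for q in qs]
            assert vals == sorted(vals)
        for q in qs:
            vals = [richness_quantile(q, t, p) for t in (10, 50, 100)]
            assert vals == sorted(vals)

    def test_matches_pmf_summation(self):
        p = BDParams(0.06, 0.5)
        t = 40.0
        cdf = np.cumsum(richness_pmf(np.arange(1, 2000), t, p))
        for q in (0.025, 0.5, 0.975):
            assert richness_quantile(q, t, p) == int(np.searchsorted(cdf, q) + 1)


class TestInternalLoglik:
    def test_three_tip_yule_closed_form(self, three_tip_rt):
        # total combined lnL for n_i = 1 tips must equal ln r - r * S
        data, _ = build_regimes(three_tip_rt, ())
        S = 10 + 10 + 15 + 5
        for r in (0.05, 0.1, 0.3):
            got = combined_loglik(data, [BDParams(r, 0.0)]).lnL_total
            assert got == pytest.approx(math.log(r) - r * S, rel=1e-12)

    def test_yule_mle_closed_form(self, yule_taxon_tree):
        # internal part alone: r_hat = (N-2)/S with S the internal branch time
        data, _ = build_regimes(yule_taxon_tree, ())
        internal_only = RegimeData(
            split_ages=data[0].split_ages,
            branch_spans=data[0].branch_spans,
            richness=np.array([]),
            stem_ages=np.array([]),
        )
        n_splits = internal_only.split_ages.size
        S = float(np.sum(internal_only.branch_spans[:, 0] - internal_only.branch_spans[:, 1]))
        p, _ = fit_params(internal_only, fixed_eps=0.0)
        assert p.r == pytest.approx(n_splits / S, rel=1e-6)

    def test_empty_regime_contributes_zero(self):
        assert internal_loglik([], np.empty((0, 2)), BDParams(0.1, 0.5)) == 0.0

    def test_additive_over_partitions(self, yule_taxon_tree):
        data, _ = build_regimes(yule_taxon_tree, ())
        d = data[0]
        k = d.split_ages.size // 2
        p = BDParams(0.07, 0.4)
        whole = internal_loglik(d.split_ages, d.branch_spans, p)
        parts = (internal_loglik(d.split_ages[:k], d.branch_spans[:k], p)
                 + internal_loglik(d.split_ages[k:], d.branch_spans[k:], p))
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_matches_nee_formula_up_to_constant(self):
        """Species-level combined lnL equals the Nee/ape closed form minus the
        (N-1)! labelling constant, for every (r, eps)."""
        chrono, _ = simulate_bd(BDParams(0.12, 0.3), crown_age=40, seed=7)
        rt = join(chrono, RichnessTable({l: 1 for l in chrono.tip_labels()}))
        data, _ = build_regimes(rt, ())
        const = math.lgamma(chrono.n_tips)
        for r, eps in [(0.12, 0.0), (0.08, 0.3), (0.2, 0.7)]:
            mine = combined_loglik(data, [BDParams(r, eps)]).lnL_total
            assert mine == pytest.approx(nee_loglik(r, eps, chrono) - const, abs=1e-8)


class TestCombinedLoglik:
    def test_star_like_terminal_component(self, three_tip_rt):
        # all n_i = 1, eps = 0: terminal part is -r * sum(stem ages)
        data, _ = build_regimes(three_tip_rt, ())
        bk = data[0].loglik(BDParams(0.1, 0.0))
        assert bk.lnL_terminal == pytest.approx(-0.1 * (10 + 10 + 15), rel=1e-12)

    def test_gradient_matches_numeric(self, yule_taxon_tree):
        data, _ = build_regimes(yule_taxon_tree, ())
        d = data[0]
        h = 1e-6
        for r, eps in [(0.05, 0.2), (0.1, 0.0), (0.02, 0.8)]:
            lnL, dr, de = d.loglik_grad(r, eps)
            assert lnL == pytest.approx(d.loglik(BDParams(r, eps)).lnL_total, rel=1e-12)
            num_dr = (d.loglik(BDParams(r + h, eps)).lnL_total
                      - d.loglik(BDParams(r - h, eps)).lnL_total) / (2 * h)
            assert dr == pytest.approx(num_dr, rel=1e-4)
            num_de = (d.loglik(BDParams(r, eps + h)).lnL_total
                      - d.loglik(BDParams(r, max(eps - h, 0))).lnL_total) / (
                          2 * h if eps > h else h)
            assert de == pytest.approx(num_de, rel=1e-4)


class TestFitParams:
    def test_matches_ape_birthdeath(self, tmp_path):
        """Independent oracle: ape::birthdeath fits the same Nee likelihood
        (additive constants cancel in the argmax)."""
        chrono, _ = simulate_bd(BDParams(0.1, 0.5), crown_age=55, seed=11)
        rt = join(chrono, RichnessTable({l: 1 for l in chrono.tip_labels()}))
        data, _ = build_regimes(rt, ())
        p, _ = fit_params(data[0])
        nwk = tmp_path / "t.nwk"
        nwk.write_text(chrono.newick() + "\n")
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            phy <- read.tree("{nwk}")
            f <- birthdeath(phy)
            cat(f$para[1], f$para[2], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             timeout=120)
        assert out.returncode == 0, out.stderr
        eps_ape, r_ape = (float(v) for v in out.stdout.strip().splitlines())
        assert p.r == pytest.approx(r_ape, rel=1e-3)
        assert p.eps == pytest.approx(eps_ape, abs=2e-3)

    def test_single_monotypic_terminal_uninformative(self):
        data = RegimeData(split_ages=np.array([]), branch_spans=np.empty((0, 2)),
                          richness=np.array([1.0]), stem_ages=np.array([30.0]))
        with pytest.raises(FitError):
            fit_params(data)

    def test_fixed_eps_profile(self, yule_taxon_tree):
        data, _ = build_regimes(yule_taxon_tree, ())
        p_fix, bk_fix = fit_params(data[0], fixed_eps=0.0)
        p_free, bk_free = fit_params(data[0])
        assert p_fix.eps == 0.0
        assert bk_free.lnL_total >= bk_fix.lnL_total - 1e-6
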