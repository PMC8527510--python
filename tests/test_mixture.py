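"""Mixture-model likelihood, MLE fitting, contaminant scan and separation rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbmixups import (
    GenotypeMatrix,
    JointCategoryTable,
    Scenario,
    SimulationConfig,
    detect_contaminant,
    expected_minor_prob,
    fit_mixture,
    mixture_loglik,
    scan_contaminants,
    simulate_cohort,
    simulate_read_counts,
    tabulate_pair,
)
from mbmixups.mixture import NEG_INF, ContaminantScan, _null_eps_closed_form

GT = ("AA", "AB", "BB")
FREQ = {"AA": 0.0, "AB": 0.5, "BB": 1.0}


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_loglik(counts, p, eps):
    """Term-by-term binomial log-likelihood, plain Python loops."""
    total = 0.0
    for i, g1 in enumerate(GT):
        for j, g2 in enumerate(GT):
            f_star = (1 - p) * FREQ[g1] + p * FREQ[g2]
            pi = eps + f_star * (1 - 2 * eps)
            n_a, n_b = int(counts[i, j, 0]), int(counts[i, j, 1])
            for n, prob in ((n_b, pi), (n_a, 1 - pi)):
                if n > 0:
                    if prob <= 0.0:
                        return NEG_INF
                    total += n * math.log(prob)
    return total


def grid_fit(counts, n_coarse=201, refine_step=2e-5, refine_span=3):
    """Exhaustive two-stage grid search over (p, eps); independent of the
    package optimizer.  Returns (p, eps, loglik) at the grid maximum."""
    nB = counts[:, :, 1].astype(float)
    nA = counts[:, :, 0].astype(float)
    f1 = np.array([0.0, 0.5, 1.0])[:, None]
    f2 = np.array([0.0, 0.5, 1.0])[None, :]

    def ll_grid(p_vals, e_vals):
        p = p_vals[:, None, None, None]
        e = e_vals[None, :, None, None]
        f_star = (1 - p) * f1[None, None] + p * f2[None, None]
        pi = e + f_star * (1 - 2 * e)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(nB > 0, nB * np.log(pi), 0.0) + np.where(
                nA > 0, nA * np.log(1 - pi), 0.0
            )
        return np.nansum(np.where(np.isneginf(term), -1e300, term), axis=(2, 3))

    p_vals = np.linspace(0.0, 1.0, n_coarse)
    e_vals = np.linspace(1e-9, 0.4999, n_coarse)
    ll = ll_grid(p_vals, e_vals)
    ip, ie = np.unravel_index(np.argmax(ll), ll.shape)
    span_p = refine_span * (p_vals[1] - p_vals[0])
    span_e = refine_span * (e_vals[1] - e_vals[0])
    p_fine = np.clip(np.arange(p_vals[ip] - span_p, p_vals[ip] + span_p, refine_step), 0, 1)
    e_fine = np.clip(np.arange(e_vals[ie] - span_e, e_vals[ie] + span_e, refine_step), 1e-9, 0.4999)
    ll2 = ll_grid(p_fine, e_fine)
    jp, je = np.unravel_index(np.argmax(ll2), ll2.shape)
    return float(p_fine[jp]), float(e_fine[je]), float(ll2[jp, je])


def random_table(rng, depth=2000):
    """Joint table drawn under the model at random (p, eps) and random
    joint-genotype composition; returns (table, p, eps)."""
    p = float(rng.uniform(0, 1))
    eps = float(rng.uniform(0.0005, 0.05))
    mass = rng.dirichlet(np.ones(9)).reshape(3, 3)
    totals = rng.poisson(depth * mass)
    f1 = np.array([0.0, 0.5, 1.0])[:, None]
    f2 = np.array([0.0, 0.5, 1.0])[None, :]
    pi = eps + ((1 - p) * f1 + p * f2) * (1 - 2 * eps)
    nB = rng.binomial(totals, pi)
    counts = np.stack([totals - nB, nB], axis=2)
    return JointCategoryTable("m", "self", "other", counts), p, eps


# ---------------------------------------------------------------------------
# Expected minor-allele probability
# ---------------------------------------------------------------------------

class TestExpectedMinorProb:
    def test_contaminated_homozygous_cell(self):
        """In the (AA, BB) cell the minor-read fraction is essentially the
        contaminant proportion itself: 0.409 contamination with 0.3% error
        gives a 40.9% minor-read probability."""
        val = expected_minor_prob("AA", "BB", p=0.409, eps=0.003)
        assert val == pytest.approx(0.409, abs=1e-3)

    def test_pure_sample_no_error(self):
        assert expected_minor_prob("AA", "AA", p=0.0, eps=0.0) == 0.0
        assert expected_minor_prob("BB", "BB", p=0.0, eps=0.0) == 1.0

    @pytest.mark.parametrize("p", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("eps", [0.0, 0.01, 0.4])
    def test_double_het_is_exactly_half(self, p, eps):
        assert expected_minor_prob("AB", "AB", p, eps) == pytest.approx(0.5, abs=1e-15)

    def test_monotone_in_contaminant_proportion(self):
        p_grid = np.linspace(0, 1, 21)
        for g1 in GT:
            for g2 in GT:
                vals = [expected_minor_prob(g1, g2, p, 0.01) for p in p_grid]
                diffs = np.diff(vals)
                if FREQ[g2] > FREQ[g1]:
                    assert (diffs > 0).all()
                elif FREQ[g2] < FREQ[g1]:
                    assert (diffs < 0).all()
                else:
                    assert np.allclose(diffs, 0)

    def test_allele_swap_symmetry(self):
        """Swapping A and B in both genotypes reflects the probability."""
        flip = {"AA": "BB", "AB": "AB", "BB": "AA"}
        rng = np.random.default_rng(2)
        for _ in range(20):
            g1, g2 = rng.choice(GT, 2)
            p, eps = rng.uniform(0, 1), rng.uniform(0, 0.49)
            assert expected_minor_prob(g1, g2, p, eps) == pytest.approx(
                1.0 - expected_minor_prob(flip[g1], flip[g2], p, eps)
            )

    @pytest.mark.parametrize("p,eps", [(-0.1, 0.01), (1.1, 0.01), (0.5, 0.5), (0.5, -0.01)])
    def test_out_of_bounds_params_rejected(self, p, eps):
        with pytest.raises(ValueError):
            expected_minor_prob("AA", "AA", p, eps)

    @settings(derandomize=True, max_examples=100)
    @given(
        g1=st.sampled_from(GT),
        g2=st.sampled_from(GT),
        p=st.floats(0.0, 1.0),
        eps=st.floats(0.0, 0.499),
    )
    def test_probability_bounded_by_error_rate(self, g1, g2, p, eps):
        """The read-level probability always lies in [eps, 1 - eps]: errors
        bound how extreme an allele fraction can be."""
        val = expected_minor_prob(g1, g2, p, eps)
        assert eps - 1e-12 <= val <= 1 - eps + 1e-12


# ---------------------------------------------------------------------------
# Log-likelihood
# ---------------------------------------------------------------------------

class TestMixtureLoglik:
    def test_empty_table_gives_zero(self):
        assert mixture_loglik(np.zeros((3, 3, 2), dtype=int), 0.3, 0.01) == 0.0

    def test_single_cell_closed_form(self):
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[0, 0, 0] = 10  # (AA, AA), all major reads
        assert mixture_loglik(counts, 0.0, 0.01) == pytest.approx(10 * math.log(0.99))

    def test_contradicted_zero_probability_is_neg_inf(self):
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[0, 0, 1] = 1  # a minor read where pi = 0
        assert mixture_loglik(counts, 0.0, 0.0) == NEG_INF

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_summation(self, seed):
        rng = np.random.default_rng(seed)
        t, _, _ = random_table(rng)
        p, eps = rng.uniform(0, 1), rng.uniform(0.001, 0.49)
        assert mixture_loglik(t, p, eps) == pytest.approx(
            naive_loglik(t.counts, p, eps), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFitMixture:
    def test_noise_free_pure_sample(self):
        """All reads concordant at eps = 0: the no-contamination null is the
        global optimum and the LRT vanishes."""
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[0, 0, 0] = 5000  # AA/AA, all A
        counts[2, 2, 1] = 3000  # BB/BB, all B
        counts[0, 2, 0] = 2000  # AA/BB, still all A
        fit = fit_mixture(JointCategoryTable("m", "s", "o", counts))
        assert fit.p_hat == pytest.approx(0.0, abs=1e-3)
        assert fit.lrt == pytest.approx(0.0, abs=1e-4)

    def test_null_eps_matches_closed_form(self):
        """The numeric null fit agrees with the pooled-discordance closed
        form for eps under p = 0."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            t, _, _ = random_table(rng, depth=5000)
            fit = fit_mixture(t)
            # the closed form can exceed the eps < 0.5 parameter bound on
            # heavily discordant tables; the MLE then sits at the bound
            expected = min(_null_eps_closed_form(t.counts), 0.5 - 1e-9)
            assert fit.eps0_hat == pytest.approx(expected, abs=1e-5)

    def test_grid_search_oracle_agreement(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            t, _, _ = random_table(rng, depth=5000)
            fit = fit_mixture(t)
            p_g, e_g, ll_g = grid_fit(t.counts)
            assert abs(fit.p_hat - p_g) < 2e-3
            assert fit.loglik_alt >= ll_g - 1e-4

    def test_pure_swap_estimated_as_total_contamination(self):
        """A sample whose reads come entirely from another individual is
        estimated as ~100% contaminated by it."""
        cfg = SimulationConfig(seed=77, n_samples=2, n_snps=2000, mean_depth=100,
                               depth_multiplier_range=(1, 1))
        geno, _, _ = simulate_cohort(cfg)
        rng = np.random.default_rng(78)
        sac = simulate_read_counts(geno, "S001", Scenario("swap", "S002"), rng,
                                   mean_depth=100, eps_true=0.005)
        fit = fit_mixture(tabulate_pair(sac, geno, "S001", "S002"))
        assert fit.p_hat > 0.99
        assert fit.lrt > 1e4

    def test_unidentifiable_without_discordant_genotype_cells(self):
        counts = np.zeros((3, 3, 2), dtype=int)
        counts[0, 0] = (100, 1)  # only diagonal cells populated
        counts[1, 1] = (50, 50)
        counts[2, 2] = (2, 100)
        fit = fit_mixture(JointCategoryTable("m", "s", "o", counts))
        assert not fit.identifiable
        assert fit.p_hat == 0.0
        assert fit.lrt == 0.0

    def test_empty_table(self):
        fit = fit_mixture(JointCategoryTable("m", "s", "o", np.zeros((3, 3, 2), int)))
        assert fit.n_reads == 0
        assert fit.loglik_alt == 0.0

    def test_lrt_never_negative(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            t, _, _ = random_table(rng, depth=300)
            assert fit_mixture(t).lrt >= 0.0


# ---------------------------------------------------------------------------
# Scan and separation rule
# ---------------------------------------------------------------------------

def fake_scan(lrts):
    frame = pd.DataFrame(
        {
            "candidate_id": [f"c{i}" for i in range(len(lrts))],
            "p_hat": 0.1,
            "eps_hat": 0.005,
            "lrt": lrts,
            "n_reads": 10**6,
            "identifiable": True,
        }
    ).sort_values("lrt", ascending=False, kind="stable").reset_index(drop=True)
    return ContaminantScan("m", "m", frame)


class TestDetectContaminant:
    def test_clear_separation_flagged(self):
        scan = fake_scan([1.1e6, 900, 850, 700])
        flagged, sep = detect_contaminant(scan)
        assert flagged == "c0"
        assert sep == pytest.approx(1.1e6 / 900)

    def test_no_separation_not_flagged(self):
        scan = fake_scan([1200.0, 900.0, 850.0])
        flagged, sep = detect_contaminant(scan)
        assert flagged is None
        assert sep == pytest.approx(1200 / 900)

    def test_trivially_small_top_lrt_not_flagged(self):
        """A single tiny nonzero LRT over a floor of zeros is numerical
        noise, not evidence of separation."""
        flagged, sep = detect_contaminant(fake_scan([0.4, 1e-11, 0.0]))
        assert flagged is None
        assert sep > 10

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            detect_contaminant(fake_scan([5.0]))

    def test_gap_factor_configurable(self):
        scan = fake_scan([5000.0, 1200.0])
        assert detect_contaminant(scan, gap_factor=4)[0] == "c0"
        assert detect_contaminant(scan, gap_factor=10)[0] is None


class TestScanContaminants:
    def test_true_contaminant_attains_max_lrt(self):
        cfg = SimulationConfig(
            seed=55, n_samples=6, n_snps=2000, mean_depth=100,
            depth_multiplier_range=(1, 1),
            scenarios={"S001": Scenario("mixture", "S004", 0.4)},
        )
        geno, counts, _ = simulate_cohort(cfg)
        scan = scan_contaminants(counts["S001"], geno, "S001")
        assert len(scan.results) == 5
        assert scan.results["candidate_id"].iloc[0] == "S004"
        assert scan.results["lrt"].iloc[0] > 10 * scan.results["lrt"].iloc[1]
        assert scan.fits["S004"].p_hat == pytest.approx(0.4, abs=0.03)

    def test_single_candidate_scan(self):
        cfg = SimulationConfig(seed=56, n_samples=2, n_snps=500, mean_depth=50,
                               depth_multiplier_range=(1, 1))
        geno, counts, _ = simulate_cohort(cfg)
        scan = scan_contaminants(counts["S001"], geno, "S001")
        assert len(scan.results) == 1

    def test_unknown_sample_rejected(self):
        cfg = SimulationConfig(seed=57, n_samples=2, n_snps=100, mean_depth=10)
        geno, counts, _ = simulate_cohort(cfg)
        with pytest.raises(KeyError):
            scan_contaminants(counts["S001"], geno, "missing")
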