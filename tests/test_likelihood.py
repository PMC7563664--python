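import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from trdscan import (
    ALPHA_BOUND,
    FamilyRecord,
    FamilySet,
    TransmissionCounts,
    fit_full,
    fit_null,
    loglik,
    lrt_pvalue,
    offspring_probs,
    tabulate,
)
from trdscan.family_data import MISSING

from conftest import make_table
from oracle import grid_loglik_max, random_counts


def _model_counts(rng, n_fam, alpha, pi, dam_freq):
    """Draw (d, o, E-sire) cell counts from the transmission model with
    HWE dam genotypes — an independent forward sampler for fit checks."""
    cells = {}
    hwe = [(1 - dam_freq) ** 2, 2 * dam_freq * (1 - dam_freq), dam_freq**2]
    n_by_dam = rng.multinomial(n_fam, hwe)
    for d in range(3):
        ns = rng.multinomial(n_by_dam[d], offspring_probs(d, alpha, pi))
        for o in range(3):
            if ns[o]:
                cells[(d, o, 0)] = int(ns[o])
    return cells


def counts_from(cells):
    """Build TransmissionCounts from {(d, o, s): count} (s: 0=E, 1=R)."""
    n = np.zeros((3, 3, 2), dtype=np.int64)
    for (d, o, s), c in cells.items():
        n[d, o, s] = c
    return TransmissionCounts(n)


class TestOffspringProbs:
    @pytest.mark.parametrize(
        "d, alpha, pi, expected",
        [
            (1, 0.0, 0.5, (0.25, 0.5, 0.25)),        # Mendelian limit
            (2, 0.3, 0.3, (0.0, 0.7, 0.3)),          # A1A1 dam: (0, 1-pi, pi)
            (0, -0.2, 0.3, (0.7, 0.3, 0.0)),         # A2A2 dam mirror
            (1, -0.25, 0.4, (0.45, 0.45, 0.10)),     # closed-form products
        ],
    )
    def test_closed_form_values(self, d, alpha, pi, expected):
        probs = offspring_probs(d, alpha, pi)
        assert probs == pytest.approx(expected, abs=1e-12)

    @given(
        d=st.sampled_from([0, 1, 2]),
        alpha=st.floats(-ALPHA_BOUND, ALPHA_BOUND),
        pi=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization(self, d, alpha, pi):
        assert sum(offspring_probs(d, alpha, pi)) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_dam_genotype(self):
        with pytest.raises(ValueError):
            offspring_probs(3, 0.0, 0.5)


class TestTabulate:
    def test_uniform_cells(self):
        row = np.array([1, 1, 1, 2, 2, 2])  # dams cols 0-2, offspring 3-5
        fams = [(3, 0, "E"), (4, 1, "E"), (5, 2, "E")]
        counts = tabulate(row, fams)
        assert counts.n[1, 2, 0] == 3 and counts.total == 3

    def test_incompatible_pair_excluded(self):
        row = np.array([2, 0])
        counts = tabulate(row, [(1, 0, "E")])
        assert counts.total == 0

    def test_mixed_fixture_matches_hand_tally(self):
        #    dams: d0..d5 cols 0-5, offspring o0..o5 cols 6-11
        row = np.array([1, 1, 2, 0, 1, 2,  2, 0, 1, 1, MISSING, 0])
        fams = [(6 + i, i, "E" if i % 2 == 0 else "R") for i in range(6)]
        counts = tabulate(row, fams)
        # hand tally: (1,2,E)=1, (1,0,R)=1, (2,1,E)=1, (0,1,R)=1;
        # family 4 dam het/off missing -> dropped; family 5 (2,0) incompatible
        assert counts.n[1, 2, 0] == 1
        assert counts.n[1, 0, 1] == 1
        assert counts.n[2, 1, 0] == 1
        assert counts.n[0, 1, 1] == 1
        assert counts.total == 4

    def test_resolves_family_set_against_table(self):
        table = make_table([[1, 2]], individual_ids=["dam1", "off1"])
        fams = FamilySet(records=[FamilyRecord("off1", "dam1", "R")])
        counts = tabulate(table.genotypes[0], fams, table)
        assert counts.n[1, 2, 1] == 1

    def test_structural_zero_enforced(self):
        with pytest.raises(ValueError):
            counts_from({(2, 0, 0): 1})


class TestLoglik:
    def test_hand_evaluated_het_dam_table(self):
        counts = counts_from({(1, 2, 0): 3, (1, 1, 0): 4, (1, 0, 0): 3})
        expected = 6 * math.log(0.25) + 4 * math.log(0.5)  # = -11.0904
        assert loglik(counts, 0.0, 0.5, float("nan")) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-11.0904, abs=5e-5)

    def test_empty_counts_zero(self):
        assert loglik(counts_from({}), 0.2, 0.3, 0.7) == 0.0

    def test_populated_zero_probability_cell_is_minus_inf(self):
        counts = counts_from({(2, 2, 0): 1})
        assert loglik(counts, 0.0, 0.0, 0.5) == -math.inf

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_label_swap_symmetry(self, seed):
        """Relabeling A1<->A2 (codes reflected, alpha -> -alpha,
        pi -> 1-pi) leaves the likelihood invariant."""
        rng = np.random.default_rng(seed)
        n = random_counts(rng)
        swapped = TransmissionCounts(n[::-1, ::-1, :].copy())
        alpha = rng.uniform(-ALPHA_BOUND, ALPHA_BOUND)
        pi_e, pi_r = rng.uniform(0.01, 0.99, size=2)
        a = loglik(TransmissionCounts(n), alpha, pi_e, pi_r)
        b = loglik(swapped, -alpha, 1 - pi_e, 1 - pi_r)
        assert a == pytest.approx(b, abs=1e-10)


class TestFitNull:
    def test_homozygous_dam_binomial_mle(self):
        counts = counts_from({(2, 2, 0): 30, (2, 1, 0): 70})
        fit = fit_null(counts)
        assert fit.pi_e == pytest.approx(0.30, abs=1e-12)
        assert np.isnan(fit.pi_r)  # no R-sired families at this SNP

    def test_mirror_case_a2a2_dams(self):
        counts = counts_from({(0, 1, 0): 12, (0, 0, 0): 28})
        assert fit_null(counts).pi_e == pytest.approx(0.30, abs=1e-12)

    def test_mixed_dams_match_grid_search(self):
        counts = counts_from(
            {(2, 2, 0): 5, (2, 1, 0): 9, (1, 2, 0): 4, (1, 1, 0): 10,
             (1, 0, 0): 6, (0, 1, 0): 3, (0, 0, 0): 7}
        )
        fit = fit_null(counts)
        grid = np.arange(0.0, 1.0001, 0.001)
        lnls = [loglik(counts, 0.0, pi, float("nan")) for pi in grid]
        best = grid[int(np.argmax(lnls))]
        assert fit.pi_e == pytest.approx(best, abs=1e-3)
        assert fit.lnl >= max(lnls) - 1e-9

    def test_empty_counts_not_estimable(self):
        assert not fit_null(counts_from({})).estimable


class TestFitFull:
    def test_null_data_recovers_alpha_near_zero(self):
        """Large sample, alpha=0, mixed dam genotypes (homozygous-dam
        families pin pi, so the het-dam families identify alpha)."""
        counts = counts_from(_model_counts(np.random.default_rng(42),
                                           2000, 0.0, 0.5, 0.5))
        fit = fit_full(counts)
        assert abs(fit.alpha) < 0.1

    def test_all_mass_on_a1_hits_upper_bounds(self):
        counts = counts_from({(1, 2, 0): 50})
        fit = fit_full(counts)
        assert fit.alpha == pytest.approx(ALPHA_BOUND, abs=1e-3)
        assert fit.pi_e == pytest.approx(1.0, abs=1e-3)

    def test_no_het_dam_families_alpha_not_estimable(self):
        fit = fit_full(counts_from({(2, 2, 0): 10, (2, 1, 0): 10}))
        assert not fit.estimable and np.isnan(fit.alpha)

    def test_lnl_at_least_null(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = TransmissionCounts(random_counts(rng))
            assert fit_full(counts).lnl >= fit_null(counts).lnl - 1e-9

    def test_matches_grid_search_oracle(self):
        """ML fit reaches the exhaustive 0.001-step 3-D grid maximum."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = random_counts(rng)
            fit = fit_full(TransmissionCounts(n))
            assert fit.lnl >= grid_loglik_max(n) - 1e-6


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        # cell fractions (0.25, 0.5, 0.25) are attained exactly at the
        # Mendelian point, so the full fit cannot improve on the null
        counts = counts_from({(1, 0, 0): 5, (1, 1, 0): 10, (1, 2, 0): 5})
        full, null = fit_full(counts), fit_null(counts)
        stat, p = lrt_pvalue(full, null)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("stat, expected_p", [(3.841, 0.05), (10.83, 0.001)])
    def test_chi_square_quantiles(self, stat, expected_p):
        assert chi2.sf(stat, df=1) == pytest.approx(expected_p, rel=5e-3)

    def test_non_estimable_fit_gives_nan(self):
        counts = counts_from({(2, 2, 0): 5})
        stat, p = lrt_pvalue(fit_full(counts), fit_null(counts))
        assert np.isnan(stat) and np.isnan(p)


def test_null_lrt_statistic_follows_chi_square_1df(null_lrt_stats):
    """Under alpha = 0 the LRT statistic is chi-square (1 df) apart from a
    point mass at 0 left by clipping; the positive part passes a one-sided
    KS test against chi2(1) at level 0.01 (alternative: stochastically
    larger than chi2, the anticonservative direction)."""
    from scipy.stats import chi2, kstest

    stats, _ = null_lrt_stats
    pos = stats[stats > 1e-12]
    assert pos.size >= 1500
    res = kstest(pos, chi2(1).cdf, alternative="less")
    assert res.pvalue > 0.01


def test_monotone_information():
    """With fixed distortion, the median LRT statistic grows with the
    number of families (more het-dam draws, tighter pi from hom dams)."""
    rng = np.random.default_rng(99)
    medians = []
    for n_fam in (25, 100, 400):
        stats = []
        for _ in range(25):
            counts = counts_from(_model_counts(rng, n_fam, -0.3, 0.5, 0.5))
            s, _p = lrt_pvalue(fit_full(counts), fit_null(counts))
            stats.append(s)
        medians.append(np.median(stats))
    assert medians[0] < medians[1] < medians[2]
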