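"""RC contrast ratios, paired CIs, non-inferiority/superiority, kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import usirhf as u
from usirhf.clinical import (
    kappa_range,
    rc_differences,
    score_differences,
    wilcoxon_signed_rank,
)
from usirhf.errors import (
    DegenerateMarginalsError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedRatioError,
)


class TestComputeRC:
    @pytest.mark.parametrize("d,p,expect", [(5, 5, 0.0), (1, 0, 1.0),
                                            (9, 1, 0.8)])
    def test_examples(self, d, p, expect):
        assert u.compute_rc(d, p) == pytest.approx(expect)

    def test_both_zero(self):
        with pytest.raises(UndefinedRatioError):
            u.compute_rc(0, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        rc = u.compute_rc(a, b)
        assert -1 <= rc <= 1
        assert rc == pytest.approx(-u.compute_rc(b, a))


class TestPairedCI:
    def test_constant_differences_degenerate(self):
        lo, hi = u.paired_ci(np.full(10, 0.37))
        assert lo == hi == pytest.approx(0.37)

    def test_t_and_bootstrap_agree(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.3, 0.9, 41)
        t_lo, t_hi = u.paired_ci(d, method="t")
        b_lo, b_hi = u.paired_ci(d, method="bootstrap", n_boot=10000,
                                 seed=5)
        assert abs(t_lo - b_lo) < 0.05
        assert abs(t_hi - b_hi) < 0.05

    def test_coverage_is_about_95_percent(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            lo, hi = u.paired_ci(rng.normal(0, 1, 41))
            hits += lo <= 0 <= hi
        assert 0.935 <= hits / n_rep <= 0.965

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            u.paired_ci([0.1])


class TestNonInferiority:
    def test_zero_differences_clear_margin(self):
        cmp = u.assess_noninferiority(np.zeros(41), 0.07)
        assert cmp.verdict == "non_inferior"

    def test_clearly_inferior(self):
        rng = np.random.default_rng(2)
        d = rng.normal(-0.2, 0.05, 41)
        cmp = u.assess_noninferiority(d, 0.07)
        assert cmp.verdict == "inconclusive"

    def test_boundary_strict_inequality(self):
        cmp = u.assess_noninferiority(np.zeros(41), 0.0)
        assert cmp.verdict == "inconclusive"

    def test_enlarging_margin_never_loses_verdict(self):
        rng = np.random.default_rng(4)
        d = rng.normal(-0.05, 0.1, 41)
        verdicts = [u.assess_noninferiority(d, m).verdict
                    for m in (0.02, 0.05, 0.1, 0.2)]
        seen_non_inferior = False
        for v in verdicts:
            if seen_non_inferior:
                assert v == "non_inferior"
            seen_non_inferior |= v == "non_inferior"

    def test_negative_margin(self):
        with pytest.raises(InvalidParameterError):
            u.assess_noninferiority(np.zeros(5), -0.1)


class TestSuperiority:
    def test_clear_positive_shift(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.4, 0.5, 123)
        assert u.assess_superiority(d).verdict == "superior"

    def test_zero_differences_not_superior(self):
        assert u.assess_superiority(np.zeros(41)).verdict != "superior"

    def test_null_draw_not_superior(self):
        d = np.random.default_rng(8).normal(0, 1, 41)
        assert u.assess_superiority(d).verdict == "inconclusive"


def _brute_force_weighted_kappa(a, b, scheme):
    """Textbook weighted kappa via explicit confusion-matrix sums."""
    cats = range(1, 6)
    n = len(a)
    power = 1 if scheme == "linear" else 2
    obs = exp = 0.0
    for i in cats:
        for j in cats:
            w = (abs(i - j)) ** power
            nij = np.sum((np.asarray(a) == i) & (np.asarray(b) == j))
            obs += w * nij / n
            exp += w * np.mean(np.asarray(a) == i) \
                * np.mean(np.asarray(b) == j)
    return 1.0 - obs / exp


class TestWeightedKappa:
    def test_identical_ratings_give_one(self):
        a = [1, 2, 3, 4, 5, 1, 2, 3]
        assert u.weighted_kappa(a, a) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 6, 10000)
        b = rng.integers(1, 6, 10000)
        assert abs(u.weighted_kappa(a, b)) < 0.05

    def test_hand_computed_table(self):
        # confusion counts (a,b): (1,1) (1,2) (2,2) (3,3) (3,1), each once.
        # linear:   kappa = 1 - 0.15/0.23  = 8/23
        # quadratic: kappa = 1 - 0.0625/0.0875 = 2/7
        a = [1, 1, 2, 3, 3]
        b = [1, 2, 2, 3, 1]
        assert u.weighted_kappa(a, b, "linear") == pytest.approx(8 / 23)
        assert u.weighted_kappa(a, b, "quadratic") == pytest.approx(2 / 7)

    def test_against_brute_force_on_random_data(self):
        rng = np.random.default_rng(42)
        a = rng.integers(1, 6, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 1, 5)
        for scheme in ("linear", "quadratic"):
            assert u.weighted_kappa(a, b, scheme) == pytest.approx(
                _brute_force_weighted_kappa(a, b, scheme))

    def test_quadratic_at_least_linear_for_adjacent_disagreement(self):
        a = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        b = [2, 2, 3, 4, 5, 1, 3, 3, 4, 4]
        assert u.weighted_kappa(a, b, "quadratic") \
            >= u.weighted_kappa(a, b, "linear")

    def test_degenerate_marginals(self):
        with pytest.raises(DegenerateMarginalsError):
            u.weighted_kappa([3, 3, 3], [3, 3, 3])

    def test_perfect_anticorrelation_minus_one(self):
        assert u.weighted_kappa([1, 2], [2, 1],
                                "linear") == pytest.approx(-1.0)


class TestKappaInterpretation:
    @pytest.mark.parametrize("k,label", [
        (0.70, "substantial"), (0.95, "excellent"), (0.50, "moderate"),
        (0.205, "fair"), (0.10, "poor"), (-0.2, "poor (below chance)"),
        (0.81, "excellent"), (0.80, "substantial"),
    ])
    def test_bands(self, k, label):
        assert u.kappa_interpretation(k) == label


class TestGenerator:
    def test_reproducible(self):
        a_rc, a_sc = u.generate_clinical_dataset(seed=3)
        b_rc, b_sc = u.generate_clinical_dataset(seed=3)
        assert a_rc.equals(b_rc) and a_sc.equals(b_sc)

    def test_zero_shift_balances_arms(self):
        _, sc = u.generate_clinical_dataset(n_patients=400,
                                            score_shift=0.0, seed=5)
        means = sc.groupby("arm")["score"].mean()
        assert abs(means["U_plus"] - means["U_minus"]) < 0.05

    def test_rc_values_bounded(self):
        rc, _ = u.generate_clinical_dataset(seed=1)
        assert rc["rc"].between(-1, 1).all()
        # stored rc consistent with the stored intensities
        recomputed = (rc["si_duct"] - rc["si_periduct"]) \
            / (rc["si_duct"] + rc["si_periduct"])
        assert np.allclose(rc["rc"], recomputed)

    def test_invalid_correlation(self):
        with pytest.raises(InvalidParameterError):
            u.generate_clinical_dataset(paired_correlation=1.5)

    def test_default_pipeline_reproduces_study_pattern(self):
        """Defaults emulate the study: RC non-inferior for every duct,
        scores superior for every item, substantial reader agreement."""
        rc, sc = u.generate_clinical_dataset(seed=0)
        ni = u.noninferiority_report(rc)
        assert all(c.verdict == "non_inferior" for c in ni.values())
        sup = u.superiority_report(sc)
        assert all(c.verdict == "superior" for c in sup.values())
        kmin, kmax, _ = kappa_range(sc)
        assert 0.4 <= kmin <= kmax <= 1.0

    def test_type_one_error_control(self):
        """Null generator: superiority claimed in <= 7% of replicates."""
        false_pos = 0
        n_rep = 500
        for s in range(n_rep):
            _, sc = u.generate_clinical_dataset(
                n_patients=41, score_shift=0.0, seed=20000 + s)
            d = score_differences(sc, "overall")
            false_pos += u.assess_superiority(d).verdict == "superior"
        assert false_pos / n_rep <= 0.07


def test_rc_differences_shape():
    rc, _ = u.generate_clinical_dataset(n_patients=17, seed=2)
    d = rc_differences(rc, "MPD")
    assert d.shape == (17,)


def test_wilcoxon_convenience():
    rng = np.random.default_rng(0)
    a = rng.normal(160, 20, 30)
    res = wilcoxon_signed_rank(a, a + rng.normal(0, 1, 30))
    assert 0 <= res.pvalue <= 1
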