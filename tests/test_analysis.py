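import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import stereodepth as sd
from stereodepth.analysis import (
    bootstrap_ci,
    code_natural,
    continuity_correct,
    probit_average,
    probit_fit_counts,
    probit_loglik,
)


def make_trials(rows):
    return pd.DataFrame(rows, columns=["participant", "eccentricity_arcmin",
                                       "disparity_arcmin", "response",
                                       "confident"])


class TestCodeNatural:
    def test_definition(self):
        t = make_trials([(1, 0.0, 28.0, "near", True),
                         (1, 0.0, -28.0, "near", True),
                         (1, 0.0, -28.0, "far", False)])
        coded = code_natural(t)
        assert coded["natural"].tolist() == [True, False, True]

    def test_zero_disparity_rows_dropped(self, rng):
        rows = [(1, 0.0, d, "near", True)
                for d in [28.0] * 40 + [-28.0] * 40 + [0.0] * 40]
        assert len(code_natural(make_trials(rows))) == 80

    def test_missing_disparity_column_rejected(self):
        with pytest.raises(KeyError):
            code_natural(pd.DataFrame({"response": ["near"]}))


class TestProbitAverage:
    def test_chance_is_a_fixed_point(self):
        assert probit_average([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_two_participant_value_against_high_precision_oracle(self):
        # Phi((Phi^-1(0.6) + Phi^-1(0.9)) / 2), 20-digit reference value
        assert probit_average([0.6, 0.9]) == pytest.approx(0.77859279703427109, rel=1e-12)

    def test_single_participant_is_identity(self):
        assert probit_average([0.73]) == pytest.approx(0.73)

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValueError, match="continuity"):
            probit_average([0.5, 1.0])

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded_by_inputs(self, ps):
        a = probit_average(ps)
        assert probit_average(ps[::-1]) == pytest.approx(a)
        assert min(ps) - 1e-12 <= a <= max(ps) + 1e-12

    def test_continuity_correction_pulls_extremes_inside(self):
        p = continuity_correct(np.array([0.0, 1.0, 0.5]), np.array([40, 40, 40]))
        np.testing.assert_allclose(p, [1 / 80, 1 - 1 / 80, 0.5])


class TestBootstrapCI:
    def test_interval_straddles_half_for_chance_data(self):
        lo, hi = bootstrap_ci([40, 40, 40], [80, 80, 80], n_boot=2000, rng=0)
        assert lo < 0.5 < hi

    def test_fixed_seed_reproducible_endpoints(self):
        a = bootstrap_ci([55, 60, 50], [80, 80, 80], n_boot=2000, rng=3)
        b = bootstrap_ci([55, 60, 50], [80, 80, 80], n_boot=2000, rng=3)
        assert a == b

    def test_width_shrinks_as_root_n(self):
        rng = np.random.default_rng(5)
        widths = {80: [], 320: []}
        for _ in range(30):
            for n in (80, 320):
                k = rng.binomial(n, 0.7, 3)
                lo, hi = bootstrap_ci(k, np.full(3, n), n_boot=2000, rng=rng)
                widths[n].append(hi - lo)
        ratio = np.mean(widths[80]) / np.mean(widths[320])
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_empty_participant_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1], [0])


class TestProbitFit:
    def test_matches_statsmodels_probit_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        ecc = np.array([0.0, 186.0, 372.0, 570.0, 762.0])
        p = norm.cdf(1.29 - 0.0022 * ecc)
        k = rng.binomial(400, p)
        fit = probit_fit_counts(ecc, k, np.full(5, 400))
        ref = sm.GLM(np.column_stack([k, 400 - k]), sm.add_constant(ecc),
                     family=sm.families.Binomial(sm.families.links.Probit())).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-8)
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-8)
        assert fit.se_intercept == pytest.approx(ref.bse[0], rel=1e-6)
        assert fit.se_slope == pytest.approx(ref.bse[1], rel=1e-6)

    def test_matches_independent_grid_search(self):
        rng = np.random.default_rng(8)
        ecc = np.array([0.0, 186.0, 372.0, 570.0, 762.0])
        k = rng.binomial(100, norm.cdf(0.8 - 0.001 * ecc))
        n = np.full(5, 100)
        fit = probit_fit_counts(ecc, k, n)
        # coarse-to-fine grid maximisation of the binomial-probit likelihood
        b0s = np.linspace(-2.0, 3.0, 41)
        b1s = np.linspace(-0.01, 0.01, 41)
        for _ in range(6):
            ll = np.array([[probit_loglik(np.array([a, b]), ecc, k, n)
                            for b in b1s] for a in b0s])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            w0, w1 = b0s[2] - b0s[0], b1s[2] - b1s[0]
            b0s = np.linspace(b0s[i] - w0, b0s[i] + w0, 41)
            b1s = np.linspace(b1s[j] - w1, b1s[j] + w1, 41)
        assert fit.intercept == pytest.approx(b0s[20], abs=1e-4)
        assert fit.slope == pytest.approx(b1s[20], abs=1e-4)

    def test_zero_slope_data_rarely_yields_significant_slope(self):
        rng = np.random.default_rng(9)
        ecc = np.array([0.0, 186.0, 372.0, 570.0, 762.0])
        ok = 0
        for _ in range(200):
            k = rng.binomial(200, 0.7, size=5)
            f = probit_fit_counts(ecc, k, np.full(5, 200))
            ok += abs(f.slope) < 3 * f.se_slope
        assert ok >= 190

    def test_separation_is_flagged(self):
        ecc = np.array([0.0, 186.0, 372.0])
        fit = probit_fit_counts(ecc, np.array([50, 50, 50]), np.full(3, 50))
        assert not fit.converged
        assert fit.message

    def test_single_eccentricity_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            probit_fit_counts(np.zeros(3), np.array([1, 2, 3]), np.full(3, 10))

    def test_dataframe_interface_and_slope_sign(self):
        trials = sd.simulate_trials(
            sd.exp1_design(configurations=("edge",), durations_ms=(700.0,),
                           correlations=("anticorrelated",), participants=2,
                           repeats_per_disparity=400),
            rng=11)
        fit = sd.probit_glm_fit(code_natural(trials))
        assert fit.converged
        assert fit.slope < 0          # generating slope is negative
        assert fit.intercept > 0


@pytest.fixture(scope="module")
def trials():
    design = sd.exp1_design(configurations=("edge",), durations_ms=(80.0,),
                            eccentricities_deg=(0.0, 6.2), participants=3,
                            repeats_per_disparity=10)
    return sd.simulate_trials(design, rng=13)


class TestSummarize:
    def test_summary_structure_and_bounds(self, trials):
        s = sd.summarize(trials, n_boot=300, rng=0)
        assert len(s) == 2 * 2 * 1 * 1   # correlations x eccentricities
        assert ((s.ci_low_natural <= s.proportion_natural)
                & (s.proportion_natural <= s.ci_high_natural)).all()
        assert s.n_trials.eq(3 * 2 * 10 * 2).all() or s.n_trials.gt(0).all()

    def test_condition_fits_table(self, trials):
        f = sd.fit_conditions(trials)
        assert set(f.columns) >= {"intercept", "slope", "se_slope", "converged"}
        assert len(f) == 2
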