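"""Model enumeration, WLS fitting, AICc weighting and model averaging."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from linecross import (
    DatasetObservations,
    akaike_weights,
    build_cmatrix,
    confidence_set,
    drop_collinear,
    enumerate_models,
    fit_wls,
    model_average,
    standard_cohorts,
)
from linecross.engine import ModelFit, collinearity_diagnostic


def _obs(means, ses, weighted=True):
    return DatasetObservations(
        y=np.asarray(means, dtype=float),
        v=np.asarray(ses, dtype=float) ** 2 if weighted else np.ones(len(means)),
        weighted=weighted,
    )


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_effects, n_cohorts, expected",
        [
            (5, 6, 31),   # all non-empty subsets, cap 5
            (5, 3, 15),   # cap 2: C(5,1) + C(5,2)
            (1, 10, 1),
            (8, 16, 254),  # cap 7 of 8 effects
        ],
    )
    def test_counts(self, n_effects, n_cohorts, expected):
        names = [f"e{i}" for i in range(n_effects)]
        subsets = enumerate_models(names, n_cohorts)
        assert len(subsets) == expected
        # deterministic order: by size then lexicographic position
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes)
        assert len(set(subsets)) == len(subsets)

    def test_matches_brute_force_powerset(self):
        names = ["Aa", "Ad", "AaAa"]
        got = set(enumerate_models(names, n_cohorts=8))
        want = {
            s
            for r in range(1, 4)
            for s in itertools.combinations(names, r)
        }
        assert got == want

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models([], 5)


class TestCollinearity:
    def test_identical_columns_dropped(self):
        # under the reduced set, reciprocal backcrosses duplicate rows but
        # Aa and AaAa columns can also coincide; build an exact duplicate
        cohorts = standard_cohorts(["P1", "P2", "F1", "BC1", "rBC1"])
        cm = build_cmatrix(cohorts, model_set="full")
        # Ma equals Aa of the dam; craft a subset with literally equal
        # columns by comparing Ad with Ad (self-duplication via near-dup)
        cm.coefficients[:, cm.effect_names.index("Ma") + 1] = cm.coefficients[
            :, cm.effect_names.index("Aa") + 1
        ]
        assert drop_collinear(cm, ["Aa", "Ma"])

    def test_orthogonal_design_kept(self, classic6_cmatrix):
        assert not drop_collinear(classic6_cmatrix, ["Aa", "Ad"])

    def test_near_duplicate_columns_dropped(self, classic6_cmatrix):
        cm = classic6_cmatrix
        j = cm.effect_names.index("AaAa") + 1
        i = cm.effect_names.index("Aa") + 1
        cm.coefficients[:, j] = cm.coefficients[:, i] + 1e-12
        cond, pair = collinearity_diagnostic(cm, ["Aa", "AaAa"])
        # independent singular-value check of the same submatrix
        ref = np.linalg.cond(cm.columns(["Aa", "AaAa"]))
        assert cond == pytest.approx(ref)
        assert cond > 1e8
        assert drop_collinear(cm, ["Aa", "AaAa"])
        assert set(pair) == {"Aa", "AaAa"}


class TestWLS:
    def test_noise_free_interpolation(self, classic6_cmatrix):
        beta_true = {"Aa": 3.0, "AdAd": 2.0}
        x = classic6_cmatrix.columns(["Aa", "AdAd"])
        y = x @ np.array([10.0, 3.0, 2.0])
        fit = fit_wls(_obs(y, np.full(6, 0.5)), classic6_cmatrix, ["Aa", "AdAd"])
        assert fit.beta == pytest.approx([10.0, 3.0, 2.0], abs=1e-10)

    def test_equal_ses_reduce_to_ols(self, classic6_cmatrix):
        rng = np.random.default_rng(7)
        y = rng.normal(10, 1, 6)
        fit_w = fit_wls(_obs(y, np.full(6, 2.5)), classic6_cmatrix, ["Aa", "Ad"])
        x = classic6_cmatrix.columns(["Aa", "Ad"])
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert fit_w.beta == pytest.approx(beta_ols)

    def test_four_cohort_toy_exact_solution(self, toy4_dataset):
        """Frozen solution of the 3x3 weighted normal equations.

        With unit SEs the normal equations are X'X b = X'y; solving by
        exact rational row-reduction gives b = (65/11, 4, 32/11).
        """
        cm = build_cmatrix(toy4_dataset, model_set="reduced")
        obs = _obs([10, 2, 9, 7], [1, 1, 1, 1])
        fit = fit_wls(obs, cm, ["Aa", "Ad"])
        expected = [Fraction(65, 11), Fraction(4), Fraction(32, 11)]
        assert fit.beta == pytest.approx([float(f) for f in expected], abs=1e-12)

    def test_beta_invariant_to_se_rescaling(self, classic6_cmatrix):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 1, 6)
        ses = rng.uniform(0.1, 1.0, 6)
        f1 = fit_wls(_obs(y, ses), classic6_cmatrix, ["Aa", "Ad", "AaAa"])
        f2 = fit_wls(_obs(y, 37.0 * ses), classic6_cmatrix, ["Aa", "Ad", "AaAa"])
        assert f1.beta == pytest.approx(f2.beta)

    def test_statsmodels_cross_check(self, classic6_cmatrix):
        """Independent WLS route: estimates and covariance agree."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        y = rng.normal(10, 1, 6)
        ses = rng.uniform(0.1, 0.5, 6)
        fit = fit_wls(_obs(y, ses), classic6_cmatrix, ["Aa", "Ad"])
        x = classic6_cmatrix.columns(["Aa", "Ad"])
        ref = sm.WLS(y, x, weights=1.0 / ses**2).fit()
        assert fit.beta == pytest.approx(ref.params)
        # with V known, the coefficient covariance is the unscaled
        # inverse normal matrix
        assert fit.beta_cov == pytest.approx(
            ref.normalized_cov_params, abs=1e-10
        )

    def test_unscorable_small_sample_flagged(self, toy4_dataset):
        cm = build_cmatrix(toy4_dataset, model_set="reduced")
        obs = _obs([10, 2, 9, 7], [1, 1, 1, 1])
        # weighted: k = 3 effects + intercept = 4, n - k - 1 = -1
        fit = fit_wls(obs, cm, ["Aa", "Ad", "AdAd"])
        assert fit is not None and math.isinf(fit.aicc)
        # unweighted counts the residual variance: even 2 effects unscorable
        obs_u = _obs([10, 2, 9, 7], None, weighted=False)
        assert math.isinf(fit_wls(obs_u, cm, ["Aa", "Ad"]).aicc)
        with pytest.raises(ValueError, match="excluded"):
            akaike_weights([fit])


def _fake_fit(effects, aicc):
    k = len(effects) + 1
    return ModelFit(
        effects=tuple(effects),
        beta=np.zeros(k),
        beta_cov=np.eye(k),
        loglik=0.0,
        aicc=aicc,
        k=k,
    )


class TestAkaikeWeights:
    def test_equal_scores_split_evenly(self):
        fits = akaike_weights([_fake_fit(["Aa"], 10.0), _fake_fit(["Ad"], 10.0)])
        assert [f.weight for f in fits] == pytest.approx([0.5, 0.5])

    def test_delta_two_closed_form(self):
        fits = akaike_weights([_fake_fit(["Aa"], 10.0), _fake_fit(["Ad"], 12.0)])
        w = 1.0 / (1.0 + math.exp(-1.0))
        assert fits[0].weight == pytest.approx(w, abs=1e-6)
        assert fits[1].weight == pytest.approx(1 - w, abs=1e-6)
        assert fits[0].weight == pytest.approx(0.7311, abs=5e-5)
        assert fits[1].weight == pytest.approx(0.2689, abs=5e-5)

    def test_single_model_gets_unit_weight(self):
        (fit,) = akaike_weights([_fake_fit(["Aa"], 3.0)])
        assert fit.weight == 1.0 and fit.delta == 0.0

    def test_weights_sum_to_one_and_stable_for_huge_aicc(self):
        fits = akaike_weights(
            [_fake_fit(["Aa"], 1e6), _fake_fit(["Ad"], 1e6 + 3), _fake_fit(["AaAa"], 1e6 + 9)]
        )
        assert sum(f.weight for f in fits) == pytest.approx(1.0)
        assert all(np.isfinite(f.weight) for f in fits)
        assert min(f.delta for f in fits) == 0.0


class TestConfidenceSet:
    def test_dominant_model_alone(self):
        fits = akaike_weights([_fake_fit(["Aa"], 0.0), _fake_fit(["Ad"], 8.0)])
        assert fits[0].weight > 0.95
        cs = confidence_set(fits)
        assert len(cs) == 1 and cs[0].effects == ("Aa",)
        assert cs[0].weight == pytest.approx(1.0)

    def test_renormalized_prefix(self):
        # engineer weights (0.5, 0.3, 0.15, 0.05) via exact AICc spacing
        target = np.array([0.5, 0.3, 0.15, 0.05])
        aiccs = -2.0 * np.log(target)
        fits = akaike_weights(
            [_fake_fit([f"e{i}"], a) for i, a in enumerate(aiccs)]
        )
        assert [f.weight for f in fits] == pytest.approx(list(target))
        cs = confidence_set(fits, level=0.95)
        assert [f.effects[0] for f in cs] == ["e0", "e1", "e2"]
        assert [f.weight for f in cs] == pytest.approx(
            [0.5 / 0.95, 0.3 / 0.95, 0.15 / 0.95]
        )

    def test_uniform_weights_take_95_of_100(self):
        fits = akaike_weights([_fake_fit([f"e{i}"], 5.0) for i in range(100)])
        assert len(confidence_set(fits, level=0.95)) == 95


class TestModelAverage:
    def test_effect_in_all_models_with_common_value(self):
        fits = []
        for w_aicc in (0.0, 0.0):
            f = _fake_fit(["Aa"], w_aicc)
            f.beta = np.array([1.0, 4.2])
            fits.append(f)
        akaike_weights(fits)
        avg = model_average(fits, ["Aa"])
        assert avg["Aa"]["estimate"] == pytest.approx(4.2)
        assert avg["Aa"]["importance"] == pytest.approx(1.0)

    def test_hand_computed_mixture(self):
        """Effect in one model (w=0.6, est=2, var=0.1), absent in the other."""
        f1 = _fake_fit(["Aa"], 0.0)
        f1.beta = np.array([0.0, 2.0])
        f1.beta_cov = np.diag([0.0, 0.1])
        f1.weight, f1.delta = 0.6, 0.0
        f2 = _fake_fit(["Ad"], 0.0)
        f2.weight, f2.delta = 0.4, 0.0
        avg = model_average([f1, f2], ["Aa"])
        row = avg["Aa"]
        assert row["estimate"] == pytest.approx(1.2)
        assert row["importance"] == pytest.approx(0.6)
        assert row["se"] ** 2 == pytest.approx(1.02)

    def test_absent_effect_is_zero_and_insignificant(self):
        f = _fake_fit(["Aa"], 0.0)
        f.weight = 1.0
        avg = model_average([f], ["Aa", "Ad"])
        row = avg["Ad"]
        assert row["estimate"] == 0.0
        assert row["importance"] == 0.0
        assert not row["significant"]

    def test_estimate_bounded_by_per_model_estimates(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fits = []
            est = []
            raw = rng.uniform(0, 1, 3)
            weights = raw / raw.sum()
            for w in weights:
                f = _fake_fit(["Aa"], 0.0)
                b = rng.normal(0, 3)
                f.beta = np.array([0.0, b])
                f.weight = w
                est.append(b)
                fits.append(f)
            avg = model_average(fits, ["Aa"])
            assert min(est + [0.0]) - 1e-12 <= avg["Aa"]["estimate"] <= max(est + [0.0]) + 1e-12
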