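"""Model fitting: phi screen, regressions, high-intensity profiles."""

import numpy as np
import pytest
from scipy import stats

from revcorrfaces import (
    ObserverTemplate,
    fit_intensity_gradient,
    fit_models,
    fit_temporal,
    high_intensity_profile,
    phi_correlation,
    simulate_observer_log,
)
from revcorrfaces.revcorr_fit import MIN_REGRESSION_TRIALS
from revcorrfaces.stimgen import DEFAULT_CATALOG, PARAM_NAMES, sample_profile_params
from revcorrfaces.synthetic_observer import OTHER, PAIN, ObserverLog


def _make_log(au, params, response, intensity, observer_id="t", culture="western"):
    return ObserverLog(
        observer_id, culture,
        np.asarray(au, dtype=np.uint8),
        np.asarray(params, dtype=float),
        np.asarray(response, dtype=np.int8),
        np.asarray(intensity, dtype=float),
    )


def _synthetic_log(rng, n, au_cols, response, amplitude=None, intensity=None):
    """Build a log with given active-AU columns per trial and responses."""
    n_aus = DEFAULT_CATALOG.size
    au = np.zeros((n, n_aus), dtype=np.uint8)
    for i, cols in enumerate(au_cols):
        au[i, cols] = 1
    params = np.full((n, n_aus, 7), np.nan)
    amp_idx = PARAM_NAMES.index("amplitude")
    for i in range(n):
        for j in np.flatnonzero(au[i]):
            row = sample_profile_params(rng, 1)[0]
            if amplitude is not None:
                row[amp_idx] = amplitude[i]
            params[i, j] = row
    response = np.asarray(response, dtype=np.int8)
    if intensity is None:
        intensity = np.where(response != OTHER, 3.0, np.nan)
    return _make_log(au, params, response, intensity)


class TestPhiCorrelation:
    def test_identical_vectors_give_r_one(self):
        x = np.array([0, 1, 1, 0, 1])
        r, p = phi_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_contingency_table_closed_form(self):
        # 2x2 cell counts a=40 (present, orgasm), b=10, c=10, d=40
        x = np.array([1] * 40 + [1] * 10 + [0] * 10 + [0] * 40)
        y = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        r, p = phi_correlation(x, y)
        assert r == pytest.approx(1500 / 2500, abs=1e-12)  # (ad-bc)/sqrt(margins)
        # independent oracle: t-transform of r
        t = 0.6 * np.sqrt(98 / (1 - 0.36))
        assert p == pytest.approx(2 * stats.t.sf(t, 98), rel=1e-9)
        assert p < 1e-9

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            phi_correlation(np.ones(10), np.array([0, 1] * 5))

    def test_matches_pearson_on_random_binary_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if x.std() == 0 or y.std() == 0:
                continue
            r, p = phi_correlation(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestFitModels:
    def test_deterministic_single_au_observer_recovered(self, catalog):
        template = ObserverTemplate(
            "det", "western", frozenset({4}), frozenset({12}),
            match_threshold=0.5, lapse_rate=0.0,
        )
        log = simulate_observer_log(template, 3600, np.random.default_rng(21), catalog)
        pain, orgasm = fit_models(log)
        assert 4 in pain.au_set and 12 in orgasm.au_set
        assert not pain.au_set & orgasm.au_set
        # sign coherence on the full correlation vectors
        for m, sign in ((pain, -1), (orgasm, +1)):
            for a in m.au_set:
                assert sign * m.au_r[catalog.index(a)] > 0

    def test_random_responder_false_positive_rate_matches_alpha(self):
        """Under a null responder the expected count of significant AUs is
        alpha x 42 = 2.1 per observer (pain + orgasm models combined)."""
        rng = np.random.default_rng(77)
        n_obs, counts = 40, []
        for _ in range(n_obs):
            n = 400
            cols = [rng.choice(42, size=rng.integers(1, 5), replace=False)
                    for _ in range(n)]
            response = rng.integers(0, 2, n)  # only pain/orgasm
            log = _synthetic_log(rng, n, cols, response)
            pain, orgasm = fit_models(log)
            counts.append(len(pain.au_set) + len(orgasm.au_set))
        expected = 0.05 * 42
        se = np.sqrt(expected / n_obs)  # Poisson-ish spread over observers
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_missing_class_is_an_error(self, rng):
        n = 50
        cols = [np.array([0, 1]) for _ in range(n)]
        log = _synthetic_log(rng, n, cols, [PAIN] * n)
        with pytest.raises(ValueError, match="pain and one orgasm"):
            fit_models(log)


class TestTemporalRegressions:
    def _paired_log(self, rng, n=200, amplitude=None, intensity=None, response=None):
        if response is None:
            response = rng.integers(0, 2, n)
        cols = [np.array([3]) for _ in range(n)]  # AU 5 active on all trials
        return _synthetic_log(rng, n, cols, response, amplitude, intensity), response

    def test_null_slopes_when_params_uninformative(self, rng):
        log, _ = self._paired_log(rng)
        w = fit_temporal(log, 5)
        # crude SE bound: |w| < 3 / sqrt(n) on standardized-ish scales
        assert np.all(np.abs(w) < 1.0)

    def test_planted_amplitude_coefficient_recovered(self, rng):
        response = rng.integers(0, 2, 300)
        log, _ = self._paired_log(rng, 300, amplitude=response.astype(float) * 0.8 + 0.1,
                                  response=response)
        w = fit_temporal(log, 5)
        amp_idx = PARAM_NAMES.index("amplitude")
        assert w[amp_idx] == pytest.approx(1 / 0.8, abs=1e-6)
        others = np.delete(w, amp_idx)
        assert np.all(np.abs(others) < 1e-6)

    def test_too_few_trials_is_an_error(self, rng):
        log, _ = self._paired_log(rng, MIN_REGRESSION_TRIALS - 1,
                                  response=[0, 1] * 4)
        with pytest.raises(ValueError, match="at least"):
            fit_temporal(log, 5)

    def test_intensity_gradient_recovers_planted_amplitude_effect(self, rng):
        n = 300
        amplitude = rng.uniform(0.05, 1.0, n)
        intensity = np.clip(np.rint(1 + 4 * amplitude), 1, 5)
        log, _ = self._paired_log(rng, n, amplitude=amplitude, intensity=intensity,
                                  response=np.ones(n, dtype=int))
        w = fit_intensity_gradient(log, 5, "orgasm")
        assert w[PARAM_NAMES.index("amplitude")] > 3.0

    def test_intensity_gradient_requires_matching_affect_trials(self, rng):
        log, _ = self._paired_log(rng, 50, response=np.ones(50, dtype=int))
        with pytest.raises(ValueError, match="no pain trials"):
            fit_intensity_gradient(log, 5, "pain")


class TestHighIntensityProfile:
    def _log_with_intensities(self, rng, intensities):
        n = len(intensities)
        cols = [np.array([3]) for _ in range(n)]
        log = _synthetic_log(rng, n, cols, np.ones(n, dtype=int),
                             intensity=np.asarray(intensities, dtype=float))
        return log

    def test_single_qualifying_trial_returned_verbatim(self, rng):
        log = self._log_with_intensities(rng, [5, 2, 3])
        prof = high_intensity_profile(log, 5, "orgasm")
        assert np.allclose(prof.as_array(), log.params[0, 3])

    def test_two_qualifying_trials_averaged_elementwise(self, rng):
        log = self._log_with_intensities(rng, [5, 4, 2])
        prof = high_intensity_profile(log, 5, "orgasm")
        assert np.allclose(prof.as_array(), log.params[:2, 3].mean(axis=0))

    def test_no_high_intensity_trials_advises_widening(self, rng):
        log = self._log_with_intensities(rng, [2, 3, 1])
        with pytest.raises(ValueError, match="widening"):
            high_intensity_profile(log, 5, "orgasm")
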