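"""Synthetic observers: templates, response rule, cohort and validation sims."""

import numpy as np
import pytest

from revcorrfaces import (
    DEFAULT_TEMPLATES,
    ObserverParams,
    ObserverTemplate,
    make_template,
    respond,
    simulate_cohort,
    simulate_observer_log,
    simulate_validation,
)
from revcorrfaces.stimgen import TemporalProfile, aus_to_vector
from revcorrfaces.stimgen import StimulusSpec
from revcorrfaces.synthetic_observer import ValidationTrial


def _stimulus(aus, catalog, amplitude=0.75):
    profiles = {
        a: TemporalProfile(0.2, 1.0, amplitude, 0.7, 0.3, 2.0, 1.8) for a in aus
    }
    return StimulusSpec(aus_to_vector(aus, catalog), profiles, catalog=catalog)


class TestMakeTemplate:
    def test_defaults_reproduce_group_templates(self, rng):
        west = make_template("western", rng=rng, add_prob=0, drop_prob=0)
        assert west.pain_aus == frozenset({4, 6, 9, 10, 20})
        assert west.orgasm_aus == frozenset({1, 2, 5, 26, 27, 43})
        east = make_template("east_asian", rng=rng, add_prob=0, drop_prob=0)
        assert east.orgasm_aus == frozenset({1, 2, 12, 43})

    def test_full_drop_falls_back_to_one_au(self, rng):
        t = make_template("western", rng=rng, add_prob=0, drop_prob=1.0)
        assert len(t.pain_aus) == 1 and t.pain_aus <= DEFAULT_TEMPLATES["western"]["pain"]
        assert len(t.orgasm_aus) == 1

    def test_invalid_probabilities_rejected(self, rng):
        with pytest.raises(ValueError):
            make_template("western", rng=rng, add_prob=1.5)

    def test_affect_templates_stay_disjoint_under_addition(self, rng):
        for _ in range(50):
            t = make_template("western", rng=rng, add_prob=0.3, drop_prob=0.2)
            assert not t.pain_aus & t.orgasm_aus


class TestRespond:
    def _template(self, **kw):
        defaults = dict(
            observer_id="o", culture="western",
            pain_aus=frozenset({4, 6, 9}), orgasm_aus=frozenset({12, 25}),
            match_threshold=0.5, lapse_rate=0.0,
        )
        defaults.update(kw)
        return ObserverTemplate(**defaults)

    def test_full_overlap_yields_affect_and_intensity(self, rng, catalog):
        resp, inten = respond(self._template(), _stimulus({4, 6, 9}, catalog), rng)
        assert resp == "pain" and 1 <= inten <= 5

    def test_disjoint_stimulus_yields_other_without_intensity(self, rng, catalog):
        resp, inten = respond(self._template(), _stimulus({17, 20}, catalog), rng)
        assert resp == "other" and inten is None

    def test_tied_overlap_goes_to_other(self, rng, catalog):
        t = self._template(pain_aus=frozenset({4}), orgasm_aus=frozenset({12}),
                           match_threshold=0.5)
        resp, _ = respond(t, _stimulus({4, 12}, catalog), rng)
        assert resp == "other"

    def test_intensity_tracks_peak_amplitude(self, catalog):
        t = self._template(intensity_noise=0.0)
        rng = np.random.default_rng(0)
        _, lo = respond(t, _stimulus({4, 6, 9}, catalog, amplitude=0.05), rng)
        _, hi = respond(t, _stimulus({4, 6, 9}, catalog, amplitude=1.0), rng)
        assert lo == 1 and hi == 5

    def test_full_lapse_gives_uniform_responses(self, catalog):
        t = self._template(lapse_rate=1.0)
        rng = np.random.default_rng(99)
        log = simulate_observer_log(t, 10_000, rng, catalog)
        freqs = np.bincount(log.response, minlength=3) / 10_000
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        assert np.all(np.abs(freqs - 1 / 3) < 3 * se)


class TestCohort:
    def test_shapes_and_determinism(self, catalog):
        logs1 = simulate_cohort(2, "western", 50, np.random.default_rng(5))
        logs2 = simulate_cohort(2, "western", 50, np.random.default_rng(5))
        assert len(logs1) == 2 and all(l.n_trials == 50 for l in logs1)
        for a, b in zip(logs1, logs2):
            assert np.array_equal(a.au, b.au)
            assert np.array_equal(a.response, b.response)
            assert np.array_equal(a.params, b.params, equal_nan=True)
            assert a.template == b.template

    def test_trial_records_satisfy_invariants(self, rng):
        log = simulate_cohort(1, "western", 40, rng)[0]
        for rec in log.trials:
            assert (rec.intensity is None) == (rec.response == "other")

    def test_deterministic_rule_with_zero_lapse(self, catalog):
        params = ObserverParams(match_threshold=0.5, lapse_rate=0.0,
                                add_prob=0.0, drop_prob=0.0)
        log = simulate_observer_log(
            make_template("western", rng=np.random.default_rng(1), params=params),
            2000, np.random.default_rng(2), catalog,
        )
        # recompute responses from the AU matrix alone
        tp = aus_to_vector(DEFAULT_TEMPLATES["western"]["pain"], catalog)
        to = aus_to_vector(DEFAULT_TEMPLATES["western"]["orgasm"], catalog)
        op = log.au @ tp / tp.sum()
        oo = log.au @ to / to.sum()
        expect = np.full(2000, 2)
        expect[(op >= 0.5) & (op > oo)] = 0
        expect[(oo >= 0.5) & (oo > op)] = 1
        assert np.array_equal(log.response, expect)

    def test_template_aus_enriched_on_matching_trials(self, rng, catalog):
        """Reverse correlation presupposes that template AUs appear more often
        on affect-labeled trials than non-template AUs do."""
        log = simulate_cohort(1, "western", 3000, rng)[0]
        t = log.template
        pain_rows = log.au[log.response == 0]
        assert len(pain_rows) > 10
        in_t = [catalog.index(a) for a in t.pain_aus]
        out_t = [j for j in range(catalog.size)
                 if catalog.ids[j] not in t.pain_aus | t.orgasm_aus]
        assert pain_rows[:, in_t].mean() > 2 * pain_rows[:, out_t].mean()

    def test_invalid_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_cohort(0, "western", 10, rng)
        with pytest.raises(ValueError):
            simulate_observer_log(make_template("western", rng=rng), 0, rng)


class _FakeModel:
    def __init__(self, model_id, affect, aus):
        self.model_id = model_id
        self.affect = affect
        self.au_set = frozenset(aus)


class TestValidation:
    def _models(self, n_pairs=20):
        out = []
        for i in range(n_pairs):
            out.append(_FakeModel(f"m{i}_pain", "pain", {4, 6, 9, 10, 20}))
            out.append(_FakeModel(f"m{i}_orgasm", "orgasm", {1, 2, 5, 26, 27, 43}))
        return out

    def _observers(self, n, lapse=0.0):
        return [
            ObserverTemplate(f"v{i}", "western",
                             frozenset({4, 6, 9, 10, 20}),
                             frozenset({1, 2, 5, 26, 27, 43}),
                             match_threshold=0.5, lapse_rate=lapse)
            for i in range(n)
        ]

    def test_session_structure(self, rng):
        sessions = simulate_validation(self._models(20), self._observers(3), rng)
        assert len(sessions) == 3
        for session in sessions:
            assert len(session) == 800  # 20 pairs x 2 affects x 10 identities x 2
            assert sum(t.matched for t in session) == 400
            assert len({(t.model_id, t.word) for t in session}) == 40 * 2

    def test_perfect_templates_give_perfect_rates(self, rng):
        sessions = simulate_validation(self._models(5), self._observers(2), rng)
        for session in sessions:
            assert all(t.answer for t in session if t.matched)
            assert not any(t.answer for t in session if not t.matched)

    def test_full_lapse_gives_half_rates(self):
        sessions = simulate_validation(
            self._models(10), self._observers(4, lapse=1.0), np.random.default_rng(11)
        )
        trials = [t for s in sessions for t in s]
        hit = np.mean([t.answer for t in trials if t.matched])
        fa = np.mean([t.answer for t in trials if not t.matched])
        se = 3 / np.sqrt(len(trials) / 2)
        assert abs(hit - 0.5) < se and abs(fa - 0.5) < se

    def test_empty_model_list_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_validation([], self._observers(1), rng)

    def test_validation_trial_word_checked(self):
        with pytest.raises(ValueError):
            ValidationTrial("o", 0, "anger", "m", True, True)
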