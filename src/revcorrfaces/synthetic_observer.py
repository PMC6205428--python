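"""Simulated observers for the categorization and validation tasks.

The real experiments collect human judgments; this module supplies a
generative stand-in so every downstream analysis can be exercised and its
parameter recovery measured against known ground truth.  Each simulated
observer carries a *template* per affect (the AU sets of their internal
representation of pain and of orgasm) and responds to a stimulus by
template overlap: if at least a threshold fraction of one template's AUs
is active, and strictly more so than for the other affect, the observer
reports that affect and rates its intensity; otherwise "other".  A lapse
rate injects uniformly random responses, and Gaussian noise perturbs the
intensity ratings.

The default templates are the group-level cross-cultural AU sets of the
pipeline's own comparison analyses: pain shares brow lowerer (4), cheek
raiser (6), nose wrinkler (9), upper lip raiser (10) and lip stretcher
(20) across cultures; orgasm combines brow raiser (1, 2) and eyes closed
(43) with upper lid raiser (5), jaw drop (26) and mouth stretch (27) in
the Western template and lip corner puller (12) in the East Asian one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .stimgen import (
    DEFAULT_CATALOG,
    DEFAULT_COUNT_PROBS,
    DEFAULT_RANGES,
    DURATION,
    PARAM_NAMES,
    ActionUnitCatalog,
    ProfileRanges,
    StimulusSpec,
    TemporalProfile,
    aus_to_vector,
    sample_profile_params,
)

CULTURES = ("western", "east_asian")
RESPONSES = ("pain", "orgasm", "other")
PAIN, ORGASM, OTHER = 0, 1, 2

#: Group-level template AU sets per culture and affect.
DEFAULT_TEMPLATES: dict[str, dict[str, frozenset[int]]] = {
    "western": {
        "pain": frozenset({4, 6, 9, 10, 20}),
        "orgasm": frozenset({1, 2, 5, 26, 27, 43}),
    },
    "east_asian": {
        "pain": frozenset({4, 6, 9, 10, 20}),
        "orgasm": frozenset({1, 2, 12, 43}),
    },
}

#: Index of the amplitude channel in :data:`PARAM_NAMES`.
_AMP = PARAM_NAMES.index("amplitude")


@dataclass(frozen=True)
class ObserverParams:
    """Behavioral parameters of the simulated observer population.

    match_threshold
        Minimum fraction of a template's AUs that must be active for a
        match.  0.2 means one or two AUs of a four- to ten-AU template
        suffice, which yields workable response rates (roughly 10-15%
        of trials per affect) under the 1-4-AU stimulus law.
    lapse_rate
        Probability of a uniformly random response among the three
        options, regardless of the stimulus.
    intensity_noise
        SD of the Gaussian noise added to the 1-5 intensity rating.
    add_prob / drop_prob
        Individual variability: each non-template catalog AU is added to
        an observer's template with ``add_prob``; each group-template AU
        is dropped with ``drop_prob`` (at least one AU always remains).
    """

    match_threshold: float = 0.2
    lapse_rate: float = 0.05
    intensity_noise: float = 0.5
    add_prob: float = 0.05
    drop_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.match_threshold <= 1.0):
            raise ValueError("match_threshold must be in (0, 1]")
        for name in ("lapse_rate", "add_prob", "drop_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intensity_noise < 0:
            raise ValueError("intensity_noise must be non-negative")


DEFAULT_PARAMS = ObserverParams()


@dataclass(frozen=True)
class ObserverTemplate:
    """Ground truth for one simulated observer."""

    observer_id: str
    culture: str
    pain_aus: frozenset[int]
    orgasm_aus: frozenset[int]
    match_threshold: float = DEFAULT_PARAMS.match_threshold
    lapse_rate: float = DEFAULT_PARAMS.lapse_rate
    intensity_noise: float = DEFAULT_PARAMS.intensity_noise

    def __post_init__(self) -> None:
        if self.culture not in CULTURES:
            raise ValueError(f"culture must be one of {CULTURES}")
        if not self.pain_aus or not self.orgasm_aus:
            raise ValueError("template AU sets must be non-empty")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")

    @property
    def all_aus(self) -> frozenset[int]:
        return self.pain_aus | self.orgasm_aus


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus joined with the observer's response."""

    trial_id: int
    stimulus: StimulusSpec
    response: str
    intensity: int | None

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if (self.intensity is None) != (self.response == "other"):
            raise ValueError("intensity must be present iff response is not 'other'")
        if self.intensity is not None and not (1 <= self.intensity <= 5):
            raise ValueError("intensity must be an integer in 1-5")


@dataclass
class ObserverLog:
    """One observer's full trial log in columnar (array) form.

    ``au`` is the (n_trials, n_aus) presence matrix in catalog order;
    ``params`` holds the temporal parameters (n_trials, n_aus, 7) with NaN
    at inactive positions; ``response`` uses the integer codes
    PAIN=0 / ORGASM=1 / OTHER=2 and ``intensity`` is NaN on "other"
    trials.  ``trials`` iterates :class:`TrialRecord` views for
    record-level access.
    """

    observer_id: str
    culture: str
    au: np.ndarray
    params: np.ndarray
    response: np.ndarray
    intensity: np.ndarray
    template: ObserverTemplate | None = None
    catalog: ActionUnitCatalog = field(default=DEFAULT_CATALOG, repr=False)

    def __post_init__(self) -> None:
        n = len(self.response)
        if self.au.shape != (n, self.catalog.size):
            raise ValueError("au matrix shape does not match responses/catalog")
        if self.params.shape != (n, self.catalog.size, 7):
            raise ValueError("params array shape does not match au matrix")
        present = ~np.isnan(self.intensity)
        if not np.array_equal(present, self.response != OTHER):
            raise ValueError("intensity must be present iff response is not 'other'")

    @property
    def n_trials(self) -> int:
        return len(self.response)

    def trial(self, i: int) -> TrialRecord:
        idx = np.flatnonzero(self.au[i])
        profiles = {
            int(self.catalog.ids[j]): TemporalProfile.from_array(self.params[i, j])
            for j in idx
        }
        stim = StimulusSpec(self.au[i].astype(np.uint8), profiles, DURATION, self.catalog)
        resp = RESPONSES[int(self.response[i])]
        inten = None if resp == "other" else int(self.intensity[i])
        return TrialRecord(i, stim, resp, inten)

    @property
    def trials(self) -> Iterator[TrialRecord]:
        return (self.trial(i) for i in range(self.n_trials))


@dataclass(frozen=True)
class ValidationTrial:
    """One yes/no trial of the word-expression matching task."""

    observer_id: str
    trial_id: int
    word: str
    model_id: str
    matched: bool
    answer: bool

    def __post_init__(self) -> None:
        if self.word not in ("pain", "orgasm"):
            raise ValueError("word must be 'pain' or 'orgasm'")


def make_template(
    culture: str,
    base_templates: Mapping[str, Mapping[str, frozenset[int]]] | None = None,
    rng: np.random.Generator | None = None,
    add_prob: float = 0.0,
    drop_prob: float = 0.0,
    observer_id: str = "obs0",
    params: ObserverParams = DEFAULT_PARAMS,
    catalog: ActionUnitCatalog | None = None,
) -> ObserverTemplate:
    """Draw an individual observer template around the group-level AU sets.

    Each group AU is dropped with ``drop_prob`` (at least one survives;
    if all are dropped one is retained at random) and each catalog AU
    outside both affects' current sets is added with ``add_prob``.
    Additions are disjoint across affects, so individual templates stay
    non-overlapping like the group templates.
    """
    if not (0.0 <= add_prob <= 1.0 and 0.0 <= drop_prob <= 1.0):
        raise ValueError("add_prob and drop_prob must be in [0, 1]")
    base = base_templates or DEFAULT_TEMPLATES
    if culture not in base:
        raise ValueError(f"unknown culture {culture!r}")
    catalog = catalog or DEFAULT_CATALOG
    rng = rng or np.random.default_rng()
    catalog_ids = set(int(a) for a in catalog.ids)
    sets: dict[str, set[int]] = {}
    taken: set[int] = set(base[culture]["pain"]) | set(base[culture]["orgasm"])
    for affect in ("pain", "orgasm"):
        aus = sorted(base[culture][affect])
        if not set(aus) <= catalog_ids:
            raise ValueError("base template AUs must belong to the catalog")
        kept = [a for a in aus if rng.random() >= drop_prob]
        if not kept:  # minimum-one-AU fallback
            kept = [aus[int(rng.integers(len(aus)))]]
        candidates = sorted(catalog_ids - taken)
        added = [a for a in candidates if rng.random() < add_prob]
        sets[affect] = set(kept) | set(added)
        taken |= set(added)
    return ObserverTemplate(
        observer_id=observer_id,
        culture=culture,
        pain_aus=frozenset(sets["pain"]),
        orgasm_aus=frozenset(sets["orgasm"]),
        match_threshold=params.match_threshold,
        lapse_rate=params.lapse_rate,
        intensity_noise=params.intensity_noise,
    )


def _overlap(active: frozenset[int], template_aus: frozenset[int]) -> float:
    return len(active & template_aus) / len(template_aus)


def respond(
    template: ObserverTemplate,
    stimulus: StimulusSpec,
    rng: np.random.Generator,
) -> tuple[str, int | None]:
    """Simulate one categorical response and intensity rating.

    Overlap o_A = |active AUs ∩ template_A| / |template_A| per affect;
    with probability ``lapse_rate`` the response is uniform over the
    three options.  Otherwise the affect with the larger overlap is
    reported if its overlap reaches the match threshold and strictly
    exceeds the other affect's (ties go to "other").  The intensity is
    1 + 4 x (mean peak amplitude of the matched template AUs) plus
    Gaussian noise, rounded and clamped to 1-5; on lapse trials without
    matched AUs the mean over all active AUs is used.
    """
    active = stimulus.active_aus
    o_pain = _overlap(active, template.pain_aus)
    o_org = _overlap(active, template.orgasm_aus)
    if rng.random() < template.lapse_rate:
        response = RESPONSES[int(rng.integers(3))]
    elif o_pain >= template.match_threshold and o_pain > o_org:
        response = "pain"
    elif o_org >= template.match_threshold and o_org > o_pain:
        response = "orgasm"
    else:
        response = "other"
    if response == "other":
        return response, None
    matched = active & (template.pain_aus if response == "pain" else template.orgasm_aus)
    pool = matched or active
    mean_amp = float(np.mean([stimulus.profiles[a].peak_amplitude for a in sorted(pool)]))
    raw = 1.0 + 4.0 * mean_amp + rng.normal(0.0, template.intensity_noise)
    return response, int(np.clip(np.rint(raw), 1, 5))


def _sample_au_matrix(
    rng: np.random.Generator,
    n_trials: int,
    catalog: ActionUnitCatalog,
    count_probs: Mapping[int, float],
) -> np.ndarray:
    """Vectorized draw of the (n_trials, n_aus) presence matrix."""
    ks = np.array(sorted(count_probs), dtype=int)
    ps = np.array([count_probs[k] for k in ks], dtype=float)
    counts = rng.choice(ks, size=n_trials, p=ps)
    # rank trick: the k smallest of i.i.d. uniforms select a uniform k-subset
    r = rng.random((n_trials, catalog.size))
    rank = r.argsort(axis=1).argsort(axis=1)
    return rank < counts[:, None]


def simulate_observer_log(
    template: ObserverTemplate,
    n_trials: int,
    rng: np.random.Generator,
    catalog: ActionUnitCatalog | None = None,
    count_probs: Mapping[int, float] | None = None,
    ranges: ProfileRanges = DEFAULT_RANGES,
) -> ObserverLog:
    """Simulate a full trial log for one observer (vectorized)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    catalog = catalog or DEFAULT_CATALOG
    count_probs = dict(DEFAULT_COUNT_PROBS if count_probs is None else count_probs)
    n_aus = catalog.size

    active = _sample_au_matrix(rng, n_trials, catalog, count_probs)
    params = sample_profile_params(rng, (n_trials, n_aus), ranges)
    params[~active] = np.nan

    tp = aus_to_vector(template.pain_aus, catalog).astype(float)
    to = aus_to_vector(template.orgasm_aus, catalog).astype(float)
    o_pain = active @ tp / tp.sum()
    o_org = active @ to / to.sum()

    thr = template.match_threshold
    response = np.full(n_trials, OTHER, dtype=np.int8)
    response[(o_pain >= thr) & (o_pain > o_org)] = PAIN
    response[(o_org >= thr) & (o_org > o_pain)] = ORGASM
    lapse = rng.random(n_trials) < template.lapse_rate
    response[lapse] = rng.integers(0, 3, int(lapse.sum()))

    amp = params[:, :, _AMP]
    noise = rng.normal(0.0, template.intensity_noise, n_trials)
    intensity = np.full(n_trials, np.nan)
    for code, template_aus in ((PAIN, tp), (ORGASM, to)):
        rows = np.flatnonzero(response == code)
        if rows.size == 0:
            continue
        matched = active[rows] & (template_aus > 0)
        use = np.where(matched.any(axis=1)[:, None], matched, active[rows])
        mean_amp = np.nansum(np.where(use, amp[rows], 0.0), axis=1) / use.sum(axis=1)
        raw = 1.0 + 4.0 * mean_amp + noise[rows]
        intensity[rows] = np.clip(np.rint(raw), 1, 5)

    return ObserverLog(
        observer_id=template.observer_id,
        culture=template.culture,
        au=active.astype(np.uint8),
        params=params,
        response=response,
        intensity=intensity,
        template=template,
        catalog=catalog,
    )


def simulate_cohort(
    n_observers: int,
    culture: str,
    n_trials: int = 3600,
    rng: np.random.Generator | None = None,
    params: ObserverParams = DEFAULT_PARAMS,
    base_templates: Mapping[str, Mapping[str, frozenset[int]]] | None = None,
    catalog: ActionUnitCatalog | None = None,
    count_probs: Mapping[int, float] | None = None,
    ranges: ProfileRanges = DEFAULT_RANGES,
) -> list[ObserverLog]:
    """Simulate independent observers; fully reproducible from the seed."""
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    rng = rng or np.random.default_rng()
    logs = []
    for i, child in enumerate(rng.spawn(n_observers)):
        template = make_template(
            culture,
            base_templates,
            child,
            add_prob=params.add_prob,
            drop_prob=params.drop_prob,
            observer_id=f"{culture}_{i:02d}",
            params=params,
            catalog=catalog,
        )
        logs.append(
            simulate_observer_log(template, n_trials, child, catalog, count_probs, ranges)
        )
    return logs


def _model_identity(model, idx: int) -> tuple[str, str, frozenset[int]]:
    """Duck-typed access to (id, affect, AU set) of a fitted model."""
    affect = getattr(model, "affect")
    model_id = getattr(model, "model_id", None) or f"{getattr(model, 'observer_id', idx)}_{affect}"
    aus = getattr(model, "au_set", None)
    if aus is None:
        aus = frozenset(model)  # plain iterable of AU ids
    return str(model_id), str(affect), frozenset(int(a) for a in aus)


def simulate_validation(
    models: Sequence,
    observer_templates: Sequence[ObserverTemplate],
    rng: np.random.Generator,
    n_identities: int = 10,
) -> list[list[ValidationTrial]]:
    """Simulate the yes/no word-expression validation task.

    Each displayed model (an object exposing ``affect`` and ``au_set``)
    is shown on ``n_identities`` face identities (simulated as i.i.d.
    repeats) once with the matching word and once with the mismatching
    word, so each observer completes ``2 x n_identities x len(models)``
    trials, exactly half matched, in random order.  The yes/no answer
    applies the observer's own overlap rule: yes iff the model's AU set
    overlaps the cued word's template at threshold and strictly more
    than the other affect's template; lapses answer at random.
    """
    if not models:
        raise ValueError("model list must not be empty")
    ident = [_model_identity(m, i) for i, m in enumerate(models)]
    sessions: list[list[ValidationTrial]] = []
    for template, child in zip(observer_templates, rng.spawn(len(observer_templates))):
        trials: list[tuple[str, str, bool]] = []
        for model_id, affect, aus in ident:
            o = {
                "pain": _overlap(aus, template.pain_aus),
                "orgasm": _overlap(aus, template.orgasm_aus),
            }
            for word in ("pain", "orgasm"):
                other = "orgasm" if word == "pain" else "pain"
                base_yes = o[word] >= template.match_threshold and o[word] > o[other]
                for _ in range(n_identities):
                    trials.append((model_id, word, word == affect, base_yes))
        order = child.permutation(len(trials))
        lapse = child.random(len(trials)) < template.lapse_rate
        coin = child.random(len(trials)) < 0.5
        session = []
        for tid, j in enumerate(order):
            model_id, word, matched, base_yes = trials[j]
            answer = bool(coin[tid]) if lapse[tid] else bool(base_yes)
            session.append(
                ValidationTrial(template.observer_id, tid, word, model_id, matched, answer)
            )
        sessions.append(session)
    return sessions
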