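"""Random dynamic action-unit stimuli for reverse-correlation experiments.

A stimulus is a 2.25 s facial animation described numerically: a binary
vector over a catalog of 42 FACS action units (AUs), of which 1-4 are
active on any trial (median 3), plus a seven-parameter temporal activation
profile per active AU (onset latency, acceleration, peak amplitude, peak
latency, sustainment, deceleration, offset latency).  No faces are
rendered; downstream analyses operate on the numeric AU time courses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Stimulus duration in seconds.
DURATION = 2.25

#: Size of the default action-unit catalog.
N_AUS = 42

#: Column order used everywhere a 7-parameter temporal profile is stored
#: as a flat vector (CSV exports, regression designs, fitted coefficients).
PARAM_NAMES = (
    "onset",
    "acceleration",
    "amplitude",
    "peak",
    "sustain",
    "deceleration",
    "offset",
)

#: Probability mass over the number of active AUs per trial.  The protocol
#: fixes minimum 1, maximum 4 and median 3; these masses realise that
#: median (CDF at 2 is 0.40 < 0.5, at 3 is 0.80 >= 0.5).
DEFAULT_COUNT_PROBS: dict[int, float] = {1: 0.10, 2: 0.30, 3: 0.40, 4: 0.20}

# FACS codes and names for the default 42-AU catalog.  Includes every AU
# named in the analyses (1, 2, 4-7, 9-12, 17, 20, 25-27, 43, 45) padded to
# 42 with further standard FACS codes.
_DEFAULT_AU_ENTRIES: tuple[tuple[int, str], ...] = (
    (1, "inner brow raiser"),
    (2, "outer brow raiser"),
    (4, "brow lowerer"),
    (5, "upper lid raiser"),
    (6, "cheek raiser"),
    (7, "lid tightener"),
    (9, "nose wrinkler"),
    (10, "upper lip raiser"),
    (11, "nasolabial deepener"),
    (12, "lip corner puller"),
    (13, "sharp lip puller"),
    (14, "dimpler"),
    (15, "lip corner depressor"),
    (16, "lower lip depressor"),
    (17, "chin raiser"),
    (18, "lip pucker"),
    (19, "tongue show"),
    (20, "lip stretcher"),
    (21, "neck tightener"),
    (22, "lip funneler"),
    (23, "lip tightener"),
    (24, "lip pressor"),
    (25, "lips part"),
    (26, "jaw drop"),
    (27, "mouth stretch"),
    (28, "lip suck"),
    (29, "jaw thrust"),
    (30, "jaw sideways"),
    (31, "jaw clencher"),
    (32, "lip bite"),
    (33, "cheek blow"),
    (34, "cheek puff"),
    (35, "cheek suck"),
    (36, "tongue bulge"),
    (37, "lip wipe"),
    (38, "nostril dilator"),
    (39, "nostril compressor"),
    (41, "lid droop"),
    (42, "eyelid slit"),
    (43, "eyes closed"),
    (45, "blink"),
    (46, "wink"),
)


@dataclass(frozen=True)
class ActionUnitCatalog:
    """Ordered catalog of (FACS code, name) pairs.

    AU ids must be unique and sorted ascending; the default catalog has
    exactly 42 entries.
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ids = [au_id for au_id, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate AU ids in catalog: {dupes}")
        if ids != sorted(ids):
            raise ValueError("catalog AU ids must be sorted ascending")
        if not ids:
            raise ValueError("catalog must not be empty")

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> np.ndarray:
        return np.array([au_id for au_id, _ in self.entries], dtype=int)

    def index(self, au_id: int) -> int:
        """Position of ``au_id`` in the catalog order."""
        ids = [a for a, _ in self.entries]
        try:
            return ids.index(int(au_id))
        except ValueError:
            raise KeyError(f"AU {au_id} not in catalog") from None

    def name(self, au_id: int) -> str:
        return self.entries[self.index(au_id)][1]

    def __contains__(self, au_id: int) -> bool:
        return any(a == au_id for a, _ in self.entries)

    def to_json(self, path) -> None:
        data = [{"au_id": a, "au_name": n} for a, n in self.entries]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ActionUnitCatalog":
        with open(path) as fh:
            data = json.load(fh)
        return cls(tuple((int(d["au_id"]), str(d["au_name"])) for d in data))


#: The default 42-AU catalog used throughout the package.
DEFAULT_CATALOG = ActionUnitCatalog(_DEFAULT_AU_ENTRIES)


def build_catalog(custom_entries: Sequence[tuple[int, str]] | None = None) -> ActionUnitCatalog:
    """Return the default 42-AU catalog, or validate and wrap a custom list."""
    if custom_entries is None:
        catalog = DEFAULT_CATALOG
        if catalog.size != N_AUS:  # pragma: no cover - guards the constant
            raise ValueError("default catalog must contain exactly 42 AUs")
        return catalog
    return ActionUnitCatalog(tuple((int(a), str(n)) for a, n in custom_entries))


@dataclass(frozen=True)
class TemporalProfile:
    """Seven-parameter activation profile of one AU over the stimulus.

    Times are absolute seconds within [0, duration]; ``offset_latency`` is
    the absolute time at which activation returns to zero (not a gap).
    The activation rises from zero at ``onset_latency`` to
    ``peak_amplitude`` at ``peak_latency`` as a power law with exponent
    ``acceleration``, holds the peak for ``sustainment`` seconds, then
    decays back to zero at ``offset_latency`` with exponent
    ``deceleration``.
    """

    onset_latency: float
    acceleration: float
    peak_amplitude: float
    peak_latency: float
    sustainment: float
    deceleration: float
    offset_latency: float
    duration: float = DURATION

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_latency < self.peak_latency):
            raise ValueError(
                f"need 0 <= onset ({self.onset_latency}) < peak latency ({self.peak_latency})"
            )
        if self.sustainment < 0:
            raise ValueError("sustainment must be non-negative")
        plateau_end = self.peak_latency + self.sustainment
        if not (plateau_end <= self.offset_latency <= self.duration):
            raise ValueError(
                f"need peak+sustain ({plateau_end}) <= offset "
                f"({self.offset_latency}) <= duration ({self.duration})"
            )
        if not (0.0 < self.peak_amplitude <= 1.0):
            raise ValueError("peak amplitude must be in (0, 1]")
        if self.acceleration <= 0 or self.deceleration <= 0:
            raise ValueError("acceleration/deceleration exponents must be > 0")

    def as_array(self) -> np.ndarray:
        """Flatten to the canonical :data:`PARAM_NAMES` order."""
        return np.array(
            [
                self.onset_latency,
                self.acceleration,
                self.peak_amplitude,
                self.peak_latency,
                self.sustainment,
                self.deceleration,
                self.offset_latency,
            ],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: Sequence[float], duration: float = DURATION) -> "TemporalProfile":
        on, acc, amp, pk, sus, dec, off = (float(v) for v in values)
        return cls(on, acc, amp, pk, sus, dec, off, duration)


@dataclass(frozen=True)
class StimulusSpec:
    """One random facial animation: active AUs plus their temporal profiles."""

    au_vector: np.ndarray
    profiles: Mapping[int, TemporalProfile]
    duration: float = DURATION
    catalog: ActionUnitCatalog = field(default=DEFAULT_CATALOG, repr=False)

    def __post_init__(self) -> None:
        vec = np.asarray(self.au_vector, dtype=np.uint8)
        object.__setattr__(self, "au_vector", vec)
        if vec.shape != (self.catalog.size,):
            raise ValueError(f"au_vector must have length {self.catalog.size}")
        k = int(vec.sum())
        if not (1 <= k <= 4):
            raise ValueError(f"number of active AUs must be in [1, 4], got {k}")
        active = {int(self.catalog.ids[i]) for i in np.flatnonzero(vec)}
        if set(self.profiles) != active:
            raise ValueError("profiles must be defined for exactly the active AUs")
        if self.duration != DURATION:
            raise ValueError(f"stimulus duration must be {DURATION} s")

    @property
    def active_aus(self) -> frozenset[int]:
        return frozenset(self.profiles)


@dataclass(frozen=True)
class ProfileRanges:
    """Uniform sampling ranges for the temporal parameters.

    ``onset`` and the rise time (peak latency minus onset) are drawn
    uniformly; sustainment occupies at most ``max_sustain_frac`` of the
    remaining time after the peak, leaving at least ``min_fall`` seconds
    for the decay so the profile always returns to zero by the offset.
    """

    onset: tuple[float, float] = (0.0, 0.5)
    rise: tuple[float, float] = (0.15, 0.9)
    acceleration: tuple[float, float] = (0.5, 3.0)
    amplitude: tuple[float, float] = (0.2, 1.0)
    max_sustain_frac: float = 0.5
    min_fall: float = 0.05
    deceleration: tuple[float, float] = (0.5, 3.0)


DEFAULT_RANGES = ProfileRanges()


def sample_profile_params(
    rng: np.random.Generator,
    shape: int | tuple[int, ...],
    ranges: ProfileRanges = DEFAULT_RANGES,
    duration: float = DURATION,
) -> np.ndarray:
    """Sample temporal-parameter arrays of the given shape.

    Returns an array of shape ``shape + (7,)`` in :data:`PARAM_NAMES`
    order; every row satisfies the :class:`TemporalProfile` invariants.
    """
    if isinstance(shape, int):
        shape = (shape,)
    onset = rng.uniform(*ranges.onset, shape)
    peak = onset + rng.uniform(*ranges.rise, shape)
    acc = rng.uniform(*ranges.acceleration, shape)
    amp = rng.uniform(*ranges.amplitude, shape)
    sustain = rng.uniform(0.0, 1.0, shape) * ranges.max_sustain_frac * (
        duration - peak - ranges.min_fall
    )
    plateau_end = peak + sustain
    offset = plateau_end + ranges.min_fall + rng.uniform(0.0, 1.0, shape) * (
        duration - plateau_end - ranges.min_fall
    )
    dec = rng.uniform(*ranges.deceleration, shape)
    return np.stack([onset, acc, amp, peak, sustain, dec, offset], axis=-1)


def sample_stimulus(
    rng: np.random.Generator,
    catalog: ActionUnitCatalog | None = None,
    count_probs: Mapping[int, float] | None = None,
    ranges: ProfileRanges = DEFAULT_RANGES,
    exclusions: Iterable[tuple[int, int]] = (),
) -> StimulusSpec:
    """Draw one random stimulus.

    The AU count is drawn from ``count_probs`` (default masses
    0.10/0.30/0.40/0.20 over 1-4), AUs uniformly without replacement, and
    each active AU receives an independent random temporal profile.
    ``exclusions`` lists mutually incompatible AU pairs; draws containing
    an excluded pair are rejected and resampled.
    """
    catalog = catalog or DEFAULT_CATALOG
    probs = dict(DEFAULT_COUNT_PROBS if count_probs is None else count_probs)
    ks = np.array(sorted(probs), dtype=int)
    ps = np.array([probs[k] for k in ks], dtype=float)
    if np.any(ps < 0) or not np.isclose(ps.sum(), 1.0):
        raise ValueError("count probabilities must be non-negative and sum to 1")
    excluded = {frozenset(pair) for pair in exclusions}
    k = int(rng.choice(ks, p=ps))
    while True:
        aus = rng.choice(catalog.ids, size=k, replace=False)
        chosen = set(int(a) for a in aus)
        if not any(pair <= chosen for pair in excluded):
            break
    params = sample_profile_params(rng, k, ranges)
    profiles = {int(a): TemporalProfile.from_array(row) for a, row in zip(aus, params)}
    vec = np.zeros(catalog.size, dtype=np.uint8)
    for a in chosen:
        vec[catalog.index(a)] = 1
    return StimulusSpec(vec, profiles, DURATION, catalog)


def activation_curve(profile: TemporalProfile, times) -> np.ndarray:
    """Evaluate one AU's activation fraction at the given times.

    Zero before onset and from the offset onward; power-law rise to the
    peak amplitude, plateau during sustainment, power-law decay to zero.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0) or np.any(t > profile.duration):
        raise ValueError(f"times must lie within [0, {profile.duration}]")
    on, acc, amp, pk, sus, dec, off = profile.as_array()
    plateau_end = pk + sus
    out = np.zeros_like(t)
    rising = (t >= on) & (t < pk)
    out[rising] = amp * ((t[rising] - on) / (pk - on)) ** acc
    out[(t >= pk) & (t <= plateau_end)] = amp
    falling = (t > plateau_end) & (t < off)
    out[falling] = amp * (1.0 - ((t[falling] - plateau_end) / (off - plateau_end)) ** dec)
    return out


def aus_to_vector(aus: Iterable[int], catalog: ActionUnitCatalog | None = None) -> np.ndarray:
    """Binary catalog-ordered vector with ones at the given AU ids."""
    catalog = catalog or DEFAULT_CATALOG
    vec = np.zeros(catalog.size, dtype=np.uint8)
    for a in aus:
        vec[catalog.index(a)] = 1
    return vec


def vector_to_aus(vec: np.ndarray, catalog: ActionUnitCatalog | None = None) -> frozenset[int]:
    """AU ids at the nonzero positions of a catalog-ordered vector."""
    catalog = catalog or DEFAULT_CATALOG
    vec = np.asarray(vec)
    if vec.shape != (catalog.size,):
        raise ValueError(f"vector must have length {catalog.size}")
    return frozenset(int(catalog.ids[i]) for i in np.flatnonzero(vec))


def stimuli_to_params_frame(stimuli: Sequence[StimulusSpec]) -> pd.DataFrame:
    """Long-format export: one row per (trial, active AU) with 7 parameters."""
    rows = []
    for trial_id, stim in enumerate(stimuli):
        for au_id in sorted(stim.profiles):
            rows.append(
                {"trial_id": trial_id, "au_id": au_id}
                | dict(zip(PARAM_NAMES, stim.profiles[au_id].as_array()))
            )
    return pd.DataFrame(rows)


def time_course_frame(stimulus: StimulusSpec, fps: float = 30.0) -> pd.DataFrame:
    """Per-frame activation of every active AU at the given frame rate."""
    n_frames = int(np.floor(stimulus.duration * fps)) + 1
    t = np.arange(n_frames) / fps
    data = {"time": t}
    for au_id in sorted(stimulus.profiles):
        data[f"au_{au_id}"] = activation_curve(stimulus.profiles[au_id], t)
    return pd.DataFrame(data)
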