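"""Comparison of fitted expression models with production-study AU patterns.

Observational studies of people actually experiencing pain or orgasm
report which AUs appear on the face; each study contributes one binary AU
pattern.  Fitted models are classified as pain or orgasm by their nearest
pattern under the Hamming distance (computed on the full 42-dimensional
binary vectors, so absences count), the resulting confusion matrix is
tested with the 2x2 chi-square, and set algebra between the majority AU
sets of models and productions is summarized as a four-set Venn
partition.

The packaged default patterns are a *synthetic-consistent* fixture: real
per-study AU tables are not redistributable here, so the shipped 11 pain
and 3 orgasm patterns are constructed to reproduce the published
set-level structure (shared production AUs, pain-only production AUs,
model/production convergences).  Users supply their own JSON for real
per-study data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distinctiveness import ConfusionMatrix2x2
from .stimgen import DEFAULT_CATALOG, ActionUnitCatalog, aus_to_vector

SET_NAMES = ("model_pain", "model_orgasm", "prod_pain", "prod_orgasm")

#: Reference Western model-majority AU sets for the worked set-algebra
#: comparison: the AUs found in the majority of individual Western
#: observer models of each affect.  Together with the default production
#: fixture these reproduce the benchmark Venn structure (e.g. AU11 is
#: model-only for pain; AUs 2 and 5 are model-only for orgasm).
REFERENCE_MODEL_MAJORITY: dict[str, frozenset[int]] = {
    "pain": frozenset({4, 6, 9, 10, 11, 12, 20}),
    "orgasm": frozenset({2, 5, 25, 26, 27, 43}),
}


@dataclass(frozen=True)
class ProductionPattern:
    """AU pattern reported by one production study."""

    study_id: str
    affect: str
    au_set: frozenset[int]
    catalog: ActionUnitCatalog = field(default=DEFAULT_CATALOG, repr=False)

    def __post_init__(self) -> None:
        if self.affect not in ("pain", "orgasm"):
            raise ValueError("affect must be 'pain' or 'orgasm'")
        if not self.au_set:
            raise ValueError("AU set must not be empty")
        unknown = [a for a in self.au_set if a not in self.catalog]
        if unknown:
            raise ValueError(f"unknown AU ids {sorted(unknown)} in study {self.study_id}")

    @property
    def au_vector(self) -> np.ndarray:
        return aus_to_vector(self.au_set, self.catalog)


def _parse_patterns(data, catalog: ActionUnitCatalog) -> list[ProductionPattern]:
    patterns = []
    for entry in data:
        if "affect" not in entry:
            raise ValueError(f"pattern entry missing affect: {entry}")
        patterns.append(
            ProductionPattern(
                study_id=str(entry["study_id"]),
                affect=str(entry["affect"]),
                au_set=frozenset(int(a) for a in entry["aus"]),
                catalog=catalog,
            )
        )
    return patterns


def read_production_patterns(path, catalog: ActionUnitCatalog | None = None) -> list[ProductionPattern]:
    """Read production AU patterns from a JSON file.

    Format: ``[{"study_id": str, "affect": "pain"|"orgasm", "aus": [int]}]``.
    """
    with open(path) as fh:
        data = json.load(fh)
    return _parse_patterns(data, catalog or DEFAULT_CATALOG)


def default_production_patterns(catalog: ActionUnitCatalog | None = None) -> list[ProductionPattern]:
    """The packaged synthetic-consistent fixture: 11 pain + 3 orgasm patterns."""
    ref = resources.files("revcorrfaces.data").joinpath("production_patterns.json")
    data = json.loads(ref.read_text())
    return _parse_patterns(data, catalog or DEFAULT_CATALOG)


def write_production_patterns(patterns: Sequence[ProductionPattern], path) -> None:
    data = [
        {"study_id": p.study_id, "affect": p.affect, "aus": sorted(p.au_set)}
        for p in patterns
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def hamming_distance(u, v) -> int:
    """Number of positions at which two binary vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return int(np.sum(u != v))


def nearest_pattern_classify(
    models: Sequence,
    patterns: Sequence[ProductionPattern],
) -> tuple[pd.DataFrame, ConfusionMatrix2x2]:
    """Classify each model by its lowest-Hamming-distance pattern.

    Ties across affects are broken by the majority affect among all tied
    patterns; residual ties by the smaller mean distance to that
    affect's full pattern set; final residual ties go to "pain" and are
    flagged in the assignment table.  Returns the per-model assignment
    frame and the true-vs-assigned confusion matrix.
    """
    if not models or not patterns:
        raise ValueError("models and patterns must be non-empty")
    affects = {p.affect for p in patterns}
    if affects != {"pain", "orgasm"}:
        raise ValueError("need at least one pattern per affect")
    pat_vecs = np.vstack([p.au_vector for p in patterns])
    pat_affects = np.array([p.affect for p in patterns])
    rows = []
    for i, m in enumerate(models):
        vec = np.asarray(m.au_vector)
        dists = np.sum(pat_vecs != vec[None, :], axis=1)
        dmin = dists.min()
        tied = np.flatnonzero(dists == dmin)
        tied_affects = pat_affects[tied]
        tie_logged = False
        if len(set(tied_affects)) == 1:
            assigned = str(tied_affects[0])
        else:
            n_pain = int(np.sum(tied_affects == "pain"))
            n_org = len(tied_affects) - n_pain
            if n_pain != n_org:
                assigned = "pain" if n_pain > n_org else "orgasm"
            else:
                mean_d = {
                    aff: float(dists[pat_affects == aff].mean())
                    for aff in ("pain", "orgasm")
                }
                if mean_d["pain"] < mean_d["orgasm"]:
                    assigned = "pain"
                elif mean_d["orgasm"] < mean_d["pain"]:
                    assigned = "orgasm"
                else:
                    assigned = "pain"
                    tie_logged = True
        rows.append(
            {
                "model_id": getattr(m, "model_id", f"model_{i}"),
                "true_affect": getattr(m, "affect"),
                "assigned_affect": assigned,
                "min_distance": int(dmin),
                "nearest_study": patterns[int(tied[0])].study_id,
                "unresolved_tie": tie_logged,
            }
        )
    frame = pd.DataFrame(rows)
    counts = np.zeros((2, 2), dtype=int)
    for _, row in frame.iterrows():
        counts[
            0 if row["true_affect"] == "pain" else 1,
            0 if row["assigned_affect"] == "pain" else 1,
        ] += 1
    confusion = ConfusionMatrix2x2(counts, ("pain", "orgasm"), ("pain", "orgasm"))
    return frame, confusion


def majority_set(collections: Sequence[Iterable[int]]) -> frozenset[int]:
    """AUs present in strictly more than half of the given AU sets."""
    sets = [frozenset(c.au_set) if hasattr(c, "au_set") else frozenset(c) for c in collections]
    if not sets:
        raise ValueError("collection must not be empty")
    cutoff = len(sets) / 2.0
    all_aus = frozenset().union(*sets)
    return frozenset(a for a in all_aus if sum(a in s for s in sets) > cutoff)


@dataclass(frozen=True)
class VennPartition:
    """Exhaustive disjoint decomposition of four AU sets.

    ``regions`` maps each non-empty membership combination (a tuple of
    set names from :data:`SET_NAMES`) to the AUs belonging to exactly
    those sets; the 15 regions are pairwise disjoint and union to all
    AUs under consideration.
    """

    sets: dict[str, frozenset[int]]
    regions: dict[tuple[str, ...], frozenset[int]]

    def region(self, *names: str) -> frozenset[int]:
        """AUs in exactly the named sets and no others."""
        key = tuple(n for n in SET_NAMES if n in names)
        if len(key) != len(names):
            raise KeyError(f"set names must be among {SET_NAMES}")
        return self.regions.get(key, frozenset())

    def only(self, name: str) -> frozenset[int]:
        """AUs specific to one set."""
        return self.region(name)

    def intersection(self, *names: str) -> frozenset[int]:
        """Plain (non-exclusive) intersection of the named sets."""
        out = None
        for n in names:
            out = self.sets[n] if out is None else out & self.sets[n]
        return frozenset(out or frozenset())

    @property
    def shared_pain_orgasm_models(self) -> frozenset[int]:
        return self.intersection("model_pain", "model_orgasm")

    @property
    def shared_pain_orgasm_productions(self) -> frozenset[int]:
        return self.intersection("prod_pain", "prod_orgasm")

    @property
    def convergent_pain(self) -> frozenset[int]:
        return self.intersection("model_pain", "prod_pain")

    @property
    def convergent_orgasm(self) -> frozenset[int]:
        return self.intersection("model_orgasm", "prod_orgasm")


def venn_partition(
    model_pain: Iterable[int],
    model_orgasm: Iterable[int],
    prod_pain: Iterable[int],
    prod_orgasm: Iterable[int],
) -> VennPartition:
    """Decompose four AU sets into their 15 exclusive Venn regions."""
    sets = {
        "model_pain": frozenset(model_pain),
        "model_orgasm": frozenset(model_orgasm),
        "prod_pain": frozenset(prod_pain),
        "prod_orgasm": frozenset(prod_orgasm),
    }
    universe = frozenset().union(*sets.values())
    regions: dict[tuple[str, ...], frozenset[int]] = {}
    for r in range(1, 5):
        for combo in combinations(SET_NAMES, r):
            inside = frozenset(universe)
            for name in combo:
                inside &= sets[name]
            for name in SET_NAMES:
                if name not in combo:
                    inside -= sets[name]
            regions[combo] = inside
    return VennPartition(sets, regions)
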