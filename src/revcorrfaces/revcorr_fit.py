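"""Per-observer reverse-correlation model fitting.

From a trial log, the AUs composing an observer's representation of each
affect are found by correlating each AU's presence/absence across trials
with the binary response (pain = 0, orgasm = 1; "other" trials are
excluded).  Significant positive correlations (two-tailed p < .05) place
an AU in the orgasm model, significant negative ones in the pain model,
so the two models of one observer are disjoint by construction.  For each
significant AU, ordinary least squares then relates the seven temporal
parameters to the response (temporal coefficients) and to the 1-5
intensity rating (intensity gradient), and the mean profile over
high-intensity trials (ratings 4-5) summarizes the most salient dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .stimgen import (
    DEFAULT_CATALOG,
    PARAM_NAMES,
    ActionUnitCatalog,
    TemporalProfile,
    vector_to_aus,
)
from .synthetic_observer import ORGASM, OTHER, PAIN, ObserverLog

#: Intensity ratings counted as "high intensity" (inclusive band).
HIGH_INTENSITY_BAND = (4, 5)

#: Minimum trials for the per-AU regressions (7 parameters + 2).
MIN_REGRESSION_TRIALS = 9


@dataclass
class ExpressionModel:
    """One observer's fitted representation of one affect.

    ``au_vector`` is the 1 x n_aus binary significance vector;
    ``au_r``/``au_p`` hold the per-AU phi coefficients and p-values over
    all catalog AUs (NaN where the correlation is undefined).  The
    per-significant-AU regression results are ``None`` when too few
    qualifying trials were available (recorded in ``notes``).
    """

    observer_id: str
    culture: str
    affect: str
    au_vector: np.ndarray
    au_r: np.ndarray
    au_p: np.ndarray
    temporal_coefficients: dict[int, np.ndarray | None]
    intensity_gradient: dict[int, np.ndarray | None]
    high_intensity_profile: dict[int, TemporalProfile | None]
    notes: list[str] = field(default_factory=list)
    catalog: ActionUnitCatalog = field(default=DEFAULT_CATALOG, repr=False)

    @property
    def model_id(self) -> str:
        return f"{self.observer_id}_{self.affect}"

    @property
    def au_set(self) -> frozenset[int]:
        return vector_to_aus(self.au_vector, self.catalog)

    def to_dict(self) -> dict:
        ids = self.catalog.ids
        sig = sorted(self.au_set)
        return {
            "observer_id": self.observer_id,
            "culture": self.culture,
            "affect": self.affect,
            "significant_aus": sig,
            "r": {int(a): float(self.au_r[self.catalog.index(a)]) for a in ids
                  if np.isfinite(self.au_r[self.catalog.index(a)])},
            "p": {int(a): float(self.au_p[self.catalog.index(a)]) for a in ids
                  if np.isfinite(self.au_p[self.catalog.index(a)])},
            "temporal_coefficients": {
                a: None if v is None else [float(x) for x in v]
                for a, v in self.temporal_coefficients.items()
            },
            "intensity_gradient": {
                a: None if v is None else [float(x) for x in v]
                for a, v in self.intensity_gradient.items()
            },
            "high_intensity_profile": {
                a: None if p is None else dict(zip(PARAM_NAMES, p.as_array()))
                for a, p in self.high_intensity_profile.items()
            },
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, data: Mapping, catalog: ActionUnitCatalog | None = None) -> "ExpressionModel":
        catalog = catalog or DEFAULT_CATALOG
        n = catalog.size
        vec = np.zeros(n, dtype=np.uint8)
        for a in data["significant_aus"]:
            vec[catalog.index(a)] = 1
        r = np.full(n, np.nan)
        p = np.full(n, np.nan)
        for a, v in data.get("r", {}).items():
            r[catalog.index(int(a))] = v
        for a, v in data.get("p", {}).items():
            p[catalog.index(int(a))] = v
        return cls(
            observer_id=data["observer_id"],
            culture=data["culture"],
            affect=data["affect"],
            au_vector=vec,
            au_r=r,
            au_p=p,
            temporal_coefficients={
                int(a): None if v is None else np.asarray(v, float)
                for a, v in data.get("temporal_coefficients", {}).items()
            },
            intensity_gradient={
                int(a): None if v is None else np.asarray(v, float)
                for a, v in data.get("intensity_gradient", {}).items()
            },
            high_intensity_profile={
                int(a): None if v is None else TemporalProfile.from_array(
                    [v[k] for k in PARAM_NAMES]
                )
                for a, v in data.get("high_intensity_profile", {}).items()
            },
            notes=list(data.get("notes", [])),
            catalog=catalog,
        )


def phi_correlation(x, y) -> tuple[float, float]:
    """Pearson (phi) correlation between two binary vectors with p-value.

    The p-value is two-sided, from the t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.  Constant
    inputs are an error (zero variance), not a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("phi correlation undefined for a constant vector")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def _retained(log: ObserverLog) -> np.ndarray:
    keep = log.response != OTHER
    if not np.any(log.response == PAIN) or not np.any(log.response == ORGASM):
        raise ValueError("log must contain at least one pain and one orgasm response")
    if int(keep.sum()) < 3:
        raise ValueError("fewer than 3 usable (non-'other') trials")
    return keep


def fit_temporal(
    log: ObserverLog,
    au_id: int,
    min_trials: int = MIN_REGRESSION_TRIALS,
) -> np.ndarray:
    """OLS slopes of the binary response on the 7 temporal parameters.

    Fitted over retained (pain/orgasm) trials on which the AU is active;
    an intercept is included but only the 7 slopes are returned.
    """
    keep = _retained(log)
    j = log.catalog.index(au_id)
    rows = keep & (log.au[:, j] > 0)
    return _ols_slopes(log.params[rows, j, :], (log.response[rows] == ORGASM).astype(float),
                       min_trials)


def fit_intensity_gradient(
    log: ObserverLog,
    au_id: int,
    affect: str,
    min_trials: int = MIN_REGRESSION_TRIALS,
) -> np.ndarray:
    """OLS slopes of the intensity rating on the 7 temporal parameters.

    Fitted over trials with the matching affect response and the AU
    active.
    """
    code = {"pain": PAIN, "orgasm": ORGASM}[affect]
    j = log.catalog.index(au_id)
    rows = (log.response == code) & (log.au[:, j] > 0)
    if not rows.any():
        raise ValueError(f"no {affect} trials with AU {au_id} active")
    return _ols_slopes(log.params[rows, j, :], log.intensity[rows], min_trials)


def _ols_slopes(X: np.ndarray, y: np.ndarray, min_trials: int) -> np.ndarray:
    m = len(y)
    if m < min_trials:
        raise ValueError(f"need at least {min_trials} qualifying trials, got {m}")
    design = np.column_stack([np.ones(m), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:]


def high_intensity_profile(
    log: ObserverLog,
    au_id: int,
    affect: str,
    band: tuple[int, int] = HIGH_INTENSITY_BAND,
) -> TemporalProfile:
    """Mean temporal profile over high-intensity matching-affect trials.

    High intensity means a rating inside ``band`` (default 4-5).  The
    element-wise mean of valid profiles satisfies the profile invariants,
    so the result is returned unclamped.
    """
    code = {"pain": PAIN, "orgasm": ORGASM}[affect]
    j = log.catalog.index(au_id)
    lo, hi = band
    rows = (
        (log.response == code)
        & (log.au[:, j] > 0)
        & (log.intensity >= lo)
        & (log.intensity <= hi)
    )
    if not rows.any():
        raise ValueError(
            f"no {affect} trials with AU {au_id} active and intensity in {band}; "
            "consider widening the intensity band"
        )
    return TemporalProfile.from_array(log.params[rows, j, :].mean(axis=0))


def fit_models(
    log: ObserverLog,
    alpha: float = 0.05,
    min_trials: int = MIN_REGRESSION_TRIALS,
    band: tuple[int, int] = HIGH_INTENSITY_BAND,
) -> tuple[ExpressionModel, ExpressionModel]:
    """Fit the (pain, orgasm) expression-model pair from one trial log.

    "Other" trials are excluded; the response is coded pain = 0,
    orgasm = 1; each AU's presence is phi-correlated with the response.
    Significant AUs (two-tailed p < ``alpha``) with r > 0 form the
    orgasm model, those with r < 0 the pain model.  AUs whose presence
    is constant over the retained trials cannot be assessed and are left
    non-significant (flagged in the model notes).  Per-AU regressions
    that lack ``min_trials`` qualifying trials yield ``None`` entries.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    keep = _retained(log)
    y = (log.response[keep] == ORGASM).astype(float)
    A = log.au[keep].astype(float)
    n_aus = log.catalog.size

    r = np.full(n_aus, np.nan)
    p = np.full(n_aus, np.nan)
    constant: list[int] = []
    for j in range(n_aus):
        col = A[:, j]
        if col.std() == 0:
            constant.append(int(log.catalog.ids[j]))
            continue
        r[j], p[j] = phi_correlation(col, y)

    sig = (p < alpha) & np.isfinite(r)
    models = []
    for affect, mask in (("pain", sig & (r < 0)), ("orgasm", sig & (r > 0))):
        vec = mask.astype(np.uint8)
        notes = [
            "other trials excluded from the correlation",
            "temporal regression pooled over all retained trials where the AU is active",
        ]
        if constant:
            notes.append(f"constant-presence AUs skipped: {constant}")
        temporal: dict[int, np.ndarray | None] = {}
        gradient: dict[int, np.ndarray | None] = {}
        hi_profile: dict[int, TemporalProfile | None] = {}
        for j in np.flatnonzero(mask):
            au_id = int(log.catalog.ids[j])
            for target, fn in (
                (temporal, lambda: fit_temporal(log, au_id, min_trials)),
                (gradient, lambda: fit_intensity_gradient(log, au_id, affect, min_trials)),
                (hi_profile, lambda: high_intensity_profile(log, au_id, affect, band)),
            ):
                try:
                    target[au_id] = fn()
                except ValueError as err:
                    target[au_id] = None
                    notes.append(f"AU {au_id}: {err}")
        models.append(
            ExpressionModel(
                observer_id=log.observer_id,
                culture=log.culture,
                affect=affect,
                au_vector=vec,
                au_r=r.copy(),
                au_p=p.copy(),
                temporal_coefficients=temporal,
                intensity_gradient=gradient,
                high_intensity_profile=hi_profile,
                notes=notes,
                catalog=log.catalog,
            )
        )
    pain_model, orgasm_model = models
    return pain_model, orgasm_model


def models_to_matrix(models) -> np.ndarray:
    """Stack fitted models' binary AU vectors into an (n_models, n_aus) array."""
    if not models:
        raise ValueError("model list must not be empty")
    return np.vstack([np.asarray(m.au_vector, dtype=np.uint8) for m in models])


def fit_cohort(logs) -> list[ExpressionModel]:
    """Fit model pairs for every log, skipping degenerate logs with a warning."""
    out: list[ExpressionModel] = []
    for log in logs:
        try:
            out.extend(fit_models(log))
        except ValueError as err:
            warnings.warn(f"observer {log.observer_id}: {err}; skipped", stacklevel=2)
    return out
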