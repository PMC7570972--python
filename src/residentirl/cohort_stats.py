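"""Cohort-level analysis of learned preference vectors.

Given per-(home, window) preference vectors θ, this module quantifies
behavioral change and difference:

* within a home over time — per-feature paired t-tests between day-matched θ
  values of an early and a late window;
* between homes within a diagnosis group — per-feature one-way ANOVA with
  homes as groups, over month-level θ samples;
* between diagnosis groups — the same ANOVA with diagnosis labels as groups;
* diagnosis classification — leave-one-out random forest (100 trees, entropy
  splits) over month-level θ samples, with cognitive decline as the positive
  class, plus impurity-decrease feature importances.

Reports carry the per-feature statistic and p-value, a significance flag at
α = 0.05 (no multiple-testing correction by default, with an optional
Benjamini–Hochberg adjustment), and the arithmetic means of the p-values over
the duration features and over all features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from .features import DURATION_FEATURES, FEATURE_NAMES, N_FEATURES
from .pipeline import HomeData
from .relent_irl import IrlConfig, bernstein_epsilon, fit

__all__ = [
    "PreferenceSample",
    "ComparisonReport",
    "ClassificationResult",
    "learn_window_vectors",
    "within_home_change",
    "between_home_anova",
    "between_group_anova",
    "classify_diagnosis",
]

ALPHA = 0.05


@dataclass
class PreferenceSample:
    """One fitted preference vector: a (home, window) analysis unit."""

    home_id: str
    window_id: int
    theta: np.ndarray
    label: str = "healthy"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (N_FEATURES,):
            raise ValueError(f"theta must have length {N_FEATURES}")


@dataclass
class ComparisonReport:
    """Per-feature test results plus the summary means of the p-values."""

    mode: str
    statistic: np.ndarray
    p_values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    alpha: float = ALPHA
    bh_adjusted: bool = False

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def duration_mean_p(self) -> float:
        idx = [i for i, n in enumerate(self.feature_names) if n in DURATION_FEATURES]
        return float(np.mean(self.p_values[idx]))

    @property
    def overall_mean_p(self) -> float:
        return float(np.mean(self.p_values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "statistic": self.statistic,
                "p_value": self.p_values,
                "significant": self.significant,
            }
        )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def learn_window_vectors(
    homes: dict[str, HomeData],
    labels: Optional[dict[str, str]] = None,
    window: str = "month",
    irl_config: Optional[IrlConfig] = None,
) -> list[PreferenceSample]:
    """Fit one θ per (home, window).

    ``window="month"`` groups each home's daily trajectories into consecutive
    30-day blocks starting at the home's first day; incomplete trailing blocks
    are dropped.  ``window="day"`` fits one θ per daily trajectory.  Windows
    with no trajectories are skipped with a warning.
    """
    if window not in ("day", "month"):
        raise ValueError("window must be 'day' or 'month'")
    labels = labels or {}
    samples: list[PreferenceSample] = []
    for home_id, home in homes.items():
        label = labels.get(home_id, "healthy")
        if not home.days:
            warnings.warn(f"home {home_id} has no trajectories; skipped")
            continue
        home_config = irl_config
        if window == "day":
            groups = [(i, [d]) for i, d in enumerate(home.days)]
            # a single day cannot calibrate its own constraint slack; pool the
            # home's day-to-day variability instead so day-level fits are
            # informative rather than collapsing to the initialization
            if home_config is None:
                home_config = IrlConfig()
            if isinstance(home_config.epsilon, str) and home_config.epsilon == "auto":
                pooled = np.vstack([d.phi for d in home.days])
                home_config = replace(
                    home_config, epsilon=bernstein_epsilon(pooled)
                )
        else:
            first = home.days[0].trajectory.date
            span = (home.days[-1].trajectory.date - first).days + 1
            n_windows = span // 30
            buckets: dict[int, list] = {}
            for d in home.days:
                w = (d.trajectory.date - first).days // 30
                if w < n_windows:
                    buckets.setdefault(w, []).append(d)
            groups = sorted(buckets.items())
            for w in range(n_windows):
                if w not in buckets:
                    warnings.warn(f"home {home_id} window {w} has no trajectories")
        for window_id, days in groups:
            result = fit(days, home.mdp, home_config)
            samples.append(
                PreferenceSample(
                    home_id=home_id, window_id=window_id, theta=result.theta, label=label
                )
            )
    return samples


def _theta_matrix(samples: Sequence[PreferenceSample]) -> np.ndarray:
    return np.vstack([s.theta for s in samples])


def within_home_change(
    daily_samples: Sequence[PreferenceSample],
    first_window_days: int = 60,
    last_window_days: int = 60,
    bh: bool = False,
) -> ComparisonReport:
    """Paired t-tests between day-level θ of the first and last windows.

    The first ``first_window_days`` samples are paired by day index with the
    last ``last_window_days`` samples (truncated to the shorter window).
    Identical windows give t = 0, p = 1 per feature.
    """
    samples = sorted(daily_samples, key=lambda s: s.window_id)
    k = min(first_window_days, last_window_days, len(samples) // 2)
    if k < 2:
        raise ValueError("need at least 2 day pairs in each window")
    first = _theta_matrix(samples[:k])
    last = _theta_matrix(samples[-k:])
    stat = np.zeros(N_FEATURES)
    p = np.ones(N_FEATURES)
    for i in range(N_FEATURES):
        diff = last[:, i] - first[:, i]
        if np.allclose(diff, 0.0):
            stat[i], p[i] = 0.0, 1.0
        else:
            res = sps.ttest_rel(first[:, i], last[:, i])
            stat[i], p[i] = res.statistic, res.pvalue
    if bh:
        p = _bh_adjust(p)
    return ComparisonReport(mode="within_home", statistic=stat, p_values=p, bh_adjusted=bh)


def _anova_by_group(
    samples: Sequence[PreferenceSample], group_of, mode: str, bh: bool
) -> ComparisonReport:
    groups: dict[str, list[PreferenceSample]] = {}
    for s in samples:
        groups.setdefault(group_of(s), []).append(s)
    kept = {}
    for g, ss in groups.items():
        if len(ss) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 samples; excluded")
            continue
        kept[g] = _theta_matrix(ss)
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples each")
    stat = np.zeros(N_FEATURES)
    p = np.ones(N_FEATURES)
    for i in range(N_FEATURES):
        cols = [m[:, i] for m in kept.values()]
        grand = np.concatenate(cols)
        if np.allclose(grand, grand[0]):
            stat[i], p[i] = 0.0, 1.0
            continue
        means = np.array([c.mean() for c in cols])
        if np.allclose(means, means[0]) and all(np.allclose(c, c.mean()) for c in cols):
            stat[i], p[i] = 0.0, 1.0
            continue
        res = sps.f_oneway(*cols)
        stat[i], p[i] = res.statistic, res.pvalue
    if bh:
        p = _bh_adjust(p)
    return ComparisonReport(mode=mode, statistic=stat, p_values=p, bh_adjusted=bh)


def between_home_anova(
    monthly_samples: Sequence[PreferenceSample], bh: bool = False
) -> ComparisonReport:
    """Per-feature one-way ANOVA with homes as groups (within one diagnosis group)."""
    return _anova_by_group(monthly_samples, lambda s: s.home_id, "between_home", bh)


def between_group_anova(
    monthly_samples: Sequence[PreferenceSample], bh: bool = False
) -> ComparisonReport:
    """Per-feature one-way ANOVA with diagnosis labels as groups."""
    return _anova_by_group(monthly_samples, lambda s: s.label, "between_group", bh)


@dataclass
class ClassificationResult:
    predictions: pd.DataFrame
    accuracy: float
    precision: float
    recall: float
    f1: float
    importances: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def importance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.feature_names), "importance": self.importances}
        ).sort_values("importance", ascending=False, ignore_index=True)


def classify_diagnosis(
    samples: Sequence[PreferenceSample],
    seed: int = 42,
    by_home: bool = False,
    n_trees: int = 100,
) -> ClassificationResult:
    """Leave-one-out diagnosis prediction from preference vectors.

    A random forest (``n_trees`` trees, entropy split criterion) is refit with
    each sample (or, with ``by_home=True``, each home — avoiding home-identity
    leakage) held out in turn.  Metrics take cognitive decline as the positive
    class; importances are the mean impurity-decrease shares over the fits,
    renormalized to sum to 1.
    """
    X = _theta_matrix(samples)
    y = np.array([s.label for s in samples])
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both diagnosis classes")
    if min(np.sum(y == lab) for lab in np.unique(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    if by_home:
        fold_ids = np.array([s.home_id for s in samples])
    else:
        fold_ids = np.arange(len(samples)).astype(str)
    preds = np.empty(len(samples), dtype=object)
    importances = np.zeros(N_FEATURES)
    n_fits = 0
    for fold in np.unique(fold_ids):
        test = fold_ids == fold
        clf = RandomForestClassifier(
            n_estimators=n_trees, criterion="entropy", random_state=seed
        )
        clf.fit(X[~test], y[~test])
        preds[test] = clf.predict(X[test])
        importances += clf.feature_importances_
        n_fits += 1
    importances /= n_fits
    total = importances.sum()
    if total > 0:
        importances = importances / total
    preds = preds.astype(str)
    frame = pd.DataFrame(
        {
            "home_id": [s.home_id for s in samples],
            "window_id": [s.window_id for s in samples],
            "label": y,
            "predicted": preds,
        }
    )
    return ClassificationResult(
        predictions=frame,
        accuracy=float(accuracy_score(y, preds)),
        precision=float(precision_score(y, preds, pos_label="decline", zero_division=0)),
        recall=float(recall_score(y, preds, pos_label="decline", zero_division=0)),
        f1=float(f1_score(y, preds, pos_label="decline", zero_division=0)),
        importances=importances,
    )
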