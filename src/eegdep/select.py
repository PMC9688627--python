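"""Data-driven selection of time-window span, electrode region and features.

Three nested sweeps, all scored by a standardized logistic-regression
baseline under stratified k-fold cross-validation of window-level feature
vectors:

1. span sweep (1..17 s in steps of 2) with the two baseline features
   (Higuchi, SampEnt) averaged over all channels; the chosen span is the
   smallest one whose fold scores are not significantly below any larger
   span (paired t-test);
2. region sweep over every fully-covered region of the electrode association
   table; the chosen region has the highest mean accuracy, with statistical
   ties broken toward fewer electrodes, then lexicographic name;
3. mutual-information feature ranking and cumulative combinations
   COMB0..COMB{n-1}; the full set is kept unless a shorter prefix is
   significantly better.

Because one-second windows nest across spans (the span-s crop is the first s
windows of the longest crop) and channel subsets only change an average, all
sweeps run off a single per-channel feature table computed once per cohort.

Cross-validation splits at the window level by default, which mirrors
vector-level splitting but lets windows of one subject appear in both train
and test folds; the optimistic bias this can introduce is the reason
``SelectionConfig.subject_level`` exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_ORDER, FeatureParams, channel_feature_table
from .io import Recording
from .montage import RegionMap, load_region_map
from .preprocess import crop_and_resample, filter_chain, vectorize

__all__ = [
    "CVResult",
    "SelectionConfig",
    "SelectionReport",
    "baseline_estimator",
    "cohort_feature_cache",
    "sweep_spans",
    "choose_span",
    "sweep_regions",
    "choose_region",
    "rank_features_mi",
    "greedy_combinations",
    "run_selection",
]


@dataclass
class CVResult:
    """Per-fold accuracies for one evaluated unit (span/region/comb/classifier)."""

    kind: str
    unit: object
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, np.float64)

    @property
    def unit_id(self) -> str:
        return f"{self.kind}:{self.unit}"

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1)) if self.scores.size > 1 else 0.0


@dataclass
class SelectionConfig:
    """Sweep grid, CV setup and significance level for the selection chain."""

    spans: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17)
    k_folds: int = 10
    baseline_features: tuple[str, str] = ("Higuchi", "SampEnt")
    alpha: float = 0.05
    seed: int = 0
    subject_level: bool = False
    feature_params: FeatureParams = field(default_factory=FeatureParams)

    def __post_init__(self):
        self.spans = tuple(self.spans)
        self.baseline_features = tuple(self.baseline_features)
        if list(self.spans) != sorted(set(self.spans)):
            raise ValueError("spans must be strictly increasing")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if isinstance(self.feature_params, dict):
            self.feature_params = FeatureParams(**self.feature_params)


def baseline_estimator(seed: int = 0) -> Pipeline:
    """The standardized logistic-regression baseline (scaler fit per fold)."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(max_iter=1000, random_state=seed)),
        ]
    )


def _cv_scores(X, y, config: SelectionConfig, groups=None) -> np.ndarray:
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("stratified CV needs both classes present")
    if config.subject_level:
        cv = StratifiedGroupKFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        return cross_val_score(
            baseline_estimator(config.seed), X, y, cv=cv, groups=groups
        )
    cv = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed
    )
    return cross_val_score(baseline_estimator(config.seed), X, y, cv=cv)


# ---------------------------------------------------------------------------
# Feature cache
# ---------------------------------------------------------------------------

def cohort_feature_cache(
    cohort: list[Recording],
    span: float,
    features: Iterable[str],
    params: FeatureParams | None = None,
    filter: bool = True,
) -> pd.DataFrame:
    """Per-channel feature table for all windows of the span-s crop.

    Columns: subject_id, window_index, channel, feature, value, y. Computed
    once at the largest span; every sweep then reduces to row filtering and
    channel averaging.
    """
    frames = []
    for rec in cohort:
        prepped = filter_chain(rec) if filter else rec
        windows = vectorize(crop_and_resample(prepped, span))
        frames.append(channel_feature_table(windows, features=features, params=params))
    return pd.concat(frames, ignore_index=True)


def _matrix_from_cache(
    cache: pd.DataFrame,
    n_windows: int,
    channels: Iterable[str] | None,
    features: Iterable[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, subject groups) with channel-averaged features per window."""
    feats = list(features)
    df = cache[cache["window_index"] < n_windows]
    if channels is not None:
        wanted = {c.lower() for c in channels}
        df = df[df["channel"].str.lower().isin(wanted)]
        if df.empty:
            raise ValueError(f"no cached channels match {sorted(wanted)}")
    wide = (
        df.groupby(["subject_id", "window_index", "feature"], sort=True)["value"]
        .mean()
        .unstack("feature")[feats]
    )
    labels = df.groupby(["subject_id", "window_index"], sort=True)["y"].first()
    X = wide.to_numpy()
    y = labels.to_numpy()
    groups = wide.index.get_level_values("subject_id").to_numpy()
    return X, y, groups


# ---------------------------------------------------------------------------
# Span sweep
# ---------------------------------------------------------------------------

def sweep_spans(
    cohort: list[Recording],
    config: SelectionConfig | None = None,
    cache: pd.DataFrame | None = None,
    filter: bool = True,
) -> list[CVResult]:
    """Baseline CV accuracy for each candidate span (all channels averaged)."""
    config = config or SelectionConfig()
    if cache is None:
        cache = cohort_feature_cache(
            cohort,
            max(config.spans),
            config.baseline_features,
            config.feature_params,
            filter=filter,
        )
    results = []
    for span in config.spans:
        X, y, groups = _matrix_from_cache(
            cache, int(span), None, config.baseline_features
        )
        scores = _cv_scores(X, y, config, groups)
        results.append(CVResult(kind="span", unit=int(span), scores=scores))
    return results


def _significantly_lower(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Paired t-test verdict for 'a scores significantly below b scores'.

    A zero-variance difference is a tie when it is exactly zero and decisive
    (beyond any significance level) when it is a constant offset.
    """
    diff = a - b
    if np.std(diff) == 0:
        return float(np.mean(diff)) < 0.0
    p = stats.ttest_rel(a, b).pvalue
    return bool(p < alpha and np.mean(diff) < 0.0)


def choose_span(results: list[CVResult], alpha: float = 0.05) -> int:
    """Smallest span not significantly worse than any larger span.

    'Significantly worse' means a paired t-test on fold scores with
    p < alpha and a lower mean. Ties (including zero-variance differences)
    break toward the smaller span.
    """
    if len(results) < 2:
        raise ValueError("need at least two span results")
    ordered = sorted(results, key=lambda r: r.unit)
    for i, cand in enumerate(ordered):
        inferior = False
        for larger in ordered[i + 1 :]:
            if _significantly_lower(cand.scores, larger.scores, alpha):
                inferior = True
                break
        if not inferior:
            return int(cand.unit)
    return int(ordered[-1].unit)


# ---------------------------------------------------------------------------
# Region sweep
# ---------------------------------------------------------------------------

def sweep_regions(
    cohort: list[Recording],
    span: int,
    region_map: RegionMap | None = None,
    config: SelectionConfig | None = None,
    cache: pd.DataFrame | None = None,
    filter: bool = True,
) -> list[CVResult]:
    """Baseline CV accuracy per fully-covered region at the chosen span."""
    config = config or SelectionConfig()
    region_map = region_map or load_region_map()
    montage = cohort[0].channel_names
    usable = region_map.usable_regions(montage)
    if not usable:
        raise ValueError(
            f"no region of the association table is fully covered by montage {montage}"
        )
    if cache is None:
        cache = cohort_feature_cache(
            cohort, span, config.baseline_features, config.feature_params, filter=filter
        )
    results = []
    for region in usable:
        X, y, groups = _matrix_from_cache(
            cache, int(span), region_map.electrodes_for(region), config.baseline_features
        )
        scores = _cv_scores(X, y, config, groups)
        results.append(CVResult(kind="region", unit=region, scores=scores))
    return results


def choose_region(
    results: list[CVResult],
    alpha: float = 0.05,
    region_map: RegionMap | None = None,
) -> str:
    """Highest-mean region; statistical ties prefer fewer electrodes, then name."""
    if not results:
        raise ValueError("no region results")
    region_map = region_map or load_region_map()
    ordered = sorted(results, key=lambda r: -r.mean)
    top = ordered[0]
    candidates = [top]
    for other in ordered[1:]:
        if not _significantly_lower(other.scores, top.scores, alpha):
            candidates.append(other)
    candidates.sort(
        key=lambda r: (len(region_map.electrodes_for(str(r.unit))), str(r.unit))
    )
    return str(candidates[0].unit)


# ---------------------------------------------------------------------------
# Feature ranking and combinations
# ---------------------------------------------------------------------------

def rank_features_mi(
    X, y, feature_names: Iterable[str] = FEATURE_ORDER, seed: int = 0
) -> list[tuple[str, float]]:
    """Features sorted by decreasing mutual information with the class label.

    k-nearest-neighbor MI estimate for continuous features against a discrete
    target; deterministic for a fixed seed, and invariant to the column order
    of ``X`` (ties break on the feature name).
    """
    from sklearn.feature_selection import mutual_info_classif

    names = list(feature_names)
    X = np.asarray(X, np.float64)
    if X.shape[1] != len(names):
        raise ValueError("feature_names length must match X columns")
    if np.unique(np.asarray(y)).size < 2:
        raise ValueError("need at least two distinct labels")
    mi = mutual_info_classif(X, y, random_state=seed)
    order = sorted(zip(names, mi.tolist()), key=lambda kv: (-kv[1], kv[0]))
    return order


def greedy_combinations(
    ranked: list[tuple[str, float]],
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Iterable[str],
    config: SelectionConfig | None = None,
    groups=None,
) -> tuple[list[CVResult], int]:
    """Evaluate cumulative prefixes COMB0..COMB{n-1} of the MI ranking.

    Returns all prefix CVResults and the index of the selected combination:
    the full set, unless some shorter prefix is significantly *better* than
    it (paired t-test at ``config.alpha``).
    """
    config = config or SelectionConfig()
    names = list(feature_names)
    X = np.asarray(X, np.float64)
    results = []
    for i in range(len(ranked)):
        prefix = [name for name, _ in ranked[: i + 1]]
        cols = [names.index(f) for f in prefix]
        scores = _cv_scores(X[:, cols], y, config, groups)
        results.append(CVResult(kind="combination", unit=f"COMB{i}", scores=scores))
    full = results[-1]
    selected = len(results) - 1
    for i, res in enumerate(results[:-1]):
        if _significantly_lower(full.scores, res.scores, config.alpha):
            selected = i
            break
    return results, selected


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Outcome of the three selection procedures, JSON-serializable."""

    span: int
    region: str
    electrodes: list[str]
    ranked_features: list[tuple[str, float]]
    combination: str
    combination_features: list[str]
    span_table: dict
    region_table: dict
    combination_table: dict
    k_folds: int
    alpha: float
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionReport":
        data = json.loads(Path(path).read_text())
        data["ranked_features"] = [tuple(kv) for kv in data["ranked_features"]]
        return cls(**data)


def _table(results: list[CVResult]) -> dict:
    return {
        str(r.unit): {"mean": r.mean, "sd": r.sd, "scores": r.scores.tolist()}
        for r in results
    }


def run_selection(
    cohort: list[Recording],
    config: SelectionConfig | None = None,
    region_map: RegionMap | None = None,
    filter: bool = True,
) -> SelectionReport:
    """Run span -> region -> feature-combination selection on a cohort."""
    config = config or SelectionConfig()
    region_map = region_map or load_region_map()
    prepped = [filter_chain(r) for r in cohort] if filter else list(cohort)

    baseline_cache = cohort_feature_cache(
        prepped,
        max(config.spans),
        config.baseline_features,
        config.feature_params,
        filter=False,
    )
    span_results = sweep_spans(prepped, config, cache=baseline_cache)
    span = choose_span(span_results, config.alpha)

    region_results = sweep_regions(
        prepped, span, region_map, config, cache=baseline_cache
    )
    region = choose_region(region_results, config.alpha, region_map)
    electrodes = region_map.electrodes_for(region)

    montage = {c.lower() for c in prepped[0].channel_names}
    present = [e for e in electrodes if e.lower() in montage]
    full_cache = cohort_feature_cache(
        [rec.pick(present) for rec in prepped],
        span,
        FEATURE_ORDER,
        config.feature_params,
        filter=False,
    )
    X, y, groups = _matrix_from_cache(full_cache, span, None, FEATURE_ORDER)
    ranked = rank_features_mi(X, y, FEATURE_ORDER, seed=config.seed)
    comb_results, comb_idx = greedy_combinations(
        ranked, X, y, FEATURE_ORDER, config, groups
    )

    return SelectionReport(
        span=span,
        region=region,
        electrodes=list(electrodes),
        ranked_features=ranked,
        combination=f"COMB{comb_idx}",
        combination_features=[name for name, _ in ranked[: comb_idx + 1]],
        span_table=_table(span_results),
        region_table=_table(region_results),
        combination_table=_table(comb_results),
        k_folds=config.k_folds,
        alpha=config.alpha,
        seed=config.seed,
    )
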