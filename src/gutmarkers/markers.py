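"""Random-forest marker selection with a cross-validation error curve.

The discovery procedure is two-stage. First, features passing the Wilcoxon
screen are ranked once by random-forest permutation importance (mean
decrease in accuracy). Second, for nested prefixes of that ranking
(sizes 1..K) the held-out misclassification rate is measured by repeated
stratified k-fold cross-validation (default: five trials of fivefold). The
optimal marker set is the smallest prefix whose mean error is below
``min(mean error) + SD at the argmin`` — the classical "minimum error plus
one standard deviation" rule of error-curve feature selection.

Because the ranking is computed once on the full discovery cohort, the
curve's error estimates are optimistic (selection leakage); that is the
procedure being reproduced, and an honest mode that re-ranks features
inside every training fold is available via ``rank_within_folds=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .diffabund import wilcoxon_screen
from .tables import OtuTable, SampleMetadata, relative_abundance

__all__ = [
    "CvErrorCurve",
    "MarkerSet",
    "MarkerDiscoveryConfig",
    "rank_features_by_importance",
    "cv_error_curve",
    "select_optimal_markers",
    "discover_markers",
]


@dataclass
class CvErrorCurve:
    """Cross-validation error as a function of the number of top features.

    ``errors`` has shape (n_trials, n_feature_counts); ``mean_error`` and
    ``sd_error`` are the per-count mean and SD across trials.
    """

    feature_counts: np.ndarray
    errors: np.ndarray

    def __post_init__(self) -> None:
        fc = np.asarray(self.feature_counts, dtype=int)
        err = np.asarray(self.errors, dtype=float)
        if err.ndim != 2 or err.shape[1] != fc.size:
            raise ValueError("errors must be trials x feature_counts")
        if np.any(np.diff(fc) <= 0):
            raise ValueError("feature_counts must be strictly increasing")
        if err.size and (err.min() < 0 or err.max() > 1):
            raise ValueError("errors must lie in [0, 1]")
        self.feature_counts = fc
        self.errors = err

    @property
    def mean_error(self) -> np.ndarray:
        return self.errors.mean(axis=0)

    @property
    def sd_error(self) -> np.ndarray:
        # ddof=1 across trials; a single trial has SD 0 by convention
        if self.errors.shape[0] < 2:
            return np.zeros(self.errors.shape[1])
        return self.errors.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_features": self.feature_counts,
            "mean_error": self.mean_error,
            "sd_error": self.sd_error,
            **{f"trial_{t + 1}": self.errors[t] for t in range(self.errors.shape[0])},
        })


@dataclass
class MarkerSet:
    """The selected markers plus the audit trail of the selection rule."""

    ranked_features: list[str]  # full importance ranking
    chosen_size: int
    min_error: float
    sd_at_min: float
    cutoff: float
    candidate_sizes: list[int]

    @property
    def markers(self) -> list[str]:
        return self.ranked_features[: self.chosen_size]

    def to_dict(self) -> dict:
        return {
            "markers": self.markers,
            "ranked_features": self.ranked_features,
            "chosen_size": self.chosen_size,
            "min_error": self.min_error,
            "sd_at_min": self.sd_at_min,
            "cutoff": self.cutoff,
            "candidate_sizes": self.candidate_sizes,
        }


def rank_features_by_importance(
    abund: pd.DataFrame,
    groups,
    n_trees: int = 500,
    seed: int = 0,
    n_repeats: int = 10,
) -> list[str]:
    """Rank features by random-forest permutation importance, descending.

    A forest is fit on all features; importance is the mean decrease in
    accuracy over ``n_repeats`` permutations of each column. Ties break by
    column order; zero-variance features are forced to the end.
    """
    groups = np.asarray(groups)
    if len(set(groups)) < 2:
        raise ValueError("need 2 classes to rank features")
    if abund.shape[1] < 2:
        raise ValueError("need at least 2 features")
    x = np.asarray(abund, dtype=float)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(x, groups)
    imp = permutation_importance(
        forest, x, groups, n_repeats=n_repeats, random_state=seed,
        scoring="accuracy",
    ).importances_mean
    constant = np.ptp(x, axis=0) == 0
    # stable sort on (constant last, importance descending, column order)
    order = np.lexsort((np.arange(len(imp)), -imp, constant))
    return [abund.columns[i] for i in order]


def cv_error_curve(
    abund: pd.DataFrame,
    groups,
    ranked: list[str],
    n_trials: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    rank_within_folds: bool = False,
) -> CvErrorCurve:
    """Repeated stratified k-fold error for nested prefixes of the ranking.

    For every trial a fresh fold partition is drawn; for each prefix size the
    error is the misclassification rate over pooled held-out predictions.
    With ``rank_within_folds`` the feature ranking is recomputed on each
    training fold (leakage-free mode).
    """
    if not ranked:
        raise ValueError("ranking must be non-empty")
    groups = np.asarray(groups)
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest group has {counts.min()} samples < n_folds={n_folds}; "
            "reduce n_folds"
        )
    x_full = abund[ranked].to_numpy(dtype=float)
    sizes = np.arange(1, len(ranked) + 1)
    errors = np.empty((n_trials, sizes.size))
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_trials)]
    for t, ts in enumerate(trial_seeds):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=ts)
        folds = list(skf.split(x_full, groups))
        fold_rankings = []
        for f, (tr, _) in enumerate(folds):
            if rank_within_folds:
                order = rank_features_by_importance(
                    abund[ranked].iloc[tr], groups[tr],
                    n_trees=n_trees, seed=ts + f,
                )
                fold_rankings.append([ranked.index(r) for r in order])
            else:
                fold_rankings.append(list(range(len(ranked))))
        for k_idx, k in enumerate(sizes):
            wrong = 0
            for f, (tr, te) in enumerate(folds):
                cols = fold_rankings[f][:k]
                clf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=ts + 1000 * f,
                )
                clf.fit(x_full[np.ix_(tr, cols)], groups[tr])
                pred = clf.predict(x_full[np.ix_(te, cols)])
                wrong += int((pred != groups[te]).sum())
            errors[t, k_idx] = wrong / len(groups)
    return CvErrorCurve(sizes, errors)


def select_optimal_markers(curve: CvErrorCurve, ranked: list[str]) -> MarkerSet:
    """Apply the min-error-plus-SD rule to the error curve.

    The cutoff is the minimum mean error plus the across-trial SD at that
    point (ties at the minimum resolve to the smallest size). Candidate
    sizes are those with mean error strictly below the cutoff; when the SD
    is zero the comparison relaxes to <= so the minimum itself qualifies.
    The chosen set is the smallest candidate prefix.
    """
    mean = curve.mean_error
    sd = curve.sd_error
    if mean.size == 0:
        raise ValueError("empty error curve")
    argmin = int(np.argmin(mean))  # np.argmin takes the first (smallest size)
    min_error = float(mean[argmin])
    sd_at_min = float(sd[argmin])
    cutoff = min_error + sd_at_min
    if sd_at_min == 0:
        candidates = np.flatnonzero(mean <= cutoff)
    else:
        candidates = np.flatnonzero(mean < cutoff)
    candidate_sizes = [int(curve.feature_counts[i]) for i in candidates]
    chosen = min(candidate_sizes)
    return MarkerSet(
        ranked_features=list(ranked),
        chosen_size=chosen,
        min_error=min_error,
        sd_at_min=sd_at_min,
        cutoff=float(cutoff),
        candidate_sizes=candidate_sizes,
    )


@dataclass
class MarkerDiscoveryConfig:
    """End-to-end marker-discovery settings."""

    screen_alpha: float = 0.05
    n_trees: int = 500
    n_trials: int = 5
    n_folds: int = 5
    seed: int = 0
    rank_within_folds: bool = False
    max_screened: int | None = None  # cap on screened features entering the curve

    audit: dict = field(default_factory=dict, repr=False)


def discover_markers(
    table: OtuTable,
    meta: SampleMetadata,
    config: MarkerDiscoveryConfig | None = None,
) -> MarkerSet:
    """Full discovery pipeline on one labeled cohort.

    relative abundance -> Wilcoxon screen -> importance ranking ->
    CV error curve -> min-error-plus-SD selection. The intermediate results
    (screen table, ranking, curve) are stored on ``config.audit``.
    """
    config = config or MarkerDiscoveryConfig()
    abund = relative_abundance(table)
    groups = meta.groups_for(table.sample_ids)
    screen = wilcoxon_screen(abund, groups, alpha=config.screen_alpha)
    screened = list(screen.index[screen["selected"]])
    if not screened:
        raise ValueError(
            f"Wilcoxon screen selected no features at alpha={config.screen_alpha}"
        )
    if config.max_screened is not None and len(screened) > config.max_screened:
        # keep the most significant features when capping the curve width
        screened = list(
            screen.loc[screened].sort_values("p_value").index[: config.max_screened]
        )
    ranked = rank_features_by_importance(
        abund[screened], groups, n_trees=config.n_trees, seed=config.seed,
    )
    curve = cv_error_curve(
        abund, groups, ranked,
        n_trials=config.n_trials, n_folds=config.n_folds,
        seed=config.seed, n_trees=config.n_trees,
        rank_within_folds=config.rank_within_folds,
    )
    markers = select_optimal_markers(curve, ranked)
    config.audit.update(screen=screen, ranked=ranked, curve=curve)
    return markers
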