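"""The probability-of-disease (POD) index and its ROC evaluation.

A random forest is trained on the selected marker abundances only. For a new
sample the POD index is the share of trees voting the case class — a score
in [0, 1] whose ordering equals the raw case-vote count ordering (the
literal case/control vote ratio is available via ``ratio=True``; it induces
the same ROC). AUC is the Mann-Whitney statistic with ties counted one half,
and its 95% confidence interval uses DeLong's method, matching the pROC
default that this style of analysis conventionally reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .diffabund import wilcoxon_rank_sum
from .tables import OtuTable, relative_abundance

__all__ = [
    "PodModel",
    "RocResult",
    "train_pod_model",
    "pod_index",
    "roc_auc",
    "delong_ci",
    "evaluate_cohorts",
]

POD_MODEL_FORMAT_VERSION = 1


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and a DeLong 95% confidence interval."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


@dataclass
class PodModel:
    """Trained marker ensemble exposing per-tree votes.

    ``case_label`` is the positive class; ``marker_ids`` fixes the feature
    order expected at prediction time.
    """

    forest: RandomForestClassifier
    marker_ids: list[str]
    case_label: str
    control_label: str
    training_sample_ids: list[str]
    format_version: int = POD_MODEL_FORMAT_VERSION

    def tree_votes(self, abund: np.ndarray) -> np.ndarray:
        """Case-vote counts per sample: shape (n_samples,)."""
        votes = np.zeros(abund.shape[0], dtype=int)
        for est in self.forest.estimators_:
            pred = self.forest.classes_[
                np.argmax(est.predict_proba(abund), axis=1)
            ]
            votes += pred == self.case_label
        return votes

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PodModel":
        model = joblib.load(path)
        if not isinstance(model, PodModel):
            raise TypeError(f"{path} does not contain a PodModel")
        if model.format_version != POD_MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format v{model.format_version} != v{POD_MODEL_FORMAT_VERSION}"
            )
        return model


def train_pod_model(
    table: OtuTable,
    groups,
    markers: list[str],
    n_trees: int = 500,
    seed: int = 0,
    case_label: str = "CASE",
) -> PodModel:
    """Fit the marker-only ensemble on a labeled training cohort."""
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {labels}")
    if case_label not in labels:
        raise ValueError(f"case label {case_label!r} absent from groups {labels}")
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per group")
    missing = [m for m in markers if m not in table.otu_ids]
    if missing:
        raise ValueError(f"marker ids absent from table: {missing}")
    abund = relative_abundance(table)[markers].to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(abund, groups)
    control_label = next(l for l in labels if l != case_label)
    return PodModel(forest, list(markers), case_label, control_label,
                    list(table.sample_ids))


def pod_index(model: PodModel, table: OtuTable, ratio: bool = False) -> pd.DataFrame:
    """Per-sample POD scores from the tree votes.

    Default: ``pod = case votes / total trees`` in [0, 1]. With
    ``ratio=True`` the literal case/control vote ratio is reported instead
    (infinite when no tree votes control); both orderings coincide.
    """
    missing = [m for m in model.marker_ids if m not in table.otu_ids]
    if missing:
        raise ValueError(f"marker ids absent from table: {missing}")
    abund = relative_abundance(table)[model.marker_ids].to_numpy()
    case_votes = model.tree_votes(abund)
    control_votes = model.n_trees - case_votes
    if ratio:
        with np.errstate(divide="ignore"):
            pod = np.where(control_votes > 0, case_votes / control_votes, np.inf)
    else:
        pod = case_votes / model.n_trees
    return pd.DataFrame({
        "sample_id": table.sample_ids,
        "n_trees_case": case_votes,
        "n_trees_control": control_votes,
        "pod": pod,
    }).set_index("sample_id")


def _auc_mann_whitney(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney statistic, ties counting one half."""
    n1, n0 = case_scores.size, control_scores.size
    ranks = stats.rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def delong_ci(case_scores, control_scores, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval.

    Uses the structural-component formulation: V10[i] is the placement of
    case score i among controls, V01[j] the placement of control score j
    among cases; the AUC variance is var(V10)/m + var(V01)/n.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    m, n = x.size, y.size
    if m < 2 or n < 2:
        raise ValueError("DeLong CI needs at least 2 samples per class")
    auc = _auc_mann_whitney(x, y)
    # placements via midranks (handles ties)
    v10 = np.empty(m)
    for i, xi in enumerate(x):
        v10[i] = ((xi > y).sum() + 0.5 * (xi == y).sum()) / n
    v01 = np.empty(n)
    for j, yj in enumerate(y):
        v01[j] = ((x > yj).sum() + 0.5 * (x == yj).sum()) / m
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def roc_auc(scores, labels, case_label: str = "CASE") -> RocResult:
    """Empirical ROC with AUC and DeLong 95% CI.

    ``scores`` may be the POD frame from :func:`pod_index` or any array of
    scores; higher score = more case-like.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["pod"].to_numpy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_case = labels == case_label
    if is_case.all() or not is_case.any():
        raise ValueError("both classes must be present")
    x, y = scores[is_case], scores[~is_case]
    auc, lo, hi = delong_ci(x, y)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(x >= t).mean() for t in thresholds])
    spec = np.array([(y < t).mean() for t in thresholds])
    return RocResult(thresholds, sens, spec, auc, lo, hi,
                     int(is_case.sum()), int((~is_case).sum()))


def evaluate_cohorts(
    model: PodModel,
    cohorts: dict[str, tuple[OtuTable, np.ndarray]],
) -> dict[str, dict]:
    """Score and ROC-evaluate the model on held-out cohorts.

    Each cohort maps a name to ``(table, labels)``. Any sample-id overlap
    with the training cohort raises a leakage error. The returned entry per
    cohort carries the POD frame, the :class:`RocResult`, and the two-sided
    Wilcoxon p-value comparing case vs control POD.
    """
    train_ids = set(model.training_sample_ids)
    out = {}
    for name, (table, labels) in cohorts.items():
        overlap = train_ids & set(table.sample_ids)
        if overlap:
            raise ValueError(
                f"cohort {name!r} shares {len(overlap)} sample(s) with the "
                f"training set (e.g. {sorted(overlap)[:3]}): evaluation would leak"
            )
        scores = pod_index(model, table)
        labels = np.asarray(labels)
        roc = roc_auc(scores, labels, case_label=model.case_label)
        pod_vals = scores["pod"].to_numpy()
        p_group = wilcoxon_rank_sum(
            pod_vals[labels == model.case_label],
            pod_vals[labels != model.case_label],
        )
        out[name] = {"scores": scores, "roc": roc, "group_p": p_group}
    return out
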