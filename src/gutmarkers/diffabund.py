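"""Differential abundance: Wilcoxon rank-sum screening and LDA effect sizes.

Two complementary screens on the relative-abundance matrix:

* :func:`wilcoxon_screen` — the two-sided Mann-Whitney/Wilcoxon rank-sum
  test per feature at a raw alpha (no multiple-testing adjustment by
  default; that is a deliberate, documented choice — pass ``bh=True`` for
  Benjamini-Hochberg).
* :func:`lda_effect_size` — the two-stage Kruskal-Wallis + linear
  discriminant effect-size screen popularised by LEfSe, restricted to the
  single-factor two-class design: features passing the Kruskal-Wallis test
  get a bootstrap-averaged discriminant effect on abundances scaled by 1e6,
  reported as log10 and thresholded (default 2.0).

:func:`aggregate_taxa` collapses the OTU table to any taxonomic rank so the
same screens apply at phylum/genus/... level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable, TaxonomyMap

__all__ = [
    "aggregate_taxa",
    "wilcoxon_rank_sum",
    "wilcoxon_screen",
    "kruskal_wallis",
    "lda_effect_size",
]


def aggregate_taxa(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU counts over taxa sharing a rank label.

    OTUs whose lineage is truncated above ``rank`` are pooled under
    ``"<deepest-assigned-label>_norank"`` (or ``"unassigned_norank"`` when
    the lineage is empty), so column sums are conserved exactly.
    """
    if not tax.lineages:
        raise ValueError("empty taxonomy map")
    labels = []
    for otu in table.otu_ids:
        lab = tax.label_at(otu, rank)
        if lab is None:
            lineage = tax.lineages.get(otu, ())
            parent = lineage[-1] if lineage else "unassigned"
            lab = f"{parent}_norank"
        labels.append(lab)
    df = table.to_dataframe()
    agg = df.T.groupby(np.asarray(labels), sort=True).sum().T
    return OtuTable(list(table.sample_ids), list(agg.columns), agg.to_numpy())


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; otherwise the tie-corrected normal approximation with midranks
    and no continuity correction (so that the two-group Kruskal-Wallis test
    is algebraically identical).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


def wilcoxon_screen(abund: pd.DataFrame, groups, alpha: float = 0.05,
                    bh: bool = False) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon rank-sum screen.

    Returns a frame indexed by feature with group mean abundances, the
    enrichment direction, the raw two-sided p-value (plus ``q_value`` when
    ``bh``), and the ``selected`` flag (p < alpha on the raw p by default).
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"wilcoxon_screen needs exactly 2 groups, got {labels}")
    g_case, g_ctrl = ("CASE", "CONTROL") if set(labels) == {"CASE", "CONTROL"} else labels
    mask_case = groups == g_case
    mask_ctrl = groups == g_ctrl
    if mask_case.sum() < 2 or mask_ctrl.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    x = np.asarray(abund, dtype=float)
    rows = []
    for j, feat in enumerate(abund.columns):
        p = wilcoxon_rank_sum(x[mask_case, j], x[mask_ctrl, j])
        m_case = float(x[mask_case, j].mean())
        m_ctrl = float(x[mask_ctrl, j].mean())
        rows.append({
            "feature_id": feat,
            "mean_rel_abund_case": m_case,
            "mean_rel_abund_control": m_ctrl,
            "direction": g_case if m_case >= m_ctrl else g_ctrl,
            "p_value": p,
        })
    out = pd.DataFrame(rows).set_index("feature_id")
    if bh:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["selected"] = out["q_value"] < alpha
    else:
        out["selected"] = out["p_value"] < alpha
    return out


def kruskal_wallis(*samples) -> float:
    """Tie-corrected Kruskal-Wallis p-value (chi-squared, k-1 df).

    Degenerate data (all observations identical) returns p = 1.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.kruskal(*arrays).pvalue)


@dataclass
class LdaEffectConfig:
    """Tunables of the LDA effect-size screen (LEfSe-style, two classes)."""

    kw_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    boot_fraction: float = 2.0 / 3.0
    scale: float = 1e6  # relative abundance multiplier before effect sizing


def lda_effect_size(
    abund: pd.DataFrame,
    groups,
    kw_alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
    scale: float = 1e6,
) -> pd.DataFrame:
    """Kruskal-Wallis prescreen followed by an LDA-style effect size.

    For each feature passing the Kruskal-Wallis test at ``kw_alpha``, the
    effect is the bootstrap average (``n_boot`` class-stratified subsamples)
    of the absolute difference of group means along the discriminant
    direction, on abundances scaled by ``scale``. With a single feature the
    unit-norm discriminant direction is +/-1, so the projected difference
    equals the scaled raw mean difference. The reported score is
    ``log10(effect)`` floored at 1; a feature ``passes`` when the
    Kruskal-Wallis p is below ``kw_alpha`` AND the score is at or above
    ``lda_threshold``. The signed bootstrap differences are averaged before
    taking the absolute value, so null sampling noise cancels. Zero-variance
    features score 0 and never pass.
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("lda_effect_size supports the two-class design")
    g_case, g_ctrl = ("CASE", "CONTROL") if set(labels) == {"CASE", "CONTROL"} else labels
    rng = np.random.default_rng(seed)
    x = np.asarray(abund, dtype=float) * scale
    idx_case = np.flatnonzero(groups == g_case)
    idx_ctrl = np.flatnonzero(groups == g_ctrl)
    n_case = max(2, int(round(len(idx_case) * 2 / 3)))
    n_ctrl = max(2, int(round(len(idx_ctrl) * 2 / 3)))

    rows = []
    for j, feat in enumerate(abund.columns):
        col = x[:, j]
        kw_p = kruskal_wallis(col[idx_case], col[idx_ctrl])
        m_case, m_ctrl = float(col[idx_case].mean()), float(col[idx_ctrl].mean())
        enriched = g_case if m_case >= m_ctrl else g_ctrl
        if np.ptp(col) == 0:
            rows.append({"taxon": feat, "enriched_group": enriched, "kw_p": kw_p,
                         "lda_score_log10": 0.0, "passes": False})
            continue
        effects = np.empty(n_boot)
        for b in range(n_boot):
            sub_case = rng.choice(idx_case, size=n_case, replace=True)
            sub_ctrl = rng.choice(idx_ctrl, size=n_ctrl, replace=True)
            effects[b] = col[sub_case].mean() - col[sub_ctrl].mean()
        # signed differences are averaged first so null noise cancels instead
        # of accumulating through the absolute value
        eff = float(abs(effects.mean()))
        score = max(np.log10(eff), 1.0) if eff > 0 else 0.0
        rows.append({
            "taxon": feat,
            "enriched_group": enriched,
            "kw_p": kw_p,
            "lda_score_log10": float(score),
            "passes": bool(kw_p < kw_alpha and score >= lda_threshold),
        })
    return pd.DataFrame(rows).set_index("taxon")
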