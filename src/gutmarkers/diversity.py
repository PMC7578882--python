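"""Alpha diversity, rarefaction curves, Bray-Curtis distances and ordination.

Alpha-diversity estimators follow their classical definitions: Shannon
entropy on proportions (natural log by default), bias-corrected Chao1
``S_obs + F1*(F1-1) / (2*(F2+1))`` and the abundance-based coverage
estimator (ACE) with the standard rare/abundant split at 10 reads. The
estimators are implemented here because the pipeline pins their exact
conventions (log base, bias correction, degenerate fallbacks); tests
cross-check them against scikit-bio.

Beta diversity is Bray-Curtis on relative abundances; ordination is
classical PCoA (delegated to scikit-bio's eigendecomposition, negative
eigenvalue axes dropped) plus a covariance-eigendecomposition PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio.stats.ordination import pcoa as _skbio_pcoa
import skbio

from .tables import OtuTable, OtuTableError, rarefy, relative_abundance

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "observed_otus",
    "shannon",
    "chao1",
    "ace",
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis",
    "pcoa",
    "pca",
    "group_overlap",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.d = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """Sample coordinates on axes ordered by non-increasing eigenvalue."""

    ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # descending, positive axes only
    proportion_explained: np.ndarray


# ---------------------------------------------------------------------------
# Alpha diversity


def _vector(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if c.size and c.min() < 0:
        raise ValueError("counts must be nonnegative")
    return c


def observed_otus(counts) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(_vector(counts)))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over positive proportions.

    Natural log by default; pass ``base=2`` for bits.
    """
    c = _vector(counts).astype(float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for a zero-total sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1) / (2*(F2+1))."""
    c = _vector(counts)
    s_obs = np.count_nonzero(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Taxa with more than ``rare_threshold`` reads are counted directly; rare
    taxa are scaled by the sample-coverage estimate ``C = 1 - F1/N_rare``
    with the usual squared coefficient of variation correction. When every
    rare read is a singleton (C = 0) the estimator is undefined and the
    bias-corrected Chao1 is returned instead.
    """
    c = _vector(counts)
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    s_abund = int((c > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:  # coverage zero: fall back
        return chao1(counts)
    coverage = 1.0 - f1 / n_rare
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = max((s_rare / coverage) * (ks * (ks - 1) * fk).sum()
                 / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma2


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed OTUs, Shannon, Chao1 and ACE, as a tidy frame."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        rows.append({
            "sample_id": sid,
            "observed_otus": observed_otus(row),
            "shannon": shannon(row),
            "chao1": chao1(row),
            "ace": ace(row),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(
    table: OtuTable,
    depths,
    reps: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean observed OTUs after rarefying to each depth, per group.

    Returns a frame indexed by depth with one column per group (column
    ``"all"`` when no groups are given). Samples below a depth are excluded
    at that depth.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depth list must be non-empty")
    if sorted(depths) != depths:
        raise ValueError("depths must be increasing")
    if groups is None:
        groups = np.array(["all"] * table.n_samples)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps)]

    out = {}
    for depth in depths:
        acc = {g: [] for g in labels}
        for rs in rep_seeds:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                sub = rarefy(table, depth, seed=rs)
            kept = {s: i for i, s in enumerate(sub.sample_ids)}
            for g in labels:
                vals = [observed_otus(sub.counts[kept[s]])
                        for s, gg in zip(table.sample_ids, groups)
                        if gg == g and s in kept]
                if vals:
                    acc[g].append(np.mean(vals))
        out[depth] = {g: (float(np.mean(v)) if v else np.nan) for g, v in acc.items()}
    return pd.DataFrame(out).T.rename_axis("depth")


# ---------------------------------------------------------------------------
# Beta diversity and ordination


def bray_curtis(table_or_abund) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x,y) = 1 - 2*sum(min(x,y)) / (sum x + sum y).

    Accepts an :class:`OtuTable` (converted to relative abundance first) or a
    samples x features abundance DataFrame.
    """
    if isinstance(table_or_abund, OtuTable):
        abund = relative_abundance(table_or_abund)
    else:
        abund = table_or_abund
    if abund.shape[0] < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    x = np.asarray(abund, dtype=float)
    if np.any(x.sum(axis=1) == 0):
        raise OtuTableError("zero-total sample in abundance matrix")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(abund.index.astype(str)), d)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centred Gower matrix; axes with
    non-positive eigenvalues (non-Euclidean part of the distance) are
    dropped. ``proportion_explained`` is relative to the positive part.
    """
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(skbio.DistanceMatrix(dm.d, ids=dm.ids), method="eigh",
                          number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig > max(eig.max(), 0) * 1e-12
    coords = res.samples.to_numpy()[:, pos]
    eig_pos = eig[pos]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        eig_pos = eig_pos[:n_axes]
    prop = eig_pos / eig[eig > 0].sum()
    return OrdinationResult(list(dm.ids), coords, eig_pos, prop)


def pca(abund: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """PCA of relative abundances via covariance eigendecomposition."""
    x = np.asarray(abund, dtype=float)
    xc = x - x.mean(axis=0)
    cov = np.cov(xc, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_axes]
    coords = xc @ eigvec[:, order]
    eig = np.maximum(eigval[order], 0.0)
    total = eigval[eigval > 0].sum()
    return OrdinationResult(
        list(abund.index.astype(str)), coords, eig,
        eig / total if total > 0 else np.zeros_like(eig),
    )


def group_overlap(table: OtuTable, groups, presence_min: int = 1) -> dict:
    """Venn-style accounting of OTU presence across groups.

    An OTU is present in a group when its summed count there is at least
    ``presence_min``. Returns the number present in every group (``shared``),
    the number present only in each single group (``unique_per_group``), and
    the number present anywhere (``total``).
    """
    groups = np.asarray(groups)
    if len(groups) != table.n_samples:
        raise ValueError("one group label per sample required")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    presence = {}
    for g in labels:
        sums = table.counts[groups == g].sum(axis=0)
        presence[g] = sums >= presence_min
    stacked = np.vstack([presence[g] for g in labels])
    any_present = stacked.any(axis=0)
    shared = int(stacked.all(axis=0).sum())
    unique = {
        g: int((presence[g] & ~np.delete(stacked, i, axis=0).any(axis=0)).sum())
        for i, g in enumerate(labels)
    }
    return {"shared": shared, "unique_per_group": unique, "total": int(any_present.sum())}
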