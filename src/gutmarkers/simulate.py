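"""Synthetic two-group microbiome cohorts with known ground truth.

Real 16S OTU tables are sparse, overdispersed and compositional. The
generator emulates those properties with a log-normal/Dirichlet-multinomial
model:

1. a base community profile is drawn log-normally on the relative-abundance
   scale and normalised to a composition;
2. the case-group profile multiplies a small planted set of OTUs by
   ``2**log2_fold_change`` (half enriched in cases, half depleted) and
   renormalises;
3. each sample draws a library size log-normally, a composition from a
   Dirichlet centred on its group profile (concentration = ``dispersion``),
   and counts multinomially — i.e. Dirichlet-multinomial counts;
4. clinical indicators are drawn normally with a per-indicator group shift
   expressed in SD units, anchored to realistic units.

The overall zero fraction is calibrated to ``sparsity`` by scaling the
log-abundance spread (a temperature on the base profile) so that the
analytic beta-binomial zero probability, averaged over OTUs and drawn
library sizes, matches the target. All randomness flows from one seed via
``numpy.random.SeedSequence``: the biology streams (base profile,
planted-OTU choice) depend on the seed alone, while the sample streams
(library sizes, compositions/counts, clinical values, site effect) also
depend on a ``draw`` index — so identical specs give bit-identical cohorts,
and different draws give fresh patients from the same populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import CLINICAL_INDICATORS, OtuTable, SampleMetadata

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "spike_worked_example",
    "CLINICAL_ANCHORS",
    "DEFAULT_CLINICAL_EFFECT",
]

#: control-group mean and SD per indicator, in recorded units
CLINICAL_ANCHORS: dict[str, tuple[float, float]] = {
    "SCr": (67.6, 12.9),       # umol/L
    "BUN": (4.6, 1.0),         # mmol/L
    "eGFR": (104.3, 9.8),      # mL/min/1.73m2
    "ALB": (48.0, 2.6),        # g/L
    "Hb": (140.0, 10.0),       # g/L
    "phosphate": (1.15, 0.15), # mmol/L
}

#: case-minus-control shift per indicator, in pooled-SD units; signs follow
#: the renal-failure phenotype (creatinine/urea/phosphate rise, filtration
#: rate / albumin / haemoglobin fall)
DEFAULT_CLINICAL_EFFECT: dict[str, float] = {
    "SCr": 1.5,
    "BUN": 1.7,
    "eGFR": -2.5,
    "ALB": -1.7,
    "Hb": -1.0,
    "phosphate": 0.6,
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort draw.

    Attributes
    ----------
    n_case, n_control :
        Group sizes.
    n_otus :
        Total OTUs, including the planted ones.
    n_diff :
        Number of differentially abundant OTUs planted between groups.
    log2_fold_change :
        Planted effect size; enriched-in-case OTUs are multiplied by
        ``2**log2_fold_change`` in the case profile, depleted ones divided.
    base_abundance_mean, base_abundance_sd :
        Mean and SD of log relative abundance before normalisation (the SD is
        rescaled when sparsity calibration is on).
    dispersion :
        Dirichlet concentration scalar; smaller = more sample-to-sample
        compositional noise.
    library_size_log_mean, library_size_log_sd :
        Log-normal parameters of per-sample totals.
    sparsity :
        Target marginal zero fraction of the count matrix (calibrated
        analytically); ``None`` disables calibration.
    clinical_effect :
        Indicator name -> group shift in SD units.
    clinical_missing_rate :
        Fraction of clinical cells set missing at random.
    seed :
        Master seed; drives every sub-stream.
    """

    n_case: int = 50
    n_control: int = 50
    n_otus: int = 105
    n_diff: int = 5
    log2_fold_change: float = 3.0
    base_abundance_mean: float = 0.0
    base_abundance_sd: float = 1.5
    dispersion: float = 20.0
    library_size_log_mean: float = float(np.log(10_000.0))
    library_size_log_sd: float = 0.3
    sparsity: float | None = 0.5
    clinical_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECT)
    )
    clinical_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.n_diff <= self.n_otus:
            raise ValueError(f"n_diff={self.n_diff} must lie in [0, n_otus={self.n_otus}]")
        for name in ("base_abundance_sd", "dispersion", "library_size_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sparsity is not None and not 0 <= self.sparsity < 1:
            raise ValueError(f"sparsity={self.sparsity} must lie in [0, 1)")
        if not 0 <= self.clinical_missing_rate < 1:
            raise ValueError("clinical_missing_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """Which OTUs were planted, their direction, and the realised profile ratio."""

    diff_otu_ids: set[str]
    direction: dict[str, str]  # otu id -> "enriched_case" | "enriched_control"
    realized_fold_change: dict[str, float]  # otu id -> case/control profile ratio


def _zero_fraction(log_p: np.ndarray, temperature: float, dispersion: float,
                   library_sizes: np.ndarray) -> float:
    """Analytic expected zero fraction of the Dirichlet-multinomial matrix.

    The marginal of one OTU is beta-binomial(N, a=c*p_j, b=c*(1-p_j)), whose
    zero mass is B(a, b+N)/B(a, b) = exp(gammaln terms).
    """
    z = temperature * log_p
    p = np.exp(z - z.max())
    p /= p.sum()
    a = dispersion * p
    b = dispersion * (1.0 - p)
    # average over OTUs and over the drawn library sizes
    N = library_sizes[:, None].astype(float)
    logp0 = gammaln(b + N) + gammaln(a + b) - gammaln(b) - gammaln(a + b + N)
    return float(np.mean(np.exp(logp0)))


def _calibrate_temperature(log_p: np.ndarray, target: float, dispersion: float,
                           library_sizes: np.ndarray) -> float:
    """Bisection on the log-abundance temperature to hit the target zero fraction."""
    lo, hi = 1e-3, 1.0
    f_lo = _zero_fraction(log_p, lo, dispersion, library_sizes)
    if f_lo > target:
        raise ValueError(
            "infeasible sparsity: even a near-uniform profile yields zero "
            f"fraction {f_lo:.3f} > target {target:.3f}; lower the target, "
            "raise library sizes, or raise dispersion"
        )
    f_hi = _zero_fraction(log_p, hi, dispersion, library_sizes)
    while f_hi < target:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError(
                "infeasible sparsity: cannot reach target zero fraction "
                f"{target:.3f} by skewing the profile (reached {f_hi:.3f}); "
                "lower library sizes or the target"
            )
        f_hi = _zero_fraction(log_p, hi, dispersion, library_sizes)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _zero_fraction(log_p, mid, dispersion, library_sizes) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    spec: SyntheticSpec,
    cohort: str = "discovery",
    sample_prefix: str = "S",
    site_effect_sd: float = 0.0,
    draw: int = 0,
) -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Draw one cohort: counts, metadata and the planted-marker ground truth.

    The community biology — base profile, which OTUs are planted and their
    directions — is a deterministic function of ``spec.seed`` alone, while
    sample-level randomness (library sizes, compositions, counts, clinical
    values) additionally depends on ``draw``. Two calls with the same spec
    and different ``draw`` therefore yield independent cohorts from the SAME
    underlying populations (fresh patients, same biology), which is how
    validation and independent cohorts are emulated.

    ``site_effect_sd > 0`` multiplies both group profiles by a shared
    log-normal perturbation before renormalisation, emulating a second
    sampling site with a shifted community.
    """
    spec.validate()
    # biology streams: spec.seed only
    rng_profile, rng_plant = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(2)
    )
    # sample streams: spec.seed + draw index
    rng_lib, rng_counts, rng_clin, rng_site = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence([spec.seed, 7919 + draw]).spawn(4)
    )

    n = spec.n_case + spec.n_control
    lib = rng_lib.lognormal(spec.library_size_log_mean, spec.library_size_log_sd, size=n)
    lib = np.maximum(lib.round().astype(np.int64), 1)

    log_p = rng_profile.normal(spec.base_abundance_mean, spec.base_abundance_sd, spec.n_otus)
    if spec.sparsity is not None:
        # calibration library sizes come from the biology stream so the
        # calibrated profile is identical across draws of the same spec
        calib_lib = np.maximum(rng_profile.lognormal(
            spec.library_size_log_mean, spec.library_size_log_sd, size=100
        ).round().astype(np.int64), 1)
        t = _calibrate_temperature(log_p, spec.sparsity, spec.dispersion, calib_lib)
        log_p = t * log_p
    control_p = np.exp(log_p - log_p.max())
    control_p /= control_p.sum()

    otu_ids = [f"OTU{i + 1:04d}" for i in range(spec.n_otus)]

    # plant markers among consistently detectable taxa (50th-90th abundance
    # percentile band) so the effect is about abundance shifts, not detection
    order = np.argsort(control_p)
    lo_q, hi_q = int(0.5 * spec.n_otus), max(int(0.9 * spec.n_otus), int(0.5 * spec.n_otus) + spec.n_diff)
    band = order[lo_q:hi_q]
    if spec.n_diff > len(band):
        band = order[-spec.n_diff:]
    planted = rng_plant.choice(band, size=spec.n_diff, replace=False) if spec.n_diff else np.array([], dtype=int)

    # Assign enrichment directions greedily so the planted mass change nearly
    # cancels: renormalising the case profile then barely perturbs unplanted
    # OTUs (otherwise closure would hand every unplanted taxon a spurious
    # fold change).
    case_p = control_p.copy()
    direction: dict[str, str] = {}
    fold = 2.0 ** spec.log2_fold_change
    delta = 0.0
    for j in sorted(planted, key=lambda j: -control_p[j]):
        d_enrich = (fold - 1.0) * control_p[j]
        d_deplete = -(1.0 - 1.0 / fold) * control_p[j]
        if abs(delta + d_enrich) <= abs(delta + d_deplete):
            case_p[j] *= fold
            direction[otu_ids[j]] = "enriched_case"
            delta += d_enrich
        else:
            case_p[j] /= fold
            direction[otu_ids[j]] = "enriched_control"
            delta += d_deplete
    case_p /= case_p.sum()

    if site_effect_sd > 0:
        # shared community shift of the second site, applied to both groups
        # AFTER planting so the marker biology is preserved across sites
        shift = np.exp(rng_site.normal(0.0, site_effect_sd, spec.n_otus))
        control_p = control_p * shift
        control_p /= control_p.sum()
        case_p = case_p * shift
        case_p /= case_p.sum()

    realized = {otu_ids[j]: float(case_p[j] / control_p[j]) for j in planted}
    truth = GroundTruth(set(direction), direction, realized)

    groups = np.array(["CASE"] * spec.n_case + ["CONTROL"] * spec.n_control)
    counts = np.empty((n, spec.n_otus), dtype=np.int64)
    for i in range(n):
        p = case_p if groups[i] == "CASE" else control_p
        comp = rng_counts.dirichlet(spec.dispersion * p)
        counts[i] = rng_counts.multinomial(lib[i], comp)

    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    table = OtuTable(sample_ids, otu_ids, counts)

    clin = {}
    for name in CLINICAL_INDICATORS:
        mu0, sd0 = CLINICAL_ANCHORS[name]
        shift = spec.clinical_effect.get(name, 0.0)
        mu = np.where(groups == "CASE", mu0 + shift * sd0, mu0)
        vals = rng_clin.normal(mu, sd0)
        if spec.clinical_missing_rate > 0:
            mask = rng_clin.random(n) < spec.clinical_missing_rate
            vals = np.where(mask, np.nan, vals)
        clin[name] = vals
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "cohort": cohort,
        **clin,
    }))
    return table, meta, truth


#: the fixed documentation/test fixture: 10+10 samples x 30 OTUs, 5 planted
#: markers with a moderate effect (so no single OTU suffices and the error
#: curve genuinely selects a multi-marker set), exercising the full
#: discovery pipeline end-to-end in seconds
WORKED_EXAMPLE_SPEC = SyntheticSpec(
    n_case=10,
    n_control=10,
    n_otus=30,
    n_diff=5,
    log2_fold_change=2.5,
    base_abundance_sd=1.2,
    dispersion=10.0,
    library_size_log_mean=float(np.log(5_000.0)),
    library_size_log_sd=0.2,
    sparsity=0.3,
    seed=20200902,
)


def spike_worked_example() -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """The fixed small fixture cohort, regenerated deterministically."""
    return generate_cohort(WORKED_EXAMPLE_SPEC, sample_prefix="WX")
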