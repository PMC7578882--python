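"""Core containers and I/O for OTU count tables, sample metadata and taxonomy.

The pipeline's universal currency is the :class:`OtuTable`: a samples x OTUs
matrix of nonnegative integer read counts with unique, ordered sample and OTU
identifiers. Tables are read and written as plain TSV (default: OTUs in rows,
the common amplicon convention) or as BIOM-JSON v1.0.

Also provided here are the two count transforms everything downstream relies
on: total-sum scaling to relative abundance and rarefaction (random
subsampling without replacement to a common depth).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "TaxonomyMap",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "relative_abundance",
    "rarefy",
]

CANONICAL_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: clinical indicators carried by the cohort metadata, with units as recorded
CLINICAL_INDICATORS = ("SCr", "BUN", "eGFR", "ALB", "Hb", "phosphate")


class OtuTableError(ValueError):
    """Raised when a count table violates its invariants or cannot be parsed."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise OtuTableError(f"duplicate {what} ids: {sorted(dups)[:5]}")
    return ids


@dataclass
class OtuTable:
    """Samples x OTUs matrix of nonnegative integer counts.

    Parameters
    ----------
    sample_ids :
        Ordered unique sample identifiers (rows of ``counts``).
    otu_ids :
        Ordered unique OTU identifiers (columns of ``counts``).
    counts :
        Integer array of shape ``(n_samples, n_otus)``; all entries >= 0.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.otu_ids = _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac = np.modf(np.asarray(counts, dtype=float))[0]
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise OtuTableError(
                    f"non-integer count at sample {self.sample_ids[r]!r}, "
                    f"OTU {self.otu_ids[c]!r}"
                )
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise OtuTableError(
                f"negative count at sample {self.sample_ids[r]!r}, OTU {self.otu_ids[c]!r}"
            )
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a samples x OTUs DataFrame."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.otu_ids]
        if missing:
            raise OtuTableError(f"OTU ids absent from table: {missing}")
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample group label, cohort tag and clinical indicators.

    ``group`` values are ``"CASE"`` / ``"CONTROL"``; ``cohort`` values are
    ``"discovery"`` / ``"validation"`` / ``"independent"``. Clinical
    indicators are stored as floats with NaN marking missing values and are
    excluded pairwise in downstream correlation.
    """

    frame: pd.DataFrame = field(repr=False)

    GROUPS = ("CASE", "CONTROL")
    COHORTS = ("discovery", "validation", "independent")

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("sample_id", "group"):
            if col not in df.columns:
                raise OtuTableError(f"metadata is missing required column {col!r}")
        _check_unique(df["sample_id"], "metadata sample")
        bad = set(df["group"].dropna()) - set(self.GROUPS)
        if bad:
            raise OtuTableError(f"unknown group labels: {sorted(bad)} (expected {self.GROUPS})")
        if "cohort" in df.columns:
            bad = set(df["cohort"].dropna()) - set(self.COHORTS)
            if bad:
                raise OtuTableError(f"unknown cohort labels: {sorted(bad)}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]

    def groups_for(self, sample_ids) -> np.ndarray:
        """Group labels aligned to ``sample_ids``; every id must be labeled."""
        lookup = dict(zip(self.frame["sample_id"].astype(str), self.frame["group"]))
        missing = [s for s in sample_ids if s not in lookup or pd.isna(lookup[s])]
        if missing:
            raise OtuTableError(f"samples without a group label: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids])

    def clinical_table(self) -> pd.DataFrame:
        """Indicator columns (everything beyond sample_id/group/cohort), indexed by sample."""
        cols = [c for c in self.frame.columns if c not in ("sample_id", "group", "cohort")]
        out = self.frame.set_index("sample_id")[cols].astype(float)
        out.index = out.index.astype(str)
        return out

    def subset(self, sample_ids) -> "SampleMetadata":
        df = self.frame.set_index(self.frame["sample_id"].astype(str))
        return SampleMetadata(df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class TaxonomyMap:
    """OTU id -> lineage (ordered rank labels, kingdom..genus, possibly truncated)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, lineage in self.lineages.items():
            if len(lineage) > len(CANONICAL_RANKS):
                raise OtuTableError(
                    f"lineage for {otu!r} has {len(lineage)} ranks; "
                    f"max is {len(CANONICAL_RANKS)}"
                )
        self.lineages = {str(k): tuple(v) for k, v in self.lineages.items()}

    def label_at(self, otu_id: str, rank: str) -> str | None:
        """Rank label for an OTU, or None if the lineage is truncated above it."""
        if rank not in CANONICAL_RANKS:
            raise OtuTableError(f"unknown rank {rank!r}; expected one of {CANONICAL_RANKS}")
        depth = CANONICAL_RANKS.index(rank)
        lineage = self.lineages.get(otu_id, ())
        return lineage[depth] if depth < len(lineage) else None


# ---------------------------------------------------------------------------
# I/O


def read_otu_table(path, format: str = "tsv", samples_in: str = "columns") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    format :
        ``"tsv"`` (first column = OTU id by default, header = sample ids) or
        ``"biom-json"`` (BIOM v1.0).
    samples_in :
        TSV orientation, ``"columns"`` (OTUs in rows; default amplicon
        convention) or ``"rows"``. Declared, never guessed.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # malformed header / ragged rows
            raise OtuTableError(f"cannot parse TSV table {path}: {exc}") from exc
        if samples_in not in ("rows", "columns"):
            raise OtuTableError("samples_in must be 'rows' or 'columns'")
        if samples_in == "columns":
            df = df.T  # now rows = samples
        try:
            counts = df.to_numpy(dtype=float) if df.size else np.zeros(df.shape)
        except ValueError as exc:
            raise OtuTableError(f"non-numeric cell in {path}: {exc}") from exc
        return OtuTable(list(df.index.astype(str)), list(df.columns.astype(str)), counts)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _from_biom(doc)
    raise OtuTableError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv", samples_in: str = "columns") -> None:
    """Write a table so that :func:`read_otu_table` round-trips it exactly."""
    if format == "tsv":
        df = table.to_dataframe()
        if samples_in == "columns":
            df = df.T
            df.index.name = "otu_id"
        else:
            df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        return
    if format == "biom-json":
        with open(path, "w") as fh:
            json.dump(_to_biom(table), fh)
        return
    raise OtuTableError(f"unknown format {format!r}")


def _to_biom(table: OtuTable) -> dict:
    """Minimal BIOM v1.0 (JSON) document; rows = observations (OTUs)."""
    dense = table.counts.T  # BIOM rows are observations
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "gutmarkers",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": dense.tolist(),
    }


def _from_biom(doc: dict) -> OtuTable:
    if "shape" not in doc or "data" not in doc:
        raise OtuTableError("not a BIOM v1.0 document (missing shape/data)")
    n_obs, n_samp = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    dense = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    else:
        dense = np.asarray(doc["data"], dtype=float).reshape(n_obs, n_samp)
    return OtuTable(sample_ids, otu_ids, dense.T)


def read_metadata(path) -> SampleMetadata:
    """Read a metadata TSV with header ``sample_id  group  cohort  <indicator...>``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    """Read an OTU -> lineage TSV (otu_id, then semicolon-joined lineage or one column per rank)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise OtuTableError("taxonomy TSV needs an otu_id column plus lineage column(s)")
    lineages = {}
    if df.shape[1] == 2:
        for otu, lin in zip(df.iloc[:, 0], df.iloc[:, 1]):
            lineages[otu] = tuple(t.strip() for t in str(lin).split(";") if t.strip())
    else:
        for _, row in df.iterrows():
            vals = [v for v in row.iloc[1:] if isinstance(v, str) and v]
            lineages[row.iloc[0]] = tuple(vals)
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# Transforms


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Total-sum scaling: each sample's counts divided by its library size.

    No pseudocount is added; rows of the result sum to exactly 1. Samples
    with zero total are rejected (there is nothing to normalise).
    """
    totals = table.sample_totals()
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise OtuTableError(f"samples with zero total count: {zero}")
    rel = table.counts / totals[:, None]
    return pd.DataFrame(rel, index=table.sample_ids, columns=table.otu_ids)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose library size is below ``depth`` are dropped with a warning.
    The same seed always produces the same table (multivariate hypergeometric
    draw per sample).
    """
    if depth <= 0:
        raise OtuTableError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), table.n_otus), dtype=np.int64)
    row = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        if totals[i] == depth:
            out[row] = table.counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(table.counts[i], depth)
        row += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(sample_ids, list(table.otu_ids), out)
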