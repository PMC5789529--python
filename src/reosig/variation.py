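"""Replicate-level variation analysis of quantitative expression measurements.

Quantifies how unstable raw expression magnitudes are across technical
replicates of the same RNA sample: per-gene coefficient of variation
(CV = SD / mean) after assay-specific gene exclusion, then the percentage
of genes at or above CV thresholds (10%, 15% by default).  Large replicate
CVs are the empirical motivation for preferring within-sample orderings
over magnitudes.

Assay-specific exclusion rules:

* StaRT-PCR-style: a gene with a zero or missing measurement in at least
  one replicate is excluded.
* TaqMan-style: a gene is absent when its cycle threshold (CT) exceeds a
  cutoff (default 35); the default mode excludes a gene absent in at least
  one replicate, an alternate mode averages CT across replicates first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ValidationError

ASSAY_START_PCR = "start_pcr"
ASSAY_TAQMAN = "taqman"
ASSAY_GENERIC = "generic"


@dataclass
class ReplicateTable:
    """Genes × replicates measurements for one sample type.

    ``ct`` optionally holds a parallel genes × replicates table of TaqMan
    cycle-threshold values used for absence calls.
    """

    values: pd.DataFrame
    assay: str = ASSAY_GENERIC
    ct: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in replicate table")
        self.values = self.values.astype(float)
        if self.ct is not None:
            self.ct = self.ct.astype(float)
            if not self.ct.index.equals(self.values.index) or not self.ct.columns.equals(
                self.values.columns
            ):
                raise ValidationError("CT table must be parallel to the value table")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def drop_genes(self, genes: Sequence[str]) -> "ReplicateTable":
        keep = self.values.index.difference(genes, sort=False)
        return ReplicateTable(
            values=self.values.loc[keep].copy(),
            assay=self.assay,
            ct=None if self.ct is None else self.ct.loc[keep].copy(),
        )


@dataclass
class FilterResult:
    """Filtered table plus gene → exclusion-reason provenance."""

    table: ReplicateTable
    exclusions: dict[str, str]


def filter_start_pcr(table: ReplicateTable) -> FilterResult:
    """Exclude genes with a zero or missing value in any replicate."""
    if table.assay != ASSAY_START_PCR:
        raise ValidationError(f"expected a {ASSAY_START_PCR} table, got {table.assay!r}")
    exclusions: dict[str, str] = {}
    vals = table.values
    zero_any = (vals == 0).any(axis=1)
    nan_any = vals.isna().any(axis=1)
    for gene in vals.index[zero_any & ~nan_any]:
        exclusions[gene] = "zero replicate"
    for gene in vals.index[nan_any]:
        exclusions[gene] = "missing replicate"
    return FilterResult(table=table.drop_genes(list(exclusions)), exclusions=exclusions)


def filter_taqman(
    table: ReplicateTable, ct_cutoff: float = 35.0, mode: str = "per_replicate"
) -> FilterResult:
    """Exclude genes called absent by the CT cutoff.

    ``mode='per_replicate'`` (default): a gene absent (CT > cutoff) in at
    least one replicate is excluded.  ``mode='mean'``: absence is called on
    the mean CT across replicates instead.
    """
    if table.assay != ASSAY_TAQMAN:
        raise ValidationError(f"expected a {ASSAY_TAQMAN} table, got {table.assay!r}")
    if table.ct is None:
        raise ValidationError("TaqMan filtering requires a CT table")
    if mode == "per_replicate":
        absent = (table.ct > ct_cutoff).any(axis=1)
        reason = f"CT > {ct_cutoff:g} in at least one replicate"
    elif mode == "mean":
        absent = table.ct.mean(axis=1) > ct_cutoff
        reason = f"mean CT > {ct_cutoff:g}"
    else:
        raise ValidationError(f"unknown TaqMan absence mode: {mode!r}")
    exclusions = {gene: reason for gene in table.ct.index[absent]}
    missing = table.values.isna().any(axis=1)
    for gene in table.values.index[missing & ~absent]:
        exclusions[gene] = "missing replicate"
    return FilterResult(table=table.drop_genes(list(exclusions)), exclusions=exclusions)


def compute_cv(
    table: ReplicateTable,
    exclusions: Mapping[str, str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-gene mean, SD and CV = SD / mean across replicates.

    The SD uses the sample (n−1) denominator by default; ``ddof=0`` gives
    the population reading.  Genes from *exclusions*, genes with fewer than
    two values, and genes with non-positive means are flagged excluded and
    given NaN statistics.  Returns a frame indexed by gene id with columns
    mean, sd, cv, included, reason.
    """
    if table.n_replicates < 2:
        raise ValidationError("CV requires at least 2 replicates")
    rows = []
    for gene in table.gene_ids:
        vals = table.values.loc[gene].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            rows.append((gene, np.nan, np.nan, np.nan, False, "insufficient replicates"))
            continue
        mean = float(np.mean(vals))
        if mean <= 0:
            rows.append((gene, mean, np.nan, np.nan, False, "non-positive mean"))
            continue
        sd = float(np.std(vals, ddof=ddof))
        rows.append((gene, mean, sd, sd / mean, True, ""))
    records = pd.DataFrame(
        rows, columns=["gene_id", "mean", "sd", "cv", "included", "reason"]
    ).set_index("gene_id")
    if exclusions:
        for gene, reason in exclusions.items():
            if gene in records.index:
                records.loc[gene, ["included", "reason"]] = [False, reason]
                records.loc[gene, ["sd", "cv"]] = [np.nan, np.nan]
            else:
                records.loc[gene] = [np.nan, np.nan, np.nan, False, reason]
    return records


@dataclass
class CVSummary:
    """Percent of included genes at or above each CV threshold."""

    percentages: dict[float, float]
    n_included: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": list(self.percentages),
                "percent_at_least": list(self.percentages.values()),
                "n_included": self.n_included,
            }
        )


def cv_threshold_summary(
    records: pd.DataFrame, thresholds: Sequence[float] = (0.10, 0.15)
) -> CVSummary:
    """Percentage of included genes with CV ≥ threshold (inclusive).

    Percentages are on the 0–100 scale; the included-gene count is reported
    alongside.
    """
    included = records[records["included"].astype(bool)]
    if included.empty:
        raise ValidationError("no included genes to summarize")
    cvs = included["cv"].to_numpy(dtype=float)
    percentages = {
        float(t): float(100.0 * np.mean(cvs >= t)) for t in thresholds
    }
    return CVSummary(percentages=percentages, n_included=int(len(included)))
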