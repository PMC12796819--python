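"""Row hygiene, missing-value filtering, log2 transform and left-censored imputation.

The filter rule is replicate-based: with threshold ``thr`` a protein is kept
iff some condition c detected it in at least ``n_c - thr`` of its ``n_c``
replicates.  ``thr = 0`` therefore demands complete detection in at least one
condition; each unit of threshold relaxes that requirement by one replicate.

Imputation assumes label-free dropout is left-censored (missing-not-at-
random, concentrated at low abundance): missing entries in a sample are drawn
from a Gaussian anchored near the low tail of that sample's observed log2
intensities, the MinProb-style model familiar from Perseus and DEP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .maxquant_io import ExperimentDesign, ProteinGroupsTable

log = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Proteins x samples intensity matrix tied to its experimental design.

    ``matrix`` is indexed by unique protein identifier with one column per
    sample, ordered as the design rows; NaN marks "not quantified" until the
    imputation stage, after which the matrix is complete.  ``annotations``
    carries the raw gene-name string and accession list per row for the
    mining and lookup operations.
    """

    matrix: pd.DataFrame
    design: ExperimentDesign
    annotations: pd.DataFrame  # columns: gene_name, protein_ids
    stage: str = "raw"  # raw | filtered | normalized | imputed
    threshold_used: Optional[int] = None
    seed_used: Optional[int] = None

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != self.design.labels:
            raise ValidationError("matrix column order must match design row order")
        if self.stage == "imputed" and self.matrix.isna().any().any():
            raise ValidationError("stage 'imputed' forbids missing entries")

    @property
    def ids(self) -> list[str]:
        return list(self.matrix.index)

    @classmethod
    def from_table(
        cls, table: ProteinGroupsTable, design: ExperimentDesign
    ) -> "ExpressionDataset":
        """Align raw LFQ intensities to the design's sample order."""
        want, got = set(design.labels), set(table.sample_labels)
        if want != got:
            raise ValidationError(
                f"design/sample label mismatch: design-only {sorted(want - got)}, "
                f"data-only {sorted(got - want)}"
            )
        matrix = table.lfq[design.labels].copy()
        matrix.index = pd.Index(table.unique_id, name="id")
        ann = pd.DataFrame(
            {
                "gene_name": table.gene_names,
                "protein_ids": table.protein_ids,
            },
            index=matrix.index,
        )
        return cls(matrix=matrix, design=design, annotations=ann, stage="raw")

    def _subset(self, keep: pd.Series) -> "ExpressionDataset":
        return replace(
            self,
            matrix=self.matrix.loc[keep],
            annotations=self.annotations.loc[keep],
        )


def remove_flagged_rows(table: ProteinGroupsTable) -> ProteinGroupsTable:
    """Drop reverse decoys, potential contaminants and site-only identifications."""
    f = table.flags
    for key in ("reverse", "contaminant", "only_by_site"):
        log.info("removing %d rows flagged %s", int(f[key].sum()), key)
    bad = f.any(axis=1)
    if bad.all():
        log.warning("all %d rows carried a removal flag; table is now empty", len(table))
    return table.subset((~bad).tolist())


def detection_keep_mask(
    detected: pd.DataFrame, design: ExperimentDesign, thr: int
) -> pd.Series:
    """Keep-rule: exists condition c with (#detected in c) >= n_c - thr."""
    keep = pd.Series(False, index=detected.index)
    for cond, n_c in design.replicate_counts().items():
        cols = design.samples_of(cond)
        keep |= detected[cols].sum(axis=1) >= (n_c - thr)
    return keep


def filter_missing(ds: ExpressionDataset, thr: int = 0) -> ExpressionDataset:
    """Apply the per-condition detection threshold filter.

    ``thr`` must be smaller than the smallest replicate count, otherwise the
    rule degenerates to "any detection anywhere" and is rejected.
    """
    if thr < 0:
        raise ValidationError("threshold must be nonnegative")
    min_reps = min(ds.design.replicate_counts().values())
    if thr >= min_reps:
        raise ValidationError(
            f"threshold {thr} >= smallest replicate count {min_reps}; "
            "the filter would be vacuous"
        )
    keep = detection_keep_mask(ds.matrix.notna(), ds.design, thr)
    out = ds._subset(keep)
    out.stage = "filtered"
    out.threshold_used = thr
    log.info("missing-value filter thr=%d kept %d/%d proteins", thr, keep.sum(), len(keep))
    return out


def log2_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Entrywise log2; missing entries stay missing."""
    if ((ds.matrix <= 0).any().any()):
        raise ValidationError("log2 transform requires positive intensities")
    return replace(ds, matrix=np.log2(ds.matrix))


def normalize_median(ds: ExpressionDataset) -> ExpressionDataset:
    """Shift each sample so its observed median equals the grand observed median.

    Optional (default off in the pipeline); a column with no observed values
    is left untouched with a warning.
    """
    grand = ds.matrix.stack().median()
    matrix = ds.matrix.copy()
    for col in matrix.columns:
        med = matrix[col].median()
        if np.isnan(med):
            log.warning("sample %s has no observed values; left unnormalized", col)
            continue
        matrix[col] = matrix[col] - med + grand
    return replace(ds, matrix=matrix, stage="normalized")


def impute_left_censored(
    ds: ExpressionDataset,
    seed: int,
    width: float = 0.3,
    downshift_quantile: float = 0.01,
) -> ExpressionDataset:
    """Fill missing entries from a down-shifted per-sample Gaussian.

    For sample s, missing values are drawn from Normal(mu_s, sigma) with
    mu_s the ``downshift_quantile`` quantile of s's observed log2 values and
    sigma = ``width`` x (median over proteins of the per-protein observed
    SD).  Observed entries are never touched; given a seed the result is
    bit-reproducible.
    """
    if not (0 < downshift_quantile < 1):
        raise ValidationError("downshift_quantile must lie in (0, 1)")
    if width <= 0:
        raise ValidationError("width must be positive")
    matrix = ds.matrix.copy()
    n_obs = matrix.notna().sum(axis=0)
    starved = n_obs[n_obs < 2]
    if len(starved):
        raise ValidationError(
            f"samples with < 2 observed values, censoring distribution "
            f"not estimable: {list(starved.index)}"
        )
    if not matrix.isna().any().any():
        return replace(ds, stage="imputed", seed_used=seed)
    row_sd = matrix.std(axis=1, ddof=1)
    sigma = width * float(row_sd.median())
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValidationError("cannot estimate imputation width from observed values")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for col in matrix.columns:
        mask = matrix[col].isna()
        if not mask.any():
            continue
        mu = float(matrix[col].quantile(downshift_quantile))
        matrix.loc[mask, col] = rng.normal(mu, sigma, size=int(mask.sum()))
    return replace(ds, matrix=matrix, stage="imputed", seed_used=seed)


def filtered_protein_count(
    pg_path: str, design_path: str, threshold: int = 0
) -> int:
    """Proteins surviving flag removal + the detection filter for a dataset.

    The headline quality-control number of a run: parse the MaxQuant file,
    drop decoy/contaminant/site-only rows, and count proteins detected in
    enough replicates of at least one condition.
    """
    from .maxquant_io import parse_design, parse_protein_groups

    table = parse_protein_groups(pg_path)
    design = parse_design(design_path, table)
    clean = remove_flagged_rows(table)
    ds = ExpressionDataset.from_table(clean, design)
    return len(filter_missing(ds, threshold).matrix)


def preprocess_pipeline(
    table: ProteinGroupsTable,
    design: ExperimentDesign,
    threshold: int = 0,
    seed: int = 0,
    normalize: bool = False,
    width: float = 0.3,
    downshift_quantile: float = 0.01,
) -> ExpressionDataset:
    """Flag removal -> filter -> log2 -> (optional median normalization) -> impute."""
    clean = remove_flagged_rows(table)
    ds = ExpressionDataset.from_table(clean, design)
    ds = filter_missing(ds, threshold)
    ds = log2_transform(ds)
    if normalize:
        ds = normalize_median(ds)
    return impute_left_censored(
        ds, seed=seed, width=width, downshift_quantile=downshift_quantile
    )
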